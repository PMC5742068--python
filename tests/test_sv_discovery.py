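"""CNV / indel / inversion / SNP calling and copy-number verification."""
import numpy as np
import pytest

from svmap._seq import random_seq, revcomp
from svmap.alignment_core import BaseAlignment, SyntenyBlock, cluster_matches, find_mems
from svmap.io import SequenceRecord
from svmap.pipeline import call_svs
from svmap.sv_discovery import (
    RepeatAnnotation,
    SvCall,
    annotate_te_status,
    call_duplications,
    call_indels,
    call_inversions,
    call_snps_small_indels,
    merge_complex_events,
    normalize_indel,
    verify_copy_number,
)

RNG = np.random.default_rng(991)


def _clusters(ref, qry, **kw):
    r = SequenceRecord("ref", ref)
    q = SequenceRecord("qry", qry)
    ms = find_mems(r, q, min_len=kw.pop("min_len", 20))
    return cluster_matches(ms, {"qry": len(qry)}), r, q


class TestCallDuplications:
    def test_exact_tandem_duplication_recovered(self):
        g = random_seq(RNG, 30_000, 0.45)
        qry = g[:12_000] + g[10_000:12_000] + g[12_000:]
        clusters, *_ = _clusters(g, qry)
        calls = call_duplications(clusters, [], min_len=100)
        assert any(
            c.sv_type == "CNV_GAIN_QRY"
            and abs(c.ref_start - 10_000) <= 20
            and abs(c.ref_end - 12_000) <= 20
            for c in calls
        )

    def test_identical_genomes_yield_no_calls(self):
        g = random_seq(RNG, 20_000, 0.45)
        clusters, *_ = _clusters(g, g)
        assert call_duplications(clusters, [], min_len=100) == []

    def test_spacered_duplication_records_spacer(self):
        # the Cyp28d1-like geometry: copies separated by a 1.5-kb fragment
        g = random_seq(RNG, 30_000, 0.45)
        spacer = random_seq(RNG, 1_500, 0.45)
        qry = g[:12_000] + spacer + g[10_000:12_000] + g[12_000:]
        clusters, *_ = _clusters(g, qry)
        calls = call_duplications(clusters, [], min_len=100)
        hit = [
            c for c in calls
            if c.sv_type == "CNV_GAIN_QRY" and abs(c.ref_start - 10_000) <= 20
        ]
        assert hit and hit[0].spacer is not None
        s0, s1 = hit[0].spacer
        assert abs((s1 - s0) - 1_500) <= 40

    def test_swapped_run_yields_loss_calls(self):
        # duplication in the reference genome = loss in the query; the
        # swapped run anchors the single-copy query genome as reference
        g = random_seq(RNG, 30_000, 0.45)
        ref_with_dup = g[:12_000] + g[10_000:12_000] + g[12_000:]
        clusters_rev, *_ = _clusters(g, ref_with_dup, min_len=20)
        calls = call_duplications([], clusters_rev, min_len=100)
        loss = [c for c in calls if c.sv_type == "CNV_LOSS_QRY"]
        assert loss and abs(loss[0].qry_start - 10_000) <= 20


class TestVerifyCopyNumber:
    def test_single_copy_in_both_genomes_rejected(self):
        g = random_seq(RNG, 15_000, 0.45)
        cand = g[5_000:5_400]
        rep = verify_copy_number(cand, [SequenceRecord("a", g)],
                                 [SequenceRecord("b", g)])
        assert (rep.copies_ref, rep.copies_qry) == (1, 1)
        assert rep.is_false_positive

    def test_one_vs_two_copies_accepted(self):
        g = random_seq(RNG, 15_000, 0.45)
        qry = g[:6_000] + g[5_000:6_000] + g[6_000:]
        cand = g[5_000:6_000]
        rep = verify_copy_number(cand, [SequenceRecord("a", g)],
                                 [SequenceRecord("b", qry)])
        assert (rep.copies_ref, rep.copies_qry) == (1, 2)
        assert not rep.is_false_positive

    def test_interrupted_copy_still_counts(self):
        # 5-kb insertion inside the second copy is below qco = 10 kb
        g = random_seq(RNG, 15_000, 0.45)
        cand = g[5_000:6_000]
        broken = cand[:500] + random_seq(RNG, 5_000, 0.45) + cand[500:]
        qry = g[:8_000] + broken + g[8_000:]
        rep = verify_copy_number(cand, [SequenceRecord("a", g)],
                                 [SequenceRecord("b", qry)])
        assert (rep.copies_ref, rep.copies_qry) == (1, 2)

    def test_absent_candidate_warns(self):
        g = random_seq(RNG, 2_000, 0.45)
        cand = random_seq(RNG, 300, 0.45)
        with pytest.warns(UserWarning):
            rep = verify_copy_number(cand, [SequenceRecord("a", g)],
                                     [SequenceRecord("b", g)])
        assert (rep.copies_ref, rep.copies_qry) == (0, 0)

    def test_short_candidate_rejected(self):
        with pytest.raises(ValueError):
            verify_copy_number("ACGT" * 10, [], [])


def _block(rs, re_, qs, qe, strand="+", w=None):
    return SyntenyBlock(
        BaseAlignment("ref", "qry", strand, rs, re_, qs, qe, [],
                      w if w is not None else (re_ - rs))
    )


class TestCallIndels:
    def test_insertion_from_query_gap(self):
        blocks = [_block(0, 5_000, 0, 5_000), _block(5_000, 9_000, 5_500, 9_500)]
        (call,) = call_indels(blocks)
        assert call.sv_type == "INS_QRY" and call.length == 500

    def test_gap_below_threshold_not_called(self):
        blocks = [_block(0, 5_000, 0, 5_000), _block(5_000, 9_000, 5_080, 9_080)]
        assert call_indels(blocks) == []

    def test_reciprocal_gap_flags_divergent_region(self):
        blocks = [_block(0, 5_000, 0, 5_000), _block(5_400, 9_000, 5_500, 9_100)]
        calls, divergent = call_indels(blocks, return_divergent=True)
        assert calls == [] and divergent == [("ref", 5_000, 5_400)]

    def test_deletion_from_reference_gap(self):
        blocks = [_block(0, 5_000, 0, 5_000), _block(5_700, 9_000, 5_010, 8_310)]
        (call,) = call_indels(blocks)
        assert call.sv_type == "DEL_QRY" and call.length == 700


class TestCallInversions:
    def test_reversed_block_between_forward_flanks(self):
        blocks = [
            _block(0, 5_000, 0, 5_000),
            _block(5_000, 7_000, 5_000, 7_000, strand="-"),
            _block(7_000, 12_000, 7_000, 12_000),
        ]
        (call,) = call_inversions(blocks)
        assert call.sv_type == "INV" and call.length == 2_000

    def test_no_reverse_blocks_no_calls(self):
        blocks = [_block(0, 5_000, 0, 5_000), _block(5_000, 9_000, 5_000, 9_000)]
        assert call_inversions(blocks) == []

    def test_te_covered_inversion_removed(self):
        repeats = RepeatAnnotation({"ref": [(5_000, 7_000, "roo")]})
        blocks = [
            _block(0, 5_000, 0, 5_000),
            _block(5_000, 7_000, 5_000, 7_000, strand="-"),
            _block(7_000, 12_000, 7_000, 12_000),
        ]
        assert call_inversions(blocks, repeats) == []


class TestSmallVariants:
    def _call(self, ref, qry):
        from svmap.pipeline import build_synteny_blocks

        r, q = SequenceRecord("ref", ref), SequenceRecord("qry", qry)
        ms = find_mems(r, q, min_len=20)
        blocks = build_synteny_blocks([r], [q], cluster_matches(ms, {"qry": len(qry)}))
        return call_snps_small_indels(blocks, {"ref": r}, {"qry": q})

    def test_identical_genomes_no_variants(self):
        g = random_seq(RNG, 10_000, 0.45)
        assert self._call(g, g) == []

    def test_implanted_snps_and_small_indels_recovered_exactly(self):
        rng = np.random.default_rng(3)
        g = random_seq(rng, 20_000, 0.45)
        positions = sorted(rng.choice(np.arange(1_000, 19_000, 120), size=13,
                                      replace=False))
        snp_pos, ins_pos, del_pos = positions[:10], positions[10:12], positions[12:]
        qry, truth, shift = g, [], 0
        edits = [("SNP", p) for p in snp_pos] + [("INS", p) for p in ins_pos] + [
            ("DEL", p) for p in del_pos
        ]
        for kind, p in sorted(edits, key=lambda e: e[1]):
            dp = p + shift
            if kind == "SNP":
                alt = "A" if qry[dp] != "A" else "G"
                truth.append(("SNP", p, g[p], alt))
                qry = qry[:dp] + alt + qry[dp + 1 :]
            elif kind == "INS":
                payload = random_seq(rng, 8, 0.5)
                np_, npay = normalize_indel(g, p, payload)
                truth.append(("INS", np_, "", npay))
                qry = qry[:dp] + payload + qry[dp:]
                shift += 8
            else:
                np_, npay = normalize_indel(g, p, g[p : p + 12])
                truth.append(("DEL", np_, npay, ""))
                qry = qry[:dp] + qry[dp + 12 :]
                shift -= 12
        got = {
            (v.kind, v.ref_pos, v.ref_allele, v.qry_allele) for v in self._call(g, qry)
        }
        assert got == set(truth)

    def test_large_deletion_absent_from_small_variants(self):
        g = random_seq(RNG, 12_000, 0.45)
        qry = g[:6_000] + g[6_150:]  # 150-bp deletion
        variants = self._call(g, qry)
        assert all(v.length < 100 for v in variants)
        assert not any(v.kind == "DEL" and abs(v.ref_pos - 6_000) < 200
                       for v in variants)


class TestMergeAndAnnotate:
    def _cnv(self, start, end, te="non-TE"):
        return SvCall("CNV_GAIN_QRY", "ref", start, end, "qry", start, end,
                      end - start, te_status=te)

    def test_nearby_cnvs_merge_into_complex_event(self):
        cat = merge_complex_events([self._cnv(0, 1_000), self._cnv(2_500, 3_000)])
        assert cat.counts["CNV_GAIN_QRY"] == 1
        assert cat.affected_bp["CNV_GAIN_QRY"] == 1_500  # from unmerged calls

    def test_distant_cnvs_stay_separate(self):
        cat = merge_complex_events([self._cnv(0, 1_000), self._cnv(3_500, 4_000)])
        assert cat.counts["CNV_GAIN_QRY"] == 2

    def test_single_call_unchanged(self):
        cat = merge_complex_events([self._cnv(0, 1_000)])
        assert len(cat.calls) == 1 and cat.calls[0].length == 1_000

    @pytest.mark.parametrize(
        "covered,expected", [(0, "non-TE"), (900, "TE"), (800, "TE"), (799, "non-TE")]
    )
    def test_te_annotation_boundary_inclusive(self, covered, expected):
        call = SvCall("DEL_QRY", "ref", 0, 1_000, "qry", 0, 0, 1_000)
        repeats = RepeatAnnotation({"ref": [(0, covered, "roo")]} if covered else {})
        assert annotate_te_status(call, repeats).te_status == expected

    def test_missing_annotation_defaults_to_non_te(self):
        call = SvCall("INS_QRY", "ref", 0, 0, "qry", 0, 500, 500)
        assert annotate_te_status(call, None).te_status == "non-TE"


class TestNormalizeIndel:
    def test_left_shift_in_homopolymer(self):
        #  deletion of one A from 'CAAAT': canonical position is first A
        assert normalize_indel("CAAAT", 3, "A") == (1, "A")

    def test_no_shift_when_context_differs(self):
        assert normalize_indel("CGTAT", 3, "C") == (3, "C")


class TestEndToEndSmall:
    def test_all_variant_classes_recovered(self, small_sim):
        s = small_sim
        catalog = call_svs(
            [s["ancestral"]], [s["derived"]],
            repeats_ref=RepeatAnnotation(s["repeats"]),
            repeats_qry=RepeatAnnotation(s["derived_repeats"]),
        )
        kind_types = {
            "TE_INS": ("INS_QRY",), "NONTE_INS": ("INS_QRY",),
            "DEL": ("DEL_QRY",), "DUP": ("CNV_GAIN_QRY",), "INV": ("INV",),
        }
        for kind, types in kind_types.items():
            truth = [t for t in s["truth"] if t.kind == kind]
            hits = sum(
                any(
                    c.sv_type in types
                    and abs(c.ref_start - t.anc_start) <= 20
                    and abs(c.ref_end - t.anc_end) <= 20
                    for c in catalog.calls
                )
                for t in truth
            )
            assert hits == len(truth), f"{kind}: {hits}/{len(truth)}"

    def test_symmetry_of_polarity_under_genome_swap(self, small_sim):
        s = small_sim
        fwd = call_svs([s["ancestral"]], [s["derived"]],
                       repeats_ref=RepeatAnnotation(s["repeats"]),
                       repeats_qry=RepeatAnnotation(s["derived_repeats"]))
        rev = call_svs([s["derived"]], [s["ancestral"]],
                       repeats_ref=RepeatAnnotation(s["derived_repeats"]),
                       repeats_qry=RepeatAnnotation(s["repeats"]))
        def n(cat, t):
            return sum(1 for c in cat.calls if c.sv_type == t)
        assert n(fwd, "INS_QRY") == n(rev, "DEL_QRY")
        assert n(fwd, "DEL_QRY") == n(rev, "INS_QRY")
        assert n(fwd, "INV") == n(rev, "INV")

    def test_no_sv_call_shorter_than_threshold(self, small_sim):
        s = small_sim
        catalog = call_svs([s["ancestral"]], [s["derived"]],
                           repeats_ref=RepeatAnnotation(s["repeats"]),
                           repeats_qry=RepeatAnnotation(s["derived_repeats"]))
        assert all(c.length >= 100 for c in catalog.calls)
        assert all(v.length < 100 for v in catalog.small_variants)
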