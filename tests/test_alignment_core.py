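"""Anchoring, chaining, base-level filling, and one-to-one filtering."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svmap._seq import random_seq, revcomp
from svmap.alignment_core import (
    Match,
    affine_global_align,
    cluster_matches,
    fill_cluster_alignment,
    filter_mutual_best,
    find_mems,
    merge_collinear_clusters,
    score_ops,
)
from svmap.io import SequenceRecord

from .oracles import brute_force_max_weight_consistent, brute_force_mems

RNG = np.random.default_rng(20240317)


def _mutated_copy(rng, seq, snp=0.03, indel=0.01):
    out = []
    for ch in seq:
        r = rng.random()
        if r < indel / 2:
            continue  # deletion
        if r < indel:
            out.append("ACGT"[rng.integers(4)])  # insertion
        if rng.random() < snp:
            out.append("ACGT"[(("ACGT".index(ch)) + 1 + rng.integers(3)) % 4])
        else:
            out.append(ch)
    return "".join(out) or "A"


class TestFindMems:
    def test_identity(self):
        ms = find_mems(
            SequenceRecord("r", "AGCT"), SequenceRecord("q", "AGCT"),
            min_len=4, both_strands=False,
        )
        assert ms == [Match("r", 0, "q", 0, 4, "+")]

    def test_reverse_complement_symmetry(self):
        s = random_seq(RNG, 200, 0.5)
        ms = find_mems(
            SequenceRecord("r", s), SequenceRecord("q", revcomp(s)), min_len=20
        )
        minus = [m for m in ms if m.strand == "-"]
        assert any(m.ref_start == 0 and m.length == 200 for m in minus)

    @pytest.mark.parametrize("min_len", [5, 10])
    def test_matches_brute_force_enumeration(self, min_len):
        """Exact agreement with direct substring scanning on random pairs."""
        rng = np.random.default_rng(100 + min_len)
        for trial in range(50):
            n = int(rng.integers(40, 201))
            ref = random_seq(rng, n, 0.5)
            if trial % 3 == 0:
                qry = random_seq(rng, int(rng.integers(40, 201)), 0.5)
            else:
                qry = _mutated_copy(rng, ref)
            if trial % 7 == 0:  # exercise the N-never-matches rule
                pos = int(rng.integers(len(qry)))
                qry = qry[:pos] + "N" + qry[pos + 1 :]
            got = {
                (m.ref_start, m.qry_start, m.length)
                for m in find_mems(
                    SequenceRecord("r", ref), SequenceRecord("q", qry),
                    min_len=min_len, both_strands=False,
                )
            }
            expect = brute_force_mems(ref, qry, min_len)
            assert got == expect

    def test_both_strands_is_union_of_strandwise_runs(self):
        rng = np.random.default_rng(5)
        ref = random_seq(rng, 300, 0.5)
        qry = _mutated_copy(rng, ref)[:150] + revcomp(ref[200:])
        r, q = SequenceRecord("r", ref), SequenceRecord("q", qry)
        both = find_mems(r, q, min_len=15, both_strands=True)
        plus = find_mems(r, q, min_len=15, both_strands=False)
        rc = find_mems(r, SequenceRecord("q", revcomp(qry)), min_len=15,
                       both_strands=False)
        expected = {(m.ref_start, m.qry_start, m.length, "+") for m in plus} | {
            (m.ref_start, m.qry_start, m.length, "-") for m in rc
        }
        assert {(m.ref_start, m.qry_start, m.length, m.strand) for m in both} == expected

    def test_rejects_non_nucleotide_input(self):
        with pytest.raises(ValueError):
            SequenceRecord("r", "ACGTX")

    def test_masked_positions_do_not_anchor(self):
        s = random_seq(RNG, 120, 0.5)
        rec = SequenceRecord("r", s)
        rec.masked = np.ones(len(s), dtype=bool)
        assert find_mems(rec, SequenceRecord("q", s), min_len=20) == []


def _mk_match(ref_start, qry_start, length):
    return Match("r", ref_start, "q", qry_start, length, "+")


class TestClusterMatches:
    QL = {"q": 100_000}

    def test_chains_within_separation_and_drift(self):
        # 150-bp matches, 50-bp separation, 5-bp drift: 5 <= 0.12 * 50
        ms = [_mk_match(0, 0, 150), _mk_match(200, 205, 150)]
        cl = cluster_matches(ms, self.QL)
        assert len(cl) == 1 and cl[0].total_match_len == 300

    def test_splits_beyond_separation(self):
        ms = [_mk_match(0, 0, 150), _mk_match(400, 400, 150)]
        cl = cluster_matches(ms, self.QL)
        assert len(cl) == 2

    def test_splits_beyond_drift(self):
        ms = [_mk_match(0, 0, 150), _mk_match(200, 240, 150)]  # drift 40 > 6
        cl = cluster_matches(ms, self.QL)
        assert len(cl) == 2

    def test_min_cluster_length_threshold(self):
        assert len(cluster_matches([_mk_match(0, 0, 120)], self.QL)) == 1
        assert cluster_matches([_mk_match(0, 0, 80)], self.QL) == []

    def test_matches_kept_verbatim(self):
        ms = [_mk_match(0, 3, 150), _mk_match(180, 185, 200)]
        (cl,) = cluster_matches(ms, self.QL)
        assert cl.matches == sorted(ms)

    def test_empty_input(self):
        assert cluster_matches([], self.QL) == []


def _aligned_pair(rng, max_len=500):
    n = int(rng.integers(100, max_len + 1))
    ref = random_seq(rng, n, 0.45)
    qry = _mutated_copy(rng, ref, snp=0.02, indel=0.005)
    return ref, qry


class TestFillClusterAlignment:
    def _cluster(self, ref, qry, min_len=12):
        r, q = SequenceRecord("r", ref), SequenceRecord("q", qry)
        ms = find_mems(r, q, min_len=min_len, both_strands=False)
        cl = merge_collinear_clusters(
            cluster_matches(ms, {"q": len(qry)}, l=40), join_gap=200
        )
        assert cl, "no cluster formed"
        return max(cl, key=lambda c: c.total_match_len), r, q

    def test_identical_intervals_align_gap_free(self):
        s = random_seq(RNG, 1000, 0.5)
        c, r, q = self._cluster(s, s, min_len=20)
        aln = fill_cluster_alignment(c, r, q)
        assert aln.ops == [("=", 1000)]

    def test_single_substitution_yields_one_mismatch_column(self):
        s = random_seq(RNG, 600, 0.5)
        alt = "A" if s[300] != "A" else "C"
        q = s[:300] + alt + s[301:]
        c, rr, qq = self._cluster(s, q, min_len=20)
        aln = fill_cluster_alignment(c, rr, qq)
        assert sum(ln for op, ln in aln.ops if op == "X") == 1
        assert sum(ln for op, ln in aln.ops if op in "ID") == 0

    def test_score_matches_unconstrained_dp_oracle(self):
        """Spot-check agreement; the full 50-pair sweep runs in acceptance."""
        from .oracles import full_dp_affine_score

        rng = np.random.default_rng(42)
        for _ in range(8):
            ref, qry = _aligned_pair(rng, max_len=300)
            c, r, q = self._cluster(ref, qry)
            aln = fill_cluster_alignment(c, r, q)
            expect = full_dp_affine_score(
                ref[c.ref_start : c.ref_end], qry[c.qry_start : c.qry_end]
            )
            assert aln.score == pytest.approx(expect)

    def test_piecewise_path_reproduces_full_dp_score(self):
        rng = np.random.default_rng(43)
        ref, qry = _aligned_pair(rng, max_len=400)
        c, r, q = self._cluster(ref, qry)
        full = fill_cluster_alignment(c, r, q)
        piecewise = fill_cluster_alignment(c, r, q, dp_limit=10)
        assert piecewise.score == pytest.approx(full.score)

    def test_round_trip_projection(self):
        rng = np.random.default_rng(44)
        ref, qry = _aligned_pair(rng)
        c, r, q = self._cluster(ref, qry)
        aln = fill_cluster_alignment(c, r, q)
        rcons, qcons = aln.consumed()
        assert rcons == c.ref_end - c.ref_start
        assert qcons == c.qry_end - c.qry_start
        # rebuild the query interval from the reference plus the ops
        rpos, qpos, rebuilt = c.ref_start, c.qry_start, []
        for op, ln in aln.ops:
            if op in "=X":
                rebuilt.append(qry[qpos : qpos + ln])
                rpos += ln
                qpos += ln
            elif op == "I":
                rebuilt.append(qry[qpos : qpos + ln])
                qpos += ln
            else:
                rpos += ln
        assert "".join(rebuilt) == qry[c.qry_start : c.qry_end]

    def test_score_ops_consistent_with_dp(self):
        sc, ops = affine_global_align("ACGTACGTAA", "ACGTCGTAA")
        assert sc == pytest.approx(score_ops(ops))


class _Stub:
    def __init__(self, rs, re_, qs, qe, w, ref_name="r", qry_name="q"):
        self.ref_name, self.qry_name = ref_name, qry_name
        self.ref_start, self.ref_end = rs, re_
        self.qry_start, self.qry_end = qs, qe
        self.weight = w


class TestFilterMutualBest:
    def test_non_overlapping_unchanged(self):
        blocks = [_Stub(0, 100, 0, 100, 100), _Stub(200, 300, 200, 300, 100)]
        assert filter_mutual_best(blocks) == sorted(
            blocks, key=lambda b: b.ref_start
        )

    def test_heavier_block_wins_shared_interval(self):
        a = _Stub(0, 500, 0, 500, 500)
        b = _Stub(100, 400, 1000, 1300, 300)
        assert filter_mutual_best([a, b]) == [a]

    def test_empty_input(self):
        assert filter_mutual_best([]) == []

    @pytest.mark.parametrize("mode", ["one-to-one", "query"])
    def test_matches_subset_enumeration_oracle(self, mode):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            blocks = []
            for _ in range(n):
                rs = int(rng.integers(0, 800))
                qs = int(rng.integers(0, 800))
                ln = int(rng.integers(50, 400))
                blocks.append(_Stub(rs, rs + ln, qs, qs + ln, ln))
            kept = filter_mutual_best(blocks, mode=mode)
            got = sum(b.weight for b in kept)
            expect = brute_force_max_weight_consistent(
                [(b.ref_start, b.ref_end, b.qry_start, b.qry_end, b.weight)
                 for b in blocks],
                mode=mode,
            )
            assert got == pytest.approx(expect)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mem_set_invariant_under_seed(seed):
    """MEMs of a sequence against itself always include the full diagonal."""
    rng = np.random.default_rng(seed)
    s = random_seq(rng, int(rng.integers(30, 120)), 0.5)
    ms = find_mems(
        SequenceRecord("r", s), SequenceRecord("q", s),
        min_len=len(s), both_strands=False, unique_in_ref=False,
    )
    assert Match("r", 0, "q", 0, len(s), "+") in ms
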