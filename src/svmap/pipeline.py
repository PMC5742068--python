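"""End-to-end assembly-vs-assembly SV calling.

Orchestrates: MEM anchoring (both genome orderings), chaining, collinear
cluster joining, weight-ordered one-to-one resolution with anchor
trimming, base-level filling, and the individual callers. The result is
an SvCatalog with CNVs, indels, inversions, SNPs and small indels.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass

from .alignment_core import (
    Cluster,
    Match,
    SyntenyBlock,
    cluster_matches,
    fill_cluster_alignment,
    find_mems,
    merge_collinear_clusters,
)
from .io import SequenceRecord
from .sv_discovery import (
    RepeatAnnotation,
    SvCall,
    SvCatalog,
    annotate_te_status,
    call_duplications,
    call_indels,
    call_inversions,
    call_snps_small_indels,
    merge_complex_events,
    verify_copy_number,
)


class _Claims:
    """Sorted claimed intervals per sequence, with prefix/suffix coverage."""

    def __init__(self):
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def add(self, name: str, start: int, end: int) -> None:
        if end > start:
            bisect.insort(self._iv.setdefault(name, []), (start, end))

    def covered_prefix(self, name: str, start: int, end: int) -> int:
        """Length of the claimed run extending from ``start``."""
        cur = start
        for a, b in self._iv.get(name, []):
            if a > cur:
                break
            cur = max(cur, b)
        return min(cur, end) - start

    def covered_suffix(self, name: str, start: int, end: int) -> int:
        cur = end
        for a, b in reversed(self._iv.get(name, [])):
            if b < cur:
                break
            cur = min(cur, a)
        return end - max(cur, start)

    def overlaps(self, name: str, start: int, end: int) -> bool:
        for a, b in self._iv.get(name, []):
            if a >= end:
                break
            if b > start:
                return True
        return False


def _trim_amount(claims_r: _Claims, claims_q: _Claims, m: Match, qry_len: int,
                 side: str) -> int:
    """Claimed run length at the chain-start or chain-end side of a match."""
    qf_start, qf_end = m.qry_fwd_interval(qry_len)
    if side == "start":
        p_ref = claims_r.covered_prefix(m.ref_name, m.ref_start, m.ref_end)
        if m.strand == "+":
            p_qry = claims_q.covered_prefix(m.qry_name, qf_start, qf_end)
        else:
            p_qry = claims_q.covered_suffix(m.qry_name, qf_start, qf_end)
    else:
        p_ref = claims_r.covered_suffix(m.ref_name, m.ref_start, m.ref_end)
        if m.strand == "+":
            p_qry = claims_q.covered_suffix(m.qry_name, qf_start, qf_end)
        else:
            p_qry = claims_q.covered_prefix(m.qry_name, qf_start, qf_end)
    return max(p_ref, p_qry)


def one_to_one_clusters(clusters: list[Cluster], min_total: int = 100) -> list[Cluster]:
    """Resolve clusters to one-to-one coverage by weight-ordered trimming.

    Heavier clusters claim their reference and query spans first;
    lighter clusters are trimmed at the ends (anchors are exact matches,
    so partial anchors stay valid) where they re-align already-claimed
    sequence — e.g. the extra copy of a tandem duplication. Clusters
    reduced below ``min_total`` matched bp are dropped.
    """
    order = sorted(
        clusters, key=lambda c: (-c.total_match_len, c.ref_name, c.ref_start)
    )
    claims_r, claims_q = _Claims(), _Claims()
    kept: list[Cluster] = []
    for c in order:
        anchors = list(c.matches)
        # leading trim
        while anchors:
            t = _trim_amount(claims_r, claims_q, anchors[0], c.qry_len, "start")
            if t <= 0:
                break
            m = anchors[0]
            if t >= m.length:
                anchors.pop(0)
            else:
                anchors[0] = Match(
                    m.ref_name, m.ref_start + t, m.qry_name,
                    m.qry_start + t, m.length - t, m.strand,
                )
                break
        # trailing trim
        while anchors:
            t = _trim_amount(claims_r, claims_q, anchors[-1], c.qry_len, "end")
            if t <= 0:
                break
            m = anchors[-1]
            if t >= m.length:
                anchors.pop()
            else:
                anchors[-1] = Match(
                    m.ref_name, m.ref_start, m.qry_name,
                    m.qry_start, m.length - t, m.strand,
                )
                break
        # interior anchors fully claimed elsewhere are dropped
        anchors = [
            m
            for m in anchors
            if not (
                claims_r.covered_prefix(m.ref_name, m.ref_start, m.ref_end)
                >= m.length
            )
        ]
        if not anchors or sum(m.length for m in anchors) < min_total:
            continue
        trimmed = Cluster(c.ref_name, c.qry_name, c.strand, anchors, c.qry_len)
        kept.append(trimmed)
        claims_r.add(trimmed.ref_name, trimmed.ref_start, trimmed.ref_end)
        claims_q.add(trimmed.qry_name, trimmed.qry_start, trimmed.qry_end)
    kept.sort(key=lambda c: (c.ref_name, c.ref_start, c.qry_name, c.qry_start))
    return kept


def build_synteny_blocks(
    ref_records: list[SequenceRecord],
    qry_records: list[SequenceRecord],
    clusters: list[Cluster],
    join_gap: int = 100,
    min_total: int = 100,
) -> list[SyntenyBlock]:
    """Collinear joining, one-to-one resolution, and base-level filling."""
    ref_index = {r.name: r for r in ref_records}
    qry_index = {r.name: r for r in qry_records}
    merged = merge_collinear_clusters(clusters, join_gap=join_gap)
    resolved = one_to_one_clusters(merged, min_total=min_total)
    blocks = []
    for c in resolved:
        aln = fill_cluster_alignment(c, ref_index[c.ref_name], qry_index[c.qry_name])
        blocks.append(SyntenyBlock(aln))
    return blocks


def _large_indels_within_blocks(blocks, min_len: int) -> list[SvCall]:
    """In-block gap runs >= min_len surface as SV-scale indels."""
    out: list[SvCall] = []
    for b in blocks:
        if b.strand != "+":
            continue
        rpos, qpos = b.ref_start, b.qry_start
        for op, ln in b.ops:
            if op in "=X":
                rpos += ln
                qpos += ln
            elif op == "I":
                if ln >= min_len:
                    out.append(
                        SvCall("INS_QRY", b.ref_name, rpos, rpos, b.qry_name,
                               qpos, qpos + ln, ln, evidence=[b])
                    )
                qpos += ln
            elif op == "D":
                if ln >= min_len:
                    out.append(
                        SvCall("DEL_QRY", b.ref_name, rpos, rpos + ln, b.qry_name,
                               qpos, qpos, ln, evidence=[b])
                    )
                rpos += ln
    return out


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return min(a_end, b_end) > max(a_start, b_start)


def call_svs(
    ref_records: list[SequenceRecord],
    qry_records: list[SequenceRecord],
    repeats_ref: RepeatAnnotation | None = None,
    repeats_qry: RepeatAnnotation | None = None,
    min_match: int = 20,
    cluster_s: int = 200,
    cluster_f: float = 0.12,
    cluster_l: int = 100,
    min_sv: int = 100,
    reciprocal_frac: float = 0.10,
    merge_dist: int = 2000,
    te_frac: float = 0.8,
    verify: bool = True,
    regions: RepeatAnnotation | None = None,
) -> SvCatalog:
    """Full SV discovery between two assemblies. Returns an SvCatalog."""
    ref_index = {r.name: r for r in ref_records}
    qry_index = {r.name: r for r in qry_records}
    ref_lengths = {r.name: len(r) for r in ref_records}
    qry_lengths = {r.name: len(r) for r in qry_records}

    mems_fwd = find_mems(ref_records, qry_records, min_len=min_match)
    clusters_fwd = cluster_matches(
        mems_fwd, qry_lengths, s=cluster_s, f=cluster_f, l=cluster_l
    )
    mems_rev = find_mems(qry_records, ref_records, min_len=min_match)
    clusters_rev = cluster_matches(
        mems_rev, ref_lengths, s=cluster_s, f=cluster_f, l=cluster_l
    )

    cnv_calls = call_duplications(clusters_fwd, clusters_rev, min_len=min_sv)
    if verify:
        verified = []
        for i, call in enumerate(cnv_calls):
            if call.sv_type == "CNV_GAIN_QRY":
                seq = ref_index[call.ref_name].seq[call.ref_start : call.ref_end]
            else:
                seq = qry_index[call.qry_name].seq[call.qry_start : call.qry_end]
            if len(seq) < min_sv:
                continue
            report = verify_copy_number(
                seq, ref_records, qry_records, candidate_id=f"cnv_{i}"
            )
            call.copy_report = report
            if not report.is_false_positive:
                verified.append(call)
        cnv_calls = verified
    if repeats_ref is not None:
        # repeat-masked CNV filtering: copy-number changes of TE/repeat
        # sequence are dispersed-repeat turnover, not locus duplications
        def _te_cnv(c) -> bool:
            if c.sv_type == "CNV_GAIN_QRY":  # duplicated unit lives on the ref axis
                ivs = [(c.ref_start, c.ref_end)]
            else:  # retained copies of a query-side loss live on the ref axis
                ivs = c.copies or [(c.ref_start, c.ref_end)]
            return all(
                repeats_ref.coverage_fraction(c.ref_name, s, e) >= te_frac
                for s, e in ivs
            )

        cnv_calls = [c for c in cnv_calls if not _te_cnv(c)]

    blocks = build_synteny_blocks(
        ref_records, qry_records, clusters_fwd,
        join_gap=min_sv, min_total=cluster_l,
    )
    inv_calls = call_inversions(blocks, repeats_ref, min_len=min_sv, te_frac=te_frac)
    indel_calls = call_indels(blocks, min_len=min_sv, reciprocal_frac=reciprocal_frac)
    indel_calls.extend(_large_indels_within_blocks(blocks, min_sv))

    def _suppressed(call: SvCall) -> bool:
        for cnv in cnv_calls:
            if cnv.qry_name == call.qry_name and _overlaps(
                cnv.qry_start, cnv.qry_end, call.qry_start, call.qry_end
            ):
                return True
            # losses carry dispersed per-copy intervals on the ref axis
            ref_ivs = (
                cnv.copies
                if cnv.sv_type == "CNV_LOSS_QRY" and cnv.copies
                else [(cnv.ref_start, cnv.ref_end)]
            )
            if cnv.ref_name == call.ref_name and any(
                _overlaps(s, e, call.ref_start, call.ref_end) for s, e in ref_ivs
            ):
                return True
        for inv in inv_calls:
            if inv.ref_name == call.ref_name and _overlaps(
                inv.ref_start, inv.ref_end, call.ref_start, call.ref_end
            ):
                return True
        return False

    indel_calls = [c for c in indel_calls if not _suppressed(c)]

    from .sv_discovery import call_junction_small_variants, collinear_backbone

    small = call_snps_small_indels(
        collinear_backbone(blocks), ref_index, qry_index, max_indel=min_sv
    )
    small.extend(
        call_junction_small_variants(blocks, ref_index, qry_index, max_indel=min_sv)
    )
    small.sort(key=lambda v: (v.ref_name, v.ref_pos, v.kind))

    calls = cnv_calls + indel_calls + inv_calls
    for call in calls:
        ann = repeats_qry if call.sv_type == "INS_QRY" else repeats_ref
        annotate_te_status(call, ann, te_frac)

    if regions is not None:
        calls = [
            c for c in calls
            if regions.covered_bp(c.ref_name, c.ref_start, max(c.ref_end, c.ref_start + 1)) > 0
        ]
        small = [
            v for v in small
            if regions.covered_bp(v.ref_name, v.ref_pos, v.ref_pos + 1) > 0
        ]

    return merge_complex_events(calls, d=merge_dist, small_variants=small)
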