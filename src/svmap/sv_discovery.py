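"""Structural-variant discovery from whole-genome alignment.

Alignment disagreements between two assemblies are classified into copy
number variants (from overlapping anchor clusters), insertions and
deletions (from inter-block gaps), inversions (reverse-orientation
blocks), and SNPs/small indels (per-column calls inside one-to-one
synteny blocks). Candidate duplications are re-verified by aligning the
putatively duplicated sequence back to both genomes and counting copies.
"""
from __future__ import annotations

import bisect
import itertools
import logging
import warnings
from dataclasses import dataclass, field

from .alignment_core import (
    BaseAlignment,
    Cluster,
    SyntenyBlock,
    cluster_matches,
    fill_cluster_alignment,
    find_mems,
    merge_collinear_clusters,
)
from .io import SequenceRecord

logger = logging.getLogger(__name__)

MIN_SV_LEN = 100  # SvCall records are >= 100 bp; smaller events are SmallVariants


class RepeatAnnotation:
    """Per-sequence repeat/TE intervals with coverage queries."""

    def __init__(self, intervals: dict[str, list[tuple[int, int, str]]] | None = None):
        self._iv: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for name, ivs in intervals.items():
                for iv in ivs:
                    self.add(name, iv[0], iv[1])
        self._merge_all()

    def add(self, name: str, start: int, end: int) -> None:
        self._iv.setdefault(name, []).append((start, end))

    def _merge_all(self) -> None:
        for name, ivs in self._iv.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._iv[name] = merged

    def covered_bp(self, name: str, start: int, end: int) -> int:
        total = 0
        ivs = self._iv.get(name, [])
        i = bisect.bisect_left(ivs, (start, -1)) - 1
        for s, e in ivs[max(i, 0):]:
            if s >= end:
                break
            total += max(0, min(e, end) - max(s, start))
        return total

    def coverage_fraction(self, name: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.covered_bp(name, start, end) / (end - start)


@dataclass
class SvCall:
    sv_type: str  # CNV_GAIN_QRY, CNV_LOSS_QRY, INS_QRY, DEL_QRY, INV
    ref_name: str
    ref_start: int
    ref_end: int
    qry_name: str
    qry_start: int
    qry_end: int
    length: int
    te_status: str = "non-TE"
    spacer: tuple[int, int] | None = None  # query-coordinate spacer between CNV copies
    copies: list[tuple[int, int]] | None = None  # per-copy intervals (CNV calls)
    evidence: list = field(default_factory=list)
    copy_report: "CopyNumberReport | None" = None


@dataclass
class CopyNumberReport:
    candidate_id: str
    copies_ref: int
    copies_qry: int
    ref_intervals: list[tuple[str, int, int]]
    qry_intervals: list[tuple[str, int, int]]
    c: int = 500
    qco: int = 10_000
    rco: float = 0.2

    @property
    def is_false_positive(self) -> bool:
        return self.copies_ref == self.copies_qry


@dataclass
class SmallVariant:
    kind: str  # SNP, INS, DEL
    ref_name: str
    ref_pos: int
    ref_allele: str
    qry_allele: str
    qry_name: str = ""
    qry_pos: int = -1

    @property
    def length(self) -> int:
        if self.kind == "SNP":
            return 1
        return max(len(self.ref_allele), len(self.qry_allele))


@dataclass
class SvCatalog:
    calls: list[SvCall]
    small_variants: list[SmallVariant]
    counts: dict[str, int]
    affected_bp: dict[str, int]
    unmerged_calls: list[SvCall] = field(default_factory=list)


def _type_key(call: SvCall) -> str:
    if call.sv_type in ("INS_QRY", "DEL_QRY"):
        return f"{call.sv_type[:3]}_{'TE' if call.te_status == 'TE' else 'nonTE'}"
    return call.sv_type


# ---------------------------------------------------------------------------
# duplications
# ---------------------------------------------------------------------------

def _project(cluster: Cluster, ref_pos: int) -> int:
    """Forward-strand query position of a reference position via anchors."""
    best = None
    for m in cluster.matches:
        if m.ref_start <= ref_pos <= m.ref_end:
            qs = m.qry_start + (ref_pos - m.ref_start)
            best = qs
            break
        # remember nearest anchor edge
        if ref_pos < m.ref_start:
            cand = m.qry_start - (m.ref_start - ref_pos)
        else:
            cand = m.qry_end + (ref_pos - m.ref_end)
        if best is None:
            best = cand
    qs = best if best is not None else cluster.qs_start
    if cluster.strand == "+":
        return qs
    return cluster.qry_len - qs


def _dup_pairs(clusters: list[Cluster], min_len: int, qry_overlap_tol: int = 50):
    """(overlap, copy pair) for cluster pairs overlapping on the reference.

    Query intervals must be disjoint up to a small tolerance (junction
    microhomology can make flanking anchors overlap by a few bases).
    """
    out = []
    per_ref: dict[str, list[Cluster]] = {}
    for c in clusters:
        per_ref.setdefault(c.ref_name, []).append(c)
    for ref_name, cl in per_ref.items():
        cl.sort(key=lambda c: c.ref_start)
        for i, ci in enumerate(cl):
            for cj in cl[i + 1 :]:
                if cj.ref_start >= ci.ref_end:
                    break
                o1, o2 = max(ci.ref_start, cj.ref_start), min(ci.ref_end, cj.ref_end)
                if o2 - o1 < min_len:
                    continue
                if ci.qry_name == cj.qry_name:
                    q_ov = min(ci.qry_end, cj.qry_end) - max(ci.qry_start, cj.qry_start)
                    if q_ov > qry_overlap_tol:
                        continue
                out.append((ref_name, o1, o2, ci, cj))
    return out


def call_duplications(
    clusters_fwd: list[Cluster],
    clusters_rev: list[Cluster],
    repeats: RepeatAnnotation | None = None,
    min_len: int = MIN_SV_LEN,
    te_frac: float = 0.8,
) -> list[SvCall]:
    """CNV calls from overlapping anchor clusters.

    Two clusters whose reference intervals overlap by >= ``min_len``
    while their query intervals are disjoint imply the overlap segment
    is duplicated in the query (CNV gain). The same rule applied to the
    swapped-genome run (``clusters_rev``) yields query-relative losses.
    """
    calls: list[SvCall] = []
    for ref_name, o1, o2, ci, cj in _dup_pairs(clusters_fwd, min_len):
        copies = []
        for c in (ci, cj):
            qa, qb = _project(c, o1), _project(c, o2)
            copies.append((min(qa, qb), max(qa, qb)))
        copies.sort()
        spacer = None
        if copies[0][1] < copies[1][0]:
            gap = (copies[0][1], copies[1][0])
            if gap[1] - gap[0] > 0:
                spacer = gap
        call = SvCall(
            "CNV_GAIN_QRY",
            ref_name,
            o1,
            o2,
            ci.qry_name,
            copies[0][0],
            copies[1][1],
            o2 - o1,
            spacer=spacer,
            copies=copies,
            evidence=[ci, cj],
        )
        calls.append(call)
    for qry_name, o1, o2, ci, cj in _dup_pairs(clusters_rev, min_len):
        # clusters_rev reference axis is the query genome
        copies = sorted(
            (min(_project(c, o1), _project(c, o2)), max(_project(c, o1), _project(c, o2)))
            for c in (ci, cj)
        )
        # the retained-copy loci may be dispersed: report the first copy as
        # the primary reference interval and keep both copies on the call
        calls.append(
            SvCall(
                "CNV_LOSS_QRY",
                ci.qry_name,
                copies[0][0],
                copies[0][1],
                qry_name,
                o1,
                o2,
                o2 - o1,
                copies=copies,
                evidence=[ci, cj],
            )
        )
    calls = _dedup_cnv(calls)
    if repeats is not None:
        for call in calls:
            annotate_te_status(call, repeats, te_frac)
    return calls


def _dedup_cnv(calls: list[SvCall]) -> list[SvCall]:
    """Collapse near-identical calls from redundant cluster pairs."""
    out: list[SvCall] = []
    for call in sorted(calls, key=lambda c: (c.sv_type, c.ref_name, -c.length)):
        dup = False
        for kept in out:
            if kept.sv_type != call.sv_type or kept.ref_name != call.ref_name:
                continue
            ov = min(kept.ref_end, call.ref_end) - max(kept.ref_start, call.ref_start)
            if ov > 0 and ov >= 0.5 * call.length:
                kept.evidence.extend(call.evidence)
                dup = True
                break
        if not dup:
            out.append(call)
    out.sort(key=lambda c: (c.ref_name, c.ref_start))
    return out


# ---------------------------------------------------------------------------
# checkCNV-style copy verification
# ---------------------------------------------------------------------------

def _count_copies(candidate: str, genome: list[SequenceRecord], qco: int, rco: float,
                  min_match: int, cap: int):
    cand_rec = SequenceRecord("candidate", candidate)
    matches = find_mems(genome, cand_rec, min_len=min_match,
                        unique_in_ref=False, both_strands=True)
    L = len(candidate)
    copies: list[tuple[str, int, int]] = []
    keyfn = lambda m: (m.ref_name, m.strand)
    for (gname, strand), group in itertools.groupby(sorted(matches, key=keyfn), keyfn):
        chain: list = []
        covered: list[tuple[int, int]] = []

        def close():
            if not chain:
                return
            ivs = sorted(covered)
            total, hi = 0, -1
            for s, e in ivs:
                if s > hi:
                    total += e - s
                    hi = e
                elif e > hi:
                    total += e - hi
                    hi = e
            if total >= (1 - rco) * L:
                copies.append((gname, chain[0].ref_start, chain[-1].ref_end))

        for m in sorted(group, key=lambda m: m.ref_start):
            if chain:
                gap = m.ref_start - chain[-1].ref_end
                # a new copy restarts (or re-covers) the candidate axis
                progresses = m.qry_start >= chain[-1].qry_end - 50 and (
                    m.qry_start > chain[-1].qry_start
                )
                if gap > qco or not progresses or gap < -L:
                    close()
                    chain, covered = [], []
            chain.append(m)
            covered.append((m.qry_start, m.qry_end))
        close()
    # merge copies substantially sharing a genome span (e.g. + and - chains
    # over one locus); tandem copies abutting by a few bp stay distinct
    copies.sort()
    merged: list[tuple[str, int, int]] = []
    for c in copies:
        if merged and c[0] == merged[-1][0]:
            ov = min(merged[-1][2], c[2]) - max(merged[-1][1], c[1])
            span = min(merged[-1][2] - merged[-1][1], c[2] - c[1])
            if ov > 0.5 * span:
                merged[-1] = (c[0], min(merged[-1][1], c[1]), max(merged[-1][2], c[2]))
                continue
        merged.append(c)
    return min(len(merged), cap), merged


def verify_copy_number(
    candidate_seq: str,
    ref: list[SequenceRecord],
    qry: list[SequenceRecord],
    c: int = 500,
    qco: int = 10_000,
    rco: float = 0.2,
    min_match: int = 20,
    candidate_id: str = "candidate",
) -> CopyNumberReport:
    """Count copies of a candidate duplication in each genome.

    A copy is a chain of exact anchors on one genome whose internal
    unaligned runs are at most ``qco`` bp and which covers at least
    ``1 - rco`` of the candidate. Candidates with equal counts in both
    genomes are false-positive duplications.
    """
    if len(candidate_seq) < MIN_SV_LEN:
        raise ValueError("candidate shorter than 100 bp")
    n_ref, iv_ref = _count_copies(candidate_seq, ref, qco, rco, min_match, c)
    n_qry, iv_qry = _count_copies(candidate_seq, qry, qco, rco, min_match, c)
    if n_ref == 0 and n_qry == 0:
        warnings.warn(f"candidate {candidate_id} absent from both genomes")
    return CopyNumberReport(candidate_id, n_ref, n_qry, iv_ref, iv_qry, c, qco, rco)


# ---------------------------------------------------------------------------
# indels, inversions, small variants
# ---------------------------------------------------------------------------

def collinear_backbone(blocks: list[SyntenyBlock], tol: int = 50) -> list[SyntenyBlock]:
    """Maximum-weight chain of forward blocks collinear in both genomes.

    Repeat-induced stray blocks (e.g. a reference TE copy aligned to a
    non-orthologous query copy) are off the backbone and would otherwise
    corrupt adjacency-based indel calling. Reverse-strand blocks are
    kept as-is (they are inversion candidates, not backbone members).
    """
    import itertools as _it

    minus = [b for b in blocks if b.strand == "-"]
    keep: list[SyntenyBlock] = []
    keyfn = lambda b: (b.ref_name, b.qry_name)
    plus = sorted(
        (b for b in blocks if b.strand == "+"),
        key=lambda b: (b.ref_name, b.qry_name, b.ref_start),
    )
    for _, group in _it.groupby(plus, key=keyfn):
        bl = list(group)
        best = [0.0] * len(bl)
        prev = [-1] * len(bl)
        for j, bj in enumerate(bl):
            best[j] = bj.weight
            for i in range(j):
                bi = bl[i]
                if (
                    bj.ref_start >= bi.ref_end - tol
                    and bj.qry_start >= bi.qry_end - tol
                    and bj.qry_start > bi.qry_start
                    and best[i] + bj.weight > best[j]
                ):
                    best[j], prev[j] = best[i] + bj.weight, i
        if not bl:
            continue
        top = max(range(len(bl)), key=lambda j: best[j])
        chain = []
        while top != -1:
            chain.append(bl[top])
            top = prev[top]
        keep.extend(chain)
    keep.extend(minus)
    keep.sort(key=lambda b: (b.ref_name, b.ref_start))
    return keep


def call_indels(
    blocks: list[SyntenyBlock],
    min_len: int = MIN_SV_LEN,
    reciprocal_frac: float = 0.10,
    return_divergent: bool = False,
    backbone: bool = True,
):
    """Large indels from gaps between adjacent one-to-one synteny blocks.

    A query-side gap > ``min_len`` with a reference-side gap smaller than
    ``reciprocal_frac`` of it is an insertion in the query; the symmetric
    pattern is a deletion. Gap pairs failing both rules are flagged as
    divergent regions, not indels.
    """
    calls: list[SvCall] = []
    divergent: list[tuple[str, int, int]] = []
    if backbone:
        blocks = collinear_backbone(blocks)
    per_ref: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        per_ref.setdefault(b.ref_name, []).append(b)
    for ref_name, bl in per_ref.items():
        bl.sort(key=lambda b: b.ref_start)
        for prev, nxt in zip(bl, bl[1:]):
            if (
                prev.qry_name != nxt.qry_name
                or prev.strand != "+"
                or nxt.strand != "+"
                or nxt.qry_start < prev.qry_end
            ):
                continue
            ref_gap = max(0, nxt.ref_start - prev.ref_end)
            qry_gap = max(0, nxt.qry_start - prev.qry_end)
            if qry_gap > min_len and ref_gap < reciprocal_frac * qry_gap:
                calls.append(
                    SvCall(
                        "INS_QRY", ref_name, prev.ref_end, nxt.ref_start,
                        prev.qry_name, prev.qry_end, nxt.qry_start,
                        qry_gap, evidence=[prev, nxt],
                    )
                )
            elif ref_gap > min_len and qry_gap < reciprocal_frac * ref_gap:
                calls.append(
                    SvCall(
                        "DEL_QRY", ref_name, prev.ref_end, nxt.ref_start,
                        prev.qry_name, prev.qry_end, nxt.qry_start,
                        ref_gap, evidence=[prev, nxt],
                    )
                )
            elif qry_gap > min_len or ref_gap > min_len:
                divergent.append((ref_name, prev.ref_end, nxt.ref_start))
    if return_divergent:
        return calls, divergent
    return calls


def call_inversions(
    blocks: list[SyntenyBlock],
    repeats: RepeatAnnotation | None = None,
    min_len: int = MIN_SV_LEN,
    te_frac: float = 0.8,
    backbone: bool = True,
) -> list[SvCall]:
    """Reverse-orientation blocks flanked by forward synteny are inversions.

    Calls whose reference interval is mostly annotated repeat are
    removed (TE copies in opposite orientation are not inversions).
    """
    calls: list[SvCall] = []
    if backbone:
        blocks = collinear_backbone(blocks)
    per_ref: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        per_ref.setdefault(b.ref_name, []).append(b)
    for ref_name, bl in per_ref.items():
        bl.sort(key=lambda b: b.ref_start)
        for i, b in enumerate(bl):
            if b.strand != "-" or b.ref_end - b.ref_start < min_len:
                continue
            if i == 0 or i == len(bl) - 1:
                continue
            if bl[i - 1].strand != "+" or bl[i + 1].strand != "+":
                continue
            if repeats is not None and repeats.coverage_fraction(
                ref_name, b.ref_start, b.ref_end
            ) >= te_frac:
                continue
            calls.append(
                SvCall(
                    "INV", ref_name, b.ref_start, b.ref_end,
                    b.qry_name, b.qry_start, b.qry_end,
                    b.ref_end - b.ref_start, evidence=[b],
                )
            )
    return calls


def normalize_indel(seq: str, pos: int, payload: str) -> tuple[int, str]:
    """Left-align an indel: shift while the preceding base equals the
    payload's last base (standard VCF-style normalization)."""
    while pos > 0 and payload and seq[pos - 1] == payload[-1]:
        payload = payload[-1] + payload[:-1]
        pos -= 1
    return pos, payload


def call_snps_small_indels(
    blocks: list[SyntenyBlock],
    ref_index: dict[str, SequenceRecord],
    qry_index: dict[str, SequenceRecord],
    max_indel: int = MIN_SV_LEN,
) -> list[SmallVariant]:
    """Per-column SNP and <100-bp indel calls inside synteny blocks.

    Indel runs of ``max_indel`` or more are left to the large-indel
    caller. Indels are left-normalized against the reference context.
    Reverse-strand blocks report query alleles in reference orientation.
    """
    from ._seq import revcomp

    out: list[SmallVariant] = []
    for b in blocks:
        ref = ref_index[b.ref_name].seq
        qry = qry_index[b.qry_name].seq
        qseq = qry if b.strand == "+" else revcomp(qry)
        qlen = len(qry)
        q0 = b.qry_start if b.strand == "+" else qlen - b.qry_end
        rpos, qpos = b.ref_start, q0

        def fwd_qpos(p: int) -> int:
            return p if b.strand == "+" else qlen - p - 1

        for op, ln in b.ops:
            if op == "=":
                rpos += ln
                qpos += ln
            elif op == "X":
                for t in range(ln):
                    out.append(
                        SmallVariant(
                            "SNP", b.ref_name, rpos + t,
                            ref[rpos + t], qseq[qpos + t],
                            b.qry_name, fwd_qpos(qpos + t),
                        )
                    )
                rpos += ln
                qpos += ln
            elif op == "I":
                if ln < max_indel:
                    payload = qseq[qpos : qpos + ln]
                    p, payload = normalize_indel(ref, rpos, payload)
                    out.append(
                        SmallVariant(
                            "INS", b.ref_name, p, "", payload,
                            b.qry_name, fwd_qpos(qpos),
                        )
                    )
                qpos += ln
            elif op == "D":
                if ln < max_indel:
                    payload = ref[rpos : rpos + ln]
                    p, payload = normalize_indel(ref, rpos, payload)
                    out.append(
                        SmallVariant(
                            "DEL", b.ref_name, p, payload, "",
                            b.qry_name, fwd_qpos(qpos),
                        )
                    )
                rpos += ln
    out.sort(key=lambda v: (v.ref_name, v.ref_pos, v.kind))
    return out


def call_junction_small_variants(
    blocks: list[SyntenyBlock],
    ref_index: dict[str, SequenceRecord],
    qry_index: dict[str, SequenceRecord],
    max_indel: int = MIN_SV_LEN,
) -> list[SmallVariant]:
    """Small variants hiding in sub-SV gaps between adjacent blocks.

    One-to-one trimming can land a block boundary exactly on a small
    indel; the residual gap (< 100 bp on both genomes) is aligned here
    and called per column, mirroring the in-block walk.
    """
    from .alignment_core import affine_global_align

    out: list[SmallVariant] = []
    bb = collinear_backbone(blocks)
    per_ref: dict[str, list[SyntenyBlock]] = {}
    for b in bb:
        if b.strand == "+":
            per_ref.setdefault(b.ref_name, []).append(b)
    for ref_name, bl in per_ref.items():
        bl.sort(key=lambda b: b.ref_start)
        ref = ref_index[ref_name].seq
        for prev, nxt in zip(bl, bl[1:]):
            if prev.qry_name != nxt.qry_name or nxt.qry_start < prev.qry_end:
                continue
            ref_gap = nxt.ref_start - prev.ref_end
            qry_gap = nxt.qry_start - prev.qry_end
            if ref_gap < 0 or qry_gap < 0 or max(ref_gap, qry_gap) == 0:
                continue
            if max(ref_gap, qry_gap) >= max_indel:
                continue  # SV-scale gap: the large-indel caller's territory
            qry = qry_index[prev.qry_name].seq
            gr = ref[prev.ref_end : nxt.ref_start]
            gq = qry[prev.qry_end : nxt.qry_start]
            if gr and gq:
                _, ops = affine_global_align(gr, gq)
            elif gq:
                ops = [("I", len(gq))]
            else:
                ops = [("D", len(gr))]
            rpos, qpos = prev.ref_end, prev.qry_end
            for op, ln in ops:
                if op == "=":
                    rpos += ln
                    qpos += ln
                elif op == "X":
                    for t in range(ln):
                        out.append(
                            SmallVariant("SNP", ref_name, rpos + t, ref[rpos + t],
                                         qry[qpos + t], prev.qry_name, qpos + t)
                        )
                    rpos += ln
                    qpos += ln
                elif op == "I":
                    p, payload = normalize_indel(ref, rpos, qry[qpos : qpos + ln])
                    out.append(
                        SmallVariant("INS", ref_name, p, "", payload,
                                     prev.qry_name, qpos)
                    )
                    qpos += ln
                elif op == "D":
                    p, payload = normalize_indel(ref, rpos, ref[rpos : rpos + ln])
                    out.append(
                        SmallVariant("DEL", ref_name, p, payload, "",
                                     prev.qry_name, qpos)
                    )
                    rpos += ln
    return out


def annotate_te_status(
    call: SvCall, repeats: RepeatAnnotation | None, te_frac: float = 0.8
) -> SvCall:
    """Flag a call as TE when >= ``te_frac`` of its variant sequence is
    covered by the repeat annotation of the genome carrying it."""
    if repeats is None:
        logger.warning("no repeat annotation; %s left non-TE", call.sv_type)
        call.te_status = "non-TE"
        return call
    if call.sv_type == "INS_QRY":
        name, start, end = call.qry_name, call.qry_start, call.qry_end
    else:
        name, start, end = call.ref_name, call.ref_start, call.ref_end
    frac = repeats.coverage_fraction(name, start, end)
    call.te_status = "TE" if frac >= te_frac else "non-TE"
    return call


def merge_complex_events(
    calls: list[SvCall],
    d: int = 2000,
    small_variants: list[SmallVariant] | None = None,
) -> SvCatalog:
    """Merge CNV calls within ``d`` bp into complex events and build the
    catalog. Affected bp are totalled from the unmerged calls."""
    affected: dict[str, int] = {}
    for call in calls:
        affected[_type_key(call)] = affected.get(_type_key(call), 0) + call.length
    merged: list[SvCall] = []
    cnv = [c for c in calls if c.sv_type.startswith("CNV")]
    other = [c for c in calls if not c.sv_type.startswith("CNV")]
    keyfn = lambda c: (c.sv_type, c.ref_name)
    for _, group in itertools.groupby(sorted(cnv, key=lambda c: (c.sv_type, c.ref_name, c.ref_start)), keyfn):
        current = None
        for call in group:
            if current is not None and call.ref_start - current.ref_end <= d:
                current.ref_end = max(current.ref_end, call.ref_end)
                current.qry_start = min(current.qry_start, call.qry_start)
                current.qry_end = max(current.qry_end, call.qry_end)
                current.length = current.ref_end - current.ref_start
                current.evidence.extend(call.evidence)
                current.te_status = (
                    "TE" if current.te_status == call.te_status == "TE" else current.te_status
                )
            else:
                if current is not None:
                    merged.append(current)
                current = SvCall(**{
                    k: list(v) if isinstance(v, list) else v
                    for k, v in vars(call).items()
                })
        if current is not None:
            merged.append(current)
    merged.extend(other)
    merged.sort(key=lambda c: (c.ref_name, c.ref_start))
    counts: dict[str, int] = {}
    for call in merged:
        counts[_type_key(call)] = counts.get(_type_key(call), 0) + 1
    return SvCatalog(
        calls=merged,
        small_variants=small_variants or [],
        counts=counts,
        affected_bp=affected,
        unmerged_calls=list(calls),
    )
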