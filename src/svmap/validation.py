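"""Long-read validation of structural variants.

Each SV is checked against reads mapped to the assembly that carries it:
reads must span the variant with at least 250 bp of aligned flank. Two
per-read quality metrics decide whether support counts — P_aligned, the
fraction of the read's bases that are aligned, and R_gaps, the ratio of
alignment gap columns to read length. The stringent criterion demands
two fully spanning reads at P_aligned >= 0.995 and R_gaps < 0.005; the
standard criterion relaxes to P_aligned >= 0.975 / R_gaps < 0.025 for
fully spanning reads, or accepts two breakpoint-overlapping reads per
side at stringent quality.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .alignment_core import (
    Cluster,
    affine_global_align,
    cluster_matches,
    fill_cluster_alignment,
    find_mems,
)
from .io import SequenceRecord

ANCHOR_BP = 250
P_STRINGENT, R_STRINGENT = 0.995, 0.005
P_STANDARD, R_STANDARD = 0.975, 0.025


@dataclass
class ReadAlignmentRecord:
    """One read's alignment to the assembly under test.

    ``ops`` is run-length encoded with '=' /'X' (aligned), 'I' (read-only
    column), 'D' (assembly-only column), 'S' (soft clip). An empty ops
    list marks an unaligned read.
    """

    read_id: str
    read_len: int
    target_name: str
    target_start: int
    target_end: int
    ops: list[tuple[str, int]]

    @property
    def aligned_bases(self) -> int:
        return sum(ln for op, ln in self.ops if op in "=X")

    @property
    def gap_columns(self) -> int:
        return sum(ln for op, ln in self.ops if op in "ID")

    @property
    def p_aligned(self) -> float:
        return self.aligned_bases / self.read_len if self.read_len else 0.0

    @property
    def r_gaps(self) -> float:
        return self.gap_columns / self.read_len if self.read_len else 1.0


@dataclass
class SpanningReadEvidence:
    read_id: str
    span_class: str  # FULL, OVERLAP_LEFT, OVERLAP_RIGHT, NONE
    p_aligned: float
    r_gaps: float


@dataclass
class ValidationVerdict:
    sv_id: str
    verdict: str  # STRINGENT, STANDARD, UNVALIDATED
    supporting_reads: list[str] = field(default_factory=list)
    n_full: int = 0
    n_left: int = 0
    n_right: int = 0


def records_from_sam(path) -> list[ReadAlignmentRecord]:
    """Read primary alignments from SAM/BAM; CIGAR supplies the metrics."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            ops = []
            read_len = aln.infer_read_length() or len(aln.query_sequence or "")
            for code, ln in aln.cigartuples or []:
                op = {0: "=", 7: "=", 8: "X", 1: "I", 2: "D", 4: "S", 5: "S"}.get(code)
                if op is None:
                    continue
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + ln)
                else:
                    ops.append((op, ln))
            out.append(
                ReadAlignmentRecord(
                    aln.query_name,
                    read_len,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end or aln.reference_start,
                    ops,
                )
            )
    return out


def collect_spanning_evidence(
    sv_interval: tuple[str, int, int],
    records: list[ReadAlignmentRecord],
    anchor: int = ANCHOR_BP,
) -> list[SpanningReadEvidence]:
    """Classify each read's span of one SV region.

    FULL requires the aligned target span to cover the SV with at least
    ``anchor`` bp of flank on both sides; OVERLAP_LEFT/RIGHT require one
    covered breakpoint with the flank on that side.
    """
    name, s, e = sv_interval
    out = []
    for rec in records:
        if rec.target_name != name or not rec.ops:
            continue
        left_ok = rec.target_start <= s - anchor
        right_ok = rec.target_end >= e + anchor
        covers_all = rec.target_start <= s and rec.target_end >= e
        if left_ok and right_ok:
            cls = "FULL"
        elif covers_all:
            cls = "NONE"  # spans the SV but lacks an anchor-length flank
        elif left_ok and rec.target_end > s:
            cls = "OVERLAP_LEFT"
        elif right_ok and rec.target_start < e:
            cls = "OVERLAP_RIGHT"
        else:
            cls = "NONE"
        out.append(SpanningReadEvidence(rec.read_id, cls, rec.p_aligned, rec.r_gaps))
    return out


def classify_validation(
    evidence: list[SpanningReadEvidence], sv_id: str = "sv"
) -> ValidationVerdict:
    """Stringent / standard / unvalidated decision from spanning reads."""
    full_strict = [
        ev for ev in evidence
        if ev.span_class == "FULL"
        and ev.p_aligned >= P_STRINGENT
        and ev.r_gaps < R_STRINGENT
    ]
    full_std = [
        ev for ev in evidence
        if ev.span_class == "FULL"
        and ev.p_aligned >= P_STANDARD
        and ev.r_gaps < R_STANDARD
    ]
    left = [
        ev for ev in evidence
        if ev.span_class == "OVERLAP_LEFT"
        and ev.p_aligned >= P_STRINGENT
        and ev.r_gaps < R_STRINGENT
    ]
    right = [
        ev for ev in evidence
        if ev.span_class == "OVERLAP_RIGHT"
        and ev.p_aligned >= P_STRINGENT
        and ev.r_gaps < R_STRINGENT
    ]
    n_full_any = sum(1 for ev in evidence if ev.span_class == "FULL")
    n_left_any = sum(1 for ev in evidence if ev.span_class == "OVERLAP_LEFT")
    n_right_any = sum(1 for ev in evidence if ev.span_class == "OVERLAP_RIGHT")
    if len(full_strict) >= 2:
        return ValidationVerdict(
            sv_id, "STRINGENT", [ev.read_id for ev in full_strict],
            n_full_any, n_left_any, n_right_any,
        )
    if len(full_std) >= 2 or (len(left) >= 2 and len(right) >= 2):
        support = full_std if len(full_std) >= 2 else left + right
        return ValidationVerdict(
            sv_id, "STANDARD", [ev.read_id for ev in support],
            n_full_any, n_left_any, n_right_any,
        )
    return ValidationVerdict(sv_id, "UNVALIDATED", [], n_full_any, n_left_any, n_right_any)


def validate_catalog(
    sv_intervals: dict[str, tuple[str, int, int]],
    records: list[ReadAlignmentRecord],
    anchor: int = ANCHOR_BP,
) -> dict[str, ValidationVerdict]:
    return {
        sv_id: classify_validation(
            collect_spanning_evidence(iv, records, anchor), sv_id
        )
        for sv_id, iv in sv_intervals.items()
    }


# ---------------------------------------------------------------------------
# anchored read-to-window alignment (used for simulated reads)
# ---------------------------------------------------------------------------

_READ_CHAIN = dict(s=5000, f=2.0, l=60)
_SEED_LEN = 18
_END_DP_CAP = 3000


def _strip_edge_deletions(ops, leading: bool):
    """Remove window-only columns at an alignment edge; returns (ops, bp)."""
    ops = list(ops)
    removed = 0
    idx = 0 if leading else -1
    while ops and ops[idx][0] == "D":
        removed += ops[idx][1]
        ops.pop(idx)
    return ops, removed


def align_read_to_window(read_seq: str, window_seq: str):
    """Semi-global alignment of a read against a target window.

    MEM anchors are chained (permissive drift so SV-scale gaps stay in
    one chain) and inter-anchor gaps filled by affine DP; read ends
    beyond the outermost anchors are aligned by bounded DP with the
    window side free. Returns ``(ops, target_start, target_end)`` or
    None when the read cannot be anchored.
    """
    window = SequenceRecord("window", window_seq)
    read = SequenceRecord("read", read_seq)
    mems = find_mems(window, read, min_len=_SEED_LEN,
                     unique_in_ref=False, both_strands=False)
    if not mems:
        return None
    clusters = cluster_matches(mems, {"read": len(read_seq)}, **_READ_CHAIN)
    if not clusters:
        return None
    best = max(clusters, key=lambda c: c.total_match_len)
    core = fill_cluster_alignment(best, window, read)
    ops = list(core.ops)
    tstart, tend = best.ref_start, best.ref_end
    q0, q1 = best.qs_start, best.qs_end

    # read head: align against the window bases left of the first anchor
    if q0 > 0:
        head = read_seq[:q0]
        if len(head) <= _END_DP_CAP:
            w0 = max(0, tstart - len(head) - 50)
            wpart = window_seq[w0:tstart]
            if wpart:
                _, head_ops = affine_global_align(wpart, head)
                head_ops, _ = _strip_edge_deletions(head_ops, leading=True)
                consumed_w = sum(ln for op, ln in head_ops if op in "=XD")
                tstart -= consumed_w
                ops = head_ops + ops
            else:
                ops = [("S", q0)] + ops
        else:
            ops = [("S", q0)] + ops
    if q1 < len(read_seq):
        tail = read_seq[q1:]
        if len(tail) <= _END_DP_CAP:
            w1 = min(len(window_seq), tend + len(tail) + 50)
            wpart = window_seq[tend:w1]
            if wpart:
                _, tail_ops = affine_global_align(wpart, tail)
                tail_ops, _ = _strip_edge_deletions(tail_ops, leading=False)
                consumed_w = sum(ln for op, ln in tail_ops if op in "=XD")
                tend += consumed_w
                ops = ops + tail_ops
            else:
                ops = ops + [("S", len(tail))]
        else:
            ops = ops + [("S", len(tail))]
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged, tstart, tend
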