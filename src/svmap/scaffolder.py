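"""Reference-guided comparative scaffolding of a contig set.

Contigs are aligned to reference chromosome arms, alignments reduced to
mutually-best per contig region, and each contig assigned to the arm
holding at least 40% of its aligned bases. Assigned contigs are ordered
along the arm by the start of their first alignment that does not
overlap the preceding contig's alignment, oriented by majority aligned
strand, and joined with exactly 100 Ns; unassigned contigs keep their
sequence under a 'U'-prefixed name.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp
from .alignment_core import cluster_matches, filter_mutual_best, find_mems
from .io import SequenceRecord

ASSIGN_THRESHOLD = 0.40
GAP_N = 100


@dataclass
class ContigAssignment:
    contig: str
    arm: str  # reference arm name or "UNPLACED"
    aligned_fraction: float
    orientation: str
    anchor_start: int
    aligned_bp: int = 0


@dataclass
class ScaffoldPlan:
    arms: dict[str, list[tuple[str, str]]]  # arm -> ordered (contig, orientation)
    unplaced: list[str]
    gap: int = GAP_N


def align_contigs(
    arms: list[SequenceRecord],
    contigs: list[SequenceRecord],
    min_match: int = 20,
    cluster_s: int = 200,
    cluster_f: float = 0.12,
    cluster_l: int = 100,
):
    """Cluster-level alignments of each contig against the arms, filtered
    to mutually-best coverage of each contig region."""
    lengths = {c.name: len(c) for c in contigs}
    mems = find_mems(arms, contigs, min_len=min_match)
    clusters = cluster_matches(mems, lengths, s=cluster_s, f=cluster_f, l=cluster_l)
    for c in clusters:
        c.weight = c.total_match_len  # duck-typed weight for the filter
    return filter_mutual_best(clusters, mode="query")


def assign_contigs(
    alignments,
    contigs: list[SequenceRecord],
    threshold: float = ASSIGN_THRESHOLD,
) -> list[ContigAssignment]:
    """Assign each contig to the arm carrying its best aligned share.

    The share is measured over the contig's total aligned bases; contigs
    whose best arm holds less than ``threshold`` stay UNPLACED, as do
    contigs with no alignment at all.
    """
    per_contig: dict[str, list] = {c.name: [] for c in contigs}
    for aln in alignments:
        per_contig.setdefault(aln.qry_name, []).append(aln)
    out = []
    for contig in contigs:
        alns = per_contig.get(contig.name, [])
        total = sum(a.total_match_len for a in alns)
        if total == 0:
            out.append(ContigAssignment(contig.name, "UNPLACED", 0.0, "+", -1))
            continue
        by_arm: dict[str, int] = {}
        for a in alns:
            by_arm[a.ref_name] = by_arm.get(a.ref_name, 0) + a.total_match_len
        best_arm = max(sorted(by_arm), key=lambda k: by_arm[k])
        share = by_arm[best_arm] / total
        if share < threshold:
            out.append(ContigAssignment(contig.name, "UNPLACED", share, "+", -1))
            continue
        arm_alns = [a for a in alns if a.ref_name == best_arm]
        plus = sum(a.total_match_len for a in arm_alns if a.strand == "+")
        minus = sum(a.total_match_len for a in arm_alns if a.strand == "-")
        orientation = "+" if plus >= minus else "-"
        anchor = min(a.ref_start for a in arm_alns)
        out.append(
            ContigAssignment(
                contig.name, best_arm, share, orientation, anchor,
                aligned_bp=by_arm[best_arm],
            )
        )
    return out


def _order_arm(assignments, alignments) -> list[ContigAssignment]:
    """Order contigs by the first alignment start not overlapping the
    preceding contig's alignment."""
    alns_by_contig: dict[str, list] = {}
    for a in alignments:
        alns_by_contig.setdefault(a.qry_name, []).append(a)
    pending = sorted(assignments, key=lambda a: (a.anchor_start, -a.aligned_bp, a.contig))
    ordered: list[ContigAssignment] = []
    prev_end = 0
    for a in pending:
        arm_alns = sorted(
            (x for x in alns_by_contig.get(a.contig, []) if x.ref_name == a.arm),
            key=lambda x: x.ref_start,
        )
        nonoverlap = [x for x in arm_alns if x.ref_start >= prev_end]
        chosen = nonoverlap[0] if nonoverlap else arm_alns[0]
        a.anchor_start = chosen.ref_start
        prev_end = max(prev_end, chosen.ref_end)
        ordered.append(a)
    ordered.sort(key=lambda a: (a.anchor_start, -a.aligned_bp, a.contig))
    starts = [a.anchor_start for a in ordered]
    if len(set(starts)) != len(starts):
        raise ValueError("unresolvable anchor ties between contigs")
    return ordered


def build_scaffolds(
    assignments: list[ContigAssignment],
    contigs: list[SequenceRecord],
    alignments=None,
    gap: int = GAP_N,
):
    """Emit the scaffold plan, scaffold FASTA records, and AGP rows.

    Assigned contigs are reverse-complemented when oriented '-' and
    joined with exactly ``gap`` Ns; unplaced contigs are emitted as
    their own 'U'-prefixed records.
    """
    names = [c.name for c in contigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names")
    seqs = {c.name: c.seq for c in contigs}
    per_arm: dict[str, list[ContigAssignment]] = {}
    unplaced: list[str] = []
    for a in assignments:
        if a.arm == "UNPLACED":
            unplaced.append(a.contig)
        else:
            per_arm.setdefault(a.arm, []).append(a)
    plan = ScaffoldPlan(arms={}, unplaced=unplaced, gap=gap)
    records: list[SequenceRecord] = []
    agp: list[str] = []
    for arm in sorted(per_arm):
        ordered = (
            _order_arm(per_arm[arm], alignments)
            if alignments is not None
            else sorted(per_arm[arm], key=lambda a: a.anchor_start)
        )
        plan.arms[arm] = [(a.contig, a.orientation) for a in ordered]
        parts = []
        pos = 0
        obj = f"scaffold_{arm}"
        part_no = 1
        for i, a in enumerate(ordered):
            if i > 0:
                parts.append("N" * gap)
                agp.append(
                    f"{obj}\t{pos + 1}\t{pos + gap}\t{part_no}\tN\t{gap}\tscaffold\tyes\talign_genus"
                )
                pos += gap
                part_no += 1
            seq = seqs[a.contig]
            if a.orientation == "-":
                seq = revcomp(seq)
            parts.append(seq)
            agp.append(
                f"{obj}\t{pos + 1}\t{pos + len(seq)}\t{part_no}\tW\t{a.contig}\t1\t{len(seq)}\t{a.orientation}"
            )
            pos += len(seq)
            part_no += 1
        records.append(SequenceRecord(obj, "".join(parts)))
    for name in sorted(unplaced):
        records.append(SequenceRecord(f"U{name}", seqs[name]))
        agp.append(f"U{name}\t1\t{len(seqs[name])}\t1\tW\t{name}\t1\t{len(seqs[name])}\t+")
    return plan, records, agp


def scaffold_assembly(
    arms: list[SequenceRecord],
    contigs: list[SequenceRecord],
    threshold: float = ASSIGN_THRESHOLD,
    gap: int = GAP_N,
    min_match: int = 20,
):
    """Convenience wrapper: align, assign, order, and build in one call."""
    alignments = align_contigs(arms, contigs, min_match=min_match)
    assignments = assign_contigs(alignments, contigs, threshold=threshold)
    return build_scaffolds(assignments, contigs, alignments=alignments, gap=gap)
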