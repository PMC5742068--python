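"""Reading and writing the standard file formats used by the toolkit.

FASTA (optionally gzipped), BED / GFF3 interval annotations, and the TSV
reports emitted by the callers. Coordinates are 0-based half-open in
memory and 1-based inclusive in emitted reports (MUMmer convention).
"""
from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np

from ._seq import check_alphabet


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with an optional per-position mask."""

    name: str
    seq: str
    masked: np.ndarray | None = None  # True = excluded from anchoring

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.name!r} is empty")
        self.seq = self.seq.upper()
        check_alphabet(self.seq, self.name)

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[SequenceRecord]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        records = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names in FASTA")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name, seq = (rec.name, rec.seq) if hasattr(rec, "seq") else rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intervals(path, dialect: str | None = None) -> dict[str, list[tuple[int, int, str]]]:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals.

    Returns ``{seq_name: [(start, end, label), ...]}`` with 0-based
    half-open coordinates. Dialect auto-detected from the extension
    unless given explicitly ("bed" or "gff").
    """
    if dialect is None:
        base = str(path).lower()
        if base.endswith(".gz"):
            base = base[:-3]
        dialect = "gff" if base.endswith((".gff", ".gff3", ".gtf")) else "bed"
    out: dict[str, list[tuple[int, int, str]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if dialect == "bed":
                name, start, end = parts[0], int(parts[1]), int(parts[2])
                label = parts[3] if len(parts) > 3 else "repeat"
            else:
                name, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
                label = parts[2] if len(parts) > 2 else "repeat"
            out.setdefault(name, []).append((start, end, label))
    return out


def write_bed(path, intervals: dict[str, list[tuple[int, int, str]]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(intervals):
            for start, end, label in sorted(intervals[name]):
                fh.write(f"{name}\t{start}\t{end}\t{label}\n")


def mask_from_intervals(record: SequenceRecord, intervals) -> np.ndarray:
    """Boolean mask for one record from a read_intervals-style dict."""
    mask = np.zeros(len(record), dtype=bool)
    for start, end, _ in intervals.get(record.name, []):
        mask[max(0, start) : min(len(record), end)] = True
    return mask


def write_tsv(path, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate">
##INFO=<ID=TE,Number=0,Type=Flag,Description="Variant sequence is mostly annotated repeat">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=INV,Description="Inversion">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path, rows: list[dict], contigs: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2. ``rows`` carry chrom/pos (1-based)/id/ref/alt/info."""
    with open(path, "w") as fh:
        header = VCF_HEADER
        if contigs:
            contig_lines = "".join(
                f"##contig=<ID={n},length={l}>\n" for n, l in contigs.items()
            )
            header = header.replace("#CHROM", contig_lines + "#CHROM", 1)
        fh.write(header)
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t{r.get('id', '.')}\t{r['ref']}\t{r['alt']}\t.\tPASS\t{r.get('info', '.')}\n"
            )
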