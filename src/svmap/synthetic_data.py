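"""Seeded simulation of a repeat-bearing genome pair with known variants.

The generator produces an ancestral genome carrying diverged TE copies,
a derived genome with implanted TE and non-TE insertions, deletions,
tandem duplications (with and without TE-fragment spacers), inversions,
SNPs and small indels, plus error-bearing long reads and paired-end
reads. Every artifact is reproducible from one seed, and the truth
catalog maps every variant in both coordinate systems.

Default sizes target desk-scale runs (half-megabase genome, minutes of
CPU) while echoing the relative abundances of the variant classes seen
in real assembly comparisons of fly-sized genomes.
"""
from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._seq import random_seq, revcomp
from .io import SequenceRecord

BASES = "ACGT"


@dataclass
class TEFamily:
    name: str
    seq: str
    ltr: str = ""  # terminal repeat carried at both ends, if any


@dataclass
class SimulationConfig:
    genome_length: int = 500_000
    chrom_name: str = "chr2L"
    gc: float = 0.42
    # TE library / ancestral landscape
    n_te_families: int = 4
    te_len_range: tuple[int, int] = (800, 4000)
    ltr_len: int = 300
    n_ancestral_te: int = 30
    ancestral_te_divergence: float = 0.02
    # implanted variants
    te_insertions: int = 20
    non_te_insertions: int = 10
    deletions: int = 20
    tandem_dups: int = 10
    dups_with_spacer: int = 5
    inversions: int = 5
    snp_rate: float = 0.005
    small_indel_rate: float = 0.0005
    # size ranges (bp)
    non_te_ins_len: tuple[int, int] = (100, 2000)
    del_len: tuple[int, int] = (100, 3000)
    dup_len: tuple[int, int] = (300, 4000)
    spacer_len: tuple[int, int] = (1000, 2000)
    inv_len: tuple[int, int] = (500, 5000)
    small_indel_max: int = 30
    insertion_te_divergence: float = 0.01
    # placement constraints
    min_sv_spacing: int = 2500
    edge_margin: int = 5000
    snp_margin: int = 25
    small_indel_margin: int = 150
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("te_len_range", "non_te_ins_len", "del_len", "dup_len",
                    "spacer_len", "inv_len"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class TruthRecord:
    """One implanted variant, with footprints in both coordinate systems.

    ``anc_start:anc_end`` is the replaced ancestral interval and
    ``der_start:der_end`` the replacement interval in the derived
    genome; applying all records to the ancestral genome reproduces the
    derived genome exactly.
    """

    kind: str  # TE_INS, NONTE_INS, DEL, DUP, INV, SNP, SMALL_INS, SMALL_DEL
    chrom: str
    anc_start: int
    anc_end: int
    der_start: int = -1
    der_end: int = -1
    anc_seq: str = ""
    der_seq: str = ""
    spacer: tuple[int, int] | None = None  # derived-coordinate spacer (DUP only)
    unit_len: int = 0  # duplicated unit length (DUP only)


SV_KINDS = ("TE_INS", "NONTE_INS", "DEL", "DUP", "INV")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only divergence of a sequence copy."""
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [b for b in BASES if b != chars[i]]
        chars[i] = choices[rng.integers(3)]
    return "".join(chars)


def make_te_library(cfg: SimulationConfig, rng: np.random.Generator) -> list[TEFamily]:
    fams = []
    for i in range(cfg.n_te_families):
        length = int(rng.integers(cfg.te_len_range[0], cfg.te_len_range[1] + 1))
        if i == 0:  # LTR retroelement-like family (Accord-like)
            ltr = random_seq(rng, cfg.ltr_len, cfg.gc)
            internal = random_seq(rng, max(length - 2 * cfg.ltr_len, 200), cfg.gc)
            fams.append(TEFamily(f"TE{i}", ltr + internal + ltr, ltr))
        else:
            fams.append(TEFamily(f"TE{i}", random_seq(rng, length, cfg.gc)))
    return fams


def simulate_ancestral_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
):
    """Random genome with diverged TE copies at recorded positions.

    Returns ``(record, repeat_intervals, te_library)`` where
    ``repeat_intervals`` is a ``{chrom: [(start, end, family)]}`` dict.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    library = make_te_library(cfg, rng)
    copies = []
    for _ in range(cfg.n_ancestral_te):
        fam = library[rng.integers(len(library))]
        copies.append((fam.name, _mutate(rng, fam.seq, cfg.ancestral_te_divergence)))
    te_bp = sum(len(s) for _, s in copies)
    bg_len = cfg.genome_length - te_bp
    if bg_len <= cfg.n_ancestral_te:  # no room to separate copies
        raise ValueError("TE bp exceed genome length; infeasible packing")
    background = random_seq(rng, bg_len, cfg.gc)
    points = np.sort(rng.choice(bg_len, size=cfg.n_ancestral_te, replace=False))
    parts, intervals = [], []
    prev = 0
    offset = 0
    for (fam_name, seq), p in zip(copies, points):
        parts.append(background[prev : int(p)])
        start = int(p) + offset
        parts.append(seq)
        intervals.append((start, start + len(seq), fam_name))
        offset += len(seq)
        prev = int(p)
    parts.append(background[prev:])
    genome = "".join(parts)
    record = SequenceRecord(cfg.chrom_name, genome)
    return record, {cfg.chrom_name: intervals}, library


def _place_interval(
    rng, length, genome_len, cfg, footprints, te_intervals, avoid_te, max_tries=20000
):
    pad = cfg.min_sv_spacing
    for _ in range(max_tries):
        s = int(rng.integers(cfg.edge_margin, genome_len - length - cfg.edge_margin))
        e = s + length
        if any(s - pad < fe and fs < e + pad for fs, fe in footprints):
            continue
        if avoid_te and any(s - 100 < te and ts < e + 100 for ts, te, _ in te_intervals):
            continue
        return s, e
    raise RuntimeError("could not place variant; genome too crowded")


def apply_variants(
    record: SequenceRecord,
    repeats: dict[str, list[tuple[int, int, str]]],
    library: list[TEFamily],
    cfg: SimulationConfig,
    rng: np.random.Generator,
):
    """Implant the configured variants; returns (derived record, truth,
    derived-genome repeat annotation intervals)."""
    seq = record.seq
    chrom = record.name
    L = len(seq)
    te_intervals = repeats.get(chrom, [])
    footprints: list[tuple[int, int]] = []
    edits: list[TruthRecord] = []

    def add(rec: TruthRecord):
        edits.append(rec)
        footprints.append((rec.anc_start, rec.anc_end))

    # deletions: half remove whole ancestral TE copies, half unique sequence
    n_te_del = cfg.deletions // 2
    shuffled_tes = list(te_intervals)
    rng.shuffle(shuffled_tes)
    te_targets = []
    for ts, te, fam in shuffled_tes:
        if len(te_targets) == n_te_del:
            break
        if ts < cfg.edge_margin or te > L - cfg.edge_margin:
            continue
        if any(ts - cfg.min_sv_spacing < fe and fs < te + cfg.min_sv_spacing
               for fs, fe in footprints):
            continue
        te_targets.append((ts, te))
        add(TruthRecord("DEL", chrom, ts, te, anc_seq=seq[ts:te]))
    for _ in range(cfg.deletions - len(te_targets)):
        ln = int(rng.integers(cfg.del_len[0], cfg.del_len[1] + 1))
        s, e = _place_interval(rng, ln, L, cfg, footprints, te_intervals, True)
        add(TruthRecord("DEL", chrom, s, e, anc_seq=seq[s:e]))

    for _ in range(cfg.te_insertions):
        fam = library[rng.integers(len(library))]
        payload = _mutate(rng, fam.seq, cfg.insertion_te_divergence)
        s, _ = _place_interval(rng, 1, L, cfg, footprints, te_intervals, True)
        add(TruthRecord("TE_INS", chrom, s, s, der_seq=payload))

    for _ in range(cfg.non_te_insertions):
        ln = int(rng.integers(cfg.non_te_ins_len[0], cfg.non_te_ins_len[1] + 1))
        payload = random_seq(rng, ln, cfg.gc)
        s, _ = _place_interval(rng, 1, L, cfg, footprints, te_intervals, True)
        add(TruthRecord("NONTE_INS", chrom, s, s, der_seq=payload))

    ltr_fam = library[0]
    for i in range(cfg.tandem_dups):
        ln = int(rng.integers(cfg.dup_len[0], cfg.dup_len[1] + 1))
        s, e = _place_interval(rng, ln, L, cfg, footprints, te_intervals, True)
        unit = seq[s:e]
        if i < cfg.dups_with_spacer:
            sp_len = int(rng.integers(cfg.spacer_len[0], cfg.spacer_len[1] + 1))
            spacer_seq = ltr_fam.seq[:sp_len]
            der_seq = unit + spacer_seq + unit
            spacer_local = (ln, ln + sp_len)
        else:
            der_seq = unit + unit
            spacer_local = None
        add(TruthRecord("DUP", chrom, s, e, anc_seq=unit, der_seq=der_seq,
                        spacer=spacer_local, unit_len=ln))

    for _ in range(cfg.inversions):
        ln = int(rng.integers(cfg.inv_len[0], cfg.inv_len[1] + 1))
        s, e = _place_interval(rng, ln, L, cfg, footprints, te_intervals, True)
        add(TruthRecord("INV", chrom, s, e, anc_seq=seq[s:e], der_seq=revcomp(seq[s:e])))

    # small variants, kept clear of SV footprints so breakpoints stay clean
    sv_foot = sorted(footprints)

    def near_sv(p: int, margin: int) -> bool:
        i = bisect_right(sv_foot, (p, 1 << 60))
        for fs, fe in sv_foot[max(0, i - 2): i + 2]:
            if fs - margin <= p < fe + margin:
                return True
        return False

    snp_pos = np.nonzero(rng.random(L) < cfg.snp_rate)[0]
    snp_pos = [
        int(p) for p in snp_pos
        if cfg.edge_margin <= p < L - cfg.edge_margin and not near_sv(p, cfg.snp_margin)
    ]
    taken = set(snp_pos)
    n_small = rng.poisson(cfg.small_indel_rate * L)
    small_edits: list[TruthRecord] = []
    tries = 0
    while len(small_edits) < n_small and tries < 100 * n_small + 1000:
        tries += 1
        p = int(rng.integers(cfg.edge_margin, L - cfg.edge_margin))
        ln = min(int(rng.geometric(0.2)), cfg.small_indel_max)
        if near_sv(p, cfg.small_indel_margin):
            continue
        if any(q in taken for q in range(p - 40, p + ln + 40)):
            continue
        for q in range(p - 40, p + ln + 40):
            taken.add(q)
        if rng.random() < 0.5:
            small_edits.append(
                TruthRecord("SMALL_INS", chrom, p, p, der_seq=random_seq(rng, ln, cfg.gc))
            )
        else:
            small_edits.append(
                TruthRecord("SMALL_DEL", chrom, p, p + ln, anc_seq=seq[p : p + ln])
            )
    for p in snp_pos:
        alts = [b for b in BASES if b != seq[p]]
        edits.append(
            TruthRecord("SNP", chrom, p, p + 1, anc_seq=seq[p],
                        der_seq=alts[rng.integers(3)])
        )
    edits.extend(small_edits)

    edits.sort(key=lambda r: (r.anc_start, r.anc_end))
    for a, b in zip(edits, edits[1:]):
        assert a.anc_end <= b.anc_start, "overlapping edits"

    parts = []
    prev = 0
    out_len = 0
    for rec in edits:
        parts.append(seq[prev : rec.anc_start])
        out_len += rec.anc_start - prev
        rec.der_start = out_len
        parts.append(rec.der_seq)
        out_len += len(rec.der_seq)
        rec.der_end = out_len
        if rec.kind == "DUP" and rec.spacer is not None:
            rec.spacer = (rec.der_start + rec.spacer[0], rec.der_start + rec.spacer[1])
        prev = rec.anc_end
    parts.append(seq[prev:])
    derived = SequenceRecord(chrom, "".join(parts))

    lift = CoordMap.from_truth(edits)
    derived_repeats: list[tuple[int, int, str]] = []
    deleted = {(r.anc_start, r.anc_end) for r in edits if r.kind == "DEL"}
    for ts, te, fam in te_intervals:
        if (ts, te) in deleted:
            continue
        derived_repeats.append((lift.map(ts), lift.map(te), fam))
    for rec in edits:
        if rec.kind == "TE_INS":
            derived_repeats.append((rec.der_start, rec.der_end, "TE_INS"))
        elif rec.kind == "DUP" and rec.spacer is not None:
            derived_repeats.append((rec.spacer[0], rec.spacer[1], library[0].name))
    derived_repeats.sort()
    return derived, edits, {chrom: derived_repeats}


class CoordMap:
    """Monotone liftover between two coordinate systems related by edits."""

    def __init__(self, src_edges: list[int], offsets: list[int]):
        # position p with src_edges[i-1] <= p < src_edges[i] maps to p + offsets[i]
        self.src_edges = np.asarray(src_edges)
        self.offsets = np.asarray(offsets)

    @classmethod
    def from_truth(cls, records: list[TruthRecord], direction: str = "anc2der"):
        edges, offsets = [], [0]
        delta = 0
        for r in sorted(records, key=lambda r: r.anc_start):
            if direction == "anc2der":
                edges.append(r.anc_end)
                delta += (r.der_end - r.der_start) - (r.anc_end - r.anc_start)
            else:
                edges.append(r.der_end)
                delta += (r.anc_end - r.anc_start) - (r.der_end - r.der_start)
            offsets.append(delta)
        return cls(edges, offsets)

    def map(self, pos: int) -> int:
        i = int(np.searchsorted(self.src_edges, pos, side="left"))
        return int(pos + self.offsets[i])


def reconstruct_derived(ancestral: SequenceRecord, records: list[TruthRecord]) -> str:
    """Apply truth records to the ancestral sequence (round-trip check)."""
    parts, prev = [], 0
    for r in sorted(records, key=lambda r: r.anc_start):
        parts.append(ancestral.seq[prev : r.anc_start])
        parts.append(r.der_seq)
        prev = r.anc_end
    parts.append(ancestral.seq[prev:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class LongRead:
    name: str
    seq: str
    chrom: str
    start: int  # source interval on the donor genome
    end: int


def _apply_read_errors(rng, seq: str, error_rate: float,
                       profile=(0.60, 0.25, 0.15)) -> str:
    """Indel-dominant sequencing errors (insert/delete/substitute shares)."""
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    kinds = rng.choice(3, size=len(hits), p=profile)
    parts = []
    prev = 0
    for pos, kind in zip(hits, kinds):
        parts.append(seq[prev:pos])
        base = seq[pos]
        if kind == 0:  # insertion before the base
            parts.append(BASES[rng.integers(4)] + base)
        elif kind == 1:  # deletion
            pass
        else:  # substitution
            alts = [b for b in BASES if b != base]
            parts.append(alts[rng.integers(3)])
        prev = pos + 1
    parts.append(seq[prev:])
    return "".join(parts)


def simulate_long_reads(
    genome: SequenceRecord | list[SequenceRecord],
    coverage: float = 20.0,
    mean_len: int = 8000,
    sigma: float = 0.35,
    min_len: int = 2000,
    max_len: int = 20000,
    error_rate: float = 0.01,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[LongRead]:
    """Long reads as error-bearing substrings; truth interval in the name."""
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    reads: list[LongRead] = []
    i = 0
    for rec in records:
        target_bp = coverage * len(rec)
        total = 0
        while total < target_bp:
            ln = int(np.clip(rng.lognormal(np.log(mean_len), sigma), min_len, max_len))
            ln = min(ln, len(rec))
            start = int(rng.integers(0, len(rec) - ln + 1))
            raw = rec.seq[start : start + ln]
            seq = _apply_read_errors(rng, raw, error_rate)
            name = f"read_{i}:{rec.name}:{start}-{start + ln}"
            reads.append(LongRead(name, seq, rec.name, start, start + ln))
            total += ln
            i += 1
    return reads


def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


@dataclass
class ReadPair:
    name: str
    r1: str
    r2: str
    chrom: str
    frag_start: int
    frag_end: int


def simulate_paired_end_reads(
    genome: SequenceRecord | list[SequenceRecord],
    coverage: float = 20.0,
    insert_mu: int = 400,
    insert_sd: int = 40,
    read_len: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[ReadPair]:
    """Proper-orientation (forward/reverse) pairs from the donor genome."""
    if insert_mu <= 2 * read_len:
        raise ValueError("insert_mu must exceed twice the read length")
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    pairs: list[ReadPair] = []
    i = 0
    for rec in records:
        n = int(coverage * len(rec) / (2 * read_len))
        for _ in range(n):
            ins = max(2 * read_len, int(round(rng.normal(insert_mu, insert_sd))))
            ins = min(ins, len(rec))
            start = int(rng.integers(0, len(rec) - ins + 1))
            frag = rec.seq[start : start + ins]
            pairs.append(
                ReadPair(
                    f"pair_{i}:{rec.name}:{start}-{start + ins}",
                    frag[:read_len],
                    revcomp(frag[-read_len:]),
                    rec.name,
                    start,
                    start + ins,
                )
            )
            i += 1
    return pairs


# ---------------------------------------------------------------------------
# decoy assemblies and simulator-side read mapping (for validation tests)
# ---------------------------------------------------------------------------

def make_decoy_assembly(
    derived: SequenceRecord,
    truth: list[TruthRecord],
    n_decoys: int = 20,
    size_range: tuple[int, int] = (500, 1000),
    min_dist: int = 5000,
    decoy_gap: int = 1500,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Implant fake SVs (assembly errors) at shuffled breakpoints.

    Decoys keep ``min_dist`` bp away from true variants — reads long
    enough to span a true SV must be able to do so without also crossing
    a decoy — and ``decoy_gap`` bp away from each other. Returns
    ``(assembly record, decoy truth records, CoordMap der->asm)``; decoy
    records carry assembly coordinates in ``der_start/der_end`` via the
    same TruthRecord convention (anc = derived genome here).
    """
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    gc = 0.42
    avoid = sorted(
        (r.der_start - min_dist, r.der_end + min_dist)
        for r in truth
        if r.kind in SV_KINDS
    )
    L = len(derived)
    decoys: list[TruthRecord] = []
    footprints: list[tuple[int, int]] = []
    tries = 0
    while len(decoys) < n_decoys and tries < 100000:
        tries += 1
        ln = int(rng.integers(size_range[0], size_range[1] + 1))
        s = int(rng.integers(min_dist, L - ln - min_dist))
        e = s + ln
        if any(a < e and s < b for a, b in avoid):
            continue
        if any(a - decoy_gap < e and s < b + decoy_gap for a, b in footprints):
            continue
        footprints.append((s, e))
        if rng.random() < 0.5:  # decoy insertion: assembly has extra sequence
            decoys.append(
                TruthRecord("DECOY_INS", derived.name, s, s,
                            der_seq=random_seq(rng, ln, gc))
            )
        else:  # decoy deletion: assembly lacks real sequence
            decoys.append(
                TruthRecord("DECOY_DEL", derived.name, s, e,
                            anc_seq=derived.seq[s:e])
            )
    decoys.sort(key=lambda r: r.anc_start)
    parts, prev, out_len = [], 0, 0
    for rec in decoys:
        parts.append(derived.seq[prev : rec.anc_start])
        out_len += rec.anc_start - prev
        rec.der_start = out_len
        parts.append(rec.der_seq)
        out_len += len(rec.der_seq)
        rec.der_end = out_len
        prev = rec.anc_end
    parts.append(derived.seq[prev:])
    assembly = SequenceRecord(derived.name, "".join(parts))
    return assembly, decoys, CoordMap.from_truth(decoys)


def simulate_duplication_pair_records(
    n_samples: int = 20,
    n_carriers: int = 8,
    region_len: int = 12_000,
    dup_start: int = 5_000,
    dup_len: int = 2_000,
    insert_mu: int = 400,
    insert_sd: int = 40,
    read_len: int = 100,
    pairs_per_sample: int = 900,
    chrom: str = "chr2L",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Paired-end records over a candidate tandem duplication.

    Carrier samples draw fragments from a genome in which
    ``[dup_start, dup_start + dup_len)`` is tandem-duplicated; reads are
    placed back onto single-copy reference coordinates, so fragments
    spanning the copy2->copy1 junction map with everted (divergent)
    orientation around the breakpoints. Returns
    ``(records per sample, carrier set, (chrom, b1, b2))``.
    """
    from .quantstats import PairOrientationRecord

    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    b1, b2 = dup_start, dup_start + dup_len
    carriers = {f"s{i}" for i in range(n_carriers)}
    sample_ids = [f"s{i}" for i in range(n_samples)]
    records: dict[str, list[PairOrientationRecord]] = {}

    def ref_pos(p: int, carrier: bool) -> int | None:
        """Reference coordinate of donor position p; None if junction-crossing."""
        if not carrier or p < b2:
            return p
        return p - dup_len  # positions in/after copy2 shift back by one unit

    for s in sample_ids:
        carrier = s in carriers
        glen = region_len + (dup_len if carrier else 0)
        recs: list[PairOrientationRecord] = []
        for _ in range(pairs_per_sample):
            ins = max(2 * read_len, int(round(rng.normal(insert_mu, insert_sd))))
            start = int(rng.integers(0, glen - ins + 1))
            r1 = (start, start + read_len)  # + strand
            r2 = (start + ins - read_len, start + ins)  # - strand
            mapped = []
            ok = True
            for a, b in (r1, r2):
                # the copy1->copy2 junction has no reference counterpart;
                # reads crossing it stay unmapped (copy2->flank maps fine)
                if carrier and a < b2 < b:
                    ok = False
                    break
                mapped.append(ref_pos(a, carrier))
            if not ok:
                continue
            p1, p2 = mapped
            plus_first = p1 <= p2
            implied = (p2 + read_len - p1) if plus_first else (p1 + read_len - p2)
            proper = plus_first and abs(implied - insert_mu) <= 6 * insert_sd + 50
            recs.append(
                PairOrientationRecord(s, chrom, p1, "+", p2, "-", proper)
            )
        records[s] = recs
    return records, carriers, (chrom, b1, b2)


def map_simulated_reads(
    reads: list[LongRead],
    assembly: SequenceRecord,
    coord_map: CoordMap | None = None,
    pad: int = 300,
):
    """Anchored alignment of simulated reads against an assembly.

    The read's true source interval (lifted through ``coord_map`` when
    the assembly differs from the donor genome) selects a target window;
    the read is then MEM-anchored and gap-filled against that window.
    Returns validation.ReadAlignmentRecord objects.
    """
    from .validation import ReadAlignmentRecord, align_read_to_window

    out = []
    for read in reads:
        t0 = coord_map.map(read.start) if coord_map else read.start
        t1 = coord_map.map(read.end) if coord_map else read.end
        w0 = max(0, t0 - pad)
        w1 = min(len(assembly), t1 + pad)
        window = assembly.seq[w0:w1]
        res = align_read_to_window(read.seq, window)
        if res is None:
            out.append(
                ReadAlignmentRecord(read.name, len(read.seq), assembly.name, -1, -1, [])
            )
            continue
        ops, tstart, tend = res
        out.append(
            ReadAlignmentRecord(
                read.name, len(read.seq), assembly.name, w0 + tstart, w0 + tend, ops
            )
        )
    return out
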