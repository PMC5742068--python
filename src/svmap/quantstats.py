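"""Downstream quantitative procedures.

Fisher's-method meta-analysis of replicate rank-sum tests, linear
temperature interpolation along a thermal-gradient bar, paralog-specific
expression with effective transcript lengths, and duplicate-allele
presence/frequency from divergently mapped read pairs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class MetaResult:
    statistic: float  # X = -2 * sum(ln p)
    df: int
    p_value: float
    neg_log10_p: float


def fisher_combine(pvals) -> MetaResult:
    """Combine independent p-values with Fisher's method.

    X = -2 * sum(ln p) is compared to a chi-square distribution with 2k
    degrees of freedom. ``neg_log10_p`` stays informative when the
    combined p underflows.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    p_comb = float(stats.chi2.sf(x, df))
    neg_log10 = float(-stats.chi2.logsf(x, df) / math.log(10))
    return MetaResult(x, df, p_comb, neg_log10)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples (n1 + n2 <= 12),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size + y.size <= 12 and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.pvalue)


@dataclass
class ProbeCalibration:
    positions_cm: list[float]
    temperatures_c: list[float]
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        temp = np.asarray(self.temperatures_c, dtype=float)
        if len(np.unique(pos)) < 2:
            raise ValueError("need at least two distinct probe positions")
        if np.ptp(temp) == 0:  # zero slope: constant gradient
            self.slope, self.intercept = 0.0, float(temp[0])
        else:
            fit = stats.linregress(pos, temp)
            self.slope, self.intercept = float(fit.slope), float(fit.intercept)


def positions_to_temperatures(calib: ProbeCalibration, fly_positions) -> list[float]:
    """Interpolate fly temperatures from the probe regression line."""
    return [calib.intercept + calib.slope * float(p) for p in fly_positions]


@dataclass
class ExpressionQuant:
    copy_id: str
    read_count: int
    transcript_len: int
    uncovered_len: int
    total_mapped_reads: int
    fpkm: float = float("nan")

    @property
    def effective_len(self) -> int:
        return self.transcript_len - self.uncovered_len


def paralog_fpkm(quants: list[ExpressionQuant]) -> list[ExpressionQuant]:
    """FPKM over copy-specific reads and effective transcript length.

    The effective length subtracts regions no copy-distinguishing read
    can cover; FPKM = count / (effective_kb * mapped_millions).
    """
    out = []
    for q in quants:
        if q.total_mapped_reads <= 0:
            raise ValueError("total mapped reads must be positive")
        eff = q.effective_len
        if eff <= 0:
            raise ValueError(
                f"{q.copy_id}: effective length {eff} <= 0; copy indistinguishable"
            )
        fpkm = q.read_count / ((eff / 1e3) * (q.total_mapped_reads / 1e6))
        out.append(
            ExpressionQuant(
                q.copy_id, q.read_count, q.transcript_len, q.uncovered_len,
                q.total_mapped_reads, fpkm,
            )
        )
    return out


@dataclass
class PairOrientationRecord:
    sample_id: str
    chrom: str
    pos1: int
    strand1: str
    pos2: int
    strand2: str
    proper: bool


@dataclass
class DuplicationFrequencyResult:
    presence: dict[str, bool]
    frequency: float
    n_carriers: int
    n_retained: int
    excluded: dict[str, str]  # sample -> reason


def _divergent_peak(
    records: list[PairOrientationRecord],
    breakpoints: tuple[int, int],
    region: tuple[int, int],
    w: int,
) -> tuple[int, float]:
    """Peak divergent-pair count near a breakpoint and background rate."""
    div_pos: list[int] = []
    for r in records:
        if not r.proper:
            div_pos.extend([r.pos1, r.pos2])
    peak = 0
    for b in breakpoints:
        n = sum(1 for p in div_pos if abs(p - b) <= w)
        peak = max(peak, n)
    far = [
        p for p in div_pos
        if all(abs(p - b) > w for b in breakpoints) and region[0] <= p < region[1]
    ]
    n_windows = max((region[1] - region[0]) / (2 * w) - len(breakpoints), 1.0)
    background = len(far) / n_windows
    return peak, background


def divergent_pair_duplication_call(
    records: dict[str, list[PairOrientationRecord]],
    candidate_region: tuple[str, int, int],
    samples: list[str] | None = None,
    w: int = 500,
    k_min: int = 3,
    r_min: float = 5.0,
    coverage_bp: dict[str, float] | None = None,
    min_coverage_bp: float = 10_000_000,
    ibd_pairs: list[tuple[str, str]] | None = None,
    populations: dict[str, str] | None = None,
    min_population: int = 10,
) -> DuplicationFrequencyResult:
    """Per-sample duplication presence and allele frequency.

    Divergent pairs are the complement of properly oriented pairs; a
    sample carries the duplication when the divergent-pair count within
    ±``w`` of a candidate breakpoint reaches ``k_min`` and exceeds
    ``r_min`` times the background rate. Samples with low aligned
    coverage on the chromosome, samples identical by descent to an
    earlier retained sample, and samples from populations smaller than
    ``min_population`` are excluded before the frequency is computed.
    """
    chrom, b1, b2 = candidate_region
    if samples is None:
        samples = sorted(records)
    excluded: dict[str, str] = {}
    if populations is not None:
        pop_sizes: dict[str, int] = {}
        for s in samples:
            pop_sizes[populations.get(s, "?")] = pop_sizes.get(populations.get(s, "?"), 0) + 1
        for s in samples:
            if pop_sizes[populations.get(s, "?")] < min_population:
                excluded[s] = "small_population"
    if coverage_bp is not None:
        for s in samples:
            if s not in excluded and coverage_bp.get(s, 0.0) < min_coverage_bp:
                excluded[s] = "low_coverage"
    if ibd_pairs:
        retained_so_far: set[str] = set()
        ibd = {frozenset(p) for p in ibd_pairs}
        for s in samples:
            if s in excluded:
                continue
            if any(frozenset((s, t)) in ibd for t in retained_so_far):
                excluded[s] = "ibd"
            else:
                retained_so_far.add(s)
    retained = [s for s in samples if s not in excluded]
    if not retained:
        raise ValueError("no samples retained; frequency undefined")
    pad = 5 * w
    region = (max(0, b1 - pad), b2 + pad)
    presence: dict[str, bool] = {}
    for s in retained:
        recs = [r for r in records.get(s, []) if r.chrom == chrom]
        peak, background = _divergent_peak(recs, (b1, b2), region, w)
        presence[s] = peak >= k_min and peak >= r_min * max(background, 1e-9)
    carriers = sum(presence.values())
    return DuplicationFrequencyResult(
        presence, carriers / len(retained), carriers, len(retained), excluded
    )
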