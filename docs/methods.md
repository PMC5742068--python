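# Methods

## Anchoring and chaining

Exact-match anchoring uses packed 2-bit k-mers (k = min(minimum match
length, 31)); runs of consecutive seed hits on one diagonal are in
one-to-one correspondence with maximal exact matches of at least k bp,
so MEMs are enumerated without extension heuristics. `N` never matches
anything — not even another `N` — and masked positions are treated like
`N` for anchoring. Reference-uniqueness of a match is checked by direct
substring comparison at every other occurrence of its leading k-mer.

Chaining treats "separation" as max(reference gap, query gap) between
consecutive matches and "diagonal drift" as |reference gap − query gap|;
an edge requires separation ≤ s (default 200 bp) and drift ≤ f ×
max(separation, 1) (default f = 0.12). Chains are extracted iteratively
by total matched length (dynamic programming over the sorted matches),
each match joining at most one cluster; chains under l = 100 matched bp
are discarded. Ties break toward the leftmost reference, then query,
coordinate. The upstream tooling this mirrors does not document its
clustering internals, so these definitions are this package's contract,
fixed here and tested against constructed cases.

## Base-level filling

Cluster intervals are resolved to base level with an affine-gap global
aligner (match +1, mismatch −1, gap open −2, gap extend −0.5; a gap of
length g costs −2 − 0.5 g). Intervals whose DP matrix fits in 10⁶ cells
get one unconstrained Gotoh alignment (row-vectorised, with the
prefix-max trick for in-row gap opening; all scores are exact multiples
of 0.5, so float comparisons in the traceback are exact). Larger
intervals are solved piecewise: anchor columns are fixed as matches
(anchors are exact, and overlapping anchors are trimmed, which preserves
exactness) and each inter-anchor gap gets its own full DP. The chaining
constraints bound those gaps, so the piecewise path is fast and, on the
tested scales, score-identical to the unconstrained optimum.

## One-to-one resolution

Collinear clusters separated by sub-SV gaps (< 100 bp on both genomes)
are first joined, so SNPs and < 100-bp indels are resolved per column
inside one block while ≥ 100-bp gaps remain block boundaries. Several
chains are kept open during joining because repeat cross-matches and
duplication copies interleave with the orthologous chain in reference
order.

Conflicts between blocks are then resolved by weight-ordered claiming:
heavier clusters claim their reference and query spans, lighter clusters
are trimmed at the ends where they re-align already-claimed sequence.
Trimming, rather than dropping, matters: at a tandem duplication the
second copy's cluster overlaps the first on the reference, and dropping
it would leave everything downstream of the duplication unanalysed.
A trimmed block boundary can land exactly on a small indel, so residual
sub-SV gaps between adjacent blocks are re-aligned and called per column
afterwards (`call_junction_small_variants`).

Indel and inversion calling further restrict the block list to a
maximum-weight chain collinear in both genomes (per sequence pair).
Stray blocks — e.g. a deleted reference TE copy aligned to a
non-orthologous query copy — are off this backbone and would otherwise
break the adjacency on which gap classification relies.

The standalone `filter_mutual_best` keeps the delta-filter-like
contract: exact maximum-weight conflict-free subset up to 16 blocks
(verified against subset enumeration), greedy by descending weight
beyond; a query-axis-only mode serves the scaffolder's mutually-best
assignment.

## SV classification choices

- CNV gains report the duplicated reference unit as their interval;
  losses (duplications on the reference side) report the first retained
  copy and carry all copy intervals, because retained copies may be
  dispersed.
- Copy-number verification chains candidate anchors per genome: a new
  copy starts when the genome-side gap exceeds qco (10 kb) or the
  candidate coordinate fails to progress; a copy counts when it covers
  ≥ 1 − rco (80%) of the candidate; counts are capped at c = 500. Equal
  counts in both genomes mark a false positive. Copies overlapping by
  more than half their span (opposite-strand chains over one locus) are
  merged; tandem copies abutting by a few bases stay distinct.
- Query-interval disjointness in the gain rule tolerates up to 50 bp of
  overlap: junction microhomology routinely makes the flanking anchors
  of adjacent copies overlap by a few bases.
- CNV calls whose duplicated sequence is ≥ 80% covered by the repeat
  annotation are removed from the catalog (dispersed-repeat turnover,
  not locus duplication); the same 80% threshold classifies insertions
  and deletions as TE vs. non-TE, boundary inclusive. Insertion TE
  status needs an annotation for the query genome (the simulator emits
  one); without it, calls default to non-TE with a warning.
- Indel calls whose footprint overlaps a verified CNV or an inversion
  are suppressed — a tandem duplication also leaves an insertion-like
  gap at the extra-copy junction and must not be reported twice.
- Indels are left-normalised (shifted left while the preceding base
  equals the payload's last base), the standard canonical form.

## Simulator

The generator emulates a repeat-bearing genome pair at desk scale:
a 500-kb ancestral chromosome at GC 0.42 carrying 30 TE copies from a
4-family library (one family LTR-bearing, 300-bp terminal repeats;
family lengths 0.8–4 kb), each ancestral copy diverged 2% from its
family consensus — dispersed identical repeats would otherwise leave
no unique anchors inside TEs. The derived genome carries 20 TE
insertions (new copies at 1% divergence), 10 non-TE insertions
(0.1–2 kb), 20 deletions (half of them whole ancestral TE copies), 10
tandem duplications of unique sequence (0.3–4 kb; 5 with a 1–2-kb spacer
cut from the LTR family, echoing the Accord-fragment geometry between
duplicated Cyp28d1 copies), 5 inversions (0.5–5 kb), SNPs at 0.5% and
small indels (≤ 30 bp, geometric lengths) at 0.05% per bp. Variant
footprints stay ≥ 2.5 kb apart (so 2-kb complex-event merging cannot
collapse distinct truth records), ≥ 5 kb from chromosome ends, and SNPs
/ small indels keep 25 / 150 bp clear of SV breakpoints so that every
breakpoint is flanked by anchorable sequence — real breakpoints are not
always this clean, which is part of what passing tests do *not* show
about real data. Applying the truth records to the ancestral genome
reproduces the derived genome byte-for-byte, and all randomness flows
from one seed.

Long reads are substrings with log-normal lengths (mean 8 kb, clipped to
2–20 kb) and indel-dominant errors (60% insertion / 25% deletion / 15%
substitution of a 1% budget — the corrected-long-read regime). Paired
ends are proper forward/reverse fragments (insert 400 ± 40 bp).

The validation experiment implants decoy SVs (0.5–1-kb insertions or
deletions) into the assembly under test at shuffled breakpoints ≥ 5 kb
from any true variant; reads simulated from the true genome then refuse
to span a decoy cleanly, while correctly assembled variants validate.
Decoys closer than a read length to a true SV would contaminate the true
SV's spanning reads, which fixes the 5-kb floor. Simulated reads are
mapped by the package's own anchored aligner (truth-interval liftover
selects a window; MEM chaining with permissive drift keeps SV-scale gaps
in one chain; read ends beyond the outermost anchors are aligned by
bounded DP with the window side free), so the whole loop runs offline.

The duplicate-frequency experiment models 20 samples, 8 carrying a
2-kb tandem duplication, 900 fragments each over a 12-kb region: carrier
fragments spanning the copy2→copy1 junction map back to single-copy
coordinates with everted orientation, producing the divergent-pair peaks
at the breakpoints that the caller thresholds (window ±500 bp, ≥ 3
pairs, ≥ 5× background — thresholds exposed as parameters because the
published procedure states only "clear peak and high signal-to-noise").

## Numerical and statistical notes

- `rank_sum_test` delegates to scipy's Mann–Whitney U (exact method for
  tie-free samples with n₁+n₂ ≤ 12, tie-corrected normal approximation
  otherwise); the test suite checks it against full permutation
  enumeration for every tie-free rank pattern up to n₁+n₂ = 12.
- `fisher_combine` reports both the χ²₂ₖ tail probability and
  −log₁₀ p from the log survival function, which stays informative when
  the tail underflows double precision.
- Probe calibration fits ordinary least squares; an all-equal
  temperature vector short-circuits to a zero-slope line.
- The duplicate-frequency estimator excludes samples below 10 Mb of
  aligned bases on the carrying chromosome, samples identical by descent
  to an earlier retained sample (from a supplied pair table), and
  populations under 10 samples, before frequency = carriers / retained.

## Problem sizes and limitations

Default experiment sizes — 500-kb genomes, 20× long reads, 65 implanted
SVs, 10–20 decoys, 20 paired-end samples — run the full acceptance
sweep in a few minutes on one core; the anchoring engine is in-memory
numpy and is not meant for >100-Mb genomes. Other known limits: the
simulator is haploid (no heterozygosity, no signal-level read model);
inversion calls require forward flanking blocks, so inversions at
sequence ends are not callable; ancestral-state polarisation against an
outgroup is not modelled (variant polarity is reported per genome
explicitly); and the validation aligner uses the simulator's truth
liftover for window selection, so it is a simulation tool, not a general
read mapper — SAM from any aligner is the production input.
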