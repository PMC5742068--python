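# svmap

Structural-variant discovery from whole-genome alignment of two
assemblies, with a comparative scaffolder, long-read SV validation, a
truth-bearing genome/read simulator, and the small statistical
procedures that typically accompany such a study.

## The problem

Short-read callers miss a large share of the structural variation
between two genomes — tandem duplications hidden in complex repeats,
transposable-element (TE) insertions next to other TEs, indels longer
than a library insert. When high-quality assemblies of both genomes
exist, the variation can instead be read directly out of a pairwise
whole-genome alignment. `svmap` implements that route:

1. **Anchoring.** Maximal exact matches (MEMs) of length ≥ 20 that are
   unique in the reference are found between the two assemblies.
2. **Chaining.** MEMs are chained into collinear clusters: consecutive
   matches may be separated by at most *s* = 200 bp with diagonal drift
   at most *f* = 0.12 × separation, and a chain must carry ≥ *l* = 100
   matched bp (so duplications of 100 bp and longer are detectable).
3. **Classification of disagreements.**
   - *CNV gain*: two clusters whose **reference** intervals overlap by
     ≥ 100 bp while their **query** intervals are disjoint — the overlap
     is duplicated in the query. Candidates are re-verified by aligning
     the putatively duplicated sequence back to both genomes and
     counting copies (copy caps and tolerances *c* = 500,
     *qco* = 10 kb allowed insertion within a copy, *rco* = 0.2 allowed
     unaligned fraction); candidates with equal copy number in both
     genomes are rejected. CNVs within 2 kb are merged into complex
     events for counting; affected bp are totalled before merging.
   - *Indels (> 100 bp)*: a gap between adjacent one-to-one synteny
     blocks that exceeds 100 bp in one genome while the other genome's
     gap is < 10% of it.
   - *Inversions*: reverse-orientation blocks flanked by forward
     synteny; reversed TE copies are filtered out by the repeat
     annotation.
   - *SNPs and < 100-bp indels*: per-column calls inside the one-to-one
     blocks, after base-level gap filling with an affine-gap DP.
4. **Validation.** Long reads mapped to the assembly carrying a variant
   must span it with ≥ 250 bp aligned flanks. Per read,
   `P_aligned` = aligned bases / read length and `R_gaps` = gap columns
   / read length. *Stringent*: ≥ 2 fully spanning reads with
   `P_aligned` ≥ 0.995 and `R_gaps` < 0.005. *Standard*: ≥ 2 fully
   spanning reads at `P_aligned` ≥ 0.975 / `R_gaps` < 0.025, or ≥ 2
   breakpoint-overlapping reads per side at stringent quality.
5. **Scaffolding.** Contigs are assigned to chromosome arms by mutually
   best alignment (a contig needs ≥ 40% of its aligned bases on one
   arm), ordered by the first non-overlapping alignment start, oriented
   by majority strand, and joined with exactly 100 Ns; unplaced contigs
   keep their sequence under a `U` prefix.

Companion statistics: Fisher's method (X = −2Σln *p* vs. χ² with 2*k*
df) for combining replicate Wilcoxon rank-sum tests; linear temperature
interpolation along a thermal-gradient bar; paralog-specific FPKM with
effective transcript length (transcript length minus regions no
copy-distinguishing read can cover); and duplicate-allele frequency from
the density of divergently mapped read pairs at candidate breakpoints,
with low-coverage / identity-by-descent / small-population exclusions.

## Worked example

```python
import numpy as np
from svmap.synthetic_data import SimulationConfig, simulate_ancestral_genome, apply_variants
from svmap.sv_discovery import RepeatAnnotation
from svmap.pipeline import call_svs

cfg = SimulationConfig(seed=7, genome_length=120_000, n_ancestral_te=8,
                       te_insertions=4, non_te_insertions=3, deletions=5,
                       tandem_dups=3, dups_with_spacer=2, inversions=2)
rng = np.random.default_rng(cfg.seed)
ancestral, repeats, library = simulate_ancestral_genome(cfg, rng)
derived, truth, derived_repeats = apply_variants(ancestral, repeats, library, cfg, rng)

catalog = call_svs([ancestral], [derived],
                   repeats_ref=RepeatAnnotation(repeats),
                   repeats_qry=RepeatAnnotation(derived_repeats))
print(catalog.counts)
```

prints

```
{'DEL_nonTE': 3, 'INS_nonTE': 3, 'CNV_GAIN_QRY': 3, 'DEL_TE': 2, 'INV': 2, 'INS_TE': 4}
```

— all 17 implanted SVs of this 120-kb toy pair, split by class and TE
status (the two TE deletions are ancestral TE copies removed from the
derived genome). One of the gains is a spacered tandem duplication; its
call carries the duplicated reference unit, the copy intervals, and the
spacer:

```python
dup = next(c for c in catalog.calls if c.sv_type == 'CNV_GAIN_QRY' and c.spacer)
print(dup.ref_start, dup.ref_end, dup.length, dup.spacer,
      (dup.copy_report.copies_ref, dup.copy_report.copies_qry))
# 20727 22753 2026 (21822, 23358) (1, 2)
```

i.e. a 2,026-bp unit duplicated in the query (1 copy in the reference,
2 in the query) with a 1,536-bp spacer between the copies.
`catalog.small_variants` holds the 468 SNPs and < 100-bp indels of the
same comparison. The same pipeline is available from the shell:

```bash
svmap simulate --seed 7 -o sim/
svmap call --ref sim/ancestral.fa --qry sim/derived.fa \
           --repeats sim/repeats.bed --repeats-qry sim/repeats_derived.bed -o out/
svmap stats fisher 2.12e-10 6.76e-10 1.89e-6 9.21e-14 1.96e-6 1.25e-24
# {"statistic": 309.53..., "df": 12, "p": 4.67e-59, "neg_log10_p": 58.33}
```

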