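# Methods

## The data model

The package operates on *fragment files*: BED-style tables of deduplicated
tagmentation events with 0-based half-open coordinates, a cell barcode and a
chromatin-target label (one file per target). A fragment is "unique" by its
`(chrom, start, end, cell, target)` key — the target label is part of the
key because the profiled targets are separate assays that happen to share a
cell, and identical coordinates arising from two different antibodies are
distinct biological events. Deduplication sums duplicate counts, so total
duplicate mass is conserved and the operation is idempotent.

Cells enter analysis only if they carry at least `min_unique` (default 100)
unique fragments for *every* required target; the threshold can be relaxed
per target (a sparse mark such as H3K36me3 otherwise dominates cell loss).
Per-cell pass rates are monotone non-increasing in the threshold.

Gene test windows run from 1 kb upstream of the farthest-distal annotated
TSS to the TES, strand-aware (`[start−1000, end)` for `+` genes,
`[start, end+1000)` for `−` genes, clipped at 0). Any ≥ 1 bp overlap counts;
a fragment spanning two windows counts for both.

## Poisson gene-enrichment test

For cell *i*, gene *g*, target *t*: `r` = unique overlapping fragments,
`L_i` = the cell's median fragment length (bp), `f_i` = fragments mapping in
the cell (computed per target by default; a pooled mode exists),
`L_gene` = window length, `L_genome` = total reference length (the sum of
the genome-sizes table — effective non-N length is not distinguished).

```
x   = r·L_i / L_gene      observed mean per-bp coverage depth over the gene
μ_i = L_i·f_i / L_genome  expected per-bp coverage genome-wide
p   = P(Poisson(μ_i) ≥ ⌈x⌉)
```

This is the only reading under which the observed statistic and the Poisson
mean share units (per-bp coverage depth). Because Poisson support is
integral and `x` generally is not, the upper tail is evaluated at `⌈x⌉`
(so `r = 0 ⇒ x = 0 ⇒ p = 1` exactly); a continuous-tail alternative using
the regularized incomplete gamma function `P(X ≥ x) = P(x, μ)/Γ(x)` is
implemented (`method="continuous"`) and agrees at integer `x`. Tails are
computed by scipy's survival functions, which work in log space, so p-values
like 10⁻¹⁴ do not underflow.

One Benjamini–Hochberg step-up correction spans the **full grid** of
(observed cell, gene, target) triples in a run — triples with no overlapping
fragments enter with `p = 1` — and a triple is called enriched when
`q < α` (strict; default α = 0.01).

A consequence worth knowing when designing experiments or simulations:
`E[x] = multiplier · μ_i`, so detecting an enrichment requires appreciable
coverage *depth* over the gene (x of ~3–5, i.e. tens of overlapping
fragments when `L_gene/L_i ≈ 40`), not merely a handful of overlapping
fragments. At shallow depth the ceiling collapses r = 1 and r = 5 onto the
same `⌈x⌉ = 1` and they are indistinguishable.

## Derived co-occurrence statistics

- **Normalized counts**: per-cell counts scaled to 10⁴ total per target
  (`norm = r·10⁴/f_i`), used for heat-map-style outputs and bivalency.
- **Bivalency score**: for each cell, a gene is in a *bivalent context* when
  the repressive target (H3K27me3) and ≥ 1 active target (H3K4me1/2 or
  H3K36me3) are both flagged enriched in that gene; the score sums the
  normalized counts of every enriched mark over those genes. Cells with no
  bivalent gene score 0.
- **Cramér's V**: per cell and target pair, the 2×2 table over genes
  (enriched for a? × enriched for b?); `χ²` without continuity correction;
  `V = sqrt(χ²/n)` (for a 2×2 table `min(k,c)−1 = 1`). Any zero marginal —
  common in sparse cells — yields `V = 0` with a degenerate flag rather than
  NaN, keeping per-cell summaries deterministic.
- **Target proportions**: per-cell unique-read fractions per target; rows
  sum to 1; zero-read cells are excluded with a warning.

## Cell typing (LSI)

Fragments of one target are counted in fixed windows (default 50 kb; a
fragment counts in every window it overlaps, final partial window kept).
The top `keep_frac` (default 40%) of windows by aggregate count are kept,
ties at the cutoff broken by genomic coordinate for determinism. The
transform is `ln(1 + 10⁴ · TF · IDF)` with `TF_ij = c_ij/colsum_j` and
`IDF_i = N/n_i`; this is the common LSI form (the transform is configurable
via `scale`), and it makes the result invariant to per-cell depth scaling.
All-zero windows are dropped before IDF; a cell with zero counts in the
selected windows is an error naming the cell.

SVD retains every dimension whose singular value exceeds `retain_frac`
(default 0.2%) of the sum of all singular values — the first dimension is
*not* dropped, unlike some LSI conventions, because the retention rule alone
decides. Fewer than two retained dimensions triggers a fallback to the top
two with a warning. Per-cell coordinates are `d_j·V[:,j]`. k-means (10
restarts, fixed seed) runs on the retained SVD coordinates, not on the 2-D
UMAP projection — the projection is for visualisation only. NMI uses
natural-log mutual information normalized by the arithmetic mean of the two
entropies (`max`/`min`/`geometric` variants available).

Multi-target integration is deliberately simple: each target's retained
coordinates are standardized to unit total variance, weighted (default
equal) and concatenated; graph-based weighted-nearest-neighbor integration
is out of scope.

## Species mixing

Species is assigned per chromosome (explicit map or name-prefix rules,
e.g. `hg19_ → human`); per-cell counts pool all targets, since collision
calls concern the barcode, not a single assay. A cell is a collision iff
its majority-species fraction is **strictly** below the threshold (default
0.90). Display rounding is half-up to one decimal; machine output keeps the
raw rate. The QC filter is applied before the collision statistic by
default (`--no-qc` disables it).

## Group and trajectory comparisons

The low/high split on a target's per-cell read fraction uses the median,
with cells exactly at the median assigned to the low group (deterministic);
quantile and fixed-threshold modes exist. Differential enrichment per gene
is `LFC = log2((mean_low+ε)/(mean_high+ε))` with ε = 1 on the 10⁴-scaled
normalized counts, plus a two-sided pooled-variance t-test, uncorrected (by
design: these comparisons are reported per gene). Two constant equal groups
give `p = 1` with a degenerate flag.

Trajectory evaluation consumes externally inferred pseudotime (inference
itself is out of scope). Misassignment frequency is misassigned/total per
correct trajectory and pooled. Inversion frequency is formalized as the
pairwise (Kendall-style) discordance fraction: over all cell pairs with
distinct known timepoints, the fraction whose pseudotime order contradicts
the timepoint order, pseudotime ties counting ½. It is 0 iff pseudotime is
weakly monotone in timepoint, 1 when fully reversed, and invariant under
strictly monotone transforms of pseudotime.

## Synthetic data generator

`simulate_experiment` emulates the statistical skeleton of a multi-target
single-cell experiment: fragment *midpoints* are placed uniformly on a
single simulated chromosome at `background_rate` (fragments/bp/cell/target)
and uniformly on enriched gene windows at `multiplier ×` that rate
(`start = ⌊mid − len/2⌋`, symmetric overlap behaviour); lengths are normal
(mean 250, sd 80), resampled into [30, 1000] bp; per-cell depth is a
log-normal multiplier (μ = 0, σ = 0.5) on all rates, reproducing the
heavy-tailed unique-read distributions the 100-fragment filter targets.
Background defaults to 5×10⁻⁵/bp (≈ 500 fragments per cell per target on a
10 Mb genome — a realistic per-cell, per-mark unique-read count for this
assay class). `simulate_species_mix` makes each barcode a doublet with the
configured probability, splitting its reads Binomial(n, ½) between species
(`hg19_chr1` vs `mm10_chr1`); singlets carry Binomial(n, 0.002)
cross-contamination, keeping their majority fraction ≥ 99%.

What the generator does **not** model: read-level errors or alignment,
antibody cross-reactivity and adapter crossover, chromatin domain structure
(background is uniform), copy-number or mappability variation, per-target
efficiency differences (exposed as a knob, but no canonical values exist),
and doublets *within* a species. Passing recovery tests therefore
demonstrates the statistical machinery is correct under its stated model,
not that real data meet the model's assumptions.

## Problem sizes and numerical choices in the test/acceptance runs

- Barnyard recovery: 2,000 cells × 1,000 reads, planted doublet rate 0.10;
  the estimate is checked against a 3-binomial-SE band.
- Enrichment recovery: one cell type × 100 cells, 2 Mb genome, 10 genes of
  10 kb, background 10⁻³/bp (≈ 2,000 fragments/cell), multiplier 20 on five
  genes. This puts the expected gene coverage depth at
  `E[x] = 20·μ ≈ 5`, the regime where the ceiling-discretized tail is
  informative; recall is required ≥ 90% and the flagged fraction of a
  nothing-planted run ≤ α within 3 SE.
- Cell typing: 2 types × 200 cells, 10 Mb genome, ≈ 500 fragments/cell,
  eight disjoint (or identical, for the uninformative control) genes at
  multiplier 50; NMI ≥ 0.95 informative, ≤ 0.2 uninformative.
- Closed-form oracles: Poisson tail vs direct pmf summation over
  μ ∈ {0.001, 0.02, 1, 10} × k ∈ {0…20}; BH vs a hand-applied step-up;
  Cramér's V vs an independent χ² implementation on 100 random tables;
  NMI identity/independence/hand-computed cases; SVD reconstruction to
  1e−8 and the retention rule on singular values (10, 5, 1, 0.02) → 3 dims.

## Known limitations

- `count_gene_overlaps` and `peak_target_purity` loop over windows/peaks;
  fine for gene panels and synthetic data, not tuned for 20k-gene × 100k-cell
  runs.
- The Poisson test treats the genome-wide rate as uniform; regions of
  atypical background (repeats, CNVs) will inflate calls on real data.
- UMAP determinism holds for a fixed seed and library version; coordinates
  are not stable across umap-learn releases (cluster labels and NMI are).
- The inversion-frequency estimator is one reasonable formalization of
  "timepoints out of order"; bin-ordering alternatives would differ in
  detail.
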