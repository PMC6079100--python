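# Methods

This note documents the models behind each component, the defaults and
why they were chosen, what the simulators do and do not emulate, and the
numerical conventions that matter for reproducing results.

## Sorted reporter screen

### Generative model

A library of `G = n_genes × guides_per_gene + n_control_guides` guides
is delivered at one guide per cell; `cells_per_guide` (default 200,
the infection redundancy) times `G` cells are assigned to guides by a
multinomial draw over a uniform library composition (an optional
log-normal `abundance_jitter_sd` models library skew; off by default,
since sequenced libraries are typically even to within one order of
magnitude).  Each cell's reporter fluorescence is Gaussian:

```
reporter ~ Normal(effect(gene), reporter_sd)
```

with the effect in reporter-SD units.  The Gaussian is the minimal model
supporting tail sorting; nothing is claimed about the real reporter's
dynamic range, and sorter noise is not modelled (sorting is exact rank
truncation of the bottom/top `sort_fraction`, default 1%).  Control
guides (targeting the reporter tag itself) get a strong negative effect,
default −5 SD.  Each of the three samples — unsorted, low, high — is
sequenced as one multinomial of `sequencing_depth` reads (default 10⁶)
over its population's guide composition, so each sample's counts sum
exactly to the depth.  PCR amplification bias and infection multiplicity
are deliberately not modelled.

At the default design the dominant noise source is tail-composition
sampling: with 1% tails a null guide contributes ~2 cells to each tail
(Poisson-like, CV ≈ 70%), dwarfing sequencing noise at depth 10⁶. This
is why gene-level aggregation over independent guides (RSA) is needed
at all.

### Counting and enrichment

Reads carry the guide as their first 20 bases; counting is exact
prefix matching (zero mismatches, forward strand), making
`counts_to_fastq → count_reads` an exact inverse pair.  Normalization is
`(c + 1)/T` with `T` the raw assigned-read total of the sample —
unassigned reads are excluded from the denominator.  The pseudocount
keeps enrichments finite; doubling all counts changes enrichments only
through the pseudocount (relative effect < 1% at realistic counts).

### RSA statistic

All `N` guides are ranked by the enrichment of the analysed tail
population versus unsorted, most enriched first, in both directions —
the "low" direction ranks the low-tail enrichment and the "high"
direction the high-tail enrichment.  Ties receive the worst (largest)
rank of their block, so pseudocount-induced ties cannot inflate
significance.  For a gene with guides at ranks `r_1 < … < r_n`, each
prefix `i` gets the hypergeometric tail `p_i = P(X ≥ i)`,
`X ~ Hypergeom(N, n, r_i)`, and the gene score is `p_min = min_i p_i`
with `logP = log10 p_min`.  No multiplicity correction is applied across
prefixes (the classical definition), and the optional activity bounds of
the original implementation are exposed but disabled by default.

**Calibration caveat (a real property, not a defect).**  Because
`p_min` is a minimum of `n` dependent tail probabilities, each roughly
uniform marginally, `P(p_min < α) > α` under the null: Monte-Carlo with
six exchangeable guides gives ≈ 4.6% of null genes below α = 0.01.
`p_min` is therefore a ranking score rather than a calibrated p-value;
the fixed α = 0.01 hit threshold should be read accordingly.  In screens
with strong planted effects the false-hit rate among null genes drops
(≈ 2% in the recovery battery) because true hits occupy the top ranks.

### Hit filters

`call_hits` uses strict `p_min < α`; `expression_filter` removes genes
with RPKM below 1 (absent genes count as unexpressed and are logged);
`signature_from_de` applies strict `log2FC > 1` and `FDR < 0.05`.

## BioID differential abundance

### Chain and rules

Two groups of three replicates on the log2 LFQ scale.  A protein is
dropped only when it has fewer than two observed values in *both*
groups.  A missing cell is MNAR when its group has ≥ 2 of 3 missing and
the other group is fully observed; every other missing cell — including
mixed patterns like (2 missing, 1 missing) — is MAR.  MAR is the
conservative fallback because MinDet injects extreme values.  MinDet
imputes the minimum observed value of the cell's sample column; kNN
(default k = 10, the conventional default) imputes the mean over the k
nearest proteins by Euclidean distance on mutually observed entries,
restricted to neighbours observed at the target column, ties broken by
protein order.  Quantile normalization maps every column onto the vector
of row-means of sorted columns, with ties broken by stable original
order so that the sorted value vectors of all columns are *exactly*
identical afterwards (rank-averaging would break this defining
property).

### Moderated t

The pooled within-group variance `s_g²` (d_g = n₁ + n₂ − 2 df) is
shrunk toward a scaled-F prior fitted by the method of moments on
`log s_g²`: with `e = log s² − digamma(d_g/2) + log(d_g/2)`,
`d0 = 2·trigamma⁻¹(var(e) − trigamma(d_g/2))` and
`s0² = exp(mean(e) + digamma(d0/2) − log(d0/2))`; `var(e)` at or below
the pure-sampling value yields `d0 = ∞` and `s̃² = s0²` everywhere.
The statistic is `t = Δ/(s̃·√(1/n₁+1/n₂))` with `d0 + d_g` df.  The
trigamma inverse uses Newton iteration.  The test suite checks this
against a brentq-based straight-line reimplementation (1e-6) and
against R limma's `eBayes` on the same matrix.  FDR control is
Benjamini–Hochberg, a deterministic standard in place of density-based
local-FDR estimators whose exact flavour is under-specified;
alternative methods are accepted by the interface.

### Generator and calibration findings

`simulate_lfq_experiment` draws protein baselines from N(25, 3) (log2
LFQ scale), replicate noise SD 1, and enriched proteins gain
`effect_log2` in the bait group.  Dropout is detection-limit censoring:
cells below the `mnar_threshold_quantile` (default 0.15) quantile of
all true values are dropped with probability 0.9, plus uniform MAR
dropout at rate 0.05 — roughly 18% total missingness, typical of
affinity-proteomics matrices.  Truth records the mechanism of every
missing cell.

Two honest limitations of the published chain show up in calibration
batteries and are worth knowing:

* **MinDet inflates the null rejection rate.**  Null proteins near the
  detection limit occasionally present an MNAR-looking pattern by
  chance; imputing the column minimum then fabricates a large group
  difference with small variance.  At the generator defaults the
  full-chain type-I error is ≈ 0.075–0.08 at nominal 0.05 (it is ≈ 0.05
  on complete matrices).
* **Quantile normalization attenuates one-sided signal.**  When 10% of
  proteins genuinely rise in one group, forcing identical column
  distributions absorbs part of the shift: a planted log2FC of 2 is
  recovered as ≈ 1.78.  Combined with the 3-vs-3 design (standard error
  √(2/3) ≈ 0.82 on Δ), BH-significant recovery of a 4-fold effect at
  SD 1 is weak: the theoretical ceiling at BH-FDR 0.05 with 10%
  prevalence is ≈ 36% sensitivity even before attenuation, and the
  measured value is ≈ 7–10%.  Recovery batteries therefore run on
  complete matrices to isolate the testing machinery; the imputation
  rules are validated separately against the generator's mechanism
  labels.  Strong BioID preys (≥ 8-fold, or absent in controls) are
  detected reliably, which is the regime the design targets.

## Cohort signature scoring and survival

### Score

Genes are z-scored across the cohort (ddof = 1; zero-variance genes get
z = 0); within a sample, genes are ranked by decreasing z with stable
ties.  For a signature of m genes at ranks `r_1 < … < r_m` among N:

```
D+ = max_i ( i/m − (r_i − 1)/N ),   D− = max_i ( r_i/N − (i − 1)/m )
D  = D+  if D+ ≥ D−  else  −D−
```

an unweighted signed KS statistic in [−1, 1]; being rank-based it is
invariant under strictly monotone transforms of one sample's values.
The per-sample scorer is deliberately unweighted — the simplest member
of the GSEA family — and this choice is flagged as such.  A repressor's
activity is −D(repressed targets); an effector's is +D(induced set).

### Generator

Latent activities are standard bivariate normal with correlation −0.85
by default; signature genes load ±1.0 on their activity with unit noise
(unit loading = selected strong responders; chosen once a priori).
Survival is exponential with log-hazard `log(HR_per_SD) × trps1-axis
activity` (high activity → worse outcome), censored by an independent
uniform time calibrated by root-finding to the requested censor
fraction (default 0.2).  The KS scorer recovers the latent axes at
r ≈ 0.97 per axis; the remaining attenuation plus the Spearman-
versus-Pearson gap lands the recovered activity correlation at ≈ −0.78
for a planted −0.85 at n = 500.  The generator does not model subtype
structure in expression, gene–gene correlation beyond the two planted
axes, or non-proportional hazards.

### Survival comparison

Kaplan–Meier product-limit curves per stratum (via lifelines) and the
log-rank test — the standard 1-df chi-square comparison of survival
curves.  Quartile stratification marks samples strictly above the
linear-interpolation Q3 as "high".  The test suite pins the log-rank
statistic to a textbook observed-minus-expected/hypergeometric-variance
oracle at 1e-8.

### Rank-sum test

Exact enumeration when the smaller sample has ≤ 8 observations and
there are no ties (where the null distribution is exact); otherwise the
normal approximation with tie and continuity corrections.  The two
paths agree to < 0.02 at n = 8 per group.

## Interval association

Coordinates are 0-based half-open everywhere; a summit is the stated
summit column or the floor midpoint.  Summit-in-region containment uses
interval trees; a summit in both a promoter and an enhancer is classed
promoter.  Overlap significance is an upper-tail hypergeometric over an
explicit region universe — the universe is a required argument because
enrichment claims are meaningless without one.  TSS assignment uses
inclusive absolute distance (≤ 50 kb default), strand-agnostic.
Fragments split at insert size < 146 bp (sub-nucleosomal) versus
≥ 146 bp.  The interval generator plants an exact number of summits
inside regions (round(fraction × n_peaks)) with the rest
rejection-sampled strictly outside, so overlap counts are known by
construction.

## Problem sizes and determinism

All generators consume a single `numpy` Generator seeded per call; no
global state.  Batteries in the test suite and acceptance script use:
1000-gene × 6-guide screens at depth 10⁶ (5 recovery seeds, 10 null
seeds), 2000–2500-protein LFQ matrices (3 seeds per battery),
500-patient cohorts (3 seeds) and 100 survival-power seeds at n = 300 —
sizes at which every recovery/calibration estimate has a standard error
well below the width of the band it is checked against, while the whole
suite completes in about a minute.
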