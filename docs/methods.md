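# Methods

This note records the statistical models behind each `drivergene` stage,
the defaults and why they were chosen, what the synthetic-data module
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Stratification

Bulk samples are split on a per-sample scalar (normally the driver
gene's log₁₀(CPM+1) value) at the type-7 (linear-interpolation)
quantiles q and 1−q, q = 0.25 by default, with *strict* inequalities:
low < Q₁ and high > Q₃.  This convention is the one that yields
low/high groups of 31/31 from 124 distinct values, 26/26 from 103 and
13/13 from 50 — the group sizes the quartile split is expected to
produce at those cohort sizes.  Values exactly equal to a threshold are
assigned to the middle group with a warning: ties at a threshold are
ambiguous under any convention, and sending them to middle keeps the
low/high contrast clean.  Stratification refuses degenerate (constant)
inputs and, by default, cohorts of fewer than 8 samples.

Single-cell stratification is binarization: a cell is driver-positive
exactly when its value exceeds zero on whatever normalization the
dataset ships.  Positivity is invariant to library-size scaling, so no
renormalization is imposed.

## Differential expression (bulk)

The NB Wald engine is native to the package:

1. **Size factors** — median-of-ratios: reference profile is the
   per-gene geometric mean over samples (genes containing any zero are
   excluded); each sample's factor is the median ratio to the
   reference.  When no gene is everywhere-positive a pseudo-reference
   over positive entries of widely expressed genes is available behind
   a flag.
2. **Dispersions** — per-gene method of moments on normalized counts
   using the pooled *within-group* variance, α̂ = max(ε, (s² − m̄)/m̄²)
   with ε = 10⁻⁸.  A mean–dispersion trend a₀ + a₁/mean is fit by Huber
   regression, and log α̂ is averaged with the log trend using weight
   σ²_lik/(σ²_lik + σ²_prior), where σ²_lik ≈ 2/n approximates the
   sampling variance of a log dispersion estimate and σ²_prior = 0.25
   (configurable).  This is ordinary empirical-Bayes shrinkage; the
   prior variance matters little at n ≥ 30 and stabilizes small
   designs.
3. **GLM fit** — log-link NB regression with offset log(size factor)
   and a single group coefficient, fit by IRLS with working weights
   μ/(1 + αμ), vectorized across genes (the 2×2 weighted normal
   equations are solved in closed form).  Convergence tolerance 10⁻¹⁰
   on the group coefficient, at most 60 iterations, linear predictor
   clipped to ±30 to avoid overflow.
4. **Test** — Wald z = β̂₁/SE, two-sided normal p, BH adjustment over
   genes with defined statistics.  All-zero genes are reported with NaN
   and excluded from the BH denominator.
5. **LFC shrinkage** — the reported shrunken log₂ fold change is the
   MAP estimate under a zero-centered normal prior using the Wald
   quadratic approximation, i.e. lfc·s²/(s² + SE²).  The prior scale s
   is set so the prior's 95th percentile matches the observed upper-5%
   quantile of |lfc|, an adaptive choice that shrinks noisy
   low-information genes strongly and well-measured genes barely.  The
   shrunken value never changes sign.

Calibration rather than bit-compatibility with any external DE package
is the acceptance standard: on a simulated NB null (2000 genes, 15 vs
15, μ = 50, dispersion 0.1) the fraction of raw p ≤ 0.05 falls in
[0.03, 0.07], and a planted 4-fold gene is detected at padj ≤ 0.05.

## Markers and correlation

Wilcoxon rank-sum markers compare driver⁺ vs driver⁻ cells per gene,
two-sided.  When both groups have ≤ 10 cells the exact permutation null
of the rank sum is computed by a shift-algorithm convolution over
doubled mid-ranks (ties produce half-ranks; doubling makes the sums
integral); otherwise the tie-corrected normal approximation is used.
The marker call applies the cut-off on the **raw** p (p ≤ 0.05 by
default) per the protocol this stage follows, with the BH column
reported alongside so users can re-threshold.

Pearson correlation of each gene against the driver uses the
t-distributed p with n−2 degrees of freedom; genes are flagged
positive-significant when r > 0 and p ≤ α.  Stage-stratified Spearman
correlations skip strata with fewer than 4 samples (a warning is
emitted — with 3 ranks the p-value floor is 1/3 and the estimate is
meaningless).

## Enrichment

ORA uses the upper-tail hypergeometric probability P(X ≥ k) with the
universe made explicit; query genes outside the universe are dropped
with a warning, zero-overlap sets score p = 1, and BH runs across the
tested sets.

Preranked GSEA sorts genes by decreasing score (ties broken by symbol
for determinism).  Hits add |score|^p normalized by the set's total hit
weight (p = 1 default); misses subtract 1/(N−K); the enrichment score
is the signed extreme of the walk.  The null permutes gene labels —
the only null well-defined for a preranked list — with the requested
number of draws (1000 default, seeded).  NES divides ES by the mean
|null ES| of matching sign and the empirical p uses +1 smoothing.
Sets intersecting fewer than 5 ranked genes are skipped (configurable);
a set covering every ranked gene has no miss step and is an error.

## Signature scores (GSVA variant)

Per gene, each sample's value is replaced by its within-gene ECDF
statistic across samples (the non-kernel variant; kernel smoothing is
out of scope).  Per sample, genes are ranked by decreasing statistic —
ECDF values tie heavily across genes (they are multiples of 1/n), so
the raw expression value breaks ties, which keeps the ordering exactly
reversible under order-reversing transforms, with the gene symbol as
the final deterministic tie-break.  The walk weight of the gene at rank
r is |r − (N+1)/2|^τ, τ = 1: symmetric around the middle rank, so that
reversing every sample's ranking flips maxdiff scores exactly
(score → −score).  Scores are the sum of the maximal positive and
negative walk deviations (`maxdiff`, the default) or the single signed
extreme (`extreme`).  Defined for ≥ 3 samples and sets with ≥ 2 member
genes present.

## Survival

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines (censored-after-events convention at tied times).  The
optimal-cutoff machinery is native:

* **Candidates** — every distinct observed feature value whose
  below-or-equal proportion lies in the inner quantile range, 10th–90th
  percentile by default (the common choice for maximally selected
  statistics).
* **Statistic** — log-rank (Peto) scores aᵢ = δᵢ − Ĥ(tᵢ) with the
  Nelson–Aalen cumulative hazard, centered.  For a split of size m the
  standardized statistic is T = S/√(m(n−m)/(n(n−1))·Σa²), with
  S the score sum below the cutoff.  M = max|T| over candidates; ties
  resolve to the smallest cutoff.
* **p-value** — an improved Bonferroni upper bound for the maximum of
  the correlated candidate statistics:
  P(max|T| ≥ M) ≤ P(|T₁| ≥ M) + Σₖ [P(|Tₖ| ≥ M) − P(|Tₖ| ≥ M, |Tₖ₋₁| ≥ M)],
  with the joint tail from the bivariate normal at the closed-form
  correlation √(mₖ₋₁(n−mₖ)/(mₖ(n−mₖ₋₁))) of nested rank statistics.
  The bound is conservative relative to the permutation distribution
  (verified against a permutation oracle in the acceptance suite) and
  is what the survival report carries as its p-value — the naive
  log-rank p of the selected split is reported only as a diagnostic,
  because maximal selection inflates it.

`survival_by_feature` joins feature values with clinical records,
selects the cutoff, fits KM curves for both groups, and — when asked —
compares driver expression between the groups with a two-sided rank-sum
test.  When the feature *is* the driver that comparison is degenerate
by construction (high > low) and is flagged instead of tested.

## TMT proteomics

Proteins flagged contaminant, reverse-database or only-identified-by-
site anywhere are removed from all sets.  Within each labeled set every
channel is divided by the set's Global Internal Standard channel and
log₂-transformed (proteins with zero GIS intensity are dropped from
that set, logged).  Sets are inner-joined on protein identity — the
joined matrix contains proteins quantified everywhere; outer joins with
missing data are deliberately out of scope — and each remaining sample
channel is median-centered **after** the join, so per-sample medians
are exactly zero on the joined matrix.  Normal-tissue and GIS channels
are dropped from the result.

The group test is d = (mean_high − mean_low)/(pooled SE + s0) with
s0 = 0.1 by default; the permutation null over column labels is
exhaustive whenever there are ≤ 8 columns and uses 1000 seeded draws
otherwise, and BH turns permutation p's into q-values with the FDR ≤
0.05 call.  Stratification of samples by a protein's normalized level
reuses the quartile primitive on the centered matrix (a flag could
stratify pre-centering; centering is a per-sample shift and does not
change within-protein sample ranking, so the default is safe).

## qPCR

Replicate Cq values are averaged per (sample, gene) first.  ΔCq
subtracts the geometric mean of the reference-gene Cq values (taken
over Cq values, the literal multi-reference convention), ΔΔCt subtracts
the mean ΔCq of the control group, and fold = 2^(−ΔΔCt); by
construction the control group's geometric-mean fold is exactly 1.
Group comparison is a two-sided two-sample Student's t-test on ΔΔCt.
Expression stratification runs on −ΔCq, since lower quantification
cycles mean more template.  The control-group-mean calibrator is the
default; a per-sample calibrator would be a one-line change and is not
exposed.

## Consensus integration

The consensus panel intersects the bulk up-regulated genes
(padj ≤ α and shrunken lfc > 0; the shrunken sign is used for
direction) with the up-markers (raw p ≤ α, mean⁺ > mean⁻) of every
single-cell dataset.  Intersections are symbol-level; Venn region
counts are emitted for 2–3 sets.  Datasets missing the driver are
skipped with a warning; a run needs at least one usable bulk and one
single-cell dataset.  With per-dataset false-positive rate α and d
independent single-cell datasets the expected number of false panel
genes scales like N·α^(d+1), which the null simulations confirm
(median 0 false genes at N = 1000, d = 2).

## Synthetic data

The generators produce the statistical structure the pipeline assumes
and nothing more: negative-binomial counts (var = μ + αμ², sampled as
gamma–Poisson) with log-normal library sizes for bulk; the same plus
per-entry Bernoulli dropout for single cells; exponential
proportional-hazards survival with a hazard step at a value threshold;
log-normal TMT intensities with a pooled-mean GIS channel; and normal
Cq values with three reference genes and jittered duplicates.  They do
**not** emulate gene–gene correlation structure beyond the planted
program, batch effects, ambient RNA, isotope impurity, or real
marginal distributions — so passing tests demonstrate correctness of
the machinery under its stated model, not robustness to every real-data
pathology.

Coupling conventions.  A standard-normal latent activity per sample
drives the driver's log₂ mean; each program gene follows
ρ·z + √(1−ρ²)·ε so its latent correlation with the driver is ρ.  The
coupling slope is calibrated per stratification primitive: for bulk the
expected log₂ contrast between the driver's upper and lower quartile
groups equals `lfc` (the top-minus-bottom quartile gap of a standard
normal is 2φ(z₀.₇₅)/0.25 ≈ 2.54), while for single cells `lfc` is the
expected log₂ contrast between driver-positive and -negative cells
under the latent-linked dropout p(z) = 2·dropout·(1−Φ(z)), whose latent
gap is 1/(√π(1−dropout)).  The driver's single-cell zeros come *only*
from that dropout mask (its counts are otherwise shifted-NB ≥ 1), so
the positive/negative split is exactly the mask and ground truth is
exact.

Defaults are the study-scale conditions: a 124-sample bulk cohort, a
103-sample qPCR cohort, a 12-set × 6-channel TMT design with 4 normal
channels (56 tumor samples).  The recovery *fixtures* used by the
acceptance suite are sized by power analysis — a 200-sample bulk cohort
and two 1500-cell single-cell datasets over 1000 genes — so that each
stage has ≳95% per-gene power for the planted 2-fold program at
ρ = 0.6; at ρ = 0.6 the residual program-gene noise (~0.5 log₂ units)
acts as extra overdispersion, and smaller cohorts make recovery a coin
flip rather than a test of correctness.  All simulation sizes keep the
full test suite under ~2 minutes on one CPU.

## Numerical conventions and limitations

* Gene identity is the uppercased symbol everywhere; duplicate count
  rows are summed on read (deterministic and conservative for counts).
* All tabular outputs are sorted (adjusted p, then key) and carry a
  JSON provenance sidecar with the stage parameters and seed.
* Every permutation-based stage takes an explicit seed; identical
  seeds give byte-identical tables.
* BH adjustment is used throughout (no g:SCS or ontology-aware
  corrections); note BH is not idempotent, so adjusted values must not
  be re-adjusted.
* Survival times are taken as given in the declared unit; no horizon
  censoring, Cox regression, or competing-risk handling.
* No multi-factor DE designs, batch covariates, or pseudobulk; no
  ontology-graph pruning in enrichment; no missing-data imputation in
  proteomics; no amplification-efficiency correction in qPCR.
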