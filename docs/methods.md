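# Methods

## Generative model for the synthetic study

The simulator reproduces the statistical structure of a multi-batch TMT
6-plex experiment on a 60-tumour cohort.

**Cohort.** Each sample carries binary HR and HER2 status; the IHC subtype is
a pure function of the pair. Default proportions are 29/15/7/9 of 60
(HR+/HER2−, HR+/HER2+, HR−/HER2−, HR−/HER2+); `exact_counts` fixes the
largest-remainder apportionment, otherwise assignment is multinomial.

**Batch design.** Samples are randomly permuted into batches of `plex − 1`
(default 5); channel `plex` in every batch is reserved for the pooled
"supermix" reference. Cohorts that do not fill whole batches are rejected —
no partial plexes.

**Abundances.** Protein baselines are log-normal: log2 baseline ~
Normal(20, 2), a typical reporter-intensity scale. Truly differential
proteins (default 50 of 1000) receive a per-subtype log2 delta; the default
pattern (0.05, 0.30, 0.33, −1.06 for HR+/HER2−, HR+/HER2+, HR−/HER2−,
HR−/HER2+) is one subtype depressed by about one log2 unit with the others
near zero — the shape of the effects the DE stage is meant to find. The
measured sample-channel value is

    log2 I = baseline + delta(subtype) + batch_shift + Normal(0, sigma)

with `batch_shift ~ Normal(0, batch_sd)` per batch (defaults
`sigma = batch_sd = 0.5`).

**Reference channel.** The supermix is the equal-amount pool of all 60
samples, so its true linear value per protein is the arithmetic mean of the
samples' true linear abundances. Its measurement gets a *separate* noise sd
`ref_sigma` (default 0.15 log2 units ≈ 10 % CV), smaller than `sigma`, for a
physical reason: the pool carries no between-tumour biological variance, and
its protein-level value is the average over many PSMs, so only a technical
component remains. This matters quantitatively. After ratio formation the
reference error is shared by the five samples of a batch, i.e. it is a
protein×batch interaction that no column-level normalization can remove; if
the reference were as noisy as a sample channel, the ratio variance would
double and the ANOVA would lose roughly half its sensitivity at
FDR-controlling thresholds. A small residual batch-structure floor from this
term is still present and is documented by a dedicated test.

The batch shift is applied to sample channels only, modelling
channel-specific artefacts (labelling efficiency, co-isolation load) rather
than a common multiplier that ratio-to-reference would cancel exactly —
otherwise the normalization comparison would have nothing to rank.

**Missingness.** Left-censoring:
`P(missing) = logistic((midpoint − log2 I) × steepness)` applied to sample
channels only (the pooled reference is abundant by construction). Defaults
`midpoint = 17`, `steepness = 0.8` give ~5–15 % missingness on the default
intensity scale, concentrated in low-abundance proteins — a well-behaved
FFPE TMT study.

**Survival.** Event times are exponential with hazard
`h = baseline_hazard × exp(coef × centered score)`; censoring is the minimum
of an independent exponential and an administrative cutoff. Defaults
(baseline 0.02/month, coef 0.8 per score unit, censor rate 0.01/month,
120-month cutoff) describe a 10-year follow-up with moderate event rates.
The linked expression generator gives signature genes a shared per-sample
latent factor so the score is a meaningful axis of variation.

What the simulator does **not** emulate: peptide sequences and spectra,
isotope-impurity cross-talk, PSM-level identification FDR, protein
inference/grouping, non-additive batch interactions beyond the reference
term, informative censoring, and real PPI topology (the packaged edge list
is synthetic test data). Passing tests therefore demonstrate correctness of
the procedures under an additive log-normal model, not performance on any
real cohort.

## Quantitation

PSMs are filtered on precursor ion fraction with a strict inequality
(PIF > 0.75; a PSM at exactly the threshold is removed). Rollup to protein
level uses the reference-channel intensity as PSM weight, computed in linear
space and log-transformed afterwards:

    ratio(channel) = Σ_psm ref_psm · (s_psm/ref_psm) / Σ_psm ref_psm
                   = Σ_psm s_psm / Σ_psm ref_psm

which down-weights low-signal PSMs. PSMs with zero reference intensity are
excluded; proteins with no surviving PSM in a batch are missing there; a
zero sample-channel total becomes missing rather than −∞. The exact
weighting of the upstream search engine's "weighted ratio" is not published;
this choice is an explicit stand-in with the same qualitative behaviour, not
a claim of bit-compatibility. Protein-level tables can also be consumed
directly (`quantify_batches`), which keeps simulations fast.

## Preprocessing

The completeness filter keeps proteins finite in at least 70 % of samples,
boundary inclusive (42/60 passes). It is applied globally, not per subtype.
Imputation follows the downshifted-Gaussian convention for left-censored
proteomics data: per sample with observed mean `m` and sd `s` (ddof 1),
missing entries are drawn from `Normal(m − 1.8·s, (0.3·s)²)`. Both
multipliers are exposed. Imputation runs after filtering. Observed entries
are bitwise untouched; a sample with fewer than two observed values is an
error.

## Normalization and the batch-effect score

* **Median–median** — per-sample median centering alternated with per-batch
  block median centering. One pass of each cannot zero both sets of medians
  (block centering disturbs the sample medians), so the sweeps iterate to a
  joint fixed point (tol 1e−12, max 100 sweeps); convergence is geometric in
  practice.
* **Row-wise** — per-protein median centering. Note that per-row constants
  change neither the between-batch nor the total sum of squares of a
  protein, so this method cannot reduce the batch-effect score at all; it is
  the designated negative control of the comparison.
* **IRS** — operates on linear intensities before the log transform (its
  standard formulation): per protein, each batch is scaled by
  (geometric mean of its reference across batches)/(its reference in that
  batch), making the reference exactly equal across batches where observed.
  Proteins missing their reference in a batch are left unscaled there and
  flagged. Applied to ratio-to-reference data IRS is a no-op (the reference
  divides out), so its comparison entry is scored on the scaled absolute
  intensities.
* **Median polish** — Tukey's two-way additive fit on proteins × samples;
  sweeps alternate row and column medians until the largest swept median is
  below `tol` (default 1e−6) or `max_iter` (default 20) sweeps. On noisy
  matrices the sweep delta decays geometrically (~0.7×/sweep), so the
  default budget often ends with the specified non-convergence warning; the
  result is still returned and the report records the iteration count.
  Purely additive matrices are solved exactly within two sweeps. Only the
  fitted *sample* (column) effect is subtracted — protein effects are
  biology and are retained. A final exact half-sweep recenters each sample's
  median to zero: at the polish fixed point the retained protein effects
  leave a small nonzero median per sample, and the documented contract of
  the normalizer is that sample medians vanish. With the recentering the
  transform is exactly idempotent.

The **batch-effect score** operationalizes "which method removed batch
effects best": mean over proteins of η² = SSB/SST from a one-way layout over
batches. Its small-sample null is E[η²] = (B−1)/(n−1) = 11/59 ≈ 0.19 for 12
batches of 5 — scores are compared against each other, not against zero.
Constant proteins contribute 0.

## Differential expression

Classic one-way ANOVA F per protein over the four subtypes, group sizes
taken from the cohort as-is (29/15/7/9, never rebalanced). Degenerate
inputs: all observations identical is an error (0/0); zero within-group
variance with unequal means returns +∞.

Permutation FDR, pooled-null ("global") variant: each of `n_perm` (default
250) permutations shuffles the subtype labels once and recomputes the full F
vector, preserving the inter-protein correlation structure. For threshold
`t`, `FDR(t) = mean_perm #{F_perm ≥ t} / #{F_obs ≥ t}`; a protein's q is the
minimum FDR over thresholds at or below its own F (step-down), clipped to
[0, 1] — so ordering by q equals ordering by F. The `per-protein` pooling
option instead computes each protein's own permutation p-value (with the
+1 correction) and applies Benjamini–Hochberg. An `s0` term can be added to
the within-group mean square to damp near-zero-variance features; default 0.
Ties in the output table break on protein id for determinism.

Design choices of note: the per-protein one-way model is used throughout
(a mooted multivariate adjustment is not implemented); normalization runs
before the ANOVA, which also attenuates recovered effects slightly (~5 %
when 5 % of proteins share a one-sided effect — the sample medians absorb a
little of the signal).

## Network

STRING-convention combined scores (integer 0–1000). Confidence `c` maps to
the inclusive threshold `score ≥ round(1000·c)`, so 0.4 keeps 400 and drops
399. Reciprocal duplicate rows merge keeping the maximum score; self-loops
drop with a warning. Cluster extraction induces the subgraph on the DE
symbols and ranks connected components by edge density first (the target is
the most interconnected module, not the largest), then mean combined score,
then size; a clique of any size ≥ 2 has density exactly 1 and singletons 0.
The packaged fixture edge list is synthetic test data constructed so the
six-gene ECM module is the top-density component.

## Signature and survival

Expression enters as log2(x+1) of a non-negative RSEM-like estimate. The
signature score is the unweighted arithmetic mean of the member genes'
transformed values (default members: the six ECM genes). Quartile groups use
the linear-interpolation quantile convention with inclusive boundaries on
both tails (ties at Q1/Q3 go to the extreme groups); the middle two
quartiles are excluded from the survival comparison. Kaplan–Meier estimation
and the log-rank test (hypergeometric variance, simultaneous risk-set
accounting of ties) are delegated to lifelines behind this module's
interface and cross-checked in the tests against the counting closed form,
hand-computed O−E/V arithmetic and a permutation reference. Time units are
abstract; no calendar handling. The χ² approximation of the log-rank p is
used even at small n, where it deviates from the exact permutation p by a
few percent.

## Problem sizes and numerical conventions

Simulation-based checks use 1000 proteins × 60 samples with 250
permutations, and 200 replicates for type-I calibration — sizes at which
every Monte-Carlo band in the tests (3 standard errors) is meaningful while
the full suite runs in well under a minute. A single global seed expands
into independent per-stage substreams (`spawn_seeds`, SeedSequence-based,
values < 2³¹) so stages can be regenerated independently; every artefact is
byte-reproducible given the manifest. All tables are TSV with "NA" for
missing; matrices are float64 throughout.
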