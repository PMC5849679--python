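# Methods

This note documents the models, the estimators, the simulator, and the
numerical conventions in phosbench, including the design choices made
where more than one reasonable convention exists.

## Stoichiometry model

For one phosphosite measured across channels *j* = 1…J of a multiplexed
run, three intensities are observed: the phosphopeptide *P_j*, its
unmodified counterpart peptide *N_j*, and the parent protein *T_j*.
Every protein copy is either phosphorylated at the site or not, so with
unknown positive *response factors* a (phospho) and b (non-phospho) that
absorb ionization and recovery differences between the two peptide forms,

    a·P_j + b·N_j = κ·T_j     for every channel j,

with κ an arbitrary protein scale. The model assumes the response
factors are shared across channels (same peptides, same run) and that
*T_j* is error-free; when protein levels are unregulated by design the
caller passes T ≡ 1 (the benchmark configuration), which additionally
assumes equal channel loading.

**Parameterization.** We normalize by protein first (p = P/T, n = N/T,
absorbing κ) and fit the reduced line n = c0 + c1·p by OLS with
intercept, rather than fitting the three-variable plane directly. This
makes "the slope" a single coefficient with a standard t-test, is exact
when T is error-free, and coincides with the plane fit in the T ≡ 1
configuration. Back-transformation gives a = −c1/c0, b = 1/c0, and the
per-observation occupancy

    s_j = (−c1·p_j) / (n_j − c1·p_j),

which equals a·P_j/(a·P_j + b·N_j) and uses the observed n_j so that
off-plane noise shows up in the occupancy rather than being projected
away silently.

**Quality score.** The two-sided t-test p-value of H0: c1 = 0 with J − 2
degrees of freedom. A site whose channels do not vary in occupancy, or
whose signal is swamped by interference, yields a flat insignificant
slope. A numerically perfect fit (zero residual variance) reports p = 0,
the infinite-t limit.

**Edge cases.** Fits need ≥ 4 usable observations (P, N, T present,
T > 0); fewer raise an error. Zero variance in p yields a degenerate
result, not an exception. c0 ≤ 0 or c1 ≥ 0 contradicts positive response
factors: the fit is marked degenerate with p = 1 and all occupancies
flagged. Occupancies outside [0, 1] ("illegal" values) are flagged and
excluded from all summaries but retained in the output with a per-site
count, for auditability. Technical replicates enter as additional
observations of the same plane (no per-replicate random effect): one
model per site across the plex. Per-channel summaries reduce replicate
observations by the median (robust; the reducer is a convenience, the
per-observation values are the primary output).

## SAM significance

The SAM statistic per feature is d = r/(s + s0): the mean difference
(unpaired: difference of group means with pooled-variance standard error;
paired: mean of within-replicate differences with its standard error)
moderated by a background-variance offset s0. With s0 = 0, d is the
classical t-statistic.

*Automatic s0*: candidates are 0 plus the percentiles {0, 5, …, 100} of
the denominators s_i; features are split into 100 quantile bins of s_i,
and the candidate minimizing the coefficient of variation of the per-bin
median absolute deviations of d is chosen, ties toward the smallest
candidate. (The CV is scale-free, so whether the MAD carries the 1.4826
normal-consistency constant is immaterial; we use the raw MAD.)

*Delta / FDR*: expected order statistics of d are built from label
permutations (paired design: sign flips of the differences), exhaustively
when the arrangement count does not exceed the request (flagged on the
result), otherwise sampled from a seeded generator. A feature is called
when its ordered d deviates from the expected value by at least delta on
the matching tail; the call thresholds are the smallest d above (largest
d below) the first crossing. FDR = π0 × median permuted call count /
observed call count, with π0 the observed fraction of d inside the
central 50% of the permuted distribution (capped at 1). `delta="auto"`
scans the deviations and picks the smallest delta meeting the target FDR
(default 0.20). The default seed is 123 and the default permutation count
200; both are recorded in the result.

## Benchmark statistics

**Error decomposition.** bias = mean − truth, "positive bias" = bias²,
variance = population variance (divide by n), MSE = bias² + variance.
The squared-bias reading is the one under which the MSE identity
MSE = mean squared deviation from truth holds exactly, which is why it
is used here.

**Decompression slope.** Features in the top and bottom `tail_fraction`
(default 5%) of the *reference* (compressed) method's log2 ratios are
selected; OLS with intercept of the other method's ratios on the
reference over the union of both tails gives the slope. Selection on the
reference axis and the inclusion of an intercept are conventions of this
package; the slope is invariant to shifting both vectors equally. At
least 10 features per tail are required.

**ROC.** Thresholds sweep descending unique d-scores with ties processed
as blocks (diagonal segments); AUC by trapezoid, which equals pairwise
concordance with ties counted one half. The curve computation is
delegated to scikit-learn; the test suite cross-checks the AUC against a
brute-force concordance oracle.

**Contamination fraction.** Under the convex interference model
observed = (1 − f)·true + f·background (profiles normalized to sum 1),
the least-squares estimate is f = Σ(o−t)(g−t)/Σ(g−t)², clipped to
[0, 1], with the residual norm reported. Identical true and background
profiles are rejected as unidentifiable.

## Simulator

The generator reproduces the statistical structure of two benchmark
designs, with all draws from a single seeded generator per call.

*Mixed-species spike-in* (`fig2-mix`): 500 yeast features at relative
levels 1:4:10 across three conditions (three mixing replicates each,
nine channels) in a background of 1500 human features at 1:1:1. Base
abundances are log-normal (meanlog ln 1e6, sdlog 1.2 — a realistic
dynamic range for enriched phosphopeptide intensities); channel loading
error is a 2% CV log-normal factor.

*Occupancy series* (`fig6-stoich`): 300 sites whose true occupancy steps
0.1…0.9 across nine channels (three technical replicates). Response
factors a, b are log-uniform on [0.5, 5]; pre-noise intensities are
constructed as P = s·amount/a, N = (1−s)·amount/b so conservation holds
exactly before noise. Channel loading is equal by default: the series is
mixed from one pool, and the T ≡ 1 analysis assumes it.

*Co-isolation*: per feature, a Beta-distributed fraction f of the total
reporter signal is replaced by signal following the contaminating pool's
channel profile — the abundance-weighted average profile of the whole
sample for the mixed design, and a flat profile for the occupancy series
(its equal-amount, constant-occupancy background pool dominates the
co-isolated signal). Row totals are preserved exactly and the map is
linear in f. Under this model, noiseless occupancy estimates are pulled
linearly toward the abundance-weighted mean occupancy of the co-isolated
pool — which equals the background occupancy (0.5, "half
dephosphorylated") in the benchmark configuration — monotonically in f.

*Method profiles* (defaults; calibrated only to reproduce the
qualitative orderings of real method comparisons, not measured values):

| profile | contamination Beta (mean) | noise CV | additive floor | detection | dropout |
|---------|--------------------------|----------|----------------|-----------|---------|
| tmt-ms2 | (15, 35) (0.30)          | 0.08     | 5e2            | 1.00      | —       |
| tmt-ms3 | (4, 46) (0.08)           | 0.15     | 5e3            | 0.70      | —       |
| lfq     | —                        | 0.25     | 1e3            | 0.90      | σ(8 − 2·log10 I) |
| silac   | —                        | 0.18     | 1e3            | 0.85      | σ(6 − 2·log10 I) |

Noise is mean-one multiplicative log-normal at the stated CV plus an
additive Gaussian floor (intensity units; models the low reporter
signal-to-noise of MS3 acquisition), truncated at zero. Missingness is a
per-feature detection draw plus, for the MS1-based methods, logistic
missing-not-at-random dropout on log10 intensity. The contamination Beta
concentrations keep per-feature interference moderately dispersed; much
wider distributions would make interference variability, rather than
reporter noise, the dominant precision term, inverting the MS2/MS3
precision ordering the profiles are meant to emulate.

What the simulator does **not** model: spectrum-level structure (m/z,
isotope envelopes, elution), identification/search behavior beyond
detection subsampling, isotope-impurity leakage between channels,
peptide-specific digestion or enrichment biases, and correlated
missingness across features. Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated generative
model, not performance on any particular instrument.

## Data handling conventions

* Zero intensities are treated as missing when forming ratios (log2
  undefined; zero means "not quantified" in search-engine output).
* Quantile normalization maps each column's ranks to the per-rank means
  of the columns' order statistics; ties receive the mean of their tied
  ranks' targets; missing values are skipped per column (columns with
  unequal present counts are mapped through linear interpolation of the
  reference quantile curve, so exact idempotence holds for complete
  data). Normalization is applied to the assembled table, not per
  fraction.
* A localization probability of exactly 0 flagged as originating from
  match-between-runs transfer is treated as missing evidence, not a
  failing score; per-replicate scores reduce by the minimum over
  informative entries.
* KNN imputation (default k = 10) uses unscaled Euclidean distance over
  the columns jointly observed by donor and target, requires the donor
  to be observed in the hole's column, never alters observed values, and
  leaves holes with no eligible donor missing (reported via a warning).
  These are the package's documented "standard settings"; no row or
  column missingness caps are applied.
* SILAC channel intensities are derived from the total triplet intensity
  and the measured M/L and H/L ratios (light = total/(1 + rML + rHL)),
  so the three channels sum exactly to the total.
* Feature identifiers are opaque strings throughout; there are no
  positional semantics.

## Problem sizes and tolerances

The test suite and the acceptance script run on simulation sizes chosen
to make the stochastic checks stable at desk scale: 1000 sites for
occupancy recovery, 2000 features for SAM calibration and decompression,
100–1000 draws for the estimator cross-checks. Exactness properties
(conservation-data recovery, MSE identity, ROC concordance, SILAC sums)
are asserted at 1e-9–1e-12; stochastic properties are asserted as
orderings or banded summaries, never as point equalities.

## Known limitations

* The reduced-regression parameterization treats protein intensity as
  error-free; noisy T induces errors-in-variables attenuation that the
  model does not correct.
* Subtle occupancy differences between channels produce flat slopes and
  are filtered out by design — the method trades sensitivity to small
  changes for robustness of the absolute estimates.
* Multiply-phosphorylated peptides and shared/isoform peptides are out
  of scope: the matching step assumes one counterpart peptide and one
  protein record per site.
* The SAM FDR is the permutation-median estimate of the SAM procedure;
  it is not a proof of error control for arbitrary dependence structures.
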