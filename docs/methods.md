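# Methods

## The balanced metric family

For a 2×2 confusion matrix with cells TP, FP, FN, TN, the four conditional
probabilities are TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN); prevalence = (TP+FN)/N and bias = (TP+FP)/N. The family
consists of the geometric, harmonic and (rescaled) arithmetic-type
combinations of the quartet:

- **G4** — weighted geometric mean `(∏ cᵢ^wᵢ)^(1/Σwᵢ)`, default equal
  weights. Evaluated in log space, so rescaling all weights by a positive
  constant is exactly neutral.
- **P4** — harmonic mean `4/(Σ 1/cᵢ)`, taken to be 0 when any component is 0
  (its continuous limit).
- **MCC** — computed through the identity
  `MCC = G4² − √((1−TPR)(1−TNR)(1−PPV)(1−NPV))`, which equals the Pearson
  correlation of the two binary variables (the count form
  `(TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`); tests enforce agreement
  below 1e-10 over 10⁴ random matrices. `MCC_scaled = (MCC+1)/2`.

**Undefined-value policy.** A rate whose denominator is zero is an explicit
`None` marker, and family metrics raise `UndefinedMetricError` on such input
rather than coercing to 0 — silent zeros would contaminate bootstrap
distributions with artefactual mass at 0. A *defined* rate equal to 0 makes
G4 = P4 = 0. MCC with a zero marginal is likewise **undefined here**, not 0
as some libraries define it; this keeps the identity and count forms
consistent. Cells are floats so reader-averaged matrices are first-class.

The mean inequality `MCC_scaled ≥ G4 ≥ P4` is guaranteed when prevalence
equals bias (then TPR = PPV and TNR = NPV, and the three metrics are the
arithmetic/geometric/harmonic means of sensitivity and specificity);
`G4 ≥ P4` holds for every defined matrix. Tests assert the three-way
ordering only under prevalence = bias, where the derivation is valid.

## ROC and AUROC

Positive calls use the strict rule `score > threshold` (a score exactly at
the threshold is a negative call), uniformly across the library, the
simulator and the CLI. The empirical ROC curve takes one step per distinct
score value; tied scores form a single threshold step, which makes the
trapezoidal area equal to the Mann–Whitney statistic with half credit for
ties (asserted below 1e-12 in tests). For a binary predictor the curve has
one interior point and the trapezoidal AUROC equals balanced accuracy
exactly.

## Binormal simulation and benchmarks

A nominal AUROC A ∈ [0.5, 1) is converted to a class separation via
`t = √(ln(1/(1−A)²))`, the rational probit approximation
`z = t − (2.515517 + 0.802853·t + 0.0103328·t²)/(1 + 1.432788·t + 0.189269·t² + 0.001308·t³)`,
and `D = z·√2`. The rational approximation (absolute error ≲ 4.5e-4 on z) is
used deliberately instead of `scipy.stats.norm.ppf` so that stated constants
define the conversion; tests pin the conversion to `√2·Φ⁻¹(A)` within 7e-4.
A = 1 is outside the domain (t diverges); grids cap at 0.999.

Scores: exactly `round(n·prevalence)` positives from N(+D/2, 1) and the rest
from N(−D/2, 1) — class sizes are fixed, not binomially sampled, so every
run realises its prevalence exactly — mapped through the logistic function
onto (0, 1). Any strictly increasing map preserves AUROC; the logistic is
chosen because it sends the raw midpoint 0 to probability 0.5, making the
conventional 50% threshold the midpoint between the class means. Bias is
*not* forced equal to prevalence: at a midpoint threshold and low prevalence
the classifier over-calls positives, and the observed bias is recorded per
benchmark cell instead.

`benchmark_grid` averages (G4, P4, MCC_scaled) over 20 replicates of
n = 10,000 per (AUROC, prevalence) cell by default, with substream seeds per
replicate. At prevalence 0.5 the three metrics coincide up to Monte-Carlo
error and the cells are quantitative reference points (tests check the
AUROC 0.8/0.9 cells within ±0.01). At lower prevalence the absolute cell
values depend on the unpublished score-to-probability mapping convention of
other implementations, so only qualitative structure is asserted: values
decrease as prevalence falls at fixed AUROC, and P4 ≤ G4 ≤ MCC_scaled within
each imbalanced cell. `benchmark_lookup` interpolates bilinearly inside the
grid hull and refuses to extrapolate. The 70/60/50 rule of thumb returns a
benchmark of 0.70/0.60/0.50 for minority-class prevalence >30% / 10–30% /
<10% (band edges inclusive for the uncommon band, with a 1e-12 guard so
folding p → 1−p cannot leak float noise across an edge).

## MRMC model and bootstrap

`MrmcTable` holds long-format (modality, reader, case, truth, rating)
records with a positivity rule `rating ≥ cut` (default 4, as on a 1–6
malignancy scale). Truth must be constant per case; each reader must rate
every case of a modality (equal reader weights — weighting for nested
readers with unequal case loads is not defined here).

The reader-average confusion matrix is the cell-wise mean of per-reader
matrices. Since that matrix is linear in each case's reader-averaged
positive-call indicator, a case reduces to a single "fraction of readers
calling it positive", and the stratified clustered bootstrap resamples those
per-case fractions with replacement independently within the positive and
negative truth strata (stratum sizes preserved ⇒ every replicate has exactly
the original prevalence; duplicated cases are kept as distinct clusters with
their full reader blocks). Tests verify this representation against the
naive per-reader averaging. The metric is evaluated on each replicate's
reader-average matrix (not as an average of per-reader metrics), and the CI
is the **percentile** interval — the simplest defensible choice absent a
stated alternative — at B = 2000 by default. A replicate on which the metric
is undefined is redrawn and counted; if redraws exceed 1% of B the run
aborts, since any silent skip/zero policy would bias the interval.

Between-modality differences support `nested` mode (independent case
resamples per modality — conservative, appropriate when only summary-level
pairing is credible) and `crossed` mode (one shared case resample applied to
both modalities, requiring identical case sets). With positively correlated
modalities crossed intervals are no wider than nested ones up to Monte-Carlo
noise.

`reconstruct_counts` inverts a published (N, prevalence, rate-quartet)
summary by exhaustive search over integer matrices with `round(N·prevalence)`
positives, minimising the maximum absolute deviation of implied rates from
the published quartet (lexicographic smallest (tp, fp) on ties). It
round-trips exactly on full-precision inputs.

### Synthetic MRMC generator

The generator emulates a rare-prevalence two-modality crossed reader study:
fixed class sizes; per-reader AUROC from a normal truncated to
[0.505, 0.995] (defaults: mean 0.93, sd 0.02, matching a strong radiologist
panel); modality 2 shifts every reader's AUROC by `modality_delta`
(default +0.03). Reader scores follow the binormal latent model
`D_r·(y_c − ½) + √ρ²·z_c + √(1−ρ²)·ε` with a per-case effect z_c shared
across readers *and* modalities (ρ² = 0.5 by default), so cases are genuine
clusters and modalities are positively correlated. Scores are binned into
`rating_levels` ordinal levels at cuts spaced 0.8σ apart with the middle cut
at the class-mean midpoint (exact for even level counts), and the positivity
cut is `levels//2 + 1`. What it does **not** emulate: reader-specific
thresholds/bias styles, non-normal score distributions, case-difficulty
strata, or missing ratings — so passing coverage tests here demonstrates
correctness of the bootstrap under a well-specified clustered design, not
robustness to those real-data features.

## Power analysis

The test declares success when the one-sided lower percentile-bootstrap
confidence bound for G4 (the α quantile of the bootstrap distribution;
α/2 when two-sided) exceeds a fixed benchmark. The test statistic is this
package's own definition. Power is the fraction of simulated binormal
studies that pass. For a single classifier with fixed per-case predictions,
stratified case resampling is distributionally identical to
`tp* ~ Binomial(n₊, tp/n₊)`, `fp* ~ Binomial(n₋, fp/n₋)`; the inner
bootstrap uses that exact equivalence (B_inner = 500 by default — power
studies tolerate coarser quantiles than reported CIs). `required_n` doubles
then bisects on n, reusing the same seed at every evaluation (common random
numbers) and stopping at ~5% resolution in n; the evaluation trace is
returned. At zero effect the empirical size is within Monte-Carlo error of α
(finite-n percentile-bootstrap calibration error is below the 3-standard-
error band used in tests at n ≈ 200 cases).

## Problem sizes used in the test suite

Deterministic checks run on the published N = 663 matrices. Stochastic
checks use: benchmark cells at n = 10,000 × 20 replicates (quantitative) and
n = 4,000 × 5 (qualitative); bootstrap coverage over 200 synthetic studies
of 200 cases × 4 readers at prevalence 0.25 with B = 500; power size/
monotonicity at 200–400 outer replicates with B_inner = 400–500. These sizes
put Monte-Carlo noise comfortably inside the asserted tolerances while the
whole suite runs in well under a minute.

## Known limitations

- Published low-prevalence benchmark tables from other implementations are
  reproduced qualitatively, not cell-by-cell (mapping convention unknown;
  see above). IQR-style variability summaries across a benchmark sweep are
  not implemented (the collection over which quartiles would be taken is
  ambiguous).
- Percentile CIs can undercover for strongly skewed statistics at small
  stratum sizes (e.g. < ~30 positive cases); BCa intervals are not
  implemented.
- AUROC-based MRMC inference (e.g. OR/DBM random-effects models) is out of
  scope; the bootstrap here addresses the single-threshold family metrics.
- The metric zoo is single-matrix and binary only; no multi-class
  generalisations or calibration metrics.
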