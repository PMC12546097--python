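# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `eegflavor`, in the
order data flows through the pipeline.

## Signal model of the synthetic panel

The generator produces a virtual tasting panel whose recordings carry
exactly the structure the analysis assumes, nothing more.

Each subject has a true individual alpha frequency (IAF) drawn
uniformly from 8.5–11.5 Hz, an age drawn uniformly from 24–59 years,
an expertise group (trained/expert, Bernoulli 0.5 by default) and, for
every (phase, trial, attribute), a latent intensity drawn uniformly
from [1, 9] on the 0–10 rating scale. The latent range deliberately
avoids the scale ends so that rating clipping does not dominate the
noise model.

Every epoch is the sum of:

* **Broadband background** — Gaussian noise shaped in the frequency
  domain to the density `P(f) = pink_scale/f + white_scale` (defaults
  10 and 0.2 µV²/Hz), band-limited to 0.1–40 Hz. The limits mimic
  post-cleaning EEG: the analysis chain assumes artifact removal has
  already happened, so no blinks, EMG or line noise are simulated.
* **Occipital alpha rhythm** — an amplitude-modulated sinusoid at the
  subject's true IAF on the eight occipital channels (default peak
  amplitude 8 µV, modulation depth 0.3 with a 0.5 Hz envelope). With
  the defaults the alpha-band SNR over the occipital background is ≈ 5,
  at which the IAF center-of-gravity estimator recovers the true IAF to
  within 0.5 Hz (asserted in tests; typical error ≈ 0.15 Hz).

Tasting (TL) epochs additionally multiply the background power inside
the subject-specific band of each configured effect by
`1 + gain × latent_intensity`. The default effect map couples each
attribute to a distinct (region, band) pair — bitter→(frontal, θ),
sweet→(central, α), acid→(parietal, β), astringent→(occipital, γ) —
with gain 0.05 per rating unit, i.e. up to a 45 % band-power increase
at intensity 9. Water-rinse (WR) epochs follow the baseline law, so the
TL⊘WR normalization isolates the planted modulations by construction.
Ratings are `clip(latent + N(0, 1), 0, 10)` by default.

Durations follow the tasting protocol: 60 s eyes-closed baseline, 10 s
tasting epochs. The rinse-epoch duration is not protocol-fixed;
it defaults to 10 s so the Welch estimates of the TL and WR epochs have
equal variance.

What the generator does **not** emulate — and hence what green tests do
not establish about real recordings: inter-channel spatial correlation
(channels are independent), volume conduction, non-stationarity beyond
the slow alpha envelope, artifacts and their residues, and any real
physiological link between taste processing and specific scalp
regions. Passing tests demonstrate that the pipeline recovers the kind
of structure it assumes, not that such structure exists in human data.

## Feature extraction

* **Welch PSD**: 1 s Hamming windows, 50 % overlap, density scaling, so
  the trapezoidal integral over [0, fs/2] approximates the per-channel
  variance (Parseval check in tests, ±5 % for a pure tone). The 1 s
  window gives 1 Hz resolution; at fs = 512 Hz the grid reaches 256 Hz,
  so the γ band (≤ IAF+25 ≤ 37.5 Hz) always fits; if a caller supplies
  a coarser grid the band is truncated at the grid end with a warning.
* **IAF**: center of gravity Σ f·P̄(f)/Σ P̄(f) of the occipital-average
  PSD over bins in [7.5, 12.5] Hz; an all-zero band is an error rather
  than a silent midpoint.
* **Band powers**: trapezoidal integration on the Welch grid; a band
  edge between bins is resolved by linear interpolation of the
  cumulative integral, which makes p continuous in the IAF. The
  normalizing integral runs over the full estimable range [0, fs/2]
  (a PSD does not exist beyond Nyquist). Per channel, Σ_B p_B ≤ 1
  because the five bands cover at most the full range.
* **Hjorth parameters**: activity is the sample variance; derivatives
  are first differences scaled by fs, so mobility is in rad/s (a pure
  sinusoid at f Hz has mobility 2πf; divide by 2π to convert to a Hz
  convention). Complexity ≥ 1 by Cauchy–Schwarz, with equality for a
  sinusoid. A constant channel is an error (zero variance).

## Dataset assembly

Feature ordering is channels-major and frozen: 190 spectral features
(`<ch>.p_delta` … `<ch>.p_gamma`), 114 Hjorth features (`<ch>.hjorth_A`,
`_M`, `_C`), then `age` and `group` — 306 columns. The WR normalization
`(x − y) ⊘ y` applies only to the 304 EEG features; age and group are
appended afterwards, since normalizing a trial-invariant quantity
against itself would annihilate it. Division guards reject WR features
within 1e−12 of zero (synthetic WR features are bounded away from zero
because every band holds background power).

Group is encoded 0/1 (trained/expert) for the learners. Targets are
log(1+y) with exact inverse exp(t)−1.

Standardization is subject-wise — each subject's own trials supply the
location and scale — so leave-one-subject-out evaluation is leakage-free
by construction (asserted: a subject's standardized values are invariant
to deleting any other subject). Methods: z-score, min-max to [0, 1],
`median` (a robust z-score, (x − median)/(IQR/1.349), squashed through
a logistic into (0, 1) — this nonlinear option is under-determined in
the literature, so the definition here is documented and swappable),
and `none`. A zero subject-level scale leaves the feature centered
only, with one summary warning. A side effect worth knowing: age is
constant within subject, so any subject-wise standardizer other than
`none` flattens it; only models selecting `none` (or, marginally,
`median`'s constant 0.5) can exploit age.

## Models

**LSBoost** is stagewise least-squares boosting: F₀ = mean(y), then n
regression trees fit to residuals, each added with shrinkage ρ. Trees
use the squared-error criterion, minimum leaf size l_s, and at most n_s
internal splits, grown best-first by impurity reduction. Hyperparameter
bounds: n ∈ [1, 500], ρ ∈ [0.01, 1], l_s, n_s ∈ [1, 100]. Fewer than
2·l_s training rows is an error.

Two implementations coexist deliberately. The production path wraps
scikit-learn's `GradientBoostingRegressor` (n_estimators = n,
learning_rate = ρ, min_samples_leaf = l_s, max_leaf_nodes = n_s + 1,
squared loss) for speed. `LSBoostReference` is a pure-NumPy
implementation of the same contract with fully specified determinism:
exact greedy search over midpoints of sorted distinct values, ties
broken by lowest feature index then lowest threshold. The test suite
asserts prediction equivalence between the two to 1e−10; importance
attribution can differ where split gains tie exactly (identical
partitions, different credited features), which is why importance
equivalence is only asserted away from the interpolation regime.

Feature importance is the per-feature sum of squared-error impurity
reductions over every split node of every tree, normalized to sum 1.
An ensemble with no splits yields a zero vector with a warning rather
than an error.

**Benchmarks.** Me predicts the training-target mean. LR is the lasso
with objective (1/(2n))·RSS + λ·Σ|β| (intercept unpenalized) and
λ = 2·ln(p)/n computed from the training-fold dimensions — ≈ 0.2044 at
the study scale (n = 56, p = 306). The log is natural; a base-10
reading would give ≈ 0.089, but the natural log is the convention of
the penalty-calibration literature the formula comes from. λ = 0 falls
back to least squares (minimum-norm on rank-deficient designs);
otherwise coordinate descent at tolerance 1e−6.

## Search and evaluation

The CASH objective is the LOSO cross-validated MAE on log targets.
Folds are keyed by unique subject; each fold standardizes subject-wise
(hence once for the whole table), fits on the training subjects and
scores all trials of the held-out subject.

The Bayesian optimizer is sequential model-based minimization over the
mixed space: integers relaxed to the unit cube and rounded, the
standardizer one-hot encoded; the first 10 evaluations are a seeded
Latin hypercube; thereafter a Gaussian process (Matérn 5/2 + white
noise, standardized objective) with expected improvement maximized over
1024 seeded uniform candidates per step. A trial whose objective raises
(e.g. a leaf size the fold cannot support) is logged as failed and the
search continues. The default budget is 100 evaluations; everything is
deterministic given the seed, and per-(dataset, target) seeds derive
from the master seed through a `SeedSequence`.

**Effect sizes.** Cohen's d compares benchmark and LSBoost fold MAEs
with the pooled-SD form d = (m_b − m_m)/√((s_b² + s_m²)/2). Fold MAEs
are paired by subject, but the two-sample pooled form is used as the
field convention for this comparison; its 95 % CI comes from the
noncentral-t distribution with df = 2·n_folds − 2 and noncentrality
d·√(n_folds/2), solved for the noncentrality bounds by root-finding
(with a normal approximation where scipy's nct CDF underflows to NaN).
A model is significant only when both d_Me and d_LR CIs exclude zero.
Degenerate case: two constant, equal samples give d = 0 with a
point CI; constant unequal samples are an error.

Aggregates over significant models use the sample SD (ddof = 1) of the
per-model MAE means, their anti-logs exp(MAE)−1, and the d values. The
importance summary sums each refit model's normalized importances
across the 38 channels within each class (p_δ…p_γ, A, M, C; age and
group pass through) and averages per-channel totals across models; the
topography is emitted as (channel, x, y, score) records on a schematic
head layout, not as an interpolated image.

## Problem sizes used by tests and the acceptance script

The full study conditions (15 subjects, 2×4 trials, 100 search
evaluations, 12 dataset×target combinations) are exercised piecewise:
structural counts and IAF recovery run on the full 15-subject panel;
the planted-effect recovery experiment runs one (dataset, target)
combination with 20 search evaluations; the end-to-end determinism
check runs all 12 combinations on a 4-subject panel with a reduced
search space. These sizes are the package's own test design — large
enough that every contract is exercised at the study's row counts where
the contract is about counts, and scaled down where the contract is
about behavior.

The recovery experiment plants a strong α-band coupling (gain 0.3,
i.e. band power up to ×3.7 at the top of the latent range) rather than
the generator's default 0.05. Narrow bands (θ, α span ~4 bins of the
1 Hz Welch grid) estimate band power with markedly higher variance than
the wide β/γ bands, so a weak α coupling is recoverable in MAE but not
reliably at d > 0.5 with 15 subjects and unit rating noise; the strong
plant makes the experiment a test of the search-and-evaluation
machinery rather than of the pipeline's sensitivity floor, which is a
property of the (synthetic) data, not of the code.

## Known limitations

* Single-level LOSO with the search wrapped around it reproduces the
  analysis as specified; it does not give an unbiased post-selection
  error estimate (no nested CV).
* The subject-wise standardizer uses the held-out subject's own trials
  for location/scale; this is label-free and standard for EEG, but it
  assumes all of a subject's trials are available before prediction.
* The GP optimizer's candidate-set acquisition is simple by design;
  with multimodal objectives and tight budgets it explores less than a
  gradient-refined acquisition would.
* Cohen's d treats fold MAEs as independent samples; subject pairing is
  ignored by the pooled form, and the CI construction inherits that
  approximation.
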