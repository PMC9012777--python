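# Methods

This note documents the models and procedures implemented in `mepdecode`,
the parameter choices that were genuinely open, and what the synthetic
benchmark does and does not establish.

## EMG processing and excitability labels

Per trial the pipeline: (1) subtracts the mean voltage of the 20–1 ms
pre-stimulus interval from the whole trace (residual DC offset), (2) cuts
the post-stimulus analysis segment, (3) demeans and linearly detrends it,
(4) measures the peak-to-peak deflection of the samples whose post-TMS
latency lies in [20, 40] ms.

*Segment start.* The analysis segment starts at **20 ms** post-TMS, not
25 ms, so that the full 20–40 ms measurement window is available inside
the segment; a 25 ms segment start and a 20 ms measurement start are
mutually inconsistent, and the measurement definition wins. With the MEP
template used by the generator the difference is negligible, but the
choice is fixed and documented here.

*Exclusion rules.* Rule 1: pre-stimulus RMS above Q₇₅ + 3·IQR of the
participant's RMS distribution. Rule 2: Pearson correlation below 0.4
against the participant-average segment, where the average is computed
once over Rule-1 survivors (no iteration). Rule 1 is checked first and
wins the recorded exclusion reason. The pre-stimulus RMS window is
**100 ms ending 5 ms before the pulse** — a conventional baseline length
that avoids stimulation-adjacent samples; the protocol constant itself
is not otherwise determined.

*Labels.* Non-excluded trials are sorted by amplitude, ties broken by
trial id ascending; the lower ⌈n/2⌉ are labelled *low*, the rest *high*
(the median trial at odd n goes to *low*). Any fixed rule works; this one
keeps |#low − #high| ≤ 1 and is deterministic.

## EEG band-power features

Common average reference; six half-open 500-ms windows at
(3.005–2.505, …, 0.505–0.005) s before the pulse; per window: demean,
linear detrend, zero-phase 8th-order Butterworth low-pass at 200 Hz,
decimate 5 kHz → 500 Hz.

*Spectrum.* The printed protocol asks for a 0.25 Hz grid from a 0.5 s
window, finer than the window's natural 2 Hz resolution. The
implementation therefore uses a single Hann-tapered segment zero-padded
to 2000 samples — Welch's method degenerating to a padded periodogram;
with one 250-sample segment no averaging is possible. Bins strictly
inside (58, 62) Hz are excluded as line noise; 58 and 62 Hz themselves
are retained, consistent with low-γ ending at 58 and high-γ starting at
62 Hz. Band power is the mean retained PSD per (channel, band):
28 × 6 = 168 features per window.

*Feature scale.* Features enter the classifier as raw band power,
z-scored per fold with training-fold statistics. Standardization is
required for a stable shrinkage target; whether the original analysis
log-transformed features is unknowable from the protocol, and raw power
plus per-fold z-scoring is the leakage-free minimal choice.

## Classifier and grid search

Shrinkage LDA on standardized features: pooled within-class covariance
S (divisor n − 2), regularized as S(λ) = (1 − λ)S + λνI with
ν = tr(S)/p. Weights w = S(λ)⁻¹(m_high − m_low); threshold at the class-
mean midpoint; decision value > 0 predicts *high*. λ is read as
**covariance shrinkage** (the protocol's word "learning rate" has no
meaning for LDA): this is the only reading under which the printed grid
[10⁻¹⁰, 1] is well-defined, λ = 1 gives a scaled nearest-class-mean rule
and λ → 0 recovers plain LDA. At λ ≥ 10⁻¹⁰ the regularized covariance is
numerically invertible even when p exceeds the fold's trial count, which
is exactly the situation at small dataset sizes.

*Feature ranking.* Each feature is discretized into 10 equal-frequency
bins (edges from the training folds; duplicate edges merged, zero rows
dropped), tested for independence from the class by chi-square without
continuity correction, and scored as −log p (p clamped at the smallest
positive float, so scores stay finite and ordered). Ranking is by
descending score, ties by ascending feature index. The binning is the
conventional filter-method choice; the protocol does not define the test
for continuous features.

*Search.* One stratified 5-fold partition is drawn per participant and
shared by the entire grid. Per fold: rank on the training folds only;
for each (n, λ) train on the top-n ranked features and score the held-out
fold; average AUC over folds. Implementation detail: for a fixed fold and
n, one eigendecomposition of S[:n,:n] yields the weights for the whole
λ grid, which is why the full 16,800-configuration search runs in
seconds. The best configuration maximizes mean AUC; ties resolve toward
fewer features, then smaller λ (parsimony). Held-out predictions for
every trial come from its own fold's model at the best configuration.

*AUC.* Rank-based (Mann–Whitney) probability that a high-class score
exceeds a low-class score, ties counted ½ — verified against exhaustive
pair enumeration in the tests.

## Permutation inference

Each rep shuffles the labels uniformly, re-stratifies folds on the
shuffled labels, and re-runs the complete grid search including per-fold
ranking; the rep's best mean AUC is one null sample. Significance: true
AUC above the null's 95th percentile. The null mean (the *empirical
chance level*) sits above 0.5 because the search maximizes over 16,800
configurations; it is recomputed per dataset, never hard-coded. Desk-
scale default: 99 reps on a reduced grid (feature-count stride 8, 10
lambdas); the full 500 × 16,800 protocol is available by flag.

## Generalization analyses

*Cross-participant.* For training participant i: features re-ranked on
all of i's trials, LDA fit with i's personalized best (n, λ) on all of
i's trials, scored on every other participant's trials. Train and test
never share trials; off-diagonal AUCs are compared to theoretical chance
0.5. The matrix diagonal carries the personalized cross-validated AUCs.

*Temporal.* The final-window models (per fold: that fold's ranking and
the best configuration) score the held-out trials' features from each
earlier window, reusing the final-window fold plan. This is the
leakage-free reading, and it makes self-generalization reproduce the
personalized AUC exactly — asserted bit-for-bit in the tests.

*Trial count.* Grid search on the first N trials in occurrence order
(after exclusion), N = 50…450 by 50 where available.

*Group statistics.* Wilcoxon signed rank (zero differences discarded;
exact distribution for n ≤ 25), Mann–Whitney U, Benjamini–Hochberg FDR,
Spearman's ρ — all via scipy/statsmodels behind a thin tail-aware
surface.

## Synthetic data generator

The generator emulates one participant of the acquisition the pipeline
targets: ~600 trials of 28-channel 5 kHz EEG covering 3.005 s before each
pulse, plus single-channel 5 kHz EMG with a pre-stimulus baseline and an
MEP.

- **Latent state.** Standard-normal AR(1) across trials, lag-1
  correlation `rho_state` (default 0.5) — the minimal autocorrelated
  model for excitability states that last seconds. Within each trial the
  state is chained backwards across the six windows with the same
  per-step correlation, so the final window carries the MEP-coupled state
  and earlier windows are progressively noisier copies; `rho_state = 0`
  makes earlier windows uninformative, high values make all six windows
  decodable.
- **EEG.** Per window and channel: six band-limited Gaussian components
  (frequency-domain synthesis, Parseval-normalized) whose realized log
  power is μ_cb + γ_cb·e + N(0, σ_feature), on 1/f-shaped background
  noise (exponent 1, total power 30 µV²). Baselines μ_cb equal the
  in-band background power, so oscillation and background contribute
  comparably, and receive per-participant N(0, 0.3) offsets so
  cross-participant transfer is non-trivial.
- **EMG.** Gaussian baseline (RMS 8 µV) plus a biphasic damped-sinusoid
  template (6 ms period, 5 ms decay, onset 22 ms) scaled so its 20–40 ms
  peak-to-peak equals exp(α + β·e_t + N(0, σ_mep)) µV, α = 6.2
  (≈ 490 µV — a typical MEP at 120% of resting threshold).
- **Contamination.** Default 4% of trials with ≥10× inflated pre-stimulus
  RMS and 3% with an aberrant waveform (enveloped 80–400 Hz noise,
  orthogonalized against the template) of matched amplitude — together
  ≈ 7% excluded, matching the contaminated-trial share reported for real
  recordings of this kind.
- **Seeding.** All signal draws derive from
  `default_rng([seed, stream, trial])`, so extending `n_trials` never
  perturbs earlier trials. Contamination assignment draws an exact-count
  subset from its own stream and therefore depends on `n_trials`; this is
  the one deviation from strict per-trial counter seeding, accepted so
  that configured fractions are hit exactly.

*Effect-size calibration.* No published effect size links band power to
MEP amplitude, so the coupling scale is a modelling choice, fixed once:
`gamma_coupling = 0.4`, `sigma_feature = 0.35`, `beta_mep = 0.6`,
`sigma_mep = 0.5`. Under these defaults the personalized AUC at 300
trials falls in ≈ 0.59–0.70 across seeds and the true-split MEP
modulation is a few hundred percent — the regimes reported for real
cohorts (AUC range ≈ 0.53–0.72; true-split modulation ≈ 260%). The
σ_mep/β ratio also fixes the attainable ceiling: labels are a median
split of noisy amplitudes, so even a perfect decoder of the latent state
cannot reach AUC 1.

*What the generator does not emulate.* Volume-conducted channel
correlations beyond the common average, non-stationary drift (fatigue),
TMS artifacts (irrelevant: only pre-TMS EEG is analyzed), realistic
scalp topographies, or 50/60 Hz line noise. Passing tests therefore
establish correctness of the pipeline's statistics and its behaviour
under known coupling — not performance on any real recording.

## Problem sizes in tests and the acceptance run

The shipped configurations are sized for a single desk CPU: the
acceptance script uses one 300-trial participant (full 16,800-config
search), a 99-rep permutation null on the reduced grid, and a 4 × 150-
trial cohort; the test suite uses 40–300-trial participants and reduced
grids except where the full grid shape itself is under test. The full
protocol (600 trials, 500 permutations, 20 participants) is available
through the same functions and CLI flags.

## Known limitations

- The padded-periodogram reading of the 0.25 Hz grid is an
  interpretation; any other zero-padding scheme would change absolute
  PSD values (not band ratios) slightly.
- Equal-frequency binning for the chi-square filter is one of several
  defensible discretizations; rankings can differ near ties.
- The permutation test re-stratifies folds per permutation; reusing the
  true-label partition is an equally defensible variant and would give
  slightly different null spread.
- `measure_latency` is hardware-dependent and reported for information
  only.
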