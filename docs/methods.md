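# Methods

`herdstress` implements a circadian stress-detection pipeline for dairy
cattle: hourly behavior budgets → composite activity index → sliding-window
spectral decomposition → day/night change detection → triangulated
normal/mild/high labels → sequence classifiers with a one-hour prediction
horizon. This note records the models, the parameters that matter, the
numerical choices, and the places where the design was genuinely open —
including one structural limitation of the change statistic that the
package measures rather than hides.

## Synthetic herd generator

Real collar data of this kind is proprietary, so every stage is exercised
on a simulated herd (`herdstress.synthetic`). The generator emulates:

- **Behavior budgets.** Each cow-hour splits 60 minutes over eating,
  resting, rumination and "other" (mean split 12/22/19/7 min). A cow-specific
  cosine with modulation depth `base_amplitude` (default 0.75, jitter sd
  0.06) and acrophase near 14:00 (jitter sd 1 h) modulates the behaviors
  with fixed relative gains (eating +1.0, resting −0.8, rumination −0.5,
  other +0.6); i.i.d. Gaussian noise (sd 3 min) is added, values are clipped
  positive and rescaled so every hour sums to exactly 60 minutes.
- **Stress episodes.** Independent homogeneous Poisson processes per cow
  and severity, uniform duration 24–72 h, overlaps merged to the higher
  severity. Rates (3.84 mild and 1.09 high episodes per cow per 30 days)
  were derived analytically from the stationary occupancy of an
  M/G/∞ queue so the latent cow-hour mix lands at ≈72% normal / 21% mild /
  7% high. During an episode the modulation depth is redrawn into the
  operational band (mild 0.45–0.60, high 0.25–0.45 on the normalized
  scale), the acrophase shifts by 2–4 h (mild) or 3–6 h (high) with random
  sign, and rumination is cut by 15–25% (mild) or 42–60% (high) with the
  deficit redistributed proportionally over the other behaviors.
- **Weather.** Sinusoidal diurnal temperature (mean 14.5 °C, range 12 °C,
  peak 15:00) with AR(1) day-to-day drift (φ = 0.7, innovation sd 1.5 °C)
  and anti-phase relative humidity (mean 70%, range 25%). These values
  describe a cool highland site: the daily temperature–humidity index (THI)
  peak sits just below the 68 comfort line and crosses it on roughly a
  quarter of days, exceeding 72 only rarely.
- **Veterinary observer.** Rounds at 06:00 and 18:00 sample the latent
  state with sensitivity 0.80 and specificity 0.95; high states produce a
  marked (functional-repercussion) sign with probability 0.7.
- **Milk yield.** Per-cow baseline ≈28 kg/day minus a 10% penalty on
  episode days (half on mild-only and day-after days) plus noise.

What the generator does **not** emulate: sensor dropout and misclassified
behaviors, management events (milking, vaccination) as distinct from
episodes, seasonality/photoperiod, social structure, and between-farm
variation. Passing tests therefore show internal consistency of the
pipeline under its own assumptions, not field performance.

All randomness derives from a single seed; identical configurations give
byte-identical CSV fixtures.

## Activity index

The composite index is A_t = Σᵢ wᵢ·zᵢ,t over the four z-scored budgets,
with weights from the first principal component of the correlation matrix
on a calibration subset (default: each cow's chronologically first 14
days; herd-pooled means/sds are reused for all later z-scoring).

A structural fact matters here: when the four budgets sum to exactly 60,
the standardized behaviors satisfy Σᵢ sdᵢ·zᵢ = 0, so every principal axis
is orthogonal to a strictly positive vector and **cannot** have all-positive
loadings. A strictly positive weight vector on such data also cancels the
diurnal signal almost exactly (verified numerically). The package therefore
exposes two calibration modes:

- `mode="positive"` (the conventional reading): requires all-positive
  loadings, normalizes them to sum to one, and raises a calibration error
  otherwise — which is the guaranteed outcome for exactly compositional
  budgets. It is appropriate for sensor data whose behavior minutes do not
  exhaust the hour.
- `mode="contrast"` (the pipeline default): keeps the signed component
  (flipped so the eating loading is positive) at unit L1 norm. For
  compositional data the latent "general activity" factor necessarily
  appears as this active-vs-rest contrast, and the diurnal rhythm is fully
  preserved.

PC1 explains ≈74% of calibration variance on default synthetic herds.

## Spectral analysis

Rectangular 36-sample windows (36 h = 1.5 circadian cycles at Δt = 1 h)
slide with a 1 h step; a series of T hours yields T − 36 + 1 windows. The
forward DFT is unnormalized (S[k] = Σ s[t]·e^{−i2πkt/N}; the inverse
carries the 1/N). The frequency grid is f_k = k/(N·Δt), so Δf = 1/36 ≈
0.028 h⁻¹ and the circadian line 1/24 ≈ 0.042 h⁻¹ falls between bins 1
(36 h) and 2 (18 h); both are retained by the band-pass, the DC bin is
always zeroed, and harmonics (bins 3–4; 12 h and 9 h) are retained only
when they individually pass the clear-peak screen (`auto` mode).

The clear-peak screen follows the operational criteria: prominence ≥ 2
median-absolute-deviations above the local median in a ±2-bin neighborhood
(edge-truncated, peak excluded) and SNR = 20·log₁₀(magnitude/local median)
≥ 6 dB. Two measured properties of these criteria are worth knowing:
under pure white noise the dominant bin passes them in roughly 60% of
windows (the 4-bin neighborhood is a weak null reference), and the off-bin
24 h tone fails them in roughly half of windows because its own leakage
into the adjacent bin inflates the local median. The criteria are kept as
stated; tests verify them against an independent re-implementation rather
than against an idealized false-positive rate.

Per-window features:

- **amplitude** = 2·max_{k∈band}|S[k]|/N — exact for an on-bin cosine; the
  off-bin 24 h tone is underestimated by a scalloping factor ≈ 0.74
  (measured, documented, not corrected);
- **acrophase** = clock time of the reconstruction's maximum within the
  central 24 h of the window (avoids edge effects); undefined for an
  all-zero window and flagged missing;
- **coherence** = retained-band share of non-DC spectral power, in [0, 1].
  The reference protocol reports a "circadian coherence" without a formula;
  this definition is a declared proxy.

Cow-level stability is the fraction of windows whose clear peak lies in
the circadian band (operational threshold 0.60).

## Change detection and labeling

For each window the first 24 h of the band-passed reconstruction are
z-normalized with the cow's event-free baseline mean/sd and split by civil
clock into day (A, 06:00–18:00) and night (B, 18:00–06:00) subseries of
n = 12; the change statistic is d_t = √(Σ(Aᵢ−Bᵢ)²/n). Per-cow thresholds
T1 = x̄ + s and T2 = x̄ + 2s come from the d_t distribution over event-free
windows (sample sd, ddof = 1), flagging ≈84% and ≈97.7% points of an
approximately Gaussian baseline. "Event-free" means: no veterinary finding
that day, all THI ≤ 68, and (when a truth track exists) a fully normal
latent day; both the start and end date of the 24 h span must qualify.

The label rule is conservative: d_t ≤ T1 → normal regardless of context;
T1 < d_t ≤ T2 → mild and d_t > T2 → high **only if** at least one context
flag fires, else normal. Flags: a positive veterinary record, an hour with
THI > 68, or a circadian deviation (acrophase shifted > 3 h from the cow's
event-free median, circular distance, or amplitude < 0.45× the cow's
event-free median amplitude). The label's reference time is the end of its
24 h day/night span (window start + 24 h); flags are evaluated within ±1 h
of it and never propagate further. Cow-days take the maximum severity of
their hourly labels; contiguous nonzero runs are reported as episodes for
description only.

**Known limitation (measured, structural).** The d_t statistic is, to
first order, proportional to the circadian-band magnitude: the day/night
contrast *is* the rhythm. Any rhythm-loss phenomenon — amplitude
depression, phase shift at reduced amplitude, nocturnal restlessness that
flattens the cycle — *lowers* d_t below its baseline, while the thresholds
flag only the upper tail. A phase-shift scan (0–22 h at 0.55× and 0.35×
amplitude) never produced a single window above T2. Consequently, on
synthetic herds whose episodes depress amplitude into the operational
bands, cow-day sensitivity for high episodes is near zero (≈2%) and
max-rollup false positives push specificity to ≈0.6; the acceptance suite
asserts the nominal recovery targets (sensitivity ≥ 0.8, specificity
≥ 0.9) and that check is expected to fail under these study conditions.
The statistic does respond to contrast *amplification* (e.g. daytime
agitation under heat load), which is plausibly the regime the operational
rule was designed in. A two-sided or lower-tail deviation rule, or a
distance to a per-cow baseline template rather than between A and B, would
detect rhythm loss; both are deliberate departures from the stated rule
and are therefore not the default.

THI = (1.8·T + 32) − (0.55 − 0.0055·RH)·(1.8·T − 26) with comfort ≤ 68,
mild 68–72, high > 72. Note the formula is *increasing* in RH for
T > 14.44 °C (humid heat is worse), and collapses to 1.8·T + 32 at
RH = 100.

Veterinary binarization per cow-day: no signs → 0; signs in exactly one
round → 1; signs in both rounds, or any marked/functional sign → 2;
coexisting findings take the maximum.

Leakage-safe covariates (for the covariate-extended models): VAS is a
declared proxy — the cow-standardized mean absolute deviation of circadian
amplitude and coherence, standardized against each cow's *past only*
(expanding statistics) and taken from the most recent daily summary whose
36 h data span ends strictly before the clinical exam (lag 1 day for
evening exams, 2 for morning ones); milk yield enters as the previous-day
value and the vet indicator only in lagged form.

## Sequence models

Samples are 24 h windows of causal hourly channels — the four z-scored
budgets plus, when enabled, five circadian channels (s_circ from the
window ending at that hour, amplitude, acrophase as sin/cos, coherence) —
with the label at the anchor (contemporary) or anchor + 1 h (prospective)
as target. The veterinary indicator, THI and d_t are never features: they
drive the labels and would leak the answer. Channel scalers are fitted on
training samples only.

No deep-learning framework is pre-installed in the supported environment,
so the recurrent and convolutional models are implemented directly in
numpy (`herdstress.models.nn`) with manual backpropagation, verified
against numerical gradients: LSTM/GRU cells, 1-D convolution with global
average pooling, batch norm, dropout, Adam with optional global-norm
clipping. The primary classifier is LSTM(144, tanh cell, sigmoid gates,
input dropout 0.2) → batch norm → dense(36, ReLU) → softmax(3), Adam at
1e-3, batch size 36, up to 100 epochs with early stopping on validation
macro-F1 (chronological last 15% per cow) and reduce-on-plateau. Batch
normalization is placed between the LSTM output and the dense layer (the
stated architecture leaves this open). The ReLU-cell variant adds
clipnorm = 1.0 and recurrent dropout 0.1. Training is deterministic given
the seed (single-threaded, seeded init/shuffling/dropout); early-stopping
snapshots capture batch-norm running statistics along with the weights.

Baselines: logistic regression, random forest (200 trees), RBF-SVM
(C = 1, γ = scale), k-NN, one/two-layer dense networks (64 and 64–32,
declared since only the family names are stated), optional XGBoost, and
sequence baselines GRU(16), stacked LSTM(32→16), and a light 1-D CNN
(32 filters, kernel 3, global average pooling). Class weighting is off by
default; an inverse-frequency option exists because triangulated labels
are heavily imbalanced (≈96% normal), which makes unweighted macro-F1
degenerate on small herds. Probability ties break toward the lower
severity class.

## Evaluation

Chronological split at September 1 (10 cows × non-leap year → 2430/1220
train/test cow-days; the simulator's default start date is chosen in a
non-leap year so these counts hold exactly, and the leap-year divergence
244/122 per cow is tested explicitly). LOCO cross-validation holds out one
cow per outer fold with 3 expanding chronological inner folds (the inner
count is a package default; it is not externally specified); every
artifact — activity weights, scalers, thresholds — refits on the training
herd only. Metrics: accuracy, macro precision/recall/F1, per-class scores,
one-vs-rest ROC-AUC and PR-AUC macro-averaged over classes present in the
truth (absent classes are dropped with a warning). Uncertainty uses the
percentile cluster bootstrap resampling whole cows (B = 2000 default);
measured coverage of the 95% interval is ≈93% at 60 clusters — the usual
small-cluster undercoverage of the percentile method, documented rather
than corrected (BCa was considered and rejected for simplicity). Agreement
uses Cohen's kappa with linear or quadratic ordinal weights. Pairwise model
comparison bootstraps per-cow paired deltas, Holm–Bonferroni-adjusts the
p-values and reports Cohen's d on the deltas.

Ablation arms: labeling arms (no_vet, no_thi, no_vet_no_thi) force the
corresponding flag off and re-derive labels; feature arms keep labels
fixed and modify model inputs only (no_harmonics disables harmonic
retention, no_coherence zeroes that channel, no_circadian_filter feeds raw
activity in place of the reconstruction). Arms share seeds with the full
arm and are bit-identical upstream of the ablated element.

The power utility simulates paired per-cow macro-F1 values from a declared
correlated-Gaussian model (the comparison's generative model is not
externally specified) and reports the rejection rate of a one-sided paired
t-test; it is indicative only.

## Problem sizes and reproducibility

Default problem sizes were chosen to keep a full verification run on a
single CPU core comfortably under half an hour: the episode-recovery herd
is 10 cows × 120 days, the model benchmark 8 cows × 60 days with sequence
stride 3, three seeded replicates, a 20-epoch cap with early stopping, and
balanced class weights for all families (without which macro-F1 on ≈1%
minority labels is mostly luck). The benchmark's logistic-regression
baseline uses the raw behavior channels, matching its role as the simple
reference model. `scripts/acceptance.py --seed N --out results.json`
recomputes every headline quantity from scratch; all randomness descends
from the given seed.

## Known limitations

- The change statistic cannot detect rhythm loss under the stated
  upper-tail rule (see above) — the central scientific caveat.
- Coherence and VAS are declared proxies for quantities the reference
  protocol names but does not define.
- The clear-peak criteria are permissive under noise and penalize the
  off-bin circadian tone; stability fractions should be read relative to
  these criteria, not as rhythm prevalence.
- Percentile bootstrap intervals undercover slightly at herd-scale cluster
  counts.
- The numpy sequence models are CPU-scale; they reproduce the stated
  architectures and training protocol, not any particular trained weights.
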