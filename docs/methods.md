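# Methods

This note documents the models, numerical choices, and limitations of the
`emgrehab` pipeline: what each stage computes, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely open.

## Signal preprocessing

Raw EMG is cleaned per channel with a 50 Hz IIR notch (quality factor 30,
about 1.7 Hz rejection bandwidth) and a 4th-order Butterworth bandpass at
20–450 Hz. Both filters are applied zero-phase (forward–backward), so
contraction envelopes are not phase-shifted; the cost is an effective
doubling of the filter order, which is immaterial for these wide margins.
The two filters are linear and nearly commute: swapping their order changes
per-window RMS by well under 1 % (property-tested).

Contraction epochs are cut from the cue timeline stored in each recording's
sidecar, not detected from amplitude — the acquisition protocol is visually
cued with fixed 5 s rest / 5 s contraction timing, so cue-based epoching is
both simpler and unbiased by amplitude pathology. Each epoch is trimmed by a
250 ms guard at both ends to exclude the on/off ramps (configurable to 0).

Milliseconds convert to samples by flooring: at 1926 Hz, a 250 ms window is
481 samples (481.5 floored) and a 50 % overlap steps by 240 samples. A 5 s
contraction (9630 samples) therefore yields 39 windows without guard trim,
and a guard-trimmed epoch of 8668 samples yields 35. The trailing partial
window is discarded.

## Feature bank

Sixteen features per window per channel, concatenated across the five
channels (80 feature columns), never pooled — muscle identity is
information. Definitions are in the `emgrehab.features` docstring. Choices
that a name alone does not fix:

* **VAR/SD** use the sample (N−1) denominator; **RMS/AENG** use N. The
  identities IEMG = N·MAV, AENG = RMS², VAR = SD², WL = (N−1)·AAC hold to
  machine precision and are property-tested.
* **ZC/SSC** deadband thresholds default to 0; clinical practice sometimes
  uses small positive deadbands, so both are configurable.
* **CARD** (cardinality) counts distinct values after sorting, merging
  consecutive sorted values that differ by at most 1e−4 of the window SD —
  tying the tolerance to the SD makes the feature scale-invariant.
* **Kurtosis** defaults to the Fisher (excess) convention with the biased
  (population-moment) estimator; a constant window, where the moment ratio
  is undefined, is reported as 0 with a logged warning.
* **MNF/MDF** come from a Welch PSD (256-sample segments, 50 % overlap),
  which has usefully lower variance than a raw periodogram on 481-sample
  windows; a periodogram mode is retained because its bin structure makes
  closed-form oracle tests exact. MDF interpolates linearly inside the bin
  where cumulative power crosses half the total. All-zero windows report
  (0, 0) with a warning.

## Classification and progression

Per patient per week, the 80-column window table is classified into the
seven movements with KNN (k = 5, Euclidean), random forest (100 trees), and
RBF-SVM (C = 1), hyperparameters fixed with no tuning — tuning would change
the measurand. Features are standardized with statistics fitted on training
folds only.

Cross-validation folds are grouped by **repetition**, not window:
overlapping windows within one contraction share signal, and window-level
folds would leak train into test, inflating accuracy. Each repetition
contains every movement, so grouped folds keep every class in every training
fold. With three repetitions at most three folds are possible; the pipeline
default is 3 (requesting more folds than repetition groups is a
configuration error). A window-level stratified mode exists for sensitivity
analysis.

Accuracies are computed per patient and averaged within group — the
patient, not the pooled window set, is the unit of analysis. Longitudinal
summaries: (a) week-pair progression cells — within-group mean per-patient
accuracy change in percentage points, averaged over the two groups — with
paired two-tailed t per group, one-way ANOVA between groups on the
per-patient difference scores, and a Shapiro–Wilk normality record; the
follow-up-vs-baseline cell telescopes exactly as the sum of the
consecutive-pair cells; (b) per group-week, the mean and sample SD across
the three classifier-level accuracies.

## Clinical statistics

Spearman correlations use average-rank tie handling; the two-sided p-value
is the t approximation for n > 8 and an exact permutation p (all n!
pairings) for n ≤ 8. Mann–Whitney U (reported for the first sample, ties
counted half) uses the full exact relabeling distribution when m + n ≤ 12 —
valid under ties, unlike the classical exact tables — and the tie-corrected
normal approximation with continuity correction otherwise. Both are
calibrated: under the null the type-I error at α = 0.05 lies in
[0.03, 0.07] over 1000 replications (tested).

Correlation strength labels use |ρ| cutoffs 0.3 (moderate) and 0.6 (strong),
a common guideline; they are configurable because they are a reporting
convention, not a property of the data. No multiple-testing correction is
applied by default (replication of raw P < .05 reporting); a
Benjamini–Hochberg mode is available.

The EMG summary entering each correlation is, by default, the grand mean of
a feature over windows, repetitions, and movements, then over channels —
the least-assuming aggregation; per-channel and median modes exist. This is
a replication-sensitive choice: with per-movement or per-channel summaries
the correlation table changes.

Clinical outcomes: group means/SDs pre and post, Mann–Whitney p at each
timepoint, and the difference-in-differences
(exp_post − exp_pre) − (ctrl_post − ctrl_pre) compared against the MCID
(FMA-UE 9, ARAT 6, BBT 6 points) under **strict** inequality — a difference
exactly at the threshold is not clinically meaningful. The
difference-in-differences is exactly invariant to adding a constant to all
scores (tested).

## Synthetic cohort generator

The generator exists so that every downstream stage is testable without
patient data; it is a statistical surrogate, not a physiological simulator.

**Latent.** Each patient carries a recovery latent
λ(w) = min(plateau, λ0 + gain·w) ∈ [0, 1], the *separability* of their
movement-specific activation patterns. Group-level rate models supply the
means; per-patient draws of λ0 (SD 0.05), gain (relative SD 0.18), and the
ceiling (SD 0.15) make patients start, recover, and saturate at different
levels. The per-patient ceiling matters: with a shared hard plateau, every
patient in a group reaches the identical latent at late weeks, and
within-group EMG–clinical correlations — which the analysis must be able to
detect — would collapse by construction.

**EMG.** Per channel, an amplitude-modulated band-limited (20–450 Hz)
Gaussian carrier — the standard sEMG surrogate — under a trapezoidal
envelope with 250 ms ramps, zero at rest. The movement-m pattern at latent λ
is the blend (1−λ)·Ā + λ·A[m] of the patient's 7×5 activation matrix A with
its movement-average Ā: at λ = 0 all movements look alike, at λ = 1 they
are fully distinct. Recovery also (a) shrinks per-repetition multiplicative
jitter (scale 0.7·0.15^λ) and (b) raises overall activation strength by a
factor 1 + 1.5·λ — recovering muscle both stabilizes and strengthens, and
the amplitude term is what links amplitude-type EMG features to the clinical
scores. Activation matrices are drawn once per patient (uniform 0.2–1.5)
and normalized to a common grand mean, treating overall electrode gain as a
held nuisance. Added noise: 50 Hz line interference (amplitude 0.05,
random phase), < 2 Hz drift (0.08 RMS), and white noise 18 dB below the
mean activation. All streams derive from one master seed by hashing
(patient, week, movement), so any subset regenerates identically.

**Clinical scores.** FMA-UE = clip(round(F0 + β·λ·(66−F0) + ε)) with β = 1
(λ = 1 means full recovery), ε ~ N(0, 1); ARAT analogous into [0, 57]; BBT
adds β·λ·35 blocks. Baseline FMA-UE is drawn from a clipped normal
(mean 40, SD 6) inside the inclusion band [25, 55]; ARAT and BBT baselines
are correlated with it. Scores are non-decreasing in expectation in λ, so
Spearman correlations and MCID effects are recoverable by design.

**Calibration of defaults.** Group rate defaults (experimental λ0 = 0.35,
gain 0.063/week, plateau 0.76; control gain 0.05/week, plateau 0.68) and the
jitter scale were chosen, once, so that the default full-protocol accuracy
trajectory lies in the vicinity of ~37 % at baseline rising to ~80 % at
follow-up with the experimental arm ahead from week 4 — while keeping the
group contrast (~6–7 accuracy points at weeks 6–9) large enough to be
detectable at the reduced cohort sizes used in tests. The generator makes no
claim to reproduce any real patient population; a single latent driving
accuracy, amplitude, and all three scales is a deliberate simplification
that real cohorts (with dissociations between dexterity and strength,
spasticity, fatigue, electrode-placement drift across sessions) will
violate. Passing parameter-recovery tests therefore shows the *pipeline*
recovers structure a cohort contains, not that real recovery has this
structure.

**Problem sizes in tests.** The test and acceptance runs use a shortened
protocol (1 s rest, 2 s contraction; 11 windows per epoch instead of 35)
and 5–8 patients per arm over three assessment weeks with 3–5 replicate
seeds — large enough for the ordering and calibration properties being
asserted, small enough to keep the suite quick. Absolute accuracies under
the shortened protocol are systematically lower than full-protocol values
(fewer windows, same class count); all cross-arm and cross-week comparisons
are unaffected.

## Known limitations

* No motor-unit physiology, spasticity grading, fatigue, or electrode-shift
  modelling in the generator; amplitude and separability are tied to one
  latent.
* The per-patient-per-week classification scheme, classifier
  hyperparameters, EMG aggregation entering correlations, ZC/SSC deadbands,
  CARD tolerance, and PSD estimator are all choices a strict replication of
  the original analysis could differ on; each is configurable and the
  defaults are documented above.
* Item-level clinical scoring, responder analysis beyond the MCID flag, and
  causal effect estimation are out of scope.
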