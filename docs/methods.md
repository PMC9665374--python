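# Methods

`pulsewave` re-implements, at desk scale and on synthetic data, an
electro-mechanical pulse-wave analysis pipeline for predicting elevated
left ventricular end-diastolic pressure (LVEDP ≥ 25 mmHg vs normal
≤ 12 mmHg). The real study data — per-patient orthogonal voltage
gradient (OVG) and photoplethysmography (PPG) recordings paired with
catheterization LVEDP — are proprietary, so the package pairs every
analysis stage with a synthetic generator that emulates the acquisition
and encodes known ground truth. What can be reproduced exactly from
published numbers (the Bayesian chaining values, the Clopper–Pearson
interval behind the printed sensitivity CI, and the BNP comparator
simulation) is reproduced exactly; what depended on the proprietary
cohort (the headline validation AUC of 0.81 and its secondary analyses)
is covered as pipeline capability demonstrated on synthetic cohorts.

## Synthetic cohort and signals

**Cohort.** Subjects are assigned to the three LVEDP strata
(≤ 12 / 13–24 / ≥ 25 mmHg) multinomially with default proportions
258 : 347 : 79 (the validation cohort's split of 684). Within a stratum,
LVEDP is a truncated normal with the published stratum moments
(9 ± 3 on [0, 12]; 18 ± 3 on [13, 24]; 29 ± 4 on [25, 38] mmHg).
Demographics use the published moments as truncated normals (age
63 ± 10 y on [18, 95], BMI 32 ± 7, EF 60 ± 7%), 45% women, and
per-stratum obstructive-CAD probabilities (0.43 / 0.33 / 0.24). Only
moments and counts are published; the distributional families are this
package's choice.

**Signals.** Per subject: 3 OVG channels at 8 kHz quantized to the
0.024 µV amplitude grid, and 2 PPG channels (red/infrared) at 500 Hz,
default duration 210 s (the 3.5-minute acquisition). Each cardiac cycle
is a sum of three Gaussian bumps per channel — atrial wave (120 µV,
centred 180 ms before the fiducial), ventricular depolarization
(1000 µV, σ = 12 ms, the fiducial itself), ventricular repolarization
(250 µV, σ = 45 ms, +300 ms) — each with a fixed 3-D orientation, the
minimal morphology that produces the loop structure the phase-space
features quantify. Heart rate defaults to 70 bpm with 20 ms
beat-to-beat RR jitter. The PPG is a baseline plus a gamma-shaped pulse
whose foot trails the OVG fiducial by 200 ms; the pre-systolic nadir
(pulse base) is the per-beat minimum. A respiration-like 0.25 Hz
amplitude modulation (depth 0.10) rides on the pulse train.

**Effect encoding.** LVEDP enters through the normalized excess
`e = clip((lvedp − 12)/13, 0, 1)` linearly linked to three latent
parameters: atrial-duration jitter SD (2 ms + 6 ms·e — 8 ms when
elevated), PPG pulse-base level (+80 optical units·e), and fractional
repolarization-loop perturbation SD (0.02 + 0.15·e). The direction
(features discriminate elevation) is published; the linear-ramp form
and slopes are this package's choice. Every record stores the realized
per-beat quantities (`GroundTruth`) so extractors are tested by
parameter recovery rather than by circular re-computation.

**What the generator does not emulate.** Electrode geometry and
lead-field physics, real morphological variability (P/QRS/T shape
families, ectopy, AF), baseline wander, motion artifacts, and
covariate-linked confounding (age/BMI do not influence the signals).
Signals are noiseless apart from quantization unless noise is injected
explicitly. Two consequences matter for interpreting green tests:
(i) classification on synthetic cohorts is far easier than on patients —
the default effect links separate the primary strata essentially
perfectly, so held-out AUC ≈ 1.0 here says the pipeline recovers an
encoded effect, not that real-world accuracy would be 1.0; and (ii) the
effect dose-response is steep (because `e` is exactly 0 vs 1 for the two
primary strata and measurement noise is minimal), so the monotonicity
test samples the transition region at small fractions of the default
slopes.

## Signal quality gates

Powerline SNR = 10·log10 of (0.5–40 Hz band power / 59.5–60.5 Hz band
power), Welch periodogram with 4 s Hann segments at 50% overlap,
averaged in dB over the three channels (worst-channel mode available).
High-frequency SNR uses the > 150 Hz band. The published acceptance
values 57 (powerline) and 19 (high-frequency) carry no units; they are
interpreted here as dB of band-power ratio, which the noise-injection
oracle tests make consistent (injecting 60 Hz at relative power `r`
degrades the measured SNR to −10·log10 r dB). PPG saturation is the
fraction of samples at/above the configured sensor ceiling (4096
arbitrary units), gated at 5% — a fraction, not an SNR, since
saturation is transient. Band edges, thresholds and the ceiling are
config-overridable; the signal band 0.5–40 Hz and noise bands are
documented constants chosen where the source is silent.

## Feature extraction

Beats are detected on the band-passed (0.5–40 Hz, zero-phase Butterworth
order 4) three-channel magnitude with 250 ms refractory peak picking.
Atrial duration is the width of the atrial bump at 10% of its local
peak, measured on the raw magnitude (the band-passed signal carries slow
undershoot from the large ventricular bump that would corrupt a
10%-of-peak threshold). The feature families carry representative,
documented members (the full proprietary 292+ feature set is not
public): atrial duration mean/SD and RR statistics plus a median-beat
template residual (time domain); atrial-loop vector magnitude and
orientation, and repolarization-loop dispersion — mean pairwise distance
between band-pass-filtered, time-aligned repolarization segments of the
3-D trajectory, skipping beats within 3 s of the record edges where the
zero-phase filter is still settling (phase space); pulse-base max /
mean / SD and pulse-amplitude statistics (PPG indicators); band-power
fractions over 0.5–5 / 5–15 / 15–40 Hz (OVG spectral); OVG-fiducial to
PPG-foot delay statistics (sync); and the dominant frequency and depth
of the pulse-train amplitude-modulation envelope (respiration).
Windows are half-open `[start, end)` in seconds; sample indices 0-based.

## Ensemble modelling

Isolation-Forest outlier exclusion (default contamination 5%) precedes
training. Thirteen constituents — 4 random forests (depths 3, 4, 5, 7),
5 gradient-boosted tree configurations (depths 3–7, conservative
learning rates), 4 elastic-net logistic regressions (l1 ratios
0.15–0.85) — are varied by stratified bootstrap of the training
subjects, random feature subsets, and label-threshold pairs cycled over
(≥25 vs ≤12), (≥25 vs ≤15), (≥20 vs ≤12) mmHg. The nominal subset-size
range 89–194 applies to feature tables at the original scale and is
clipped to the available column count on this package's ~25-column
table. Each constituent's output is min–max normalized on its training
outputs and clipped to [0, 1] on new data; the ensemble score is the
arithmetic mean of the 13 normalized outputs. Cross-validation is
stratified 5-fold repeated 100 iterations with re-randomized folds. The
binary operating point is chosen on development data as the largest
threshold achieving 82% sensitivity. All stochastic steps derive child
seeds from one integer seed (`numpy SeedSequence`), making training and
prediction bit-reproducible.

## Diagnostic evaluation

AUC is the Mann–Whitney statistic with ties worth ½; its variance and
the paired AUC test follow DeLong–DeLong–Clarke-Pearson structural
components (an unpaired z-variant serves between-subgroup comparisons,
where subjects differ). Clopper–Pearson intervals are exact beta
quantiles. The threshold sweep recomputes the AUC per
(elevated, non-elevated) definition pair, and the (≥25, ≤12) cell is by
construction bit-identical to the primary analysis on the same scores.
Propensity matching fits a logistic model on age and gender and pairs
greedily 1:1 nearest-neighbour without replacement, treated order
randomized by seed, optional caliper; the published work names only
"propensity matching", so the greedy variant is this package's choice.
Mid-stratum (13–24 mmHg) subjects are excluded from primary metrics.

## BNP simulation and Bayesian analysis

The comparator (BNP) exists only as published five-number summaries:
non-cardiac dyspnea (0, 75, 190, 475, 1075) and obese HFpEF
(0, 250, 250, 750, 5000). Samples honour the constraints by
piecewise-uniform interpolation: one of the four inter-statistic
segments with probability ¼ each, uniform within; the zero-width HFpEF
q25 = median segment is a 25% point mass at 250. This scheme was chosen
because its closed-form threshold exceedances reproduce both published
NRIs from the published summaries together with the ML operating point:
at 150, BNP sens = 0.85 and spec ≈ 0.413, giving
(0.82 − 0.85) + (0.68 − 0.413) ≈ 0.24; at 50, sens = 0.95 and
spec ≈ 0.167, giving ≈ 0.38. Its closed-form AUC is ≈ 0.655 — inside
the published interval 0.61–0.71 though below the printed mean 0.69;
both values are reported and the discrepancy is left unresolved, as is
the source's ng/mL-vs-pg/mL axis inconsistency (values are compared on
one axis). Per iteration the two groups are drawn at n = 258/79, AUC
and threshold statistics computed, and 1000 iterations aggregated as
mean with a 2.5–97.5 percentile interval. Post-test probabilities use
LR+ = sens/(1 − spec) and LR− = (1 − sens)/spec on the odds scale, with
degenerate specificities mapped to posterior 1 (positive) for
non-degenerate priors. The NRI is the two-category marginal form,
(Δsens + Δspec), again because it reproduces both published values.

## Problem sizes and numerical choices

Tests run the identical code paths at desk scale: most signal tests use
12–40 s acquisitions (the 3.5-minute default is exercised where the
study-scale beat count matters, e.g. jitter-SD recovery over ~244
beats); modelling properties use cohorts of 90–300 subjects. The
parameter-recovery acceptance checks use n = 300 with a half-normal /
half-elevated split. Repolarization segments are resampled to 80 points
per beat by linear interpolation; the atrial width threshold crossing is
linearly interpolated between samples; Welch band powers are rectangle
sums of the periodogram, which keeps a discrete sinusoid's full power
inside its ±0.5 Hz band. Degenerate inputs fail loudly: all-zero
signals raise an undefined-SNR error, flat-line records raise
`NoCyclesDetected` (< 10 beats), single-class label sets raise, and
min–max normalizers with zero span emit 0.5.

## Known limitations

The feature definitions are representative reconstructions, not the
proprietary set; real-data accuracies are out of reach by design. The
percentile CI of the simulated NRI is wider than the published CI
(0.18–0.30 at the 150 threshold) — only the means are anchored; the
published CI presumably reflects a different aggregation that the
source does not specify. The synthetic PPG carries no sensor noise, so
saturation is the only PPG failure mode modelled. Propensity matching
assumes enough covariate overlap for full 1:1 pairing; with a caliper
it may return fewer pairs, with a warning left to the caller.
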