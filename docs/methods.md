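# Methods

## Signal model

The measurement chain assumes continuous-wave fNIRS with two wavelengths
(730 and 850 nm) and a fixed source-detector separation. Optical-density
change is taken against an epoch-start reference intensity,
ΔOD(λ,t) = −log₁₀(I(λ,t)/I_ref(λ)); the modified Beer-Lambert law then
relates ΔOD at the two wavelengths linearly to the two chromophore
concentration changes,

    ΔOD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR) · L · DPF(λ),

solved exactly per sample as a 2×2 system. The shipped extinction
coefficients are standard tabulated molar values (1/(mM·cm)):
ε(730) = (0.446, 1.1022), ε(850) = (1.058, 0.6913) for (HbO, HbR), with
pathlength L = 2.5 cm and DPF = 6.0 at both wavelengths. All are
configurable; their absolute values scale concentrations but cancel in
the sign and normalized magnitude of the left-right asymmetry difference,
which is what the feedback loop consumes.

Filtering uses a linear-phase FIR low-pass (order 20, cutoff 0.1 Hz at
fs = 2 Hz, Hamming windowed-sinc). The design method and the zero-lag
alignment (edge padding plus a group-delay shift of order/2 samples) are
the package's choices; DC gain is exactly 1 by construction and the
response at 0.5 Hz is below −20 dB.

Motion artifacts are flagged by a sliding-window statistic: a window
(default 10 s) advancing sample-by-sample is flagged when its internal
sample SD exceeds `z_thresh` (default 3.0) times the channel's reference
SD, taken as the median of all rolling SDs over the recording; the mask
covers every sample of flagged windows, and channels with more than
`max_reject` (default 0.5) of samples flagged are unusable. These
parameters are deliberately config-exposed rather than fixed: the method
family is standard but its exact parameterization varies between
laboratories. Note one consequence of the self-referencing design: a
channel contaminated during most of the recording raises its own
reference SD and escapes flagging — the reference assumes artifacts are
a minority of the data.

Each block's HbO is re-referenced to the per-channel unmasked mean of
the last 10 s of that block's first Rest epoch, so all concentrations
are changes relative to a within-block baseline. Rebasing is idempotent.

## Protocol model

A session is 8 identical blocks of
Rest(20 s) → Prompt(3 s) → View(40 s) → Rest(10 s) → Prompt(3 s) →
NF(40 s) → Rest(7 s), sampled at 2 Hz. The initial-Rest duration of 20 s
is a package default (it must only exceed the 10-s baseline tail).
Analysis windows for View and NF are the epoch extent shifted forward by
the hemodynamic delay (default 7 s): the first 7 s of each epoch are
excluded and the 7 s after it included, giving exactly 80 samples per
40-s epoch. Prompt epochs never enter any analysis. Coordinates are
seconds from session start, half-open intervals, sample index
= floor(t·fs). Under the default schedule the shifted View and NF
windows cannot overlap; a strict mode errors on any window that would
run past the recording.

## Feedback mapping

Asymmetry is mean(HbO) over the four left-group channels minus mean(HbO)
over the four right-group channels, per sample, with artifact-masked
channels dropped from each side's mean (a sample is invalid only when a
whole side is masked). The per-block map is fit on the delayed View
window after a single-pass 3-SD outlier trim:

    Min = mean + 1.28·SD        Max = Min + (max − min)

computed on the trimmed values with the sample SD (n−1; a population-SD
flag exists). 1.28 is the 90th-percentile normal quantile, so about 90%
of View-like values earn no feedback. The delayed window (not the raw
epoch extent) feeds the fit, consistent with every other View statistic.
NF asymmetry maps linearly onto [0, 1] between Min and Max; values above
Max clamp to 1 (the actuator is bounded; over-range behaviour is a
package decision), values at or below Min give 0. During streaming,
invalid samples hold the last valid score to avoid feedback
discontinuities; the trim is single-pass, not iterated.

## Agent control

Four engagement levels partition the score: exactly 0 → disengaged idle,
(0, 1/3] → neutral, (1/3, 2/3] → mild positive, (2/3, 1] → high positive
(bins configurable, including a positive-only three-level variant). The
placement of the disengaged behaviors at score 0 is a design choice: the
loop gives no explicit negative reward, so "no feedback" is rendered as
idle disengagement. Eight behaviors cover the levels — three disengaged
(gaze aversion/down, pout, lowered lip corners: AU15, AU17, AU18, AU23,
AU24, AU43, AU61, AU62, AU64 plus cervical/lumbar vertebra movements),
one neutral (empty AU set), two mild positive and two high positive
smiles (AU1, AU2, AU5, AU6, AU12, AU25, AU26 plus head tilts). AU
intensities within a behavior default to 1.0 with a reduced smile gain
(AU12 = 0.6) at the mild level; which AUs are active, not the listed
magnitudes, is what distinguishes the repertoire.

Holding a level for ~2 s (dwell) switches to a different behavior of the
same level; switching is deterministic round-robin (a seeded random mode
exists) and never repeats the immediately preceding behavior when the
level offers more than one. Every behavior change cross-fades AU/BAP
values over 1 s with a smoothstep ease (both package choices); blending
is convex per key, so intensities never overshoot [0, 1]. Frames are
emitted at 25 fps with the 2 Hz score held between ticks. The
score→level→AU/BAP propagation is the package's documented monotone gain
structure; within a level's bin, no emitted intensity decreases as the
score rises.

## Statistics

Block success: one-tailed pooled-variance two-sample t-test of NF > View
on the windowed, filtered, artifact-cleaned asymmetry samples (masked
samples dropped listwise per epoch), at α = 0.0125 — the per-subject
Bonferroni-adjusted threshold taken at its stated value rather than
re-derived. The entire NF window enters the test, not only
above-threshold samples. A seeded percentile bootstrap (1000 resamples
of each epoch, 95% CI of the mean difference) is reported alongside the
analytic decision; a strict-bootstrap mode decides by the CI lower bound
instead, since which rule produced any given historical count cannot be
recovered. Zero pooled variance with equal means fails with p = 1; with
unequal means the sign decides and the result is flagged degenerate.

Effect sizes use the pooled-SD Cohen's d, r = |t|/√(t²+df) (sign carried
with the mean difference), OVL = 2·Φ(−|d|/2) and PoS = Φ(d/√2) under the
equal-variance normal model, and the normal-approximation detection
limits d_min = z·√(2/n), r_min = z/√(z²+2n−2) with z = Φ⁻¹(1−α). At the
protocol's operating point (n = 80, α = 0.0125) these give d_min ≈ 0.35
and r_min ≈ 0.18. A subject is a respondent with ≥ 1 successful block;
`received_feedback` records whether any NF sample crossed the block's
Min. The Epoch×Side interaction is computed as a paired t on the
per-block contrast (L−R)_NF − (L−R)_View, reported with F = t² — the
full repeated-measures ANOVA machinery is out of scope.

## Virtual subjects

Each channel is gain·(NF boxcar ⊛ HRF) + view_gain·(View boxcar ⊛ HRF) +
drift + oscillations + white noise. The HRF is the canonical double
gamma (modes 6 s and 16 s, undershoot ratio 1/6, unit peak; the
convolution kernel is unit-sum so a sustained epoch plateaus at the
gain). Defaults: responder gain 0.47 μMol/L on left-group channels, 0.13
on the right, bilateral View gain 0.2, noise SD 0.2 μMol/L per channel,
drift 0.05 μMol/L/min, Mayer wave 0.05 μMol/L at 0.1 Hz and respiration
0.03 μMol/L at 0.25 Hz with independent phase per channel, no artifacts
unless requested. These magnitudes emulate a strongly responding subject
(per-block standardized shifts around d ≈ 2–3) with View showing no
lateralized difference in expectation. A non-respondent is modelled with
zero left gain and a positive right gain — its asymmetry *falls* during
NF, which is the only configuration that reproduces "never crosses the
threshold": a flat subject with iid noise would cross a mean+1.28·SD
threshold somewhere in ~640 NF samples with near certainty. Ground truth
per block records the realized noiseless window means and the implied
standardized shift d_true = Δmean/√(σ_noise² + within-window signal
variance), so estimator recovery can be checked against what was
actually programmed. A per-block gain schedule can emulate strategy
shifts. All randomness flows from explicit seeds; identical seeds are
bit-identical.

A separate asymmetry-scale generator (`simulate_epoch_pair`: View
~ N(0,1), NF ~ N(d,1), 80 samples each) drives the type-I calibration
and effect-recovery studies, where iid samples are the intended model.

## What the simulator does and does not show

The generator reproduces the *structure* the pipeline assumes — delayed
hemodynamics, lateralized gain, drift, oscillations, spikes — not real
optode physics (no photon transport, no skin blood flow, no
channel-specific coupling). Two honest consequences surface in
end-to-end runs. First, after 0.1 Hz low-pass filtering the 2 Hz samples
are strongly autocorrelated, and slow oscillations survive into the
analysis windows; the t-test's independence assumption is then violated
and its type-I rate on *filtered session data* exceeds the nominal α
(flat-gain subjects show occasional spurious successes). The nominal
calibration (0.0125 ± MC error) holds exactly at the iid sample level,
which is what the calibration criterion checks. Second, recovered d̂ on
filtered data exceeds the raw-noise ground truth because filtering
removes most white-noise variance; recovery is unbiased against ground
truth on unfiltered asymmetry. Both effects are properties of the
analysis design itself, not implementation artifacts.

## Problem sizes and numerical choices

Monte-Carlo checks run at the sizes their statements name: 10⁵ samples
for the 90%-threshold calibration (tolerance ±0.01), 10⁴ null replicates
for type-I (±0.004), 500 replicates per effect size for recovery
(±0.1). The MBLL round trip is exact to 1e-9 (double-precision 2×2
solve); FIR DC gain is within 1%; sample SD (n−1) is used everywhere for
consistency between the mapping and the statistics. Degenerate inputs
(zero spread, fully-masked windows, too-short series) raise named
errors rather than producing silent NaNs.
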