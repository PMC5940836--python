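# Methods

This note documents the models, rules and numerical choices behind
`ppgbp`, in the order the pipeline runs, together with the design
decisions that were genuinely open and the limitations of the synthetic
validation.

## Signal model and beat extraction

A finger PPG is treated as a pulsatile (AC) waveform riding on a slowly
varying baseline (DC). Per cardiac cycle the quantities of interest are

- **IBI** — time between consecutive pulse feet, ms; **HR** = 60000/IBI
  (bpm), so HR × IBI = 60000 holds exactly by construction;
- **AC** — within-beat maximum minus the value at the beat's foot;
- **DC** — within-beat mean of the raw (unconditioned) signal;
- **mNPV** = AC/DC, used downstream as ln mNPV. Because AC and DC scale
  identically with optical gain, mNPV is invariant to the sensor's gain —
  the property that makes it comparable across devices.

*Onset definition.* The beat onset is the pulse foot: the local minimum
preceding the systolic upstroke. Systolic peaks are found on a
zero-phase band-passed copy (Butterworth order 2, 0.5–8 Hz by default)
with a prominence threshold (0.3 of the running 5–95 percentile
amplitude) and a refractory spacing (250 ms, i.e. HR ≤ 240 bpm); each
foot is the minimum of the detection signal in the preceding inter-peak
interval, ties broken by the earliest sample. Because the band-pass
skews the foot of an asymmetric pulse by a small constant amount, each
coarse foot is then snapped to the local minimum of the raw signal
within a window of 3.5% of the median inter-onset spacing (at least 2
samples). On noise-free signals this recovers the true foot to the
sample at both 60 Hz and 1000 Hz; under strong additive interference
(e.g. mains) the snap can wander within its window, bounding the onset
error by roughly ±15 ms — the corresponding tolerance is stated in the
interference tests.

*Onset timing is integer-sample.* Onsets are reported as sample indices
and all timing derives from them. At 60 Hz the worst-case quantization
is one frame (≈17 ms, ~2% of an 800-ms beat); sub-sample interpolation
was considered and rejected to keep the detect→extract contract (indices
in, features out) unambiguous.

*Polarity.* Input must be oriented so a pulse is a positive deflection.
`invert=True` (CLI `--invert`) reflects the signal about its mean —
rather than negating it — so transmittance recordings (more blood →
less light) keep a positive DC level. A non-positive per-beat DC is
rejected as an orientation/offset error.

*Open choice — the DC reading.* Whether a device's DC is the per-beat
mean, the foot value, or a low-pass track is not standardized. This
package defines DC as the per-beat mean of the raw signal; the choice is
visible in the worked example, where a pulse riding on baseline 10.0
yields DC slightly above 10.0 and a mean ln mNPV of −3.64 for a
configured −3.63.

## Outlier rule and block averaging

A beat is rejected when it *drives* the sample SD of the preceding 10-s
window above the limit — 8.0 bpm for HR or 0.25 a.u. for ln mNPV:
SD(window ∪ candidate) > limit while SD(window) ≤ limit. Operational
details fixed here (the rule's plain statement underdetermines them):

- the window holds only *accepted* beats with onsets strictly before the
  candidate; previously flagged beats are excluded from all later
  windows so one artifact cannot poison 10 s of decisions;
- sample SD uses the n−1 denominator;
- warm-up: with fewer than two accepted in-window predecessors the SD is
  undefined and the beat passes;
- HR and ln mNPV criteria are joint — either one rejects the whole beat,
  since a beat is a single observation;
- beats with undefined ln mNPV (zero pulse amplitude) are flagged
  outright.

The filter is causal: appending future beats never changes earlier
flags. It is validated beat-for-beat against an independent O(n²)
re-implementation on 1000 random series.

Accepted beats are averaged over caller-specified blocks (45 s default,
one quarter of a 3-min measurement period; the block grid is not
hard-coded). A block is *missing* when its outlier fraction strictly
exceeds 20% — exactly 20% is valid — or when it holds no beats. One
consequence worth knowing: an abrupt, genuine condition change larger
than the SD limits (e.g. a step of > 0.25 in ln mNPV between adjacent
blocks) is itself flagged as a cascade of outliers until the old level
ages out of the window, which can render the first block after the
transition missing. The closed-loop test scenario therefore uses
between-block steps below the limits.

## Blood-pressure model

Calibration is ordinary least squares of ln(reference BP) on ln HR and
ln mNPV with intercept, pooled across subjects and conditions with no
per-subject terms — avoiding individual calibration is the method's
point. Natural logs throughout. Reported diagnostics: multiple
correlation R, standardized betas (β · SD(predictor)/SD(response)), and
two-sided coefficient p-values. No regularization and no quadratic
terms: HR and HR² are nearly collinear (r > 0.99 over physiological
ranges), which destabilizes higher-order fits without improving R.
Estimation back-transforms with the exponential, so estimates are
strictly positive, and a shift δ in ln mNPV moves ln BP̂ by exactly
b·δ. The reference MAP is DBP + (SBP − DBP)/3; the formula is linear,
so the MAP of group means equals the mean of per-reading MAPs.

Fewer than 4 rows is an error (no residual degree of freedom); a
constant predictor is a degenerate design. The OLS itself is delegated
to statsmodels; tests cross-check the coefficients against a direct
least-squares solve.

Residual diagnostics are reported on the mmHg scale (reference −
estimate) as the correlation of estimates with residuals; on the ln
scale this correlation is ~0 by the normal equations, and when residual
variance is at numerical-noise level (a noiseless exact fit) it is
reported as not applicable rather than as a correlation of rounding
dust.

## Agreement statistics

- **Geometric mean regression** (reduced major axis):
  slope = sign(r) · SD(y)/SD(x), intercept through the means. Swapping
  the axes maps the slope to its reciprocal — the symmetry that makes it
  appropriate when both methods carry error.
- **Bland–Altman**: differences are second argument minus first,
  averages are pairwise means; fixed bias = mean difference. Limits
  default to bias ± 1 SD (the convention used in pulse-app validation
  figures); ±1.96 SD is available via `limit_multiplier`.
- **Paired comparison**: two-sided paired t (df = n − 1) and Cohen's d
  in the pooled-SD form d = (m₂ − m₁)/√((s₁² + s₂²)/2). This form
  reproduces the published MAP (1.42) and DBP (1.57) effect sizes from
  their printed summary statistics; `d_from_summary` exposes it without
  raw data. When the differences have zero variance and zero mean, t and
  p are reported as not applicable.
- Normality screening of residuals is delegated to scipy's Shapiro–Wilk
  and surfaced pass/fail; it is not re-implemented.

Sample SDs use n−1 everywhere.

## Synthetic data

**Waveforms.** Each beat is a gamma-shaped kernel k(u) = (u/p)^α ·
exp(α(1 − u/p)) with α = 2 and peak at p = 22% of the beat — fast
systolic upstroke, slow diastolic decay. Only the foot timing, amplitude
and baseline are contractual; the kernel shape is a free choice. The
kernel is zero (with zero slope) at the foot, so every foot sits exactly
on the baseline profile, and onsets are snapped to the sample grid;
ground-truth annotations (onset, IBI, AC, DC per beat) are computed from
the clean signal with the same definitions the extractor uses, making
oracle comparisons exact rather than approximate. HR/AC/DC profiles can
be constants, ramps, steps or arbitrary callables; Gaussian sample noise
and Gaussian-shaped artifact spikes are optional. An HR profile implying
an IBI below the refractory period is rejected. Fixed seed ⇒ bitwise
identical output.

Features of real PPG *not* emulated: dicrotic notches, respiratory
amplitude/baseline modulation, autocorrelated beat-to-beat variability,
sensor saturation, and motion artifacts more structured than additive
spikes. Passing tests therefore demonstrate correctness of the
definitions and rules, not detector performance on clinical recordings.
One known interaction: with additive noise the AC (a within-beat
maximum) is biased upward by the expected extreme of the noise, so
noisy-signal mNPV recovery is tested at loose tolerances and noiseless
recovery at tight ones.

**Cohorts.** Per subject × condition × block, ln HR and ln mNPV are
drawn independently from condition-specific normals; ln SBP and ln DBP
follow their generating (a, b, c) triples plus a Gaussian residual on
the ln scale; values are exponentiated and MAP derived by the one-third
formula. The residual draw is shared by SBP and DBP within an
observation — common-mode measurement/physiological noise — which also
keeps SBP > DBP essentially surely; mean-level coherence is checked up
front. Because generated MAP comes from the one-third formula rather
than its own log-linear equation, exact coefficient recovery is asserted
for SBP and DBP (the linearly generated indices); MAP is only
approximately log-linear.

The `study_cohort_spec` preset encodes the study conditions this
package targets: 13 subjects × 2 conditions (rest BL, mental-arithmetic
stress MA) × 2 blocks ≈ 52 rows; HR means 75.0/92.0 bpm with
between-subject SDs 14.1/19.7 bpm (converted to the ln scale by the
delta method, SD(ln HR) ≈ SD/mean); ln mNPV means −3.63/−4.37 with SDs
0.35/0.37; generating triples of realistic magnitude, e.g. MAP
(0.305, −0.084, 2.905). The default residual SD, 0.097 on the ln-BP
scale, was calibrated once by simulation so pooled fits at these
conditions average R ≈ 0.69, and is not adjusted thereafter. Blocks
within a subject × condition are independent (no within-subject
correlation is modeled — the data to estimate one are not available),
so condition effect sizes are evaluated on row-level values; simulated
d for HR (~1.0) and ln mNPV (~2.1) land at the intended magnitudes,
while BP-level effect sizes are attenuated (d ≈ 1.1 for MAP rather than
~1.4) because a generating model explaining R ≈ 0.69 of ln BP transmits
only part of the condition separation into BP.

## Problem sizes and runtime choices

The test suite and the acceptance script size their simulations for
interactive use: 30–360 s waveforms at 60 Hz (1000 Hz where sample-exact
timing at laboratory rate is the point), 1000 random series for the
outlier-filter oracle, 300–1000 Monte-Carlo cohorts of n = 49 for
coefficient-recovery checks, and an 8-block closed-loop run. The full
suite runs in well under a minute on one core.

## Known limitations

- The beat detector is validated on synthetic pulse trains; its
  parameters (band, prominence, refractory, snap window) are sensible
  defaults, not clinically tuned values.
- The AC definition (max − foot) has a positive bias under additive
  noise; a matched-filter or percentile amplitude would be more robust
  but departs from the plain foot-to-peak reading of AC.
- Calibration transfers across devices only to the extent the device's
  mNPV scale matches; wavelength and probing-depth differences shift the
  intercept c, and pooled fits are per device.
- The exponential back-transform ignores retransformation bias
  (E[exp(ε)] > 1); at residual SDs ≈ 0.1 this is a ~0.5% level effect,
  absorbed into c during calibration on the same scale.
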