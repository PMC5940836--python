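# ppgbp — cuffless blood-pressure estimation from a photoplethysmogram

`ppgbp` implements a calibration-light cuffless blood-pressure (BP)
pipeline for single-channel finger photoplethysmography (PPG), the kind
of signal a smartphone camera/LED pair or a laboratory transmittance
probe produces. It is aimed at biomedical-signal researchers who want a
transparent, testable reference implementation of the HR + mNPV
log-linear approach, complete with the quality-control rules and the
method-comparison statistics used to validate it.

## The model

Mean arterial pressure is the product of cardiac output and total
peripheral resistance, MAP = CO × TPR. Cardiac output tracks heart rate
(HR), and peripheral resistance tracks finger vascular tone, which the
PPG exposes as the **modified normalized pulse volume**
mNPV = AC / DC — the per-beat pulsatile amplitude over the baseline
light level. Taking logs motivates a linear model per BP index
(MAP, SBP, DBP):

    ln BP = a · ln HR + b · ln mNPV + c          (calibration, OLS)
    BP̂   = exp(a · ln HR + b · ln mNPV + c)     (estimation)

The pipeline stages:

1. **Beat extraction** (`ppgbp.signal`) — pulse-foot onset detection on a
   band-limited copy (0.5–8 Hz, zero phase) with raw-signal refinement;
   per beat: IBI (ms), HR = 60000/IBI (bpm), AC (foot-to-peak), DC
   (within-beat mean), mNPV = AC/DC.
2. **Quality control** (`ppgbp.quality`) — a beat is an outlier when it
   drives the SD of the preceding 10 s above 8.0 bpm (HR) or 0.25 a.u.
   (ln mNPV); accepted beats are averaged over 45-s blocks, and a block
   with strictly more than 20% outliers is missing.
3. **Calibration / estimation** (`ppgbp.model`) — pooled OLS of
   ln(reference BP) on ln HR and ln mNPV; exponential back-transform;
   reference MAP = DBP + (SBP − DBP)/3.
4. **Agreement analytics** (`ppgbp.agreement`) — geometric mean
   regression, Bland–Altman bias and limits, paired t-test and pooled-SD
   Cohen's d.
5. **Synthetic data** (`ppgbp.synthetic`) — waveform and cohort
   generators with exact ground truth, so every stage is testable
   without recorded data.

## Worked example

```python
import numpy as np
from ppgbp import (WaveformSpec, generate_waveform, detect_beats,
                   extract_beat_features, flag_outliers, block_average)

# 60 s of synthetic finger PPG at a smartphone-like 60 Hz, 75 bpm,
# with pulse amplitude set so mNPV sits at a realistic 0.0265
record, truth = generate_waveform(WaveformSpec(
    duration_s=60.0, sampling_rate=60.0, hr_profile=75.0,
    ac_profile=0.265, dc_profile=10.0))
beats = flag_outliers(extract_beat_features(record, detect_beats(record)))
block = block_average(beats, block_start_s=0.0, block_len_s=45.0)
print(f"{len(beats)} beats, block status={block.status}")
print(f"mean HR = {block.mean_hr:.2f} bpm, mean ln mNPV = {block.mean_ln_mnpv:.3f}")
```

prints

```
74 beats, block status=valid
mean HR = 75.00 bpm, mean ln mNPV = -3.643
```

Every detected inter-beat interval is exactly 800 ms (75.00 bpm), and the
recovered mean ln mNPV is within 0.02 of ln 0.0265 ≈ −3.63 — the
residual offset comes from the pulse waveform riding on the baseline,
which raises the within-beat mean slightly above the configured DC.

Calibrating and applying the BP model on a synthetic cohort:

```python
from ppgbp import fit_all, predict, generate_cohort
from ppgbp.synthetic import study_cohort_spec

rows, truth = generate_cohort(study_cohort_spec(seed=1))
coeffs = fit_all(rows)   # 13 subjects x 2 conditions x 2 blocks = 52 rows
f = coeffs["MAP"]
print(f"MAP: a={f.a:.3f} b={f.b:.3f} c={f.c:.3f} R={f.r:.2f}")
print(predict(coeffs, hr=75.0, ln_mnpv=-3.63))
```

prints

```
MAP: a=0.264 b=-0.102 c=2.989 R=0.74
BPReading(sbp=116.35063802035172, dbp=76.61981516294635, map=89.88885226360756)
```

The fitted multiple correlation sits in the R ≈ 0.7 regime the
generator's noise level targets, and the estimated triple at the resting
operating point (75 bpm, ln mNPV −3.63) lands in the normotensive range
with SBP > MAP > DBP.

A command-line interface mirrors the stages
(`ppgbp beats|filter|blocks|fit|predict|agree|simulate-waveform|simulate-cohort|run`);
see `ppgbp --help`.

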