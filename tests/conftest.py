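"""Shared fixtures: synthetic signals, beat series, and a closed-loop scenario."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ppgbp import (
    BeatFeature,
    CalibrationRow,
    WaveformSpec,
    block_averages,
    detect_beats,
    extract_beat_features,
    fit_all,
    flag_outliers,
    generate_waveform,
    predict_index,
)
from ppgbp.model import BPReading
from ppgbp.synthetic import STUDY_COEFFS


def make_beat(
    onset_time: float,
    hr: float = 75.0,
    ln_mnpv: float = -3.6,
    outlier: bool = False,
) -> BeatFeature:
    """A BeatFeature with internally consistent ibi/ac/dc for given hr, ln mNPV."""
    ibi = 60000.0 / hr
    dc = 10.0
    mnpv = math.exp(ln_mnpv)
    return BeatFeature(
        onset_time=onset_time,
        ibi=ibi,
        hr=hr,
        ac=mnpv * dc,
        dc=dc,
        mnpv=mnpv,
        ln_mnpv=ln_mnpv,
        outlier=outlier,
    )


def steady_series(
    n: int = 100, hr: float = 75.0, ln_mnpv: float = -3.6, start: float = 0.0
) -> list[BeatFeature]:
    """n beats at constant HR/ln mNPV, correctly spaced in time."""
    period = 60.0 / hr
    return [make_beat(start + i * period, hr, ln_mnpv) for i in range(n)]


def random_series(rng: np.random.Generator, n: int = 60) -> list[BeatFeature]:
    """Random jittery beat series for oracle-equivalence trials."""
    hr_level = rng.uniform(55.0, 110.0)
    lnm_level = rng.uniform(-4.5, -3.2)
    hr_jit = rng.uniform(0.5, 12.0)
    lnm_jit = rng.uniform(0.02, 0.4)
    t = 0.0
    beats = []
    for _ in range(n):
        hr = max(35.0, hr_level + rng.normal(0.0, hr_jit))
        lnm = lnm_level + rng.normal(0.0, lnm_jit)
        beats.append(make_beat(t, hr, lnm))
        t += 60.0 / hr
    return beats


@pytest.fixture(scope="session")
def train_60hz():
    """Noiseless 30-s pulse train at exactly 75 bpm, smartphone-like rate."""
    return generate_waveform(WaveformSpec(duration_s=30.0, sampling_rate=60.0, hr_profile=75.0))


@pytest.fixture(scope="session")
def train_1khz():
    """Noiseless 30-s pulse train at exactly 75 bpm, laboratory-like rate."""
    return generate_waveform(WaveformSpec(duration_s=30.0, sampling_rate=1000.0, hr_profile=75.0))


def model_exact_rows(n: int = 24, seed: int = 0) -> list[CalibrationRow]:
    """Calibration rows whose ln BP follows the generating triples exactly
    (zero residual) for all three indices; MAP stored as its own exact
    log-linear value, which stays between DBP and SBP at these levels."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        ln_hr = rng.uniform(math.log(60.0), math.log(110.0))
        lnm = rng.uniform(-4.6, -3.2)
        vals = {
            ix: math.exp(a * ln_hr + b * lnm + c)
            for ix, (a, b, c) in STUDY_COEFFS.items()
        }
        rows.append(
            CalibrationRow(
                hr=math.exp(ln_hr),
                ln_mnpv=lnm,
                reference=BPReading(sbp=vals["SBP"], dbp=vals["DBP"], map=vals["MAP"]),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Closed-loop scenario: waveform -> beats -> blocks -> fit -> predict
# ---------------------------------------------------------------------------

# Adjacent block steps stay below the outlier-filter SD limits (8 bpm,
# 0.25 a.u.) so a condition change does not flag a cascade of real beats.
BLOCK_HRS = [70.0, 75.0, 80.0, 85.0, 90.0, 95.0, 88.0, 80.0]
BLOCK_LNM = [-3.5, -3.7, -3.9, -4.1, -4.3, -4.15, -3.95, -3.75]
BLOCK_LEN = 45.0


def closed_loop_scenario(seed: int = 0, noise_sd: float = 0.0, ref_noise: float = 0.01):
    """Eight 45-s blocks with stepped HR and pulse amplitude; cuff references
    generated from the log-linear model at the block-true operating points.

    Returns (estimates, references) per index as dict of (est, ref) arrays.
    """
    dc = 10.0

    def hr_profile(t: float) -> float:
        return BLOCK_HRS[min(int(t // BLOCK_LEN), len(BLOCK_HRS) - 1)]

    def ac_profile(t: float) -> float:
        lnm = BLOCK_LNM[min(int(t // BLOCK_LEN), len(BLOCK_LNM) - 1)]
        return dc * math.exp(lnm)

    spec = WaveformSpec(
        duration_s=BLOCK_LEN * len(BLOCK_HRS),
        sampling_rate=60.0,
        hr_profile=hr_profile,
        ac_profile=ac_profile,
        dc_profile=dc,
        noise_sd=noise_sd,
        seed=seed,
    )
    record, _ = generate_waveform(spec)
    beats = extract_beat_features(record, detect_beats(record))
    flagged = flag_outliers(beats)
    summaries = block_averages(
        flagged, [(i * BLOCK_LEN, BLOCK_LEN) for i in range(len(BLOCK_HRS))]
    )
    rng = np.random.default_rng(seed + 1)
    rows = []
    for s, hr_true, lnm_true in zip(summaries, BLOCK_HRS, BLOCK_LNM):
        if s.status != "valid":  # noisy blocks may exceed the outlier budget
            continue
        ln_hr = math.log(hr_true)
        sbp = math.exp(
            STUDY_COEFFS["SBP"][0] * ln_hr
            + STUDY_COEFFS["SBP"][1] * lnm_true
            + STUDY_COEFFS["SBP"][2]
            + rng.normal(0.0, ref_noise)
        )
        dbp = math.exp(
            STUDY_COEFFS["DBP"][0] * ln_hr
            + STUDY_COEFFS["DBP"][1] * lnm_true
            + STUDY_COEFFS["DBP"][2]
            + rng.normal(0.0, ref_noise)
        )
        rows.append(
            CalibrationRow(
                hr=s.mean_hr, ln_mnpv=s.mean_ln_mnpv, reference=BPReading(sbp=sbp, dbp=dbp)
            )
        )
    coeffs = fit_all(rows)
    hr_arr = np.array([r.hr for r in rows])
    lnm_arr = np.array([r.ln_mnpv for r in rows])
    out = {}
    for ix in ("MAP", "SBP", "DBP"):
        est = predict_index(coeffs[ix], hr_arr, lnm_arr)
        ref = np.array([r.reference.value(ix) for r in rows])
        out[ix] = (est, ref)
    return out
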