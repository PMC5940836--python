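"""Beat detection and HR/mNPV feature extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgbp import (
    BeatDetectionConfig,
    PPGRecord,
    WaveformSpec,
    detect_beats,
    extract_beat_features,
    generate_waveform,
    read_ppg_csv,
    signal_conditioning,
)
from ppgbp.errors import (
    InvalidFilterConfig,
    NoBeatsFound,
    NonPositiveDC,
    SignalTooShort,
)
from ppgbp.signal import beats_to_frame, frame_to_beats


@pytest.mark.parametrize("train", ["train_60hz", "train_1khz"])
class TestCleanTrainRecovery:
    """On noiseless 75-bpm trains every beat must match ground truth."""

    def test_count_and_exact_hr(self, train, request):
        record, truth = request.getfixturevalue(train)
        onsets = detect_beats(record)
        beats = extract_beat_features(record, onsets)
        assert abs(len(beats) - 37) <= 1  # 30 s at 75 bpm -> 37 complete beats
        assert all(b.hr == pytest.approx(75.0, abs=1e-9) for b in beats)

    def test_features_match_ground_truth(self, train, request):
        record, truth = request.getfixturevalue(train)
        beats = extract_beat_features(record, detect_beats(record))
        n = min(len(beats), len(truth))
        dt = 1000.0 / record.sampling_rate
        for b, (_, row) in zip(beats[:n], truth.iloc[:n].iterrows()):
            assert abs(b.ibi - row.ibi_ms) <= dt  # within one sample period
            assert b.ac == pytest.approx(row.ac, rel=0.01)
            assert b.dc == pytest.approx(row.dc, rel=0.01)

    def test_hr_ibi_identity(self, train, request):
        record, _ = request.getfixturevalue(train)
        beats = extract_beat_features(record, detect_beats(record))
        for b in beats:
            assert b.hr * b.ibi == pytest.approx(60000.0, abs=1e-6)


def test_flat_signal_raises_no_beats():
    record = PPGRecord(samples=np.full(3000, 5.0), sampling_rate=100.0)
    with pytest.raises(NoBeatsFound):
        detect_beats(record)


def test_short_signal_rejected():
    record = PPGRecord(samples=np.sin(np.arange(50) * 0.5) + 2, sampling_rate=100.0)
    with pytest.raises(SignalTooShort):
        detect_beats(record)


def test_amplitude_change_does_not_shift_feet(train_1khz):
    """Doubling one beat's amplitude must leave all onsets where they were."""
    record, _ = train_1khz
    base = detect_beats(record)
    doubled, _ = generate_waveform(
        WaveformSpec(
            duration_s=30.0,
            sampling_rate=1000.0,
            hr_profile=75.0,
            ac_profile=lambda t: 0.53 if 10.4 <= t < 11.2 else 0.265,
        )
    )
    modified = detect_beats(doubled)
    n = min(len(base), len(modified))
    assert np.array_equal(base[:n], modified[:n])


def test_conditioning_rejects_mains_interference(train_1khz):
    """50 Hz interference: onsets stay close to the clean train's onsets."""
    record, _ = train_1khz
    clean = detect_beats(record)
    t = np.arange(record.samples.size) / record.sampling_rate
    noisy = PPGRecord(
        samples=record.samples + 0.3 * 0.265 * np.sin(2 * np.pi * 50.0 * t),
        sampling_rate=1000.0,
    )
    got = detect_beats(noisy)
    assert len(got) == len(clean)
    assert np.abs(got - clean).max() <= 16  # within the foot-snap window (16 ms)
    beats = extract_beat_features(noisy, got)
    assert np.mean([b.hr for b in beats]) == pytest.approx(75.0, abs=0.5)


def test_conditioning_toggle_identical_on_clean_signal(train_1khz):
    record, _ = train_1khz
    on = detect_beats(record, BeatDetectionConfig(conditioning=True))
    off = detect_beats(record, BeatDetectionConfig(conditioning=False))
    assert np.array_equal(on, off)


def test_invalid_filter_configuration():
    record = PPGRecord(samples=np.sin(np.arange(200)) + 2, sampling_rate=10.0)
    with pytest.raises(InvalidFilterConfig):
        signal_conditioning(record, BeatDetectionConfig(band_hz=(0.5, 8.0)))  # 8 >= Nyquist 5


def test_dc_offset_moves_dc_not_ac(train_60hz):
    record, _ = train_60hz
    onsets = detect_beats(record)
    base = extract_beat_features(record, onsets)
    shifted_rec = PPGRecord(samples=record.samples + 100.0, sampling_rate=60.0)
    shifted = extract_beat_features(shifted_rec, onsets)
    for b0, b1 in zip(base, shifted):
        assert b1.ac == pytest.approx(b0.ac, abs=1e-12)
        assert b1.dc == pytest.approx(b0.dc + 100.0, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gain=st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
def test_gain_invariance_of_mnpv(gain):
    """Multiplying all samples by k > 0 leaves every mNPV unchanged."""
    record, _ = generate_waveform(
        WaveformSpec(duration_s=10.0, sampling_rate=60.0, hr_profile=80.0)
    )
    onsets = detect_beats(record)
    base = extract_beat_features(record, onsets)
    scaled = extract_beat_features(
        PPGRecord(samples=record.samples * gain, sampling_rate=60.0), onsets
    )
    for b0, b1 in zip(base, scaled):
        assert b1.mnpv == pytest.approx(b0.mnpv, rel=1e-12)


def test_faster_train_raises_every_hr():
    slow, _ = generate_waveform(WaveformSpec(duration_s=20.0, sampling_rate=100.0, hr_profile=70.0))
    fast, _ = generate_waveform(WaveformSpec(duration_s=20.0, sampling_rate=100.0, hr_profile=90.0))
    hr_slow = [b.hr for b in extract_beat_features(slow, detect_beats(slow))]
    hr_fast = [b.hr for b in extract_beat_features(fast, detect_beats(fast))]
    assert max(hr_slow) < min(hr_fast)


def test_mean_ln_mnpv_recovery_at_smartphone_level():
    """AC/DC chosen for mNPV ~= e^-3.63: recovered mean ln mNPV within 0.02."""
    record, _ = generate_waveform(
        WaveformSpec(
            duration_s=60.0,
            sampling_rate=60.0,
            hr_profile=75.0,
            ac_profile=10.0 * math.exp(-3.63),
            dc_profile=10.0,
        )
    )
    beats = extract_beat_features(record, detect_beats(record))
    assert np.mean([b.ln_mnpv for b in beats]) == pytest.approx(-3.63, abs=0.02)


class TestFeatureArithmetic:
    """The AC/DC/IBI definitions on hand-built segments."""

    def test_single_beat_ac_dc_mnpv(self):
        # one beat: onset value 9.0, max 11.0, mean 10.0 over the interval
        fs = 10.0
        seg = np.array([9.0, 10.0, 11.0, 10.5, 9.5, 10.0, 10.0, 10.0])  # mean 10.0
        samples = np.concatenate([seg, [9.0, 11.0]])
        record = PPGRecord(samples=samples, sampling_rate=fs)
        (beat,) = extract_beat_features(record, np.array([0, 8]))
        assert beat.ac == pytest.approx(2.0)
        assert beat.dc == pytest.approx(10.0)
        assert beat.mnpv == pytest.approx(0.2)
        assert beat.ln_mnpv == pytest.approx(math.log(0.2), abs=1e-9)

    def test_ibi_and_hr_from_onset_spacing(self):
        fs = 100.0
        record = PPGRecord(samples=np.ones(200) * 10.0 + np.sin(np.arange(200)), sampling_rate=fs)
        beats = extract_beat_features(record, np.array([0, 80]))  # 800 ms apart
        assert beats[0].ibi == pytest.approx(800.0)
        assert beats[0].hr == pytest.approx(75.0)

    def test_non_positive_dc_rejected(self):
        record = PPGRecord(samples=np.linspace(-1.0, -0.5, 100), sampling_rate=100.0)
        with pytest.raises(NonPositiveDC):
            extract_beat_features(record, np.array([0, 50]))

    def test_zero_ac_beat_flagged_not_fatal(self):
        samples = np.concatenate([np.full(50, 10.0), [10.0, 12.0]])
        record = PPGRecord(samples=samples, sampling_rate=100.0)
        (beat,) = extract_beat_features(record, np.array([0, 50]))
        assert beat.mnpv == 0.0
        assert math.isnan(beat.ln_mnpv)


def test_invert_recovers_transmittance_polarity(train_60hz):
    record, _ = train_60hz
    upright = detect_beats(record)
    flipped = PPGRecord(samples=2 * record.samples.mean() - record.samples, sampling_rate=60.0)
    inverted = detect_beats(flipped, BeatDetectionConfig(invert=True))
    assert np.array_equal(upright, inverted)


def test_ppg_csv_roundtrip(tmp_path):
    record, _ = generate_waveform(WaveformSpec(duration_s=10.0, sampling_rate=60.0))
    path = tmp_path / "ppg.csv"
    import pandas as pd

    pd.DataFrame({"time_s": record.times(), "value": record.samples}).to_csv(path, index=False)
    loaded = read_ppg_csv(path)
    assert loaded.sampling_rate == pytest.approx(60.0, rel=1e-6)
    assert np.allclose(loaded.samples, record.samples)
    # value-only variant needs an explicit rate
    pd.DataFrame({"value": record.samples}).to_csv(path, index=False)
    with pytest.raises(ValueError):
        read_ppg_csv(path)
    assert read_ppg_csv(path, rate=60.0).sampling_rate == 60.0


def test_beat_table_roundtrip(train_60hz):
    record, _ = train_60hz
    beats = extract_beat_features(record, detect_beats(record))
    frame = beats_to_frame(beats)
    back = frame_to_beats(frame)
    assert [b.hr for b in back] == pytest.approx([b.hr for b in beats])
    assert [b.outlier for b in back] == [b.outlier for b in beats]
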