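"""Beat-level feature extraction from a raw photoplethysmogram (PPG).

A finger PPG is a pulsatile (AC) waveform riding on a slowly varying
baseline (DC). Each cardiac cycle contributes one pulse; the pulse *foot*
(the local minimum immediately before the systolic upstroke) marks the beat
onset. From consecutive onsets this module derives, per beat:

* the inter-beat interval IBI (ms) and heart rate HR = 60000 / IBI (bpm),
* the AC amplitude (within-beat maximum minus the value at the foot),
* the DC level (within-beat mean of the raw signal), and
* the modified normalized pulse volume mNPV = AC / DC, used downstream on
  the natural-log scale (ln mNPV) as an index of finger vascular tone.

Detection runs on a band-limited copy of the signal (default 0.5-8 Hz,
zero phase); amplitude features always read the unconditioned samples so
the DC level is preserved. The input must be oriented so a pulse is a
positive deflection; ``invert=True`` reflects the signal about its mean to
accommodate transmittance devices where more blood means less light.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    InvalidFilterConfig,
    NoBeatsFound,
    NonPositiveDC,
    SignalTooShort,
)

__all__ = [
    "PPGRecord",
    "BeatFeature",
    "BeatDetectionConfig",
    "signal_conditioning",
    "detect_beats",
    "extract_beat_features",
    "read_ppg_csv",
    "beats_to_frame",
    "frame_to_beats",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPGRecord:
    """A uniformly sampled single-channel PPG signal.

    Parameters
    ----------
    samples
        Signal amplitude in arbitrary units (or mV), uniformly sampled.
    sampling_rate
        Sampling rate in Hz; both smartphone-like (60 Hz) and
        laboratory-like (1000 Hz) rates are supported.
    start_time
        Time of the first sample in seconds.
    channel_label
        Free-text provenance, e.g. ``"transmittance-IR"``.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class BeatFeature:
    """One detected cardiac beat and its derived quantities.

    ``hr`` and ``ibi`` satisfy hr * ibi = 60000 exactly; ``mnpv`` is the
    dimensionless AC/DC ratio and ``ln_mnpv`` its natural log (NaN when the
    beat has zero pulse amplitude). ``outlier`` is set by the quality
    filter and is False on freshly extracted beats.
    """

    onset_time: float
    ibi: float
    hr: float
    ac: float
    dc: float
    mnpv: float
    ln_mnpv: float
    outlier: bool = False


@dataclass(frozen=True)
class BeatDetectionConfig:
    """Settings for onset detection.

    refractory_s
        Minimum spacing between onsets (default 0.25 s, i.e. HR <= 240 bpm).
    min_prominence_frac
        Peak prominence threshold as a fraction of the running pulsatile
        amplitude of the conditioned signal.
    band_hz
        Pass band of the zero-phase conditioning filter used for detection.
    conditioning
        When False the detector runs on the mean-removed raw signal.
    invert
        Reflect the signal about its mean before any processing.
    min_duration_s
        Shortest analyzable record (two generous beat periods).
    """

    refractory_s: float = 0.25
    min_prominence_frac: float = 0.3
    band_hz: tuple[float, float] = (0.5, 8.0)
    conditioning: bool = True
    invert: bool = False
    min_duration_s: float = 2.0


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------

def signal_conditioning(
    record: PPGRecord, config: BeatDetectionConfig | None = None
) -> PPGRecord:
    """Return a band-limited copy of *record* for onset detection.

    A second-order Butterworth band-pass is applied forward and backward
    (zero phase) so pulse feet are not shifted in time. The result is used
    only for locating onsets; amplitude features must be read from the
    original record.
    """
    config = config or BeatDetectionConfig()
    low, high = config.band_hz
    nyquist = record.sampling_rate / 2.0
    if not (0 < low < high) or high >= nyquist:
        raise InvalidFilterConfig(
            f"invalid filter configuration: band {config.band_hz} Hz with "
            f"Nyquist {nyquist} Hz"
        )
    sos = sps.butter(2, [low, high], btype="bandpass", output="sos", fs=record.sampling_rate)
    conditioned = sps.sosfiltfilt(sos, record.samples)
    return replace(record, samples=conditioned)


def _oriented(record: PPGRecord, config: BeatDetectionConfig) -> np.ndarray:
    x = record.samples
    if config.invert:
        x = 2.0 * x.mean() - x
    return x


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def detect_beats(
    record: PPGRecord, config: BeatDetectionConfig | None = None
) -> np.ndarray:
    """Locate beat onsets (pulse feet) and return their sample indices.

    Systolic peaks are found on the conditioned signal with a prominence
    threshold and a refractory spacing; each onset is then the minimum of
    the detection signal in the inter-peak interval preceding its peak.
    Indices are strictly increasing and at least the refractory period
    apart.

    Raises
    ------
    SignalTooShort
        If the record is shorter than ``config.min_duration_s``.
    NoBeatsFound
        If the signal has no resolvable pulsatile component.
    """
    config = config or BeatDetectionConfig()
    if record.duration_s < config.min_duration_s:
        raise SignalTooShort(
            f"signal too short: {record.duration_s:.2f} s < "
            f"{config.min_duration_s:.2f} s minimum"
        )
    raw = _oriented(record, config)
    if config.conditioning:
        det = signal_conditioning(
            replace(record, samples=raw), config
        ).samples
    else:
        det = raw - raw.mean()

    # Running pulsatile amplitude; a flat signal has none (the floor guards
    # against filter round-off on a constant input).
    amp = float(np.percentile(det, 95) - np.percentile(det, 5))
    if amp <= 1e-9 * max(float(np.max(np.abs(raw))), 1e-12):
        raise NoBeatsFound("no beats found: signal has no pulsatile component")

    distance = max(1, int(round(config.refractory_s * record.sampling_rate)))
    peaks, _ = sps.find_peaks(
        det, prominence=config.min_prominence_frac * amp, distance=distance
    )
    if peaks.size == 0:
        raise NoBeatsFound("no beats found")

    # Foot = minimum of the detection signal between the previous peak and
    # this peak (earliest sample wins ties, numpy argmin convention). The
    # first foot is searched within one refractory-bounded window.
    onsets = np.empty(peaks.size, dtype=np.int64)
    for k, pk in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else max(0, pk - 2 * distance)
        if lo >= pk:
            lo = max(0, pk - 1)
        onsets[k] = lo + int(np.argmin(det[lo:pk + 1]))

    # Refine each coarse foot on the raw signal: the band-pass skews the
    # foot by a small, waveform-dependent amount, so snap to the raw local
    # minimum within a window of ~3.5% of the median inter-onset spacing.
    if config.conditioning and onsets.size >= 1:
        med_ibi = float(np.median(np.diff(onsets))) if onsets.size >= 2 else distance
        w = max(2, int(round(0.035 * med_ibi)))
        for k, on in enumerate(onsets):
            lo = max(0, on - w)
            hi = min(raw.size, on + w + 1)
            onsets[k] = lo + int(np.argmin(raw[lo:hi]))

    # Enforce strict increase and refractory spacing between onsets.
    keep = [0]
    for i in range(1, onsets.size):
        if onsets[i] - onsets[keep[-1]] >= distance:
            keep.append(i)
    onsets = onsets[keep]
    if onsets.size == 0:
        raise NoBeatsFound("no beats found")
    return onsets


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_beat_features(
    record: PPGRecord,
    onsets: np.ndarray,
    config: BeatDetectionConfig | None = None,
) -> list[BeatFeature]:
    """Compute per-beat HR and mNPV from consecutive onset pairs.

    For the beat spanning onsets ``[i, j)``:

    * ``ibi`` is the onset spacing in ms and ``hr = 60000 / ibi``;
    * ``ac`` is the maximum raw value within the beat minus the value at
      the onset (foot-to-peak excursion);
    * ``dc`` is the mean raw value over the beat interval;
    * ``mnpv = ac / dc`` and ``ln_mnpv = ln(mnpv)`` (NaN when ac is 0).

    Raises
    ------
    NonPositiveDC
        If any beat's DC level is <= 0, which indicates an un-offset or
        inverted input signal.
    """
    config = config or BeatDetectionConfig()
    onsets = np.asarray(onsets, dtype=np.int64)
    if onsets.size < 2:
        raise ValueError("need at least 2 onsets to form a beat")
    x = _oriented(record, config)
    fs = record.sampling_rate
    beats: list[BeatFeature] = []
    for i, j in zip(onsets[:-1], onsets[1:]):
        seg = x[i:j]
        ibi_ms = (j - i) / fs * 1000.0
        dc = float(seg.mean())
        if dc <= 0:
            raise NonPositiveDC(
                f"non-positive DC level ({dc:.4g}) at t={record.start_time + i / fs:.3f} s"
            )
        ac = float(seg.max() - x[i])
        mnpv = ac / dc
        beats.append(
            BeatFeature(
                onset_time=record.start_time + i / fs,
                ibi=ibi_ms,
                hr=60000.0 / ibi_ms,
                ac=ac,
                dc=dc,
                mnpv=mnpv,
                ln_mnpv=float(np.log(mnpv)) if mnpv > 0 else float("nan"),
            )
        )
    return beats


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_BEAT_COLUMNS = ["onset_s", "ibi_ms", "hr_bpm", "ac", "dc", "mnpv", "ln_mnpv", "outlier"]


def read_ppg_csv(path, rate: float | None = None) -> PPGRecord:
    """Read a PPG record from CSV with columns ``time_s,value`` or ``value``.

    A lone ``value`` column requires an explicit *rate* (Hz); with a
    ``time_s`` column the rate is inferred from the median sample spacing
    unless given.
    """
    frame = pd.read_csv(path, comment="#")
    if "value" not in frame.columns:
        raise ValueError("PPG CSV must have a 'value' column")
    if "time_s" in frame.columns:
        t = frame["time_s"].to_numpy(dtype=float)
        if rate is None:
            dt = float(np.median(np.diff(t)))
            if dt <= 0:
                raise ValueError("time_s column is not increasing")
            rate = 1.0 / dt
        start = float(t[0])
    else:
        if rate is None:
            raise ValueError("sampling rate required when CSV has no time_s column")
        start = 0.0
    return PPGRecord(
        samples=frame["value"].to_numpy(dtype=float),
        sampling_rate=float(rate),
        start_time=start,
    )


def beats_to_frame(beats: list[BeatFeature]) -> pd.DataFrame:
    """Beat table with columns onset_s,ibi_ms,hr_bpm,ac,dc,mnpv,ln_mnpv,outlier."""
    return pd.DataFrame(
        {
            "onset_s": [b.onset_time for b in beats],
            "ibi_ms": [b.ibi for b in beats],
            "hr_bpm": [b.hr for b in beats],
            "ac": [b.ac for b in beats],
            "dc": [b.dc for b in beats],
            "mnpv": [b.mnpv for b in beats],
            "ln_mnpv": [b.ln_mnpv for b in beats],
            "outlier": [bool(b.outlier) for b in beats],
        },
        columns=_BEAT_COLUMNS,
    )


def frame_to_beats(frame: pd.DataFrame) -> list[BeatFeature]:
    """Inverse of :func:`beats_to_frame`."""
    return [
        BeatFeature(
            onset_time=float(r.onset_s),
            ibi=float(r.ibi_ms),
            hr=float(r.hr_bpm),
            ac=float(r.ac),
            dc=float(r.dc),
            mnpv=float(r.mnpv),
            ln_mnpv=float(r.ln_mnpv),
            outlier=bool(r.outlier),
        )
        for r in frame.itertuples(index=False)
    ]
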