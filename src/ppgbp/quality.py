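"""Beat-series quality control: outlier flagging and block averaging.

The outlier rule mirrors the screening used by smartphone pulse apps: a
beat whose HR or ln mNPV departs markedly from the preceding 10 s is
rejected. "Departs markedly" is operationalized as: adding the candidate
to the window pushes the sample SD above the limit (8.0 bpm for HR, 0.25
a.u. for ln mNPV) while the window alone is at or under it — i.e. the
candidate is what drives the excess. Flagged beats are excluded from all
later windows so a single artifact cannot poison subsequent decisions.

Accepted beats are then averaged over caller-specified blocks (45 s by
default, matching a quarter of a 3-min measurement period). A block whose
outlier fraction is strictly greater than 20%, or that contains no beats,
is marked ``missing``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .signal import BeatFeature

__all__ = [
    "OutlierConfig",
    "BlockSummary",
    "flag_outliers",
    "block_average",
    "block_averages",
    "blocks_to_frame",
]


@dataclass(frozen=True)
class OutlierConfig:
    """Sliding-window SD limits for beat rejection.

    window_s: length of the preceding comparison window in seconds.
    hr_sd_limit: SD limit for HR in bpm.
    lnmnpv_sd_limit: SD limit for ln mNPV in arbitrary units.
    """

    window_s: float = 10.0
    hr_sd_limit: float = 8.0
    lnmnpv_sd_limit: float = 0.25

    def __post_init__(self) -> None:
        if not (self.window_s > 0 and self.hr_sd_limit > 0 and self.lnmnpv_sd_limit > 0):
            raise ValueError("all outlier-config fields must be strictly positive")


@dataclass(frozen=True)
class BlockSummary:
    """Mean HR and mean ln mNPV of accepted beats over one time block."""

    block_start_s: float
    block_len_s: float
    mean_hr: float
    mean_ln_mnpv: float
    n_beats: int
    n_outliers: int
    status: str  # "valid" | "missing"


def _sample_sd(values: list[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def flag_outliers(
    beats: list[BeatFeature], config: OutlierConfig | None = None
) -> list[BeatFeature]:
    """Return a copy of *beats* with outlier flags set by the window-SD rule.

    The decision for each beat uses only accepted (non-flagged) beats whose
    onset lies in the preceding ``window_s`` seconds, strictly before the
    candidate. With fewer than two accepted predecessors in the window the
    SD is undefined and the beat passes unflagged (warm-up). Beats with a
    non-finite ln mNPV (zero pulse amplitude) are flagged outright.

    The pass is causal: appending later beats never changes earlier flags.
    """
    config = config or OutlierConfig()
    out: list[BeatFeature] = []
    accepted: list[BeatFeature] = []  # non-flagged beats, time-ordered
    for beat in beats:
        if not (math.isfinite(beat.hr) and math.isfinite(beat.ln_mnpv)):
            out.append(replace(beat, outlier=True))
            continue
        t0 = beat.onset_time - config.window_s
        window = [b for b in accepted if t0 <= b.onset_time < beat.onset_time]
        flagged = False
        if len(window) >= 2:
            for attr, limit in (
                ("hr", config.hr_sd_limit),
                ("ln_mnpv", config.lnmnpv_sd_limit),
            ):
                prior = [getattr(b, attr) for b in window]
                with_candidate = prior + [getattr(beat, attr)]
                if _sample_sd(with_candidate) > limit and _sample_sd(prior) <= limit:
                    flagged = True
                    break
        flagged_beat = replace(beat, outlier=flagged)
        out.append(flagged_beat)
        if not flagged:
            accepted.append(flagged_beat)
    return out


def block_average(
    beats: list[BeatFeature], block_start_s: float, block_len_s: float = 45.0
) -> BlockSummary:
    """Average accepted beats whose onset falls in ``[start, start + len)``.

    Means are arithmetic means of HR and ln mNPV over non-outlier beats
    only. The block is ``missing`` when the outlier fraction is strictly
    greater than 0.20 (exactly 20% is still valid) or when it contains no
    beats at all; means are NaN when no accepted beat exists.
    """
    in_block = [
        b for b in beats if block_start_s <= b.onset_time < block_start_s + block_len_s
    ]
    n_beats = len(in_block)
    n_outliers = sum(1 for b in in_block if b.outlier)
    accepted = [b for b in in_block if not b.outlier]
    mean_hr = float(np.mean([b.hr for b in accepted])) if accepted else float("nan")
    mean_ln = float(np.mean([b.ln_mnpv for b in accepted])) if accepted else float("nan")
    missing = n_beats == 0 or n_outliers / n_beats > 0.20
    return BlockSummary(
        block_start_s=block_start_s,
        block_len_s=block_len_s,
        mean_hr=mean_hr,
        mean_ln_mnpv=mean_ln,
        n_beats=n_beats,
        n_outliers=n_outliers,
        status="missing" if missing else "valid",
    )


def block_averages(
    beats: list[BeatFeature],
    blocks: list[tuple[float, float]],
    block_len_s: float | None = None,
) -> list[BlockSummary]:
    """Apply :func:`block_average` to a list of ``(start_s, len_s)`` blocks.

    When *block_len_s* is given, *blocks* may instead be a list of starts.
    """
    if block_len_s is not None:
        return [block_average(beats, float(s), block_len_s) for s in blocks]
    return [block_average(beats, float(s), float(l)) for s, l in blocks]


def blocks_to_frame(blocks: list[BlockSummary]) -> pd.DataFrame:
    """Block table with the standard CSV columns."""
    return pd.DataFrame(
        {
            "block_start_s": [b.block_start_s for b in blocks],
            "block_len_s": [b.block_len_s for b in blocks],
            "mean_hr": [b.mean_hr for b in blocks],
            "mean_ln_mnpv": [b.mean_ln_mnpv for b in blocks],
            "n_beats": [b.n_beats for b in blocks],
            "n_outliers": [b.n_outliers for b in blocks],
            "status": [b.status for b in blocks],
        }
    )
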