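"""Log-linear cuffless blood-pressure model.

The model rests on MAP = CO x TPR: cardiac output tracks heart rate and
total peripheral resistance tracks finger vascular tone (mNPV), so on the
log scale each blood-pressure index is approximately linear in ln HR and
ln mNPV:

    ln BP = a * ln HR + b * ln mNPV + c

Calibration is an ordinary least-squares fit of ln(reference BP) on ln HR
and ln mNPV, pooled across subjects and conditions with no per-subject
terms — avoiding individual calibration is the method's point. Prediction
back-transforms with the exponential, so estimates are always positive:

    BP_hat = exp(a * ln HR + b * ln mNPV + c)

The reference MAP is derived from cuff readings as
MAP = DBP + (SBP - DBP) / 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesign, InsufficientData, InvalidReading

__all__ = [
    "INDICES",
    "BPReading",
    "CalibrationRow",
    "IndexFit",
    "BPModelCoefficients",
    "map_from_sbp_dbp",
    "fit",
    "fit_all",
    "predict",
    "predict_index",
    "evaluate",
    "save_model",
    "load_model",
    "rows_to_frame",
    "frame_to_rows",
]

INDICES = ("MAP", "SBP", "DBP")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def map_from_sbp_dbp(sbp: float, dbp: float) -> float:
    """Mean arterial pressure from cuff systolic/diastolic readings.

    MAP = DBP + (SBP - DBP) / 3. Linear in (SBP, DBP), so the MAP of
    group means equals the mean of individual MAPs.
    """
    if not (sbp > dbp > 0):
        raise InvalidReading(f"invalid reading: require SBP > DBP > 0, got ({sbp}, {dbp})")
    return dbp + (sbp - dbp) / 3.0


@dataclass(frozen=True)
class BPReading:
    """One blood-pressure observation in mmHg; MAP derived if omitted."""

    sbp: float
    dbp: float
    map: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise InvalidReading(
                f"invalid reading: require SBP > DBP > 0, got ({self.sbp}, {self.dbp})"
            )
        if math.isnan(self.map):
            object.__setattr__(self, "map", map_from_sbp_dbp(self.sbp, self.dbp))
        elif not (self.dbp <= self.map <= self.sbp):
            raise InvalidReading("MAP must lie between DBP and SBP")

    def value(self, index: str) -> float:
        return {"MAP": self.map, "SBP": self.sbp, "DBP": self.dbp}[index]


@dataclass(frozen=True)
class CalibrationRow:
    """One paired (block-averaged HR/ln mNPV, reference cuff BP) observation."""

    hr: float
    ln_mnpv: float
    reference: BPReading
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.hr > 0 and math.isfinite(self.hr) and math.isfinite(self.ln_mnpv)):
            raise ValueError("hr must be positive and predictors finite")


@dataclass(frozen=True)
class IndexFit:
    """Fitted coefficients and diagnostics for one BP index.

    ``r`` is the multiple correlation coefficient; ``std_beta_*`` are the
    conventional standardized coefficients beta * SD(predictor) / SD(response).
    """

    index: str
    a: float
    b: float
    c: float
    r: float | None = None
    std_beta_a: float | None = None
    std_beta_b: float | None = None
    p_a: float | None = None
    p_b: float | None = None
    p_c: float | None = None
    n: int | None = None


@dataclass
class BPModelCoefficients:
    """(a, b, c) triples for MAP, SBP and DBP on the ln scale."""

    fits: dict[str, IndexFit] = field(default_factory=dict)

    def __getitem__(self, index: str) -> IndexFit:
        return self.fits[index]

    def __contains__(self, index: str) -> bool:
        return index in self.fits


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _design(rows: list[CalibrationRow]) -> tuple[np.ndarray, np.ndarray]:
    ln_hr = np.log([r.hr for r in rows])
    ln_mnpv = np.array([r.ln_mnpv for r in rows])
    return ln_hr, ln_mnpv


def fit(rows: list[CalibrationRow], index: str) -> IndexFit:
    """OLS of ln(reference *index*) on ln HR and ln mNPV with intercept.

    Returns the coefficient triple (a, b, c) together with the multiple
    correlation R, standardized betas, and two-sided coefficient p-values.

    Raises
    ------
    InsufficientData
        Fewer than 4 rows (no residual degree of freedom).
    DegenerateDesign
        A constant predictor makes the design rank deficient.
    """
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}")
    if len(rows) < 4:
        raise InsufficientData(f"insufficient data: {len(rows)} rows, need >= 4")
    ln_hr, ln_mnpv = _design(rows)
    y = np.log([r.reference.value(index) for r in rows])
    X = sm.add_constant(np.column_stack([ln_hr, ln_mnpv]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesign("degenerate design: constant or collinear predictor")
    res = sm.OLS(y, X).fit()
    c, a, b = res.params
    sd_y = float(np.std(y, ddof=1))
    std_a = a * float(np.std(ln_hr, ddof=1)) / sd_y if sd_y > 0 else float("nan")
    std_b = b * float(np.std(ln_mnpv, ddof=1)) / sd_y if sd_y > 0 else float("nan")
    return IndexFit(
        index=index,
        a=float(a),
        b=float(b),
        c=float(c),
        r=float(np.sqrt(max(res.rsquared, 0.0))),
        std_beta_a=std_a,
        std_beta_b=std_b,
        p_a=float(res.pvalues[1]),
        p_b=float(res.pvalues[2]),
        p_c=float(res.pvalues[0]),
        n=len(rows),
    )


def fit_all(rows: list[CalibrationRow]) -> BPModelCoefficients:
    """Fit all three indices on the same calibration rows."""
    return BPModelCoefficients(fits={ix: fit(rows, ix) for ix in INDICES})


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_index(coeffs: IndexFit, hr, ln_mnpv):
    """exp(a ln HR + b ln mNPV + c) for one index; accepts scalars or arrays."""
    hr = np.asarray(hr, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("invalid HR: must be positive")
    est = np.exp(coeffs.a * np.log(hr) + coeffs.b * np.asarray(ln_mnpv, dtype=float) + coeffs.c)
    return float(est) if est.ndim == 0 else est


def predict(coeffs: BPModelCoefficients, hr: float, ln_mnpv: float) -> BPReading:
    """Estimated (SBP, DBP, MAP) at one (HR, ln mNPV) operating point.

    Each index uses its own coefficient triple; the three estimates are
    independent back-transforms, so MAP is the model's own estimate rather
    than the one-third formula applied to estimated SBP/DBP.
    """
    est = {ix: predict_index(coeffs[ix], hr, ln_mnpv) for ix in INDICES}
    return BPReading(sbp=est["SBP"], dbp=est["DBP"], map=est["MAP"])


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(coeffs: BPModelCoefficients, rows: list[CalibrationRow]) -> dict[str, dict]:
    """Residual diagnostics per index on the mmHg scale.

    For each index: residuals (reference - estimate), the Pearson
    correlation of estimates with residuals (None when residuals have no
    variance, e.g. a noiseless exact fit), and the same correlation on the
    ln scale, which is identically ~0 for the index's own OLS fit.
    """
    if len(rows) < 3:
        raise InsufficientData("need >= 3 rows for residual diagnostics")
    out: dict[str, dict] = {}
    hr = np.array([r.hr for r in rows])
    ln_mnpv = np.array([r.ln_mnpv for r in rows])
    for ix in INDICES:
        est = predict_index(coeffs[ix], hr, ln_mnpv)
        ref = np.array([r.reference.value(ix) for r in rows])
        resid = ref - est
        ln_resid = np.log(ref) - np.log(est)
        out[ix] = {
            "residuals": resid,
            "estimates": est,
            "r_est_resid": _safe_corr(est, resid),
            "r_lnest_lnresid": _safe_corr(np.log(est), ln_resid),
        }
    return out


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float | None:
    # residual variance at numerical-noise level => correlation undefined
    scale = max(float(np.std(x)), float(np.mean(np.abs(x))), 1.0)
    if np.std(x) == 0 or np.std(y) <= 1e-10 * scale:
        return None  # not applicable (e.g. zero residuals)
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Serialization and CSV interfaces
# ---------------------------------------------------------------------------

def save_model(coeffs: BPModelCoefficients, path) -> None:
    """Write coefficients as plain text: ``index,a,b,c,R`` per line."""
    with open(path, "w") as fh:
        fh.write("index,a,b,c,R\n")
        for ix in INDICES:
            if ix in coeffs:
                f = coeffs[ix]
                r = "" if f.r is None else repr(f.r)
                fh.write(f"{ix},{f.a!r},{f.b!r},{f.c!r},{r}\n")


def load_model(path) -> BPModelCoefficients:
    """Read a model file written by :func:`save_model`."""
    fits: dict[str, IndexFit] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("index,"):
            raise ValueError("not a model file")
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) < 4:
                continue
            ix, a, b, c = parts[0], float(parts[1]), float(parts[2]), float(parts[3])
            r = float(parts[4]) if len(parts) > 4 and parts[4] else None
            fits[ix] = IndexFit(index=ix, a=a, b=b, c=c, r=r)
    return BPModelCoefficients(fits=fits)


_CALIB_COLUMNS = ["subject_id", "condition", "hr_bpm", "ln_mnpv", "sbp_mmHg", "dbp_mmHg"]


def rows_to_frame(rows: list[CalibrationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "condition": [r.condition for r in rows],
            "hr_bpm": [r.hr for r in rows],
            "ln_mnpv": [r.ln_mnpv for r in rows],
            "sbp_mmHg": [r.reference.sbp for r in rows],
            "dbp_mmHg": [r.reference.dbp for r in rows],
        },
        columns=_CALIB_COLUMNS,
    )


def frame_to_rows(frame: pd.DataFrame) -> list[CalibrationRow]:
    """Calibration rows from a CSV table; MAP is derived internally."""
    return [
        CalibrationRow(
            hr=float(r.hr_bpm),
            ln_mnpv=float(r.ln_mnpv),
            reference=BPReading(sbp=float(r.sbp_mmHg), dbp=float(r.dbp_mmHg)),
            subject_id=str(r.subject_id),
            condition=str(r.condition),
        )
        for r in frame.itertuples(index=False)
    ]
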