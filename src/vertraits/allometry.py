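"""Log10-log10 allometric fitting and body-mass reconstruction.

The scaling model is ``log10(y) = log10(a) + b * log10(x)`` fitted by
ordinary least squares with mass in grams and length in mm. Predictions
carry a propagated standard error

    se_pred = sqrt( se_resid**2 / n + (se_slope * (log10(x) - mean_log_x))**2 )

which reduces to ``se_resid / sqrt(n)`` at the mean of the fitted log
lengths. 2-se intervals are formed in log space and back-transformed
(no smearing correction), so they are asymmetric in grams.

Published constants from older lab calibrations can be applied through
:func:`apply_legacy_equation`; such equations carry no error term, so
their point estimates are checked against the 2-se interval of the
refitted model instead (:func:`legacy_within_interval`).

NOTE on coefficient order: legacy write-ups sometimes print the deer
equation with intercept and slope transposed; with mass in grams only
intercept 1.45 / slope 2.04 reproduces deer-scale masses.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AllometricFit",
    "MassPrediction",
    "LEGACY_CONSTANTS",
    "fit_allometry",
    "predict_mass",
    "legacy_within_interval",
    "apply_legacy_equation",
]

#: Published constant sets for deer astragalus -> body mass, with provenance
#: notes. Two intercept variants of the 1990s lab equation circulate.
LEGACY_CONSTANTS: dict[str, dict] = {
    "fm_eap_1990s": {
        "intercept": -6.79,
        "slope": 5.29,
        "unit": "kg",
        "note": "1990s lab calibration, n=10, R^2=0.87 (tabled intercept)",
    },
    "fm_eap_1990s_alt": {
        "intercept": -6.71,
        "slope": 5.29,
        "unit": "kg",
        "note": "1990s lab calibration, alternative printed intercept",
    },
}


@dataclass
class AllometricFit:
    intercept: float  # log10(a)
    slope: float  # b
    se_intercept: float
    se_slope: float
    se_residuals: float  # sqrt(SSR / (n - 2))
    n: int
    df: int
    mean_log_x: float
    r_squared: float
    p_value: float
    x_unit: str = "mm"
    y_unit: str = "g"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AllometricFit":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class MassPrediction:
    x_value: float
    log_prediction: float
    se_prediction: float
    point_estimate: float  # grams
    lower_2se: float
    upper_2se: float


def fit_allometry(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    x_unit: str = "mm",
    y_unit: str = "g",
) -> AllometricFit:
    """OLS of log10(y) on log10(x).

    Requires n >= 3 and strictly positive values on both axes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("allometric fit needs n >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("allometric fit requires positive values (log scale)")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in x")

    res = stats.linregress(lx, ly)
    fitted = res.intercept + res.slope * lx
    ssr = float(np.sum((ly - fitted) ** 2))
    n = int(x.size)
    return AllometricFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        se_intercept=float(res.intercept_stderr),
        se_slope=float(res.stderr),
        se_residuals=math.sqrt(ssr / (n - 2)),
        n=n,
        df=n - 2,
        mean_log_x=float(lx.mean()),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        x_unit=x_unit,
        y_unit=y_unit,
    )


def predict_mass(
    fit: AllometricFit,
    x_new: float,
    eq3_as_printed: bool = False,
) -> MassPrediction:
    """Predict mass (grams) with a propagated standard error.

    ``eq3_as_printed=True`` switches the first variance term from
    ``se_resid**2 / n`` to the literal ``(se_resid / n)**2`` variant for
    comparison; the default reduces correctly to ``se_resid/sqrt(n)`` at
    the mean log length.
    """
    if x_new <= 0:
        raise ValueError("x_new must be positive")
    lx = math.log10(x_new)
    log_pred = fit.intercept + fit.slope * lx
    if eq3_as_printed:
        base = (fit.se_residuals / fit.n) ** 2
    else:
        base = fit.se_residuals**2 / fit.n
    se = math.sqrt(base + (fit.se_slope * (lx - fit.mean_log_x)) ** 2)
    point = 10**log_pred
    if fit.y_unit == "kg":  # fits are normally in grams; convert if not
        point *= 1000.0
        lower = 10 ** (log_pred - 2 * se) * 1000.0
        upper = 10 ** (log_pred + 2 * se) * 1000.0
    else:
        lower = 10 ** (log_pred - 2 * se)
        upper = 10 ** (log_pred + 2 * se)
    return MassPrediction(
        x_value=float(x_new),
        log_prediction=log_pred,
        se_prediction=se,
        point_estimate=point,
        lower_2se=lower,
        upper_2se=upper,
    )


def legacy_within_interval(
    prediction: MassPrediction, legacy_estimate_g: float
) -> dict:
    """Check a legacy point estimate (grams) against the 2-se interval."""
    within = prediction.lower_2se <= legacy_estimate_g <= prediction.upper_2se
    if within:
        verdict = "within"
    elif legacy_estimate_g < prediction.lower_2se:
        verdict = "underestimate"
    else:
        verdict = "overestimate"
    return {
        "xValue": prediction.x_value,
        "legacyEstimate": legacy_estimate_g,
        "lower2se": prediction.lower_2se,
        "upper2se": prediction.upper_2se,
        "within": bool(within),
        "verdict": verdict,
    }


def apply_legacy_equation(
    intercept: float,
    slope: float,
    x: Sequence[float] | np.ndarray | float,
    unit: str | None = None,
) -> np.ndarray:
    """Point estimates from published constants: ``10**(intercept + slope*log10 x)``.

    ``unit`` must be declared explicitly ('g' or 'kg') and is the unit the
    result is expressed in; legacy equations attach no uncertainty, so
    none is returned.
    """
    if unit is None:
        raise ValueError("legacy constants require an explicit unit declaration")
    unit = unit.strip().lower()
    if unit not in ("g", "kg"):
        raise ValueError(f"unsupported mass unit {unit!r}")
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xs <= 0):
        raise ValueError("x values must be positive")
    return 10 ** (intercept + slope * np.log10(xs))
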