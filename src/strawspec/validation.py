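"""Calibration, cross-validation and prediction metrics, plus model transfer.

The usual chemometric scorecard for an SSC calibration:

* ``RMSE  = sqrt(mean((yhat - y)^2))`` in % Brix,
* ``R^2   = 1 - sum((y - yhat)^2) / sum((y - ybar)^2)`` (may go negative for
  models worse than the mean predictor),
* ``RPD   = sd(y_test) / RMSEP`` — ratio of performance to deviation,
* slope/offset of the least-squares line ``yhat ~ slope * y + offset`` and
  the mean bias ``mean(yhat - y)``.

Conventional RPD reading: < 1.5 unusable; 1.5-2.0 discriminates low vs high;
2.0-2.5 approximate quantitative prediction; 2.5-3.0 good; >= 3.0 excellent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, GridMismatchError
from .pls import PLSRModel, PressCurve, loo_predictions, predict
from .spectra import SpectralDataset

__all__ = [
    "ValidationReport",
    "rmse",
    "r_squared",
    "rpd",
    "rpd_class",
    "slope_offset_bias",
    "evaluate",
    "transfer_evaluate",
    "coefficient_spectrum",
]

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """Metrics for one evaluation context.

    ``rpd``, ``slope``, ``offset`` and ``bias`` are populated for the
    prediction context (test-set evaluation); ``note`` carries diagnostics
    such as the overfitting flag.
    """

    context: str                 # "calibration" | "cross_validation" | "prediction"
    r2: float
    rmse: float
    n: int
    rpd: Optional[float] = None
    slope: Optional[float] = None
    offset: Optional[float] = None
    bias: Optional[float] = None
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(y: np.ndarray, yhat: np.ndarray, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"y has {y.size} values but yhat has {yhat.size}")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {y.size}")
    return y, yhat


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error sqrt(mean((yhat - y)^2)), in % Brix."""
    y, yhat = _check_pair(y, yhat, min_n=1)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination; negative when worse than the mean."""
    y, yhat = _check_pair(y, yhat, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("y is constant; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rpd(y_test: np.ndarray, yhat_test: np.ndarray, ddof: int = 1) -> float:
    """Ratio of performance to deviation sd(y_test) / RMSEP.

    ``ddof=1`` (sample SD) is the test-set convention; ``ddof=0`` is exposed
    for completeness.  A perfect prediction returns ``inf``.
    """
    y_test, yhat_test = _check_pair(y_test, yhat_test, min_n=2)
    err = rmse(y_test, yhat_test)
    sd = float(np.std(y_test, ddof=ddof))
    if err == 0.0:
        return float("inf")
    return sd / err


def rpd_class(value: float) -> str:
    """Conventional qualitative reading of an RPD value."""
    if value < 1.5:
        return "unusable"
    if value < 2.0:
        return "discriminates low/high"
    if value < 2.5:
        return "approximate quantitative"
    if value < 3.0:
        return "good"
    return "excellent"


def slope_offset_bias(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line of predicted against measured, plus mean bias.

    Fits ``yhat ~ slope * y + offset`` (predicted regressed on measured) and
    returns ``(slope, offset, bias)`` with ``bias = mean(yhat - y)``.
    """
    y, yhat = _check_pair(y, yhat, min_n=2)
    var_y = float(np.var(y))
    if var_y == 0.0:
        raise DegenerateDataError("y is constant; slope undefined")
    slope = float(np.mean((y - y.mean()) * (yhat - yhat.mean()))) / var_y
    offset = float(yhat.mean() - slope * y.mean())
    bias = float(np.mean(yhat - y))
    return slope, offset, bias


def _prediction_report(y: np.ndarray, yhat: np.ndarray, context: str = "prediction") -> ValidationReport:
    s, o, b = slope_offset_bias(y, yhat)
    return ValidationReport(
        context=context,
        r2=r_squared(y, yhat),
        rmse=rmse(y, yhat),
        n=int(np.asarray(y).size),
        rpd=rpd(y, yhat),
        slope=s,
        offset=o,
        bias=b,
    )


def evaluate(
    model: PLSRModel,
    train: SpectralDataset,
    test: SpectralDataset,
    press: PressCurve,
) -> dict[str, ValidationReport]:
    """Three-context scorecard: calibration, cross-validation, prediction.

    Calibration metrics come from refitting predictions on the training set;
    cross-validation metrics from leave-one-out predictions at the selected
    factor count; prediction metrics (with RPD, slope, offset, bias) from the
    held-out test set.  If the prediction R^2 exceeds the calibration R^2 by
    more than 0.15 a diagnostic note is attached (an inverted gap like that
    usually signals a lucky split rather than a sound model) — it is logged,
    never raised.
    """
    if not train.wavelengths.matches(test.wavelengths):
        raise GridMismatchError("train and test sets are on different grids")
    h = press.selected if press.selected is not None else model.n_factors

    yhat_cal = predict(model, train.absorbance)
    cal = ValidationReport(
        context="calibration",
        r2=r_squared(train.ssc, yhat_cal),
        rmse=rmse(train.ssc, yhat_cal),
        n=train.n_samples,
    )

    loo = loo_predictions(train.absorbance, train.ssc, h)[:, h - 1]
    cv = ValidationReport(
        context="cross_validation",
        r2=r_squared(train.ssc, loo),
        rmse=rmse(train.ssc, loo),
        n=train.n_samples,
    )

    pred = _prediction_report(test.ssc, predict(model, test.absorbance))

    if pred.r2 > cal.r2 + 0.15:
        pred.note = (
            f"prediction R^2 ({pred.r2:.3f}) exceeds calibration R^2 "
            f"({cal.r2:.3f}) by more than 0.15"
        )
        logger.warning("%s: %s", model.trained_on, pred.note)
    return {"calibration": cal, "cross_validation": cv, "prediction": pred}


def transfer_evaluate(model: PLSRModel, foreign_test: SpectralDataset) -> ValidationReport:
    """Apply a fitted model, unchanged, to a test set from another population.

    The wavelength grids must be identical — this guards the cross-variety
    experiment against accidentally pairing a visible-range model with
    NIR-range spectra.
    """
    if model.wavelengths is not None:
        if not model.wavelengths.matches(foreign_test.wavelengths):
            raise GridMismatchError(
                "model and foreign test set are on different wavelength grids"
            )
    elif model.n_wavelengths != foreign_test.absorbance.shape[1]:
        raise GridMismatchError(
            f"model expects {model.n_wavelengths} wavelengths, test set has "
            f"{foreign_test.absorbance.shape[1]}"
        )
    return _prediction_report(foreign_test.ssc, predict(model, foreign_test.absorbance))


def coefficient_spectrum(model: PLSRModel) -> pd.DataFrame:
    """Regression-coefficient spectrum as a (wavelength, coefficient) table.

    The coefficient magnitude per wavelength shows which absorption bands the
    calibration actually uses, which is how pigment dependence of a model is
    diagnosed.
    """
    if model.wavelengths is not None:
        wl = model.wavelengths.values
    else:
        wl = np.arange(model.n_wavelengths, dtype=float)
    return pd.DataFrame({"wavelength_nm": wl, "coefficient": model.coefficients})
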