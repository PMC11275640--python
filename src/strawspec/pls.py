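"""From-scratch NIPALS partial least squares regression (PLS1).

The model projects mean-centered spectra onto latent factors that maximize
covariance with the mean-centered response, one factor at a time with
deflation, and assembles a single regression-coefficient spectrum

    b = W (P^T W)^{-1} q,      yhat = y_mean + (X - x_mean) b

where ``W`` are the factor weights, ``P`` the X-loadings and ``q`` the
y-loadings.  The number of factors is chosen from a leave-one-out PRESS
curve with the Haaland-Thomas F-ratio rule: take the smallest factor count
whose PRESS is not significantly larger than the minimum PRESS.

X and y are mean-centered but not variance-scaled: for derivative spectra
the per-channel amplitude itself carries information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, DegenerateDataError
from .spectra import SpectralDataset, WavelengthGrid

__all__ = [
    "PLSRModel",
    "PressCurve",
    "SplitSpec",
    "split_dataset",
    "fit_nipals",
    "predict",
    "loo_press",
    "loo_predictions",
    "select_factors",
    "fit_with_selection",
    "save_model",
    "load_model",
]

_MAX_NIPALS_ITER = 500
_NIPALS_TOL = 1e-12


@dataclass
class PLSRModel:
    """A fitted PLS1 regression model.

    ``coefficients`` maps a *centered* second-derivative spectrum to the
    centered SSC; prediction adds the training means back.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, h)
    x_loadings: np.ndarray   # (p, h)
    y_loadings: np.ndarray   # (h,)
    coefficients: np.ndarray  # (p,)
    n_factors: int
    trained_on: str = ""
    wavelengths: Optional[WavelengthGrid] = None

    @property
    def n_wavelengths(self) -> int:
        return int(self.coefficients.size)


@dataclass
class PressCurve:
    """Leave-one-out PRESS per candidate factor count 1..h_max."""

    press: np.ndarray        # (h_max,), % Brix^2 summed over folds
    n: int                   # training sample count
    selected: Optional[int] = None

    @property
    def h_max(self) -> int:
        return int(self.press.size)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split specification (default 7:3)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify_by: str = "none"   # "none" or "variety"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.stratify_by not in ("none", "variety"):
            raise ValueError("stratify_by must be 'none' or 'variety'")


def split_dataset(
    dataset: SpectralDataset, spec: SplitSpec = SplitSpec()
) -> tuple[SpectralDataset, SpectralDataset]:
    """Disjoint, exhaustive random partition into train and test sets.

    Train size is ``round(train_fraction * n)``; with
    ``stratify_by="variety"`` the split is applied per variety so that each
    label keeps its proportion within one sample.  Deterministic given the
    seed.
    """
    n = dataset.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples to split (leave-one-out "
                         "factor selection is meaningless below that)")
    rng = np.random.default_rng(spec.seed)
    if spec.stratify_by == "variety":
        train_idx: list[int] = []
        test_idx: list[int] = []
        for label in dataset.varieties:
            members = np.nonzero(np.array(dataset.variety) == label)[0]
            perm = rng.permutation(members)
            k = int(round(spec.train_fraction * len(members)))
            train_idx.extend(perm[:k])
            test_idx.extend(perm[k:])
        train_idx = sorted(train_idx)
        test_idx = sorted(test_idx)
    else:
        perm = rng.permutation(n)
        k = int(round(spec.train_fraction * n))
        train_idx = sorted(perm[:k].tolist())
        test_idx = sorted(perm[k:].tolist())
    return dataset.subset(train_idx), dataset.subset(test_idx)


def _nipals_decomposition(
    X: np.ndarray, y: np.ndarray, n_factors: int
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    """Run NIPALS deflation and return (x_mean, y_mean, W, P, q)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} values")
    max_rank = min(n - 1, p)
    if not 1 <= n_factors <= max_rank:
        raise ValueError(
            f"n_factors must be in [1, {max_rank}] for an {n}x{p} problem"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("response y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean

    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    for h in range(n_factors):
        u = yr
        t_old: np.ndarray | None = None
        for _ in range(_MAX_NIPALS_ITER):
            w = Xr.T @ u
            norm = np.linalg.norm(w)
            if norm == 0.0:
                raise DegenerateDataError(
                    f"no residual X-y covariance left at factor {h + 1}"
                )
            w /= norm
            t = Xr @ w
            if t_old is not None and (
                np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t)
            ):
                break
            t_old = t
            # PLS1: the y-score is the y residual itself, so u is unchanged
        else:
            raise ConvergenceError(
                f"NIPALS inner loop did not converge within {_MAX_NIPALS_ITER} "
                f"iterations at factor {h + 1}"
            )
        tt = float(t @ t)
        p_load = Xr.T @ t / tt
        q_h = float(yr @ t) / tt
        Xr = Xr - np.outer(t, p_load)
        yr = yr - q_h * t
        W[:, h] = w
        P[:, h] = p_load
        q[h] = q_h
    return x_mean, y_mean, W, P, q


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, h: int) -> np.ndarray:
    """Regression-coefficient spectrum using the first ``h`` factors."""
    Wh, Ph, qh = W[:, :h], P[:, :h], q[:h]
    return Wh @ np.linalg.solve(Ph.T @ Wh, qh)


def fit_nipals(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    trained_on: str = "",
    wavelengths: Optional[WavelengthGrid] = None,
) -> PLSRModel:
    """Fit a PLS1 model with a fixed number of factors."""
    x_mean, y_mean, W, P, q = _nipals_decomposition(X, y, n_factors)
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=_coefficients(W, P, q, n_factors),
        n_factors=n_factors,
        trained_on=trained_on,
        wavelengths=wavelengths,
    )


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predicted SSC (% Brix): yhat = y_mean + (X - x_mean) . b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_wavelengths:
        raise ValueError(
            f"model expects {model.n_wavelengths} wavelengths but spectra "
            f"have {X.shape[1]} — wrong spectral range?"
        )
    return model.y_mean + (X - model.x_mean) @ model.coefficients


def loo_predictions(X: np.ndarray, y: np.ndarray, h_max: int) -> np.ndarray:
    """Leave-one-out predictions, shape (n, h_max).

    Column ``h-1`` holds the prediction for each held-out sample from a model
    refit on the remaining ``n - 1`` samples with ``h`` factors.  Each fold
    runs one NIPALS decomposition at ``h_max`` factors and reads off the
    coefficient vector at every smaller factor count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < h_max + 2:
        raise ValueError(f"need at least h_max + 2 = {h_max + 2} samples for "
                         f"leave-one-out at h_max={h_max}, got {n}")
    preds = np.empty((n, h_max))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        x_mean, y_mean, W, P, q = _nipals_decomposition(X[mask], y[mask], h_max)
        xc = X[i] - x_mean
        for h in range(1, h_max + 1):
            preds[i, h - 1] = y_mean + xc @ _coefficients(W, P, q, h)
        mask[i] = True
    return preds


def loo_press(X: np.ndarray, y: np.ndarray, h_max: int) -> PressCurve:
    """Leave-one-out PRESS(h) = sum_i (y_i - yhat_{-i,h})^2 for h = 1..h_max."""
    y = np.asarray(y, dtype=float).ravel()
    preds = loo_predictions(X, y, h_max)
    press = np.sum((y[:, None] - preds) ** 2, axis=0)
    return PressCurve(press=press, n=int(y.size))


def select_factors(curve: PressCurve, alpha: float = 0.25) -> int:
    """Haaland-Thomas factor selection from a PRESS curve.

    Let ``h*`` be the factor count minimizing PRESS (smallest h on ties).
    For each ``h <= h*`` form ``F(h) = PRESS(h) / PRESS(h*)`` and return the
    smallest ``h`` whose ratio does not exceed the upper critical value of an
    F distribution with ``(n, n)`` degrees of freedom at probability
    ``alpha``.  This deliberately prefers a more parsimonious model than the
    raw PRESS minimum, which tends to overfit.
    """
    if curve.h_max < 1:
        raise ValueError("PRESS curve is empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    press = curve.press
    h_star = int(np.argmin(press))          # 0-based; smallest h on ties
    if press[h_star] == 0.0:
        return h_star + 1                   # perfect fit short circuit
    critical = stats.f.ppf(1.0 - alpha, curve.n, curve.n)
    for h in range(h_star + 1):
        if press[h] / press[h_star] <= critical:
            return h + 1
    return h_star + 1                       # unreachable: F(h*) = 1 <= critical


def fit_with_selection(
    train: SpectralDataset, h_max: int, alpha: float = 0.25
) -> tuple[PLSRModel, PressCurve]:
    """PRESS factor selection followed by a full-training-set fit."""
    X, y = train.absorbance, train.ssc
    curve = loo_press(X, y, h_max)
    selected = select_factors(curve, alpha)
    curve.selected = selected
    descriptor = (
        f"varieties={','.join(train.varieties)};n={train.n_samples};"
        f"range={train.wavelengths.values[0]:g}-{train.wavelengths.values[-1]:g}nm"
    )
    model = fit_nipals(X, y, selected, trained_on=descriptor,
                       wavelengths=train.wavelengths)
    return model, curve


# ---------------------------------------------------------------------------
# JSON serialization (plain text, lossless via shortest-round-trip floats)


def save_model(model: PLSRModel, path: str | Path) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "n_factors": model.n_factors,
        "trained_on": model.trained_on,
        "wavelengths": (
            None if model.wavelengths is None else model.wavelengths.values.tolist()
        ),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PLSRModel:
    payload = json.loads(Path(path).read_text())
    wl = payload.get("wavelengths")
    return PLSRModel(
        x_mean=np.array(payload["x_mean"], dtype=float),
        y_mean=float(payload["y_mean"]),
        weights=np.array(payload["weights"], dtype=float),
        x_loadings=np.array(payload["x_loadings"], dtype=float),
        y_loadings=np.array(payload["y_loadings"], dtype=float),
        coefficients=np.array(payload["coefficients"], dtype=float),
        n_factors=int(payload["n_factors"]),
        trained_on=payload.get("trained_on", ""),
        wavelengths=None if wl is None else WavelengthGrid(np.array(wl)),
    )
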