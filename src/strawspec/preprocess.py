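"""Savitzky-Golay second-derivative preprocessing.

Second-derivative spectra remove additive baseline offsets and linear tilts
exactly (the filter reproduces polynomials up to its fit order) and sharpen
overlapping absorption bands, at the price of amplifying high-frequency
noise.  All calibration and the spectrometer noise statistic operate on
second-derivative spectra.

Edge points where the full window does not fit are dropped and the
wavelength grid trimmed accordingly: padded edge values would be fabricated
data leaking into calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import ConfigError
from .spectra import SpectralDataset, WavelengthGrid

__all__ = ["SGConfig", "second_derivative", "second_derivative_matrix",
           "transform_dataset"]

DERIVATIVE_ORDER = 2


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay filter settings.

    window
        Odd filter length in grid points; default 15.
    polyorder
        Local polynomial order; default 2, the minimal order supporting a
        second derivative and the common chemometrics choice.
    per_nm
        If True, scale the derivative per nm^2 (divides by step^2); default
        False, i.e. derivative in index units (per sample-point^2).  On a
        uniform grid the two differ by a constant factor that a linear
        calibration absorbs.
    """

    window: int = 15
    polyorder: int = 2
    per_nm: bool = False

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window < 5:
            raise ConfigError("window must be an odd integer >= 5")
        if self.polyorder < DERIVATIVE_ORDER:
            raise ConfigError("polyorder must be >= 2 for a second derivative")
        if self.polyorder >= self.window:
            raise ConfigError("polyorder must be smaller than window")

    @property
    def half_width(self) -> int:
        return (self.window - 1) // 2


def second_derivative(
    spectrum: np.ndarray, grid: WavelengthGrid, cfg: SGConfig = SGConfig()
) -> tuple[WavelengthGrid, np.ndarray]:
    """Second-derivative spectrum with the edge points dropped.

    Returns ``(trimmed_grid, d2)`` where both are shorter than the input by
    ``window - 1`` points (``(window-1)/2`` per side).
    """
    grid_out, d2 = second_derivative_matrix(np.asarray(spectrum, dtype=float),
                                            grid, cfg)
    return grid_out, d2


def second_derivative_matrix(
    spectra: np.ndarray, grid: WavelengthGrid, cfg: SGConfig = SGConfig()
) -> tuple[WavelengthGrid, np.ndarray]:
    """Row-wise second derivative of a spectrum or spectra matrix."""
    spectra = np.asarray(spectra, dtype=float)
    n_points = spectra.shape[-1]
    if n_points != len(grid):
        raise ValueError(f"spectra have {n_points} points but grid has {len(grid)}")
    if n_points < cfg.window:
        raise ValueError(
            f"spectrum length {n_points} is shorter than the SG window {cfg.window}"
        )
    delta = grid.step_nm if cfg.per_nm else 1.0
    d2 = savgol_filter(spectra, cfg.window, cfg.polyorder,
                       deriv=DERIVATIVE_ORDER, delta=delta, axis=-1)
    h = cfg.half_width
    return grid.trim(h), d2[..., h:-h]


def transform_dataset(
    dataset: SpectralDataset, cfg: SGConfig = SGConfig()
) -> SpectralDataset:
    """Apply the second derivative to every spectrum of a dataset.

    SSC references, variety labels and sample ids carry through unchanged;
    the wavelength grid is the edge-trimmed one.
    """
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")
    try:
        grid_out, d2 = second_derivative_matrix(dataset.absorbance,
                                                dataset.wavelengths, cfg)
    except ValueError as exc:
        raise ValueError(
            f"second-derivative transform failed for dataset with samples "
            f"{dataset.sample_id[:3]}...: {exc}"
        ) from exc
    return SpectralDataset(
        wavelengths=grid_out,
        absorbance=d2,
        ssc=dataset.ssc.copy(),
        variety=list(dataset.variety),
        sample_id=list(dataset.sample_id),
    )
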