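"""Spectrometer noise-level (NL) statistic from repeated white references.

A white reference plate is measured repeatedly under one acquisition
condition (exposure time, number of integrations).  Each later repeat is
converted to an *apparent absorbance* against the first repeat,

    A(lambda, t) = -log10( (W(lambda,t) - D(lambda,t))
                         / (W(lambda,t0) - D(lambda,t0)) ),

which would be exactly zero for a noiseless instrument.  The apparent
absorbance spectra are second-derivative filtered, the per-wavelength
standard deviation is taken over repeats inside a fixed wavelength window,
and the noise level is the mean of that SD spectrum:

    NL = mean_lambda( sd_t( d2 A(lambda, t) ) ).

Sweeping NL over an exposure x integration grid characterizes how averaging
and light throughput trade off against detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SpectralDomainError
from .preprocess import SGConfig, second_derivative_matrix
from .spectra import WavelengthGrid

__all__ = [
    "AcquisitionCondition",
    "IntensitySeries",
    "NoiseEntry",
    "NoiseGrid",
    "apparent_absorbance",
    "sd_spectrum",
    "noise_level",
    "grid_evaluate",
    "VIS_NIR_EXPOSURES_MS",
    "NIR_EXPOSURES_MS",
    "INTEGRATION_STEPS",
    "VIS_NIR_NOISE_WINDOW_NM",
    "NIR_NOISE_WINDOW_NM",
]

# Acquisition grids of the two instruments being characterized.
VIS_NIR_EXPOSURES_MS = (10.0, 60.0, 120.0, 180.0, 240.0, 300.0)
NIR_EXPOSURES_MS = (0.01, 1.5, 3.0, 4.5, 6.0, 7.4)
INTEGRATION_STEPS = (8, 16, 32, 64, 128)

# Evaluation windows: high-throughput regions of each detector.
VIS_NIR_NOISE_WINDOW_NM = (834.0, 872.0)
NIR_NOISE_WINDOW_NM = (1435.0, 1552.0)


@dataclass(frozen=True)
class AcquisitionCondition:
    exposure_ms: float
    integrations: int

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if self.integrations < 1:
            raise ValueError("integrations must be a positive integer")


@dataclass
class IntensitySeries:
    """Repeated white-reference and dark intensities for one condition.

    ``white`` and ``dark`` are (n_repeats, n_wavelengths); the first repeat
    serves as the reference measurement t0.
    """

    condition: AcquisitionCondition
    wavelengths: WavelengthGrid
    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.atleast_2d(np.asarray(self.white, dtype=float))
        self.dark = np.atleast_2d(np.asarray(self.dark, dtype=float))
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark matrices must have the same shape")
        if self.white.shape[1] != len(self.wavelengths):
            raise ValueError("intensity columns must match the wavelength grid")
        if self.white.shape[0] < 2:
            raise ValueError("need at least 2 repeats (the first is the reference)")
        net = self.white - self.dark
        if np.any(net <= 0):
            t, j = np.argwhere(net <= 0)[0]
            raise SpectralDomainError(
                f"white minus dark is non-positive at repeat {t}, "
                f"{self.wavelengths.values[j]:g} nm"
            )

    @property
    def n_repeats(self) -> int:
        return int(self.white.shape[0])


@dataclass(frozen=True)
class NoiseEntry:
    condition: AcquisitionCondition
    nl: float
    n_window_points: int
    n_apparent_spectra: int


@dataclass
class NoiseGrid:
    """NL per acquisition condition, sortable into the survey table."""

    entries: list[NoiseEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure_ms": [e.condition.exposure_ms for e in self.entries],
                "integrations": [e.condition.integrations for e in self.entries],
                "n_points": [e.n_window_points for e in self.entries],
                "NL": [e.nl for e in self.entries],
            }
        )


def apparent_absorbance(series: IntensitySeries) -> np.ndarray:
    """Apparent absorbance of repeats 2..n against the first repeat.

    Returns an (n_repeats - 1, n_wavelengths) matrix; 20 repeats yield 19
    apparent absorbance spectra.
    """
    net = series.white - series.dark
    return -np.log10(net[1:] / net[0])


def sd_spectrum(
    apparent_d2: np.ndarray,
    grid: WavelengthGrid,
    window_nm: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength SD (ddof=1 over the apparent spectra) inside a window.

    ``apparent_d2`` is the matrix of second-derivative apparent absorbance
    rows on ``grid`` (already edge-trimmed).  Returns ``(wavelengths, sd)``
    restricted to the closed nm interval.
    """
    apparent_d2 = np.atleast_2d(np.asarray(apparent_d2, dtype=float))
    if apparent_d2.shape[1] != len(grid):
        raise ValueError("matrix columns must match the grid")
    idx = grid.window_indices(*window_nm)
    if idx.size == 0:
        raise ValueError(
            f"window {window_nm[0]:g}-{window_nm[1]:g} nm contains no grid "
            f"points (grid covers {grid.values[0]:g}-{grid.values[-1]:g} nm)"
        )
    sd = np.std(apparent_d2[:, idx], axis=0, ddof=1)
    return grid.values[idx], sd


def noise_level(sigma: np.ndarray) -> float:
    """Scalar NL: mean of the SD spectrum over the selected wavelengths."""
    sigma = np.asarray(sigma, dtype=float).ravel()
    if sigma.size == 0:
        raise ValueError("empty SD spectrum")
    return float(np.mean(sigma))


def grid_evaluate(
    series_set: Iterable[IntensitySeries],
    sg: SGConfig = SGConfig(),
    window_nm: Sequence[float] = VIS_NIR_NOISE_WINDOW_NM,
) -> NoiseGrid:
    """Full pipeline per condition, sorted by (exposure, integrations).

    apparent absorbance -> row-wise second derivative -> windowed SD ->
    mean NL.  Errors are re-raised with the offending condition named.
    """
    entries: list[NoiseEntry] = []
    for series in series_set:
        cond = series.condition
        try:
            apparent = apparent_absorbance(series)
            trimmed, d2 = second_derivative_matrix(apparent, series.wavelengths, sg)
            _, sd = sd_spectrum(d2, trimmed, (window_nm[0], window_nm[1]))
            entries.append(
                NoiseEntry(
                    condition=cond,
                    nl=noise_level(sd),
                    n_window_points=int(sd.size),
                    n_apparent_spectra=apparent.shape[0],
                )
            )
        except (ValueError, SpectralDomainError) as exc:
            raise type(exc)(
                f"condition exposure={cond.exposure_ms:g} ms x "
                f"{cond.integrations} integrations: {exc}"
            ) from exc
    entries.sort(key=lambda e: (e.condition.exposure_ms, e.condition.integrations))
    return NoiseGrid(entries=entries)
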