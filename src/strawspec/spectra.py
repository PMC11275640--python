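"""Core spectral containers, absorbance arithmetic and tabular I/O.

Absorbance here is the standard diffuse-reflectance quantity

    A(lambda) = -log10( (S - D) / (W - D) )

where ``S`` are raw sample counts, ``W`` white-reference counts and ``D``
dark-current counts.  A :class:`SpectralDataset` bundles an absorbance
matrix with the soluble-solids (% Brix) reference values and variety labels
used for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, GridMismatchError, SpectralDomainError

__all__ = [
    "WavelengthGrid",
    "RawIntensityRecord",
    "SpectralDataset",
    "PigmentSpectrum",
    "compute_absorbance",
    "average_replicates",
    "transmittance_absorbance",
    "read_dataset",
    "write_dataset",
]

_UNIFORMITY_RTOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing, uniformly spaced wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid must be a 1-D array of length >= 2")
        diffs = np.diff(values)
        if np.any(diffs <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        step = diffs[0]
        if np.any(np.abs(diffs - step) > _UNIFORMITY_RTOL * step):
            raise ValueError("wavelength grid must be uniformly spaced")
        object.__setattr__(self, "values", values)

    @property
    def step_nm(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass wants hashability
        return hash((self.values.tobytes(), self.values.shape))

    def matches(self, other: "WavelengthGrid", rtol: float = 1e-9) -> bool:
        """Loose equality tolerant of float round-trip jitter."""
        return len(self) == len(other) and bool(
            np.allclose(self.values, other.values, rtol=rtol, atol=0.0)
        )

    def trim(self, k: int) -> "WavelengthGrid":
        """Drop ``k`` points from each end (Savitzky-Golay edge trimming)."""
        if k < 0 or 2 * k >= len(self) - 1:
            raise ValueError(f"cannot trim {k} points from each end of a "
                             f"{len(self)}-point grid")
        if k == 0:
            return self
        return WavelengthGrid(self.values[k:-k])

    def window_indices(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Indices of grid points inside the closed interval [low, high] nm."""
        return np.nonzero((self.values >= low_nm) & (self.values <= high_nm))[0]


def _check_lengths(grid: WavelengthGrid, **arrays: np.ndarray) -> None:
    for name, arr in arrays.items():
        if arr.shape[-1] != len(grid):
            raise GridMismatchError(
                f"{name} has {arr.shape[-1]} values but the grid has {len(grid)}"
            )


@dataclass(frozen=True)
class RawIntensityRecord:
    """One measurement point: sample, white-reference and dark counts."""

    wavelengths: WavelengthGrid
    sample: np.ndarray
    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sample", "white", "dark"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_lengths(self.wavelengths, sample=self.sample,
                       white=self.white, dark=self.dark)
        net_white = self.white - self.dark
        if np.any(net_white <= 0):
            lam = self.wavelengths.values[np.argmax(net_white <= 0)]
            raise SpectralDomainError(
                f"white minus dark intensity is non-positive at {lam:g} nm"
            )


@dataclass(frozen=True)
class PigmentSpectrum:
    """Absorbance spectrum of a dissolved pigment standard."""

    wavelengths: WavelengthGrid
    absorbance: np.ndarray
    pigment_name: str

    def __post_init__(self) -> None:
        absorbance = np.asarray(self.absorbance, dtype=float)
        _check_lengths(self.wavelengths, absorbance=absorbance)
        if not np.all(np.isfinite(absorbance)):
            raise ValueError("pigment absorbance must be finite")
        object.__setattr__(self, "absorbance", absorbance)


@dataclass
class SpectralDataset:
    """Absorbance matrix with per-sample SSC references and variety labels.

    ``absorbance`` is (n_samples, n_wavelengths) in AU, ``ssc`` in % Brix.
    """

    wavelengths: WavelengthGrid
    absorbance: np.ndarray
    ssc: np.ndarray
    variety: list[str]
    sample_id: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.variety = [str(v) for v in self.variety]
        n = self.absorbance.shape[0]
        if not self.sample_id:
            self.sample_id = [f"s{i:04d}" for i in range(n)]
        self.sample_id = [str(s) for s in self.sample_id]
        _check_lengths(self.wavelengths, absorbance=self.absorbance)
        if not (len(self.ssc) == len(self.variety) == len(self.sample_id) == n):
            raise ValueError("absorbance rows, ssc, variety and sample_id "
                             "must all have the same length")
        if not np.all(np.isfinite(self.ssc)) or np.any(self.ssc <= 0):
            raise ValueError("all SSC references must be finite and positive")
        if len(set(self.sample_id)) != n:
            raise ValueError("sample_id values must be unique")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def varieties(self) -> list[str]:
        """Distinct variety labels in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.variety:
            seen.setdefault(v)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            ssc=self.ssc[idx],
            variety=[self.variety[i] for i in idx],
            sample_id=[self.sample_id[i] for i in idx],
        )

    @staticmethod
    def concat(datasets: Sequence["SpectralDataset"]) -> "SpectralDataset":
        if not datasets:
            raise ValueError("need at least one dataset to concatenate")
        grid = datasets[0].wavelengths
        for ds in datasets[1:]:
            if not grid.matches(ds.wavelengths):
                raise GridMismatchError("datasets are on different wavelength grids")
        return SpectralDataset(
            wavelengths=grid,
            absorbance=np.vstack([ds.absorbance for ds in datasets]),
            ssc=np.concatenate([ds.ssc for ds in datasets]),
            variety=[v for ds in datasets for v in ds.variety],
            sample_id=[s for ds in datasets for s in ds.sample_id],
        )


def compute_absorbance(record: RawIntensityRecord) -> np.ndarray:
    """Absorbance A = -log10((S - D) / (W - D)) from raw detector counts.

    Raises :class:`SpectralDomainError` if any net intensity is non-positive;
    clipping would silently bias downstream calibration.
    """
    net_sample = record.sample - record.dark
    net_white = record.white - record.dark
    for name, net in (("sample", net_sample), ("white", net_white)):
        bad = net <= 0
        if np.any(bad):
            lam = record.wavelengths.values[np.argmax(bad)]
            raise SpectralDomainError(
                f"{name} minus dark intensity is non-positive at {lam:g} nm"
            )
    return -np.log10(net_sample / net_white)


def average_replicates(records: Iterable[RawIntensityRecord]) -> np.ndarray:
    """Mean absorbance over replicate measurement points on one fruit.

    Averages the *absorbances* (not the raw intensities) of the replicate
    points, matching the usual multi-point fruit protocol.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one replicate record")
    grid = records[0].wavelengths
    for rec in records[1:]:
        if not grid.matches(rec.wavelengths):
            raise GridMismatchError("replicate records are on different grids")
    return np.mean([compute_absorbance(rec) for rec in records], axis=0)


def transmittance_absorbance(
    wavelengths: WavelengthGrid,
    reference: np.ndarray,
    sample: np.ndarray,
    pigment_name: str = "pigment",
) -> PigmentSpectrum:
    """Pigment-solution absorbance A = -log10(I0 / It).

    .. note::
       This is the formula exactly as used for the pigment standards, with
       the reference intensity ``I0`` in the numerator.  It yields *negative*
       values for absorbing samples (It < I0); the conventional definition is
       ``-log10(It / I0)``.  The sign convention is preserved deliberately
       rather than silently corrected.
    """
    reference = np.asarray(reference, dtype=float)
    sample = np.asarray(sample, dtype=float)
    _check_lengths(wavelengths, reference=reference, sample=sample)
    for name, arr in (("reference", reference), ("sample", sample)):
        bad = arr <= 0
        if np.any(bad):
            lam = wavelengths.values[np.argmax(bad)]
            raise SpectralDomainError(
                f"{name} intensity is non-positive at {lam:g} nm"
            )
    return PigmentSpectrum(
        wavelengths=wavelengths,
        absorbance=-np.log10(reference / sample),
        pigment_name=pigment_name,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
#
# Layout: UTF-8 CSV, header "sample_id,variety,ssc,<lam1>,<lam2>,...", one
# sample per row, absorbance values in AU.  Wavelength headers are numeric.

_META_COLUMNS = ("sample_id", "variety", "ssc")


def write_dataset(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as wide CSV (shortest-round-trip float formatting)."""
    df = pd.DataFrame(
        dataset.absorbance,
        columns=[str(float(w)) for w in dataset.wavelengths.values],
    )
    df.insert(0, "ssc", dataset.ssc)
    df.insert(0, "variety", dataset.variety)
    df.insert(0, "sample_id", dataset.sample_id)
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> SpectralDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`FormatError` with row/column context on missing metadata
    columns, non-numeric or non-monotone wavelength headers, or missing
    values (ragged rows).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "variety": str},
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    spectral_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not spectral_cols:
        raise FormatError(f"{path}: no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in spectral_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header ({exc})") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise FormatError(f"{path}: wavelength headers must be strictly increasing")
    try:
        grid = WavelengthGrid(wavelengths)
    except ValueError as exc:
        raise FormatError(f"{path}: bad wavelength header ({exc})") from exc
    absorbance = df[spectral_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(absorbance)):
        row = int(np.argwhere(~np.isfinite(absorbance))[0][0])
        raise FormatError(f"{path}: missing or non-finite absorbance in data row {row}")
    ssc = df["ssc"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ssc)):
        row = int(np.argwhere(~np.isfinite(ssc))[0][0])
        raise FormatError(f"{path}: missing SSC value in data row {row}")
    return SpectralDataset(
        wavelengths=grid,
        absorbance=absorbance,
        ssc=ssc,
        variety=df["variety"].tolist(),
        sample_id=df["sample_id"].tolist(),
    )
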