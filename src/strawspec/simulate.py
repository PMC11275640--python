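"""Synthetic strawberry spectra and white-plate intensity series.

The fruit generator emulates diffuse-reflectance absorbance spectra of white
and red strawberries with the statistical structure the calibration pipeline
assumes:

* a Beer-Lambert-style additive mixture of Gaussian absorption bands for
  sugar, water, anthocyanin and chlorophyll, on a smooth per-sample
  scattering baseline (offset + slope + curvature);
* SSC drawn from the variety's normal distribution (white: 10.04 +/- 1.29
  % Brix, red: 8.13 +/- 1.18 % Brix), sugar concentration an affine map of
  SSC, pigment concentrations optionally correlated with SSC (the red
  "ripeness confound": anthocyanin accumulates as the fruit sweetens);
* a pigment-linked multiplicative scattering gain, decaying exponentially
  with wavelength, that scales the constituent bands.  Pigmented tissue
  scatters and absorbs visible photons differently, changing the effective
  optical path and hence the apparent depth of every band in the visible;
  in the NIR the pigments are transparent and the effect vanishes.  This is
  what makes a visible-range model calibrated on one skin color misread the
  other, while NIR models transfer;
* i.i.d. Gaussian instrument noise added independently per simulated
  replicate point (four points per fruit) before averaging.

The white-plate generator simulates a photon-counting detector: mean counts
proportional to exposure time, per-readout variance ``read_noise^2 +
shot_factor * counts``, and the reported intensity the average of
``integrations`` independent readouts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .noise import AcquisitionCondition, IntensitySeries
from .spectra import SpectralDataset, WavelengthGrid

__all__ = [
    "BandDef",
    "VarietyProfile",
    "BaselineConfig",
    "SimConfig",
    "DetectorModel",
    "vis_nir_grid",
    "nir_grid",
    "visnir_sim_config",
    "nir_sim_config",
    "default_bands",
    "WHITE_PROFILE",
    "RED_PROFILE",
    "generate_fruit_dataset",
    "generate_white_plate_series",
    "make_transfer_scenario",
]


def vis_nir_grid() -> WavelengthGrid:
    """Visible-NIR instrument grid: 500-978 nm, 2 nm step (240 points)."""
    return WavelengthGrid(np.arange(500.0, 980.0, 2.0))


def nir_grid() -> WavelengthGrid:
    """NIR instrument grid: 908-1675.56 nm, 6.19 nm step (125 points)."""
    return WavelengthGrid(908.0 + 6.19 * np.arange(125))


@dataclass(frozen=True)
class BandDef:
    """One Gaussian absorption band: A(l) = amplitude * exp(-(l-c)^2 / 2w^2)."""

    center_nm: float
    width_nm: float         # Gaussian SD
    amplitude_per_unit: float  # AU per unit constituent concentration

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigError("band width must be positive")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude_per_unit * np.exp(
            -0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2
        )


def default_bands(anthocyanin_secondary_nm: float = 555.0) -> dict[str, list[BandDef]]:
    """Default absorption bands per constituent, spanning both instrument grids.

    Pigment bands sit in the visible (anthocyanin near 505 nm with a
    variety-shifted secondary near 550-560 nm; chlorophyll red edge near
    673 nm).  Sugar-related O-H/C-H bands at 838, 952, 970, 1168, 1187 and
    1459 nm scale with SSC; water O-H bands at 976, 1075 and 1416 nm are
    near-constant.  Visible pigment bands are narrow (10-15 nm SD); NIR
    water/sugar overtones broad (25-40 nm SD) so second-derivative peaks
    resolve at the default window of 15 points.
    """
    return {
        "anthocyanin": [
            BandDef(505.0, 12.0, 0.6),
            BandDef(anthocyanin_secondary_nm, 15.0, 0.4),
        ],
        "chlorophyll": [BandDef(673.0, 11.0, 0.5)],
        "sugar": [
            BandDef(838.0, 25.0, 0.012),
            BandDef(952.0, 28.0, 0.009),
            BandDef(970.0, 22.0, 0.010),
            BandDef(1168.0, 30.0, 0.012),
            BandDef(1187.0, 30.0, 0.008),
            BandDef(1459.0, 38.0, 0.010),
        ],
        "water": [
            BandDef(976.0, 28.0, 0.35),
            BandDef(1075.0, 35.0, 0.20),
            BandDef(1416.0, 38.0, 0.50),
        ],
    }


@dataclass(frozen=True)
class VarietyProfile:
    """Population parameters for one strawberry variety."""

    name: str
    ssc_mean: float            # % Brix
    ssc_sd: float
    anthocyanin_mean: float    # arbitrary concentration units
    anthocyanin_sd: float
    chlorophyll_mean: float
    chlorophyll_sd: float
    pigment_ssc_correlation: float = 0.0   # anthocyanin-SSC correlation
    anthocyanin_secondary_nm: float = 555.0

    def __post_init__(self) -> None:
        if min(self.ssc_sd, self.anthocyanin_sd, self.chlorophyll_sd) < 0:
            raise ConfigError("standard deviations must be non-negative")
        if not -1.0 <= self.pigment_ssc_correlation <= 1.0:
            raise ConfigError("pigment_ssc_correlation must be in [-1, 1]")
        if self.ssc_mean <= 0 or self.ssc_sd == 0:
            raise ConfigError("ssc_mean must be positive and ssc_sd nonzero")


# White fruit: low anthocyanin, more chlorophyll, no ripeness confound.
WHITE_PROFILE = VarietyProfile(
    name="white", ssc_mean=10.04, ssc_sd=1.29,
    anthocyanin_mean=0.08, anthocyanin_sd=0.03,
    chlorophyll_mean=0.50, chlorophyll_sd=0.15,
    pigment_ssc_correlation=0.0, anthocyanin_secondary_nm=550.0,
)

# Red fruit: high anthocyanin accumulating with ripeness (SSC), little
# chlorophyll left at market maturity.
RED_PROFILE = VarietyProfile(
    name="red", ssc_mean=8.13, ssc_sd=1.18,
    anthocyanin_mean=1.00, anthocyanin_sd=0.35,
    chlorophyll_mean=0.15, chlorophyll_sd=0.05,
    pigment_ssc_correlation=0.8, anthocyanin_secondary_nm=560.0,
)


@dataclass(frozen=True)
class BaselineConfig:
    """Per-sample smooth scattering baseline b0 + b1*u + b2*u^2, u in [0, 1]."""

    offset_mean: float = 0.8
    offset_sd: float = 0.08
    slope_mean: float = 0.3
    slope_sd: float = 0.05
    curvature_mean: float = -0.1
    curvature_sd: float = 0.03


@dataclass(frozen=True)
class SimConfig:
    """Generator settings shared across varieties.

    ``noise_sd`` is the i.i.d. absorbance noise per simulated measurement
    point (AU); four replicate points per fruit are averaged, as in a
    four-point equator protocol.  ``reference_error_sd`` (% Brix) is the
    mismatch between the refractometer reference (whole-fruit juice) and the
    sugar concentration the spectra actually see at the measured points —
    the error floor that dominates real fruit calibrations.
    ``scatter_strength`` and ``scatter_decay_nm`` parameterize the
    pigment-linked multiplicative gain
    ``g(l) = 1 + strength * anthocyanin * exp(-(l - 500 nm)/decay)`` applied
    to the constituent bands; the decay confines it to the visible.
    """

    grid: WavelengthGrid = field(default_factory=vis_nir_grid)
    bands: dict[str, list[BandDef]] | None = None   # None -> default_bands()
    baseline: BaselineConfig = BaselineConfig()
    noise_sd: float = 0.002
    replicate_count: int = 4
    reference_error_sd: float = 0.35
    scatter_strength: float = 1.5
    scatter_decay_nm: float = 200.0
    water_mean: float = 1.0
    water_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.reference_error_sd < 0:
            raise ConfigError("noise_sd and reference_error_sd must be non-negative")
        if self.replicate_count < 1:
            raise ConfigError("replicate_count must be >= 1")
        if self.scatter_decay_nm <= 0:
            raise ConfigError("scatter_decay_nm must be positive")


# Wavelength at which the pigment-linked scattering gain is at full
# strength; it decays exponentially toward the NIR from here.
_SCATTER_ANCHOR_NM = 500.0


def visnir_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Simulation preset for the visible-NIR instrument (500-978 nm)."""
    return SimConfig(grid=vis_nir_grid(), seed=seed, **overrides)


def nir_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Simulation preset for the NIR instrument (908-1676 nm).

    Pigments are transparent across this range, so the pigment-linked
    scattering gain is absent: skin color leaves no signature in the
    simulated NIR spectra beyond the varieties' SSC distributions.
    """
    overrides.setdefault("scatter_strength", 0.0)
    return SimConfig(grid=nir_grid(), seed=seed, **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int, low: float = 0.0) -> np.ndarray:
    """Normal draws resampled (not clipped) until all exceed ``low``."""
    if sd == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def _band_matrix(bands: list[BandDef], wavelengths: np.ndarray) -> np.ndarray:
    if not bands:
        return np.zeros_like(wavelengths)
    return np.sum([b.profile(wavelengths) for b in bands], axis=0)


def generate_fruit_dataset(
    profile: VarietyProfile, n: int, cfg: SimConfig = SimConfig()
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Simulate ``n`` fruit of one variety; returns (dataset, truth table).

    The truth table records the per-sample constituent concentrations and
    baseline coefficients actually used, for parameter-recovery checks.
    Deterministic given ``cfg.seed``.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.grid.values
    bands = cfg.bands if cfg.bands is not None else default_bands(
        profile.anthocyanin_secondary_nm
    )

    ssc = _truncated_normal(rng, profile.ssc_mean, profile.ssc_sd, n)
    # Affine unit-slope SSC -> sugar map plus the reference mismatch: the
    # refractometer reads whole-fruit juice, the spectra see the equator.
    sugar = ssc + rng.normal(0.0, cfg.reference_error_sd, size=n) \
        if cfg.reference_error_sd > 0 else ssc.copy()
    # Pigment tracks the tissue actually measured (true sugar), not the
    # refractometer reading.
    z_sugar = (sugar - profile.ssc_mean) / profile.ssc_sd
    rho = profile.pigment_ssc_correlation
    anth = profile.anthocyanin_mean + profile.anthocyanin_sd * (
        rho * z_sugar + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    )
    np.clip(anth, 0.0, None, out=anth)
    chl = _truncated_normal(rng, profile.chlorophyll_mean,
                            profile.chlorophyll_sd, n)
    water = rng.normal(cfg.water_mean, cfg.water_sd, size=n)

    profiles = {name: _band_matrix(b, wl) for name, b in bands.items()}
    mixture = (
        np.outer(sugar, profiles["sugar"])
        + np.outer(water, profiles["water"])
        + np.outer(anth, profiles["anthocyanin"])
        + np.outer(chl, profiles["chlorophyll"])
    )

    # Pigment-linked scattering gain, anchored in the visible: pigments are
    # transparent in the NIR, so the gain decays with wavelength regardless
    # of which instrument grid is being simulated.
    decay = np.exp(-(wl - _SCATTER_ANCHOR_NM) / cfg.scatter_decay_nm)
    gain = 1.0 + cfg.scatter_strength * np.outer(anth, decay)

    bl = cfg.baseline
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    b0 = rng.normal(bl.offset_mean, bl.offset_sd, size=n)
    b1 = rng.normal(bl.slope_mean, bl.slope_sd, size=n)
    b2 = rng.normal(bl.curvature_mean, bl.curvature_sd, size=n)
    baseline = b0[:, None] + np.outer(b1, u) + np.outer(b2, u**2)

    clean = baseline + gain * mixture
    if cfg.noise_sd > 0:
        noise = rng.normal(
            0.0, cfg.noise_sd, size=(cfg.replicate_count, n, wl.size)
        ).mean(axis=0)
    else:
        noise = 0.0
    absorbance = clean + noise

    ids = [f"{profile.name}-{i:04d}" for i in range(n)]
    dataset = SpectralDataset(
        wavelengths=cfg.grid,
        absorbance=absorbance,
        ssc=ssc,
        variety=[profile.name] * n,
        sample_id=ids,
    )
    truth = pd.DataFrame(
        {
            "sample_id": ids,
            "ssc": ssc,
            "sugar": sugar,
            "water": water,
            "anthocyanin": anth,
            "chlorophyll": chl,
            "baseline_offset": b0,
            "baseline_slope": b1,
            "baseline_curvature": b2,
        }
    )
    return dataset, truth


@dataclass(frozen=True)
class DetectorModel:
    """Photon-counting detector: counts ~ source * exposure, per-readout
    noise SD sqrt(read_noise^2 + shot_factor * counts)."""

    source_per_ms: float = 200.0   # mean counts per ms exposure
    read_noise: float = 30.0       # counts per readout
    shot_factor: float = 1.0       # variance per count (1.0 = Poisson-like)

    def __post_init__(self) -> None:
        if self.source_per_ms <= 0:
            raise ConfigError("source_per_ms must be positive")
        if self.read_noise < 0 or self.shot_factor < 0:
            raise ConfigError("noise parameters must be non-negative")


# z such that P(N(0,1) < -z) ~ 1e-6: guards the log domain of Eq-7-style
# apparent absorbance against non-positive net intensities.
_POSITIVITY_Z = 4.7534


def generate_white_plate_series(
    condition: AcquisitionCondition,
    n_repeats: int = 20,
    detector: DetectorModel = DetectorModel(),
    grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> IntensitySeries:
    """Simulate repeated white-plate measurements under one condition.

    The reported intensity per repeat is the average of ``integrations``
    independent readouts, simulated directly as a normal with the averaged
    SD.  Dark frames have zero source and read noise only.  Raises
    :class:`ConfigError` if the configured detector would produce a
    non-positive net intensity with probability above ~1e-6 per draw.
    """
    if n_repeats < 2:
        raise ConfigError("n_repeats must be >= 2")
    if grid is None:
        grid = vis_nir_grid()
    rng = np.random.default_rng(seed)
    n_wl = len(grid)

    mean_counts = detector.source_per_ms * condition.exposure_ms
    single_sd = float(
        np.sqrt(detector.read_noise**2 + detector.shot_factor * mean_counts)
    )
    dark_sd = float(detector.read_noise)
    avg_factor = np.sqrt(condition.integrations)
    # net = white - dark; its SD combines both averaged readout noises
    net_sd = np.sqrt(single_sd**2 + dark_sd**2) / avg_factor
    if net_sd > 0 and mean_counts / net_sd < _POSITIVITY_Z:
        raise ConfigError(
            f"detector settings make non-positive net intensity likely "
            f"(mean {mean_counts:g} counts vs net SD {net_sd:g}); increase "
            f"source, exposure or integrations"
        )
    white = mean_counts + rng.normal(
        0.0, single_sd / avg_factor, size=(n_repeats, n_wl)
    )
    dark = rng.normal(0.0, dark_sd / avg_factor, size=(n_repeats, n_wl))
    return IntensitySeries(condition=condition, wavelengths=grid,
                           white=white, dark=dark)


def make_transfer_scenario(
    cfg: SimConfig = SimConfig(),
    n_white: int = 180,
    n_red: int = 150,
    seed: int = 0,
) -> tuple[SpectralDataset, SpectralDataset, SpectralDataset]:
    """White, red and mixed datasets for the cross-variety experiment.

    The red profile carries the pigment-SSC correlation (the confounded
    regime); the white profile does not.  Per-variety seeds are derived
    deterministically from ``seed``.
    """
    child = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    white, _ = generate_fruit_dataset(
        WHITE_PROFILE, n_white, dataclasses.replace(cfg, seed=int(child[0]))
    )
    red, _ = generate_fruit_dataset(
        RED_PROFILE, n_red, dataclasses.replace(cfg, seed=int(child[1]))
    )
    mixed = SpectralDataset.concat([white, red])
    return white, red, mixed
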