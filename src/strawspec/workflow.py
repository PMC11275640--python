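"""End-to-end orchestration of the six-model experiment and transfer matrix.

``run_experiment`` takes named (dataset x spectral-range) combinations and,
for each: second-derivative preprocessing, a 7:3 random split, leave-one-out
PRESS factor selection, a full-training fit and the three-context
validation.  ``run_transfer_matrix`` applies fitted models, unchanged, to
test sets from other populations.  All randomness flows from the named
seeds, so re-running a configuration reproduces the tables bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd
import yaml

from .pls import (PLSRModel, PressCurve, SplitSpec, fit_with_selection,
                  save_model, split_dataset)
from .preprocess import SGConfig, transform_dataset
from .spectra import SpectralDataset, read_dataset
from .validation import ValidationReport, evaluate, transfer_evaluate

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "run_transfer_matrix"]

logger = logging.getLogger(__name__)

DatasetSource = Union[SpectralDataset, str, Path]

SUMMARY_COLUMNS = [
    "dataset", "range", "factors",
    "R2_C", "RMSEC", "R2_CV", "RMSECV",
    "R2_P", "RMSEP", "RPD", "slope", "offset", "bias", "n_train", "n_test",
]

TRANSFER_COLUMNS = [
    "test_set", "model", "R2_P", "RMSEP", "RPD", "slope", "offset", "bias", "n",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: named (dataset, range) sources plus shared settings.

    ``datasets`` maps ``(dataset_name, range_label)`` to a
    :class:`SpectralDataset` or a CSV path.  The stratified split is the
    sensible default for mixed-variety datasets and a no-op for single-
    variety ones.
    """

    datasets: Mapping[tuple[str, str], DatasetSource]
    sg: SGConfig = SGConfig()
    split: SplitSpec = SplitSpec()
    h_max: int = 12
    alpha: float = 0.25
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("experiment needs at least one dataset")

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        """Load a file-based experiment description.

        Layout::

            datasets:
              white: {vis-nir: white_visnir.csv, nir: white_nir.csv}
            sg: {window: 15, polyorder: 2}
            split: {train_fraction: 0.7, seed: 7, stratify_by: none}
            h_max: 12
            alpha: 0.25
            output_dir: out/
        """
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        datasets = {
            (name, rng): str(base / src)
            for name, ranges in raw["datasets"].items()
            for rng, src in ranges.items()
        }
        return ExperimentConfig(
            datasets=datasets,
            sg=SGConfig(**raw.get("sg", {})),
            split=SplitSpec(**raw.get("split", {})),
            h_max=int(raw.get("h_max", 12)),
            alpha=float(raw.get("alpha", 0.25)),
            output_dir=raw.get("output_dir"),
        )


@dataclass
class ExperimentResult:
    """Everything a combination produced, keyed ``name/range``."""

    summary: pd.DataFrame
    models: dict[str, PLSRModel] = field(default_factory=dict)
    press: dict[str, PressCurve] = field(default_factory=dict)
    reports: dict[str, dict[str, ValidationReport]] = field(default_factory=dict)
    tests: dict[str, SpectralDataset] = field(default_factory=dict)
    trains: dict[str, SpectralDataset] = field(default_factory=dict)


def _load(source: DatasetSource) -> SpectralDataset:
    if isinstance(source, SpectralDataset):
        return source
    return read_dataset(source)


def _summary_row(key_name: str, key_range: str, model: PLSRModel,
                 reports: dict[str, ValidationReport],
                 n_train: int, n_test: int) -> dict:
    cal, cv, pred = (reports["calibration"], reports["cross_validation"],
                     reports["prediction"])
    return {
        "dataset": key_name, "range": key_range, "factors": model.n_factors,
        "R2_C": cal.r2, "RMSEC": cal.rmse,
        "R2_CV": cv.r2, "RMSECV": cv.rmse,
        "R2_P": pred.r2, "RMSEP": pred.rmse, "RPD": pred.rpd,
        "slope": pred.slope, "offset": pred.offset, "bias": pred.bias,
        "n_train": n_train, "n_test": n_test,
    }


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every (dataset, range) combination; failures are isolated.

    Returns the summary table (one row per combination) plus all fitted
    models, PRESS curves, reports and the split datasets.  When
    ``cfg.output_dir`` is set, models (JSON), reports (JSON via pandas),
    PRESS curves (CSV) and the summary (CSV) are written beneath it.
    """
    rows: list[dict] = []
    result = ExperimentResult(summary=pd.DataFrame())
    out = Path(cfg.output_dir) if cfg.output_dir is not None else None
    if out is not None:
        for sub in ("models", "reports", "press"):
            (out / sub).mkdir(parents=True, exist_ok=True)

    for (name, range_label), source in cfg.datasets.items():
        key = f"{name}/{range_label}"
        try:
            dataset = _load(source)
            derivative = transform_dataset(dataset, cfg.sg)
            train, test = split_dataset(derivative, cfg.split)
            model, press = fit_with_selection(train, cfg.h_max, cfg.alpha)
            reports = evaluate(model, train, test, press)
        except Exception:
            logger.exception("combination %s failed; continuing", key)
            continue
        rows.append(_summary_row(name, range_label, model, reports,
                                 train.n_samples, test.n_samples))
        result.models[key] = model
        result.press[key] = press
        result.reports[key] = reports
        result.tests[key] = test
        result.trains[key] = train
        if out is not None:
            safe = key.replace("/", "_")
            save_model(model, out / "models" / f"{safe}.json")
            pd.DataFrame(
                {"factors": range(1, press.h_max + 1), "PRESS": press.press}
            ).to_csv(out / "press" / f"{safe}.csv", index=False)
            pd.Series(
                {ctx: rep.to_dict() for ctx, rep in reports.items()}
            ).to_json(out / "reports" / f"{safe}.json")

    result.summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if out is not None:
        result.summary.to_csv(out / "summary.csv", index=False)
    return result


def run_transfer_matrix(
    models: Mapping[str, PLSRModel],
    foreign_tests: Mapping[str, SpectralDataset],
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """Every model applied to every test set, one row per pairing.

    Pairings whose wavelength grids are incompatible are logged and skipped;
    the rest proceed.
    """
    rows: list[dict] = []
    for test_name, test in foreign_tests.items():
        for model_name, model in models.items():
            try:
                report = transfer_evaluate(model, test)
            except Exception:
                logger.exception("transfer %s -> %s failed; continuing",
                                 model_name, test_name)
                continue
            rows.append({
                "test_set": test_name, "model": model_name,
                "R2_P": report.r2, "RMSEP": report.rmse, "RPD": report.rpd,
                "slope": report.slope, "offset": report.offset,
                "bias": report.bias, "n": report.n,
            })
    table = pd.DataFrame(rows, columns=TRANSFER_COLUMNS)
    if output_path is not None:
        table.to_csv(output_path, index=False)
    return table
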