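"""End-to-end calibration experiments on synthetic antiseptic spectra.

Three analyses mirror the study design:

* single-analyte PS calibration over 0.3–10 mg/L with an independently
  simulated test series of the same levels;
* a PS model on the 36-composition PS x SB mixture factorial, calibrated
  only on PS's characteristic-peak windows (which contain SB signal);
* the matching SB model on SB's windows (which contain PS signal);

plus an interference analysis that, for each mixture sample, reports the
deviation of its predicted target concentration from the mean prediction
over the samples sharing the same true target level — flat deviations mean
the co-solute does not leak into the calibration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import plsr
from .preprocess import WindowSet, average_replicates, extract_windows, windows_from_bands
from .synth import (
    DEFAULT_AXIS_SPEC,
    AnalyteLibrary,
    DesignTable,
    NoiseConfig,
    build_axis,
    default_libraries,
    make_mixture_design,
    make_single_analyte_design,
    simulate_dataset,
)

__all__ = [
    "ExperimentConfig",
    "CalibrationReport",
    "InterferenceReport",
    "run_single_analyte_experiment",
    "run_mixture_experiment",
    "interference_analysis",
    "reproduce_all",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to run one calibration + test experiment."""

    design: str = "single"  # "single" | "mixture"
    target: str = "PS"
    libraries: Mapping[str, AnalyteLibrary] = field(default_factory=default_libraries)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    axis: np.ndarray = field(default_factory=lambda: build_axis(*DEFAULT_AXIS_SPEC))
    window_k: float = 3.0
    windows: Mapping[str, WindowSet] | None = None
    replicates: int = 5
    seed_calibration: int = 0
    seed_test: int = 100
    max_components: int = 10

    def __post_init__(self) -> None:
        if self.design not in ("single", "mixture"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.seed_calibration == self.seed_test:
            raise ValueError("calibration and test seeds must differ")
        if self.target not in self.libraries:
            raise KeyError(f"target analyte {self.target!r} missing from libraries")

    def windows_for(self, analyte: str) -> WindowSet:
        if self.windows is not None and analyte in self.windows:
            return self.windows[analyte]
        if analyte not in self.libraries:
            raise KeyError(f"analyte {analyte!r} missing from libraries")
        return windows_from_bands(self.libraries[analyte], k=self.window_k)


@dataclass
class CalibrationReport:
    """Predicted vs. actual concentrations for calibration and test sets."""

    target: str
    sample_ids: np.ndarray
    actual_calibration: np.ndarray
    predicted_calibration: np.ndarray
    actual_test: np.ndarray
    predicted_test: np.ndarray
    r2_calibration: float
    rmse_calibration: float
    r2_test: float
    rmse_test: float
    n_components: int
    rmsecv: np.ndarray
    model: plsr.PLSRModel

    def metrics(self) -> dict[str, float]:
        return {
            "r2_calibration": self.r2_calibration,
            "rmse_calibration": self.rmse_calibration,
            "r2_test": self.r2_test,
            "rmse_test": self.rmse_test,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "actual_calibration": self.actual_calibration,
                "predicted_calibration": self.predicted_calibration,
                "actual_test": self.actual_test,
                "predicted_test": self.predicted_test,
            }
        )


@dataclass
class InterferenceReport:
    """Per-sample deviation from the mean prediction at the same true level."""

    target: str
    sample_ids: np.ndarray
    true_level: np.ndarray
    deviation: np.ndarray
    max_abs_deviation: float


def _make_design(config: ExperimentConfig) -> DesignTable:
    if config.design == "single":
        return make_single_analyte_design(replicates=config.replicates)
    return make_mixture_design(replicates=config.replicates)


def _run_experiment(config: ExperimentConfig, target: str) -> CalibrationReport:
    design = _make_design(config)
    windows = config.windows_for(target)

    cal = average_replicates(
        simulate_dataset(design, config.libraries, config.noise, config.axis, config.seed_calibration)
    )
    fm_cal = extract_windows(cal, windows, target)

    a_max = min(config.max_components, fm_cal.X.shape[0] - 2, fm_cal.X.shape[1])
    a_star, rmsecv = plsr.select_components_cv(fm_cal.X, fm_cal.y, a_max=a_max)
    model, _ = plsr.fit_nipals(
        fm_cal.X, fm_cal.y, a_star, wavenumbers=fm_cal.wavenumbers, windows=windows
    )
    pred_cal = plsr.predict(model, fm_cal.X)

    test = average_replicates(
        simulate_dataset(design, config.libraries, config.noise, config.axis, config.seed_test)
    )
    fm_test = extract_windows(test, windows, target)
    pred_test = plsr.predict(model, fm_test.X)

    report = CalibrationReport(
        target=target,
        sample_ids=fm_cal.sample_ids,
        actual_calibration=fm_cal.y,
        predicted_calibration=np.asarray(pred_cal),
        actual_test=fm_test.y,
        predicted_test=np.asarray(pred_test),
        r2_calibration=plsr.r_squared(pred_cal, fm_cal.y),
        rmse_calibration=plsr.rmse(pred_cal, fm_cal.y),
        r2_test=plsr.r_squared(pred_test, fm_test.y),
        rmse_test=plsr.rmse(pred_test, fm_test.y),
        n_components=model.n_components,
        rmsecv=rmsecv,
        model=model,
    )
    logger.info(
        "%s/%s seeds (%d, %d): A=%d, cal R2=%.4f RMSE=%.3f, test R2=%.4f RMSE=%.3f",
        config.design,
        target,
        config.seed_calibration,
        config.seed_test,
        report.n_components,
        report.r2_calibration,
        report.rmse_calibration,
        report.r2_test,
        report.rmse_test,
    )
    return report


def run_single_analyte_experiment(config: ExperimentConfig) -> CalibrationReport:
    """PS calibration on the 8-level series plus an independent test series."""
    if config.design != "single":
        raise ValueError("config.design must be 'single'")
    return _run_experiment(config, config.target)


def run_mixture_experiment(config: ExperimentConfig, target: str | None = None) -> CalibrationReport:
    """Per-analyte model on the 36-composition factorial, window-restricted."""
    if config.design != "mixture":
        raise ValueError("config.design must be 'mixture'")
    target = config.target if target is None else target
    if target not in config.libraries:
        raise KeyError(f"target analyte {target!r} missing from libraries")
    return _run_experiment(config, target)


def interference_analysis(
    report: CalibrationReport, design: DesignTable, target: str
) -> InterferenceReport:
    """Deviation of each calibration prediction from its true-level group mean.

    Mixture samples are grouped by their true target concentration (six
    groups of six in the full factorial); within-group deviations sum to
    zero by construction.
    """
    col = f"{target}_mgL"
    if col not in design.table.columns:
        raise KeyError(f"target analyte {target!r} not in design")
    levels = report.actual_calibration
    preds = report.predicted_calibration
    deviation = np.empty_like(preds)
    for level in np.unique(levels):
        idx = levels == level
        if idx.sum() < 2:
            raise ValueError(
                f"true level {level} mg/L has a singleton group; cannot average"
            )
        deviation[idx] = preds[idx] - preds[idx].mean()
    return InterferenceReport(
        target=target,
        sample_ids=report.sample_ids,
        true_level=levels,
        deviation=deviation,
        max_abs_deviation=float(np.abs(deviation).max()),
    )


def _median_metrics(reports: list[CalibrationReport]) -> dict[str, float]:
    return {
        k: float(np.median([r.metrics()[k] for r in reports]))
        for k in ("r2_calibration", "rmse_calibration", "r2_test", "rmse_test")
    }


def reproduce_all(
    master_seed: int = 0,
    n_seeds: int = 5,
    *,
    noise: NoiseConfig | None = None,
    replicates: int = 5,
    outdir: str | Path | None = None,
) -> dict:
    """Run the three reproduction experiments over a block of seeds.

    Calibration seeds are ``1000*master_seed + i`` and test seeds
    ``1000*master_seed + 100 + i`` for ``i`` in 0…n_seeds−1 (so master seed
    0 runs calibration seeds 0–4 against test seeds 100–104). Per-seed
    reports and the median of each metric are returned; with ``outdir``
    everything is also written out as JSON/CSV.
    """
    noise = NoiseConfig() if noise is None else noise
    base = 1000 * int(master_seed)
    per_seed: dict[str, list[CalibrationReport]] = {
        "single_PS": [],
        "mixture_PS": [],
        "mixture_SB": [],
    }
    interference_max: list[float] = []
    mixture_design = make_mixture_design(replicates=replicates)
    for i in range(n_seeds):
        seed_cal, seed_test = base + i, base + 100 + i
        single_cfg = ExperimentConfig(
            design="single", target="PS", noise=noise, replicates=replicates,
            seed_calibration=seed_cal, seed_test=seed_test,
        )
        mix_cfg = ExperimentConfig(
            design="mixture", target="PS", noise=noise, replicates=replicates,
            seed_calibration=seed_cal, seed_test=seed_test,
        )
        per_seed["single_PS"].append(run_single_analyte_experiment(single_cfg))
        ps_report = run_mixture_experiment(mix_cfg, "PS")
        per_seed["mixture_PS"].append(ps_report)
        per_seed["mixture_SB"].append(run_mixture_experiment(mix_cfg, "SB"))
        interference_max.append(
            interference_analysis(ps_report, mixture_design, "PS").max_abs_deviation
        )

    summary = {
        "master_seed": int(master_seed),
        "n_seeds": int(n_seeds),
        "experiments": {name: _median_metrics(reports) for name, reports in per_seed.items()},
        "mixture_PS_interference_max_abs_deviation_median": float(np.median(interference_max)),
    }
    result = {"per_seed": per_seed, "summary": summary}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        for name, reports in per_seed.items():
            for i, rep in enumerate(reports):
                rep.to_frame().to_csv(
                    outdir / f"{name}_seed{base + i}_predictions.csv", index=False
                )
        logger.info("wrote summary and prediction tables to %s", outdir)
    return result


def plot_predicted_vs_actual(report: CalibrationReport, path: str | Path) -> None:
    """Scatter of predicted vs. actual concentrations (calibration + test)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(report.actual_calibration, report.predicted_calibration,
               label="calibration", marker="o")
    ax.scatter(report.actual_test, report.predicted_test, label="test", marker="s")
    lim = [0, max(report.actual_calibration.max(), report.actual_test.max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel(f"actual {report.target} (mg/L)")
    ax.set_ylabel(f"predicted {report.target} (mg/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
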