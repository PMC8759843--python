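"""Evaluation diagnostics for the surrogate: MSE, absolute error, regression, histograms.

These mirror the standard function-fitting diagnostics: mean squared
error per data split, the pointwise absolute-error series along the
grid, the Pearson regression coefficient R between predictions and
targets, and a uniform-bin error histogram with the center of the bin
nearest zero error reported (the "zero error" annotation of fitting
toolboxes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .fde import Trajectory

__all__ = [
    "EvalReport",
    "mse",
    "absolute_error_series",
    "regression_R",
    "error_histogram",
    "evaluate",
]

OUTPUT_NAMES = ("S", "I", "P")


def mse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Mean squared difference, pooled over every sample and output supplied."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean((pred - ref) ** 2))


def absolute_error_series(pred: np.ndarray, ref: Trajectory | np.ndarray) -> dict:
    """Elementwise |pred - ref| per output, with per-output max and min.

    ``pred`` must share the reference grid: shape (n_points, n_out).
    """
    ref_states = ref.states if isinstance(ref, Trajectory) else np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if pred.shape != ref_states.shape:
        raise ValueError(
            f"prediction grid {pred.shape} does not match reference {ref_states.shape}"
        )
    ae = np.abs(pred - ref_states)
    return {
        "ae": ae,
        "max": ae.max(axis=0),
        "min": ae.min(axis=0),
    }


def regression_R(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pearson product-moment correlation between predictions and targets."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.size < 2:
        raise ValueError("need at least 2 samples for a correlation")
    if np.ptp(ref) == 0:
        raise ValueError("regression R is undefined for a constant reference")
    return float(stats.pearsonr(pred, ref).statistic)


def error_histogram(errors: np.ndarray, n_bins: int = 20) -> dict:
    """Uniform-bin histogram over [min(errors), max(errors)].

    Returns bin edges, counts, and the center of the bin containing (or
    nearest to) zero error.  Degenerate all-equal inputs occupy a single
    unit-width bin centered on the common value.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("empty error sequence")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(errors.min()), float(errors.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(errors, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    zero_bin = int(np.argmin(np.abs(centers)))
    return {
        "edges": edges,
        "counts": counts,
        "centers": centers,
        "zero_error_bin_center": float(centers[zero_bin]),
    }


@dataclass
class EvalReport:
    """All surrogate diagnostics for one case."""

    mse_train: float
    mse_validation: float
    mse_test: float
    ae: np.ndarray
    ae_max: np.ndarray
    ae_min: np.ndarray
    regression: dict[str, float]
    histogram: dict
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mse_train": self.mse_train,
            "mse_validation": self.mse_validation,
            "mse_test": self.mse_test,
            "ae_max": self.ae_max.tolist(),
            "ae_min": self.ae_min.tolist(),
            "regression": self.regression,
            "histogram": {
                "edges": self.histogram["edges"].tolist(),
                "counts": self.histogram["counts"].tolist(),
                "zero_error_bin_center": self.histogram["zero_error_bin_center"],
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def ae_to_csv(self, path: str | Path) -> None:
        data = np.column_stack([self.times, self.ae])
        np.savetxt(path, data, delimiter=",", header="tau,AE_S,AE_I,AE_P",
                   comments="", fmt="%.17g")


def evaluate(
    pred: np.ndarray,
    ref: Trajectory,
    split,
    n_bins: int = 20,
) -> EvalReport:
    """Full diagnostic suite for surrogate outputs against a reference trajectory.

    ``pred`` has shape (n_points, n_out) on the reference grid; ``split``
    provides the train/validation/test index sets.  The regression dict
    holds per-output R (keys "S", "I", "P"), pooled R over all outputs
    ("all"), and pooled R per split ("train", "validation", "test").
    """
    y = ref.states
    ae_info = absolute_error_series(pred, ref)
    regression: dict[str, float] = {}
    for k, name in enumerate(OUTPUT_NAMES[: y.shape[1]]):
        regression[name] = regression_R(pred[:, k], y[:, k])
    regression["all"] = regression_R(pred, y)
    for name, idx in (("train", split.train), ("validation", split.validation),
                      ("test", split.test)):
        regression[name] = regression_R(pred[idx], y[idx])
    errors = (y - pred).ravel()
    return EvalReport(
        mse_train=mse(pred[split.train], y[split.train]),
        mse_validation=mse(pred[split.validation], y[split.validation]),
        mse_test=mse(pred[split.test], y[split.test]),
        ae=ae_info["ae"],
        ae_max=ae_info["max"],
        ae_min=ae_info["min"],
        regression=regression,
        histogram=error_histogram(errors, n_bins=n_bins),
        times=ref.times,
    )
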