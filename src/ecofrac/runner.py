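"""End-to-end case execution: reference solve, split, LM fit, evaluation.

A "case" is one configuration of the fractional prey-predator model
(in the study setup: alpha = 0.5, 0.7 or 0.9, everything else fixed).
:func:`run_case` produces the ABM reference trajectory, trains the
surrogate with restarts, and evaluates the full diagnostic suite;
:func:`run_all` executes the three study cases and writes per-case
CSV/JSON reports plus a summary table (case, split MSEs, performance,
gradient, epochs).  Everything is deterministic given the seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fde import Grid, SolverConfig, Trajectory, caputo_abm_solve
from .metrics import EvalReport, evaluate
from .model import CaseSpec, default_case, rhs
from .surrogate import FitReport, SplitIndices, TrainConfig, forward, lm_train, split_indices

__all__ = ["CaseReport", "solve_case", "run_case", "run_all", "DEFAULT_ALPHAS"]

logger = logging.getLogger("ecofrac")

#: Fractional orders of the three study cases.
DEFAULT_ALPHAS = (0.5, 0.7, 0.9)


@dataclass
class CaseReport:
    """Everything produced by one end-to-end case run."""

    case: CaseSpec
    reference: Trajectory
    fit: FitReport
    evaluation: EvalReport
    split: SplitIndices
    version: str
    seed: int

    def summary_row(self) -> dict:
        return {
            "alpha": self.case.alpha,
            "mse_train": self.evaluation.mse_train,
            "mse_validation": self.evaluation.mse_validation,
            "mse_test": self.evaluation.mse_test,
            "performance": self.fit.final_mse_train,
            "gradient": self.fit.grad_norm[-1],
            "epochs": self.fit.epochs[-1],
            "stop_reason": self.fit.stop_reason,
            "max_ae_S": self.evaluation.ae_max[0],
            "max_ae_I": self.evaluation.ae_max[1],
            "max_ae_P": self.evaluation.ae_max[2],
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reference.to_csv(out / "reference.csv")
        self.fit.to_json(out / "fit.json")
        self.evaluation.to_json(out / "evaluation.json")
        self.evaluation.ae_to_csv(out / "absolute_error.csv")
        meta = {
            "case": self.case.to_config(),
            "version": self.version,
            "seed": self.seed,
            "split": {
                "train": self.split.train.tolist(),
                "validation": self.split.validation.tolist(),
                "test": self.split.test.tolist(),
            },
        }
        (out / "case.json").write_text(json.dumps(meta, indent=1))


def solve_case(case: CaseSpec, solver: SolverConfig | None = None) -> Trajectory:
    """ABM reference trajectory for a model configuration."""
    grid = Grid(t0=0.0, h=case.h, n_steps=case.n_steps)
    f = lambda t, y: rhs(y, case.params, variant=case.rhs_variant)
    traj = caputo_abm_solve(f, case.alpha, case.y0, grid, solver)
    if traj.diverged_at is not None:
        raise RuntimeError(
            f"reference solver diverged at step {traj.diverged_at} "
            f"(alpha={case.alpha})"
        )
    return traj


def run_case(
    case: CaseSpec,
    train: TrainConfig | None = None,
    solver: SolverConfig | None = None,
) -> CaseReport:
    """Reference solve -> 80/10/10 split -> LM fit with restarts -> evaluation."""
    train = train or TrainConfig()
    cfg_hash = hashlib.sha256(
        json.dumps({**case.to_config(), "seed": train.seed,
                    "restarts": train.restarts}, sort_keys=True).encode()
    ).hexdigest()[:12]
    logger.info("case alpha=%s seed=%s restarts=%s config=%s",
                case.alpha, train.seed, train.restarts, cfg_hash)

    reference = solve_case(case, solver)
    split = split_indices(case.n_steps + 1, seed=train.seed)
    fit = lm_train(reference, split, train)
    pred = forward(fit.weights, reference.times)
    evaluation = evaluate(pred, reference, split)
    logger.info(
        "case alpha=%s done: train MSE %.3e, max AE %s, stop=%s after %d epochs",
        case.alpha, evaluation.mse_train,
        np.array2string(evaluation.ae_max, precision=2), fit.stop_reason,
        fit.epochs[-1],
    )
    return CaseReport(
        case=case, reference=reference, fit=fit, evaluation=evaluation,
        split=split, version=__version__, seed=train.seed,
    )


def run_all(
    output_dir: str | Path,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    train: TrainConfig | None = None,
    solver: SolverConfig | None = None,
) -> tuple[list[CaseReport], pd.DataFrame]:
    """Run every study case and write reports plus a summary table."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise NotADirectoryError(f"{out} is not a writable directory")
    probe = out / ".write_probe"
    try:
        probe.write_text("")
    finally:
        probe.unlink(missing_ok=True)

    reports = []
    for i, alpha in enumerate(alphas):
        case = default_case(alpha)
        reports.append(run_case(case, train, solver))
        reports[-1].write(out / f"case_{i + 1}_alpha_{alpha:g}")
    summary = pd.DataFrame(
        [{"case": i + 1, **rep.summary_row()} for i, rep in enumerate(reports)]
    )
    summary.to_csv(out / "summary.csv", index=False)
    return reports, summary
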