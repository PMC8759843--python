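"""Neural surrogate of the reference trajectories, trained by Levenberg-Marquardt.

A single feed-forward network with one input (time tau), ``n_hidden``
tanh units and three linear outputs (S, I, P) is fitted by damped
Gauss-Newton least squares to the trajectory produced by the fractional
ABM solver.  The grid samples are split 80/10/10 into train /
validation / test subsets by a seeded random permutation; training
minimizes the pooled mean squared error on the training subset and
stops early when the validation error fails to improve.

The time input is mapped affinely from [t0, t_end] onto [-1, 1] before
entering the network; targets are used in raw units (the densities are
already O(1)).  A per-output mode (three independent single-output
networks) is available behind ``joint=False`` in :func:`lm_train`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fde import Trajectory

__all__ = [
    "NetworkWeights",
    "SplitIndices",
    "TrainConfig",
    "FitReport",
    "split_indices",
    "init_network",
    "forward",
    "jacobian",
    "lm_train",
]


@dataclass
class NetworkWeights:
    """Weights of a 1-input, n_hidden-tanh, n_out-linear network.

    Shapes: W1 (n_hidden, 1), b1 (n_hidden,), W2 (n_out, n_hidden),
    b2 (n_out,).  ``input_scale``/``input_shift`` store the affine map
    applied to tau before the first layer.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    input_scale: float = 1.0
    input_shift: float = 0.0

    def __post_init__(self) -> None:
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.atleast_2d(np.asarray(self.W2, dtype=float))
        self.b2 = np.asarray(self.b2, dtype=float)
        nh = self.W1.shape[0]
        if self.W1.shape != (nh, 1) or self.b1.shape != (nh,):
            raise ValueError("inconsistent hidden-layer shapes")
        if self.W2.shape[1] != nh or self.b2.shape != (self.W2.shape[0],):
            raise ValueError("inconsistent output-layer shapes")

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]

    @property
    def n_weights(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def with_flat(self, w: np.ndarray) -> "NetworkWeights":
        nh, no = self.n_hidden, self.n_out
        i0, i1, i2 = nh, 2 * nh, 2 * nh + no * nh
        return NetworkWeights(
            W1=w[:i0].reshape(nh, 1),
            b1=w[i0:i1].copy(),
            W2=w[i1:i2].reshape(no, nh),
            b2=w[i2:].copy(),
            input_scale=self.input_scale,
            input_shift=self.input_shift,
        )

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "input_scale": self.input_scale,
            "input_shift": self.input_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkWeights":
        return cls(
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=np.array(d["b2"]),
            input_scale=float(d.get("input_scale", 1.0)),
            input_shift=float(d.get("input_shift", 0.0)),
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test index sets covering 0..n-1 exactly once."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        n = len(all_idx)
        if not np.array_equal(np.sort(all_idx), np.arange(n)):
            raise ValueError("split index sets must partition 0..n-1")


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt schedule and stopping rules.

    mu is the LM damping: each accepted step multiplies it by ``mu_dec``
    (toward Gauss-Newton), each rejected trial by ``mu_inc`` (toward
    gradient descent).  Training stops when the sum-of-squares gradient
    norm falls below ``grad_tol``, mu exceeds ``mu_max``, ``max_epochs``
    accepted steps have been taken, or the validation MSE has increased
    for ``max_val_fails`` consecutive epochs.
    """

    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    max_epochs: int = 1000
    grad_tol: float = 1e-7
    max_val_fails: int = 6
    seed: int = 0
    restarts: int = 1
    n_hidden: int = 10
    damping: str = "marquardt"

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if not self.mu_inc > 1.0 > self.mu_dec > 0.0:
            raise ValueError("require mu_inc > 1 > mu_dec > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.damping not in ("marquardt", "identity"):
            raise ValueError("damping must be 'marquardt' or 'identity'")


@dataclass
class FitReport:
    """Per-epoch training record plus the returned (best-validation) weights."""

    epochs: list[int] = field(default_factory=list)
    mse_train: list[float] = field(default_factory=list)
    mse_validation: list[float] = field(default_factory=list)
    mse_test: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = 0
    seed: int = 0
    weights: NetworkWeights | None = None

    @property
    def final_mse_validation(self) -> float:
        return self.mse_validation[self.best_epoch]

    @property
    def final_mse_train(self) -> float:
        return self.mse_train[self.best_epoch]

    @property
    def final_mse_test(self) -> float:
        return self.mse_test[self.best_epoch]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "epochs": self.epochs,
            "mse_train": self.mse_train,
            "mse_validation": self.mse_validation,
            "mse_test": self.mse_test,
            "grad_norm": self.grad_norm,
            "mu": self.mu,
            "stop_reason": self.stop_reason,
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "weights": self.weights.to_dict() if self.weights is not None else None,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FitReport":
        try:
            p = Path(str(text_or_path))
            text = p.read_text() if p.exists() else str(text_or_path)
        except OSError:  # raw JSON string longer than a legal path
            text = str(text_or_path)
        d = json.loads(text)
        weights = NetworkWeights.from_dict(d["weights"]) if d.get("weights") else None
        return cls(
            epochs=d["epochs"], mse_train=d["mse_train"],
            mse_validation=d["mse_validation"], mse_test=d["mse_test"],
            grad_norm=d["grad_norm"], mu=d["mu"], stop_reason=d["stop_reason"],
            best_epoch=d["best_epoch"], seed=d["seed"], weights=weights,
        )


def split_indices(
    n: int,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitIndices:
    """Seeded random 80/10/10 (by default) partition of 0..n-1.

    Validation and test sizes are round(f * n); the remainder goes to
    training.  Deterministic given (n, fractions, seed).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive proportions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) == 0:
        raise ValueError(f"split of n={n} with fractions {fractions} yields an empty subset")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
    )


def init_network(
    n_hidden: int = 10,
    seed: int = 0,
    n_out: int = 3,
    t_range: tuple[float, float] = (0.0, 1.0),
) -> NetworkWeights:
    """Seeded Nguyen-Widrow initialization of the 1-input network.

    Input-layer weights take the full Nguyen-Widrow magnitude
    0.7 * n_hidden^(1/n_inputs) (n_inputs = 1) with seeded random signs,
    and the hidden biases are spread so the units' active regions tile
    the normalized input interval [-1, 1], with a small seeded jitter so
    restarts explore different bases.  Output-layer weights and biases
    are seeded uniform(-1, 1).  Deterministic per seed.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 0.7 * float(n_hidden)  # 0.7 * n_hidden^(1/1)
    t0, t1 = t_range
    if t1 <= t0:
        raise ValueError("t_range must be increasing")
    signs = np.where(rng.uniform(-1, 1, size=(n_hidden, 1)) >= 0, 1.0, -1.0)
    W1 = scale * signs
    if n_hidden > 1:
        centers = np.linspace(-1.0, 1.0, n_hidden)
    else:
        centers = np.zeros(1)
    centers = centers + rng.uniform(-0.05, 0.05, size=n_hidden)
    b1 = -W1[:, 0] * centers  # unit i centered where W1*x + b1 crosses zero
    return NetworkWeights(
        W1=W1,
        b1=b1,
        W2=rng.uniform(-1, 1, size=(n_out, n_hidden)),
        b2=rng.uniform(-1, 1, size=n_out),
        input_scale=2.0 / (t1 - t0),
        input_shift=-(t1 + t0) / (t1 - t0),
    )


def _normalize(net: NetworkWeights, tau: np.ndarray) -> np.ndarray:
    return net.input_scale * tau + net.input_shift


def forward(net: NetworkWeights, tau: float | np.ndarray) -> np.ndarray:
    """Network outputs for scalar or batched tau; shape (n_batch, n_out)."""
    if not all(np.all(np.isfinite(a)) for a in (net.W1, net.b1, net.W2, net.b2)):
        raise ValueError("network weights contain non-finite values")
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    x = _normalize(net, tau)
    hidden = np.tanh(x[:, None] * net.W1[:, 0][None, :] + net.b1[None, :])
    return hidden @ net.W2.T + net.b2[None, :]


def jacobian(net: NetworkWeights, taus: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the stacked outputs w.r.t. the flattened weights.

    Row ordering matches ``forward(net, taus).ravel()`` (sample-major,
    output-minor); column ordering matches ``net.flatten()``
    (W1, b1, W2, b2).  Shape: (n_out * n_batch, n_weights).
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if taus.size == 0:
        raise ValueError("empty input batch")
    nb, nh, no = taus.size, net.n_hidden, net.n_out
    x = _normalize(net, taus)  # (nb,)
    z = x[:, None] * net.W1[:, 0][None, :] + net.b1[None, :]  # (nb, nh)
    hidden = np.tanh(z)
    dhid = 1.0 - hidden**2  # tanh'

    J = np.zeros((nb * no, net.n_weights))
    rows = np.arange(nb * no).reshape(nb, no)
    # d out_k / d W1_j = W2[k, j] * tanh'(z_j) * x ; d/d b1_j analogous with x -> 1
    dW1 = net.W2[None, :, :] * dhid[:, None, :] * x[:, None, None]  # (nb, no, nh)
    db1 = net.W2[None, :, :] * dhid[:, None, :]
    # d out_k / d W2_{k,j} = hidden_j ; d out_k / d b2_k = 1
    i0, i1, i2 = nh, 2 * nh, 2 * nh + no * nh
    J[rows.ravel(), :i0] = dW1.reshape(nb * no, nh)
    J[rows.ravel(), i0:i1] = db1.reshape(nb * no, nh)
    for k in range(no):
        J[rows[:, k], i1 + k * nh : i1 + (k + 1) * nh] = hidden
        J[rows[:, k], i2 + k] = 1.0
    return J


def _mse(net: NetworkWeights, tau: np.ndarray, y: np.ndarray) -> float:
    r = forward(net, tau) - y
    return float(np.mean(r**2))


def _lm_single(
    tau: np.ndarray,
    y: np.ndarray,
    split: SplitIndices,
    cfg: TrainConfig,
    seed: int,
    n_out: int,
) -> FitReport:
    t_range = (float(tau.min()), float(tau.max()))
    net = init_network(cfg.n_hidden, seed=seed, n_out=n_out, t_range=t_range)
    tr, va, te = split.train, split.validation, split.test
    mu = cfg.mu0
    report = FitReport(seed=seed)

    def record(epoch: int, grad: float) -> None:
        report.epochs.append(epoch)
        report.mse_train.append(_mse(net, tau[tr], y[tr]))
        report.mse_validation.append(_mse(net, tau[va], y[va]))
        report.mse_test.append(_mse(net, tau[te], y[te]))
        report.grad_norm.append(grad)
        report.mu.append(mu)

    best_val = np.inf
    best_w = net.flatten()
    best_epoch = 0
    val_fails = 0
    stop = ""
    # epoch 0: untrained network baseline
    J = jacobian(net, tau[tr])
    r = (forward(net, tau[tr]) - y[tr]).ravel()
    grad = 2.0 * float(np.linalg.norm(J.T @ r))
    record(0, grad)
    best_val = report.mse_validation[0]

    n_res = r.size
    epoch = 0
    while not stop:
        if grad < cfg.grad_tol:
            stop = "gradient"
            break
        if epoch >= cfg.max_epochs:
            stop = "max_epochs"
            break
        sse = float(r @ r)
        JtJ = J.T @ J
        Jtr = J.T @ r
        if cfg.damping == "marquardt":
            # scaled damping: invariant under per-weight rescaling, much
            # better conditioned than mu*I when weight magnitudes spread
            D = np.diag(np.maximum(np.diag(JtJ), 1e-12))
        else:
            D = np.eye(JtJ.shape[0])
        accepted = False
        while mu <= cfg.mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * D, -Jtr)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            trial = net.with_flat(net.flatten() + step)
            r_trial = (forward(trial, tau[tr]) - y[tr]).ravel()
            if float(r_trial @ r_trial) < sse:
                net = trial
                r = r_trial
                mu = max(mu * cfg.mu_dec, np.finfo(float).tiny)
                accepted = True
                break
            mu *= cfg.mu_inc
        if not accepted:
            stop = "mu_max"
            break

        epoch += 1
        J = jacobian(net, tau[tr])
        grad = 2.0 * float(np.linalg.norm(J.T @ r))
        record(epoch, grad)

        val = report.mse_validation[-1]
        if val < best_val:
            best_val = val
            best_w = net.flatten()
            best_epoch = epoch
            val_fails = 0
        else:
            val_fails += 1
            if val_fails >= cfg.max_val_fails:
                stop = "validation"
                break

    report.stop_reason = stop
    report.best_epoch = best_epoch
    report.weights = net.with_flat(best_w)
    return report


def lm_train(
    targets: Trajectory,
    split: SplitIndices,
    cfg: TrainConfig,
    joint: bool = True,
) -> FitReport:
    """Fit the surrogate to a reference trajectory by Levenberg-Marquardt.

    Each epoch solves (J^T J + mu I) dw = -J^T r on the training subset,
    accepting the step (and relaxing mu) only if it lowers the training
    sum of squares, otherwise raising mu and retrying within the same
    epoch; so the accepted-step training MSE is strictly decreasing.
    Returns the weights of the best-validation epoch.  With
    ``cfg.restarts > 1``, training repeats from seeds cfg.seed,
    cfg.seed+1, ... and the report with the lowest best-validation MSE
    wins (ties go to the lowest seed).

    ``joint=False`` trains three independent single-output networks and
    stitches them into one block-diagonal report (per-epoch series come
    from the network with the worst validation MSE).
    """
    tau = targets.times
    y = np.asarray(targets.states, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("target trajectory contains non-finite values")
    n = len(tau)
    covered = np.sort(np.concatenate([split.train, split.validation, split.test]))
    if not np.array_equal(covered, np.arange(n)):
        raise ValueError("split does not match the trajectory length")

    n_out = y.shape[1]
    if joint:
        runs = [
            _lm_single(tau, y, split, cfg, seed=cfg.seed + i, n_out=n_out)
            for i in range(cfg.restarts)
        ]
        return min(runs, key=lambda rep: (rep.final_mse_validation, rep.seed))

    # per-output mode: independent nets, combined block-diagonally
    parts = []
    for k in range(n_out):
        runs = [
            _lm_single(tau, y[:, [k]], split, cfg, seed=cfg.seed + i, n_out=1)
            for i in range(cfg.restarts)
        ]
        parts.append(min(runs, key=lambda rep: (rep.final_mse_validation, rep.seed)))
    worst = max(parts, key=lambda rep: rep.final_mse_validation)
    combined = FitReport(
        epochs=worst.epochs, mse_train=worst.mse_train,
        mse_validation=worst.mse_validation, mse_test=worst.mse_test,
        grad_norm=worst.grad_norm, mu=worst.mu,
        stop_reason=worst.stop_reason, best_epoch=worst.best_epoch,
        seed=cfg.seed,
    )
    nets = [p.weights for p in parts]
    nh = cfg.n_hidden
    W1 = np.vstack([nw.W1 for nw in nets])
    b1 = np.concatenate([nw.b1 for nw in nets])
    W2 = np.zeros((n_out, n_out * nh))
    for k, nw in enumerate(nets):
        W2[k, k * nh : (k + 1) * nh] = nw.W2[0]
    b2 = np.array([nw.b2[0] for nw in nets])
    combined.weights = NetworkWeights(
        W1=W1, b1=b1, W2=W2, b2=b2,
        input_scale=nets[0].input_scale, input_shift=nets[0].input_shift,
    )
    return combined
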