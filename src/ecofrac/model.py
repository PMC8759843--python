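"""Fractional eco-epidemiological prey-predator model.

Three interacting populations: susceptible prey S, infected prey I, and
a cooperatively hunting predator P.  The Caputo fractional derivative of
order ``alpha`` acts on each state, and the right-hand side is

    D^a S = r (S + I) - (a P + lam) P S - delta S I - mu S
    D^a I = delta S I - (a P + lam) P I - mu I
    D^a P = e (a P + lam) P (S + I) - m P

The factor ``(a P + lam) P`` is the hunting-cooperation functional
response: the per-prey attack rate ``lam`` is boosted in proportion to
the predator density, with cooperation strength ``a``.  Infection is
transmitted horizontally at rate ``delta`` and is not passed to
offspring, so births from both prey classes enter the susceptible
class — which is why the reproduction term is ``r (S + I)``.  ``mu`` is
the prey mortality, ``m`` the predator mortality, and ``e`` converts
consumed prey biomass into predator biomass.

All quantities are dimensionless densities and per-unit-time rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "CaseSpec",
    "rhs",
    "default_case",
    "RHS_VARIANTS",
]

#: Admissible right-hand-side readings of the reproduction term.
#: "grouped" (default) reads the birth term as r*(S+I); "literal" reads
#: it as r*I + S, the other arithmetically possible parse of the model's
#: flattened notation.  Everything else is identical between the two.
RHS_VARIANTS = ("grouped", "literal")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the prey-predator system.

    Parameters
    ----------
    r : prey reproduction rate.
    lam : baseline predator attack rate (lambda).
    a : hunting-cooperation coefficient.
    delta : infection transmission rate among prey.
    mu : prey natural mortality rate.
    e : prey-to-predator biomass conversion efficiency.
    m : predator mortality rate.
    """

    r: float = 1.5
    lam: float = 0.5
    a: float = 0.5
    delta: float = 0.5
    mu: float = 0.5
    e: float = 0.5
    m: float = 0.5

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"model parameter {name!r} is not finite: {value!r}")
        negatives = [k for k, v in asdict(self).items() if v < 0]
        if negatives:
            warnings.warn(
                "negative rate constants are biologically implausible: "
                + ", ".join(negatives),
                UserWarning,
                stacklevel=2,
            )

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class State:
    """Population densities (S, I, P) at one instant."""

    S: float
    I: float
    P: float

    def __post_init__(self) -> None:
        for name in ("S", "I", "P"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"state component {name!r} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.P], dtype=float)


def rhs(
    state: State | np.ndarray,
    params: ModelParams,
    variant: str = "grouped",
) -> np.ndarray:
    """Instantaneous rates (dS, dI, dP) at a given state.

    Pure function; accepts a :class:`State` or an array of shape (3,)
    (or (3, n) for a batch of states).  ``variant`` selects the reading
    of the reproduction term, see :data:`RHS_VARIANTS`.
    """
    if variant not in RHS_VARIANTS:
        raise ValueError(f"unknown rhs variant {variant!r}; expected one of {RHS_VARIANTS}")
    y = state.as_array() if isinstance(state, State) else np.asarray(state, dtype=float)
    if y.shape[0] != 3:
        raise ValueError(f"state must have 3 components, got shape {y.shape}")
    finite = np.isfinite(y.reshape(3, -1)).all(axis=1)
    if not finite.all():
        bad = ("S", "I", "P")[int(np.argmax(~finite))]
        raise ValueError(f"state component {bad!r} is not finite")
    S, I, P = y[0], y[1], y[2]
    hunt = (params.a * P + params.lam) * P  # cooperation-boosted attack pressure
    birth = params.r * (S + I) if variant == "grouped" else params.r * I + S
    dS = birth - hunt * S - params.delta * S * I - params.mu * S
    dI = params.delta * S * I - hunt * I - params.mu * I
    dP = params.e * hunt * (S + I) - params.m * P
    return np.stack([dS, dI, dP])


@dataclass(frozen=True)
class CaseSpec:
    """A complete, solvable configuration of the model.

    Couples the rate constants, the initial densities ``y0``, the
    fractional order ``alpha`` in (0, 1], and a uniform time grid from 0
    to ``t_end`` with step ``h`` (``t_end / h`` must be integral).
    """

    params: ModelParams = field(default_factory=ModelParams)
    y0: State = field(default_factory=lambda: State(0.2, 0.7, 0.6))
    alpha: float = 0.5
    t_end: float = 1.0
    h: float = 0.01
    rhs_variant: str = "grouped"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"fractional order alpha must lie in (0, 1], got {self.alpha}")
        if self.h <= 0:
            raise ValueError(f"step size h must be positive, got {self.h}")
        n = self.t_end / self.h
        if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
            raise ValueError(f"t_end/h = {n} is not an integer number of steps")
        if self.rhs_variant not in RHS_VARIANTS:
            raise ValueError(f"unknown rhs variant {self.rhs_variant!r}")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.h)

    def to_config(self) -> dict[str, float | str]:
        """Flat key-value form (keys r, lam, a, delta, mu, e, m, k1, k2, k3, alpha, t_end, h)."""
        cfg: dict[str, float | str] = dict(self.params.as_dict())
        cfg.update(
            k1=self.y0.S,
            k2=self.y0.I,
            k3=self.y0.P,
            alpha=self.alpha,
            t_end=self.t_end,
            h=self.h,
        )
        if self.rhs_variant != "grouped":
            cfg["rhs_variant"] = self.rhs_variant
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping[str, float | str]) -> "CaseSpec":
        cfg = dict(cfg)
        variant = str(cfg.pop("rhs_variant", "grouped"))
        y0 = State(float(cfg.pop("k1")), float(cfg.pop("k2")), float(cfg.pop("k3")))
        alpha = float(cfg.pop("alpha"))
        t_end = float(cfg.pop("t_end"))
        h = float(cfg.pop("h"))
        params = ModelParams(**{k: float(v) for k, v in cfg.items()})
        return cls(params=params, y0=y0, alpha=alpha, t_end=t_end, h=h, rhs_variant=variant)


def default_case(alpha: float) -> CaseSpec:
    """The published study configuration at a given fractional order.

    All rates 0.5 except the reproduction rate r = 1.5, initial
    densities (0.2, 0.7, 0.6), integrated over [0, 1] with step 0.01
    (101 grid points).  The study's three cases use alpha = 0.5, 0.7
    and 0.9; any alpha in (0, 1] is accepted.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order alpha must lie in (0, 1], got {alpha}")
    return CaseSpec(alpha=alpha)
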