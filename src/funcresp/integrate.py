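"""Fixed-step RK4 integration of the consumption-learning dynamics.

Two experimental settings are supported:

* **Fixed density (Holling)** — the arena is continually restocked, so prey
  density ``D`` stays constant and cumulative consumption ``N`` obeys

      dN/dt = a(N) D / (1 + a(N) h(N) D).

* **Depletion (Rogers)** — prey form a fixed pool ``N0`` removed without
  replacement; the state is the remaining prey ``Na`` with

      dNa/dt = -a(N) Na / (1 + a(N) h(N) Na),    N = N0 - Na.

``a(N)`` and ``h(N)`` are the closed-form learning curves, substituted
directly into a scalar ODE (the default formulation).  A coupled formulation
that integrates ``a`` and ``h`` as extra state variables via
``da/dN = la (am - a)`` and ``dh/dN = -lh (h - hm)`` is provided as an
independent cross-check; the two agree to well below 1e-6 in final
consumption.

Integration uses classical fourth-order Runge-Kutta with a fixed step
(default 1/1024 of a time unit) over an experiment of fixed length (default
one time unit); the learning curves are re-evaluated at every internal RK
stage.  There is no randomness anywhere: results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .curve import ResponseCurve
from .errors import NumericalError, ParameterError
from .learning import PredatorParams, attack_rate, handling_time

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate_fixed_density",
    "simulate_depletion",
    "response_curve",
]

#: tolerance below zero allowed for the remaining-prey state before the
#: integration is declared failed (within it, the state is clamped to 0)
_DEPLETION_TOL = 1e-9

Formulation = Literal["substitution", "coupled"]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for one simulated feeding experiment.

    Parameters
    ----------
    t_max : float
        Experiment length in time units (default 1).
    dt : float
        RK4 step in time units (default 1/1024).  ``t_max`` must be an
        integer multiple of ``dt`` (to 1e-12 relative): the last step is
        never fractional.
    depletion : bool
        Prey removed without replacement (Rogers) versus constant density
        (Holling).
    """

    t_max: float = 1.0
    dt: float = 1.0 / 1024.0
    depletion: bool = False

    def __post_init__(self) -> None:
        if not (self.t_max > 0):
            raise ParameterError(f"t_max must be positive, got {self.t_max}")
        if not (0 < self.dt <= self.t_max):
            raise ParameterError(
                f"dt must satisfy 0 < dt <= t_max, got dt={self.dt}"
            )
        ratio = self.t_max / self.dt
        if abs(ratio - round(ratio)) > 1e-12 * ratio:
            raise ParameterError(
                f"t_max={self.t_max} is not an integer number of steps of "
                f"dt={self.dt}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))


@dataclass
class Trajectory:
    """Time course of one simulated experiment, sampled at every RK4 step.

    ``n_available`` is populated only in the depletion setting, where it
    equals ``N0 - n_consumed``.
    """

    t: np.ndarray
    n_consumed: np.ndarray
    attack: np.ndarray
    handling: np.ndarray
    n_available: np.ndarray | None = None

    @property
    def final_consumed(self) -> float:
        return float(self.n_consumed[-1])


def _unpack(p: PredatorParams):
    a = p.attack
    h = p.handling
    return a.a0, a.am, a.la, h.h0, h.hm, h.lh


def _rk4_consumed(
    a0, am, la, h0, hm, lh, offered, t_max: float, n_steps: int, depletion: bool
) -> np.ndarray:
    """Vectorised RK4 over broadcastable parameter/offered arrays.

    Returns total consumed prey with the broadcast shape of the inputs.
    Parameter arrays let many simulations (sweep cells x offered values)
    advance in lock-step, which is what makes large sweeps affordable.
    """
    offered = np.asarray(offered, dtype=float)
    shape = np.broadcast_shapes(
        *(np.shape(x) for x in (a0, am, la, h0, hm, lh, offered))
    )
    dt = t_max / n_steps
    # skip the exp() when nothing can change: rate or amplitude zero everywhere
    attack_learns = bool(np.any(np.asarray(la) * (np.asarray(am) - np.asarray(a0)) != 0.0))
    handling_learns = bool(np.any(np.asarray(lh) * (np.asarray(h0) - np.asarray(hm)) != 0.0))

    if depletion:
        n0 = np.broadcast_to(offered, shape).astype(float)
        y = n0.copy()  # remaining prey Na
    else:
        n0 = None
        y = np.zeros(shape)  # cumulative consumption N

    def rhs(state):
        if depletion:
            na = np.maximum(state, 0.0)
            n = n0 - na
        else:
            n = state
        a = am - (am - a0) * np.exp(-la * n) if attack_learns else a0
        h = hm + (h0 - hm) * np.exp(-lh * n) if handling_learns else h0
        if depletion:
            return -(a * na) / (1.0 + a * h * na)
        return (a * offered) / (1.0 + a * h * offered)

    half = 0.5 * dt
    sixth = dt / 6.0
    for step in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + half * k1)
        k3 = rhs(y + half * k2)
        k4 = rhs(y + dt * k3)
        y = y + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        if not np.all(np.isfinite(y)):
            raise NumericalError(f"non-finite state at step {step + 1}")
        if depletion:
            if np.any(y < -_DEPLETION_TOL):
                raise NumericalError(
                    f"remaining prey fell below zero at step {step + 1}"
                )
            np.clip(y, 0.0, None, out=y)

    return (n0 - y) if depletion else y


def _rk4_trajectory_substitution(
    p: PredatorParams, offered: float, cfg: SimulationConfig
) -> Trajectory:
    a0, am, la, h0, hm, lh = _unpack(p)
    n_steps = cfg.n_steps
    dt = cfg.dt
    depletion = cfg.depletion
    n0 = float(offered)

    def rhs(n):
        a = am - (am - a0) * np.exp(-la * n)
        h = hm + (h0 - hm) * np.exp(-lh * n)
        if depletion:
            na = max(n0 - n, 0.0)
            return a * na / (1.0 + a * h * na)
        return a * n0 / (1.0 + a * h * n0)

    n = 0.0
    consumed = np.empty(n_steps + 1)
    consumed[0] = 0.0
    for step in range(n_steps):
        k1 = rhs(n)
        k2 = rhs(n + 0.5 * dt * k1)
        k3 = rhs(n + 0.5 * dt * k2)
        k4 = rhs(n + dt * k3)
        n = n + dt / 6.0 * (k1 + 2.0 * (k2 + k3) + k4)
        if not np.isfinite(n):
            raise NumericalError(f"non-finite state at step {step + 1}")
        if depletion:
            if n - n0 > _DEPLETION_TOL:
                raise NumericalError(
                    f"remaining prey fell below zero at step {step + 1}"
                )
            n = min(n, n0)
        consumed[step + 1] = n

    t = np.linspace(0.0, cfg.t_max, n_steps + 1)
    return Trajectory(
        t=t,
        n_consumed=consumed,
        attack=attack_rate(p.attack, consumed),
        handling=handling_time(p.handling, consumed),
        n_available=(n0 - consumed) if depletion else None,
    )


def _rk4_trajectory_coupled(
    p: PredatorParams, offered: float, cfg: SimulationConfig
) -> Trajectory:
    """Cross-check formulation: (N, a, h) integrated as a coupled system.

    The learning ODEs da/dN = la (am - a) and dh/dN = -lh (h - hm) are
    chain-ruled through dN/dt, so a and h become state variables instead of
    closed-form substitutions.
    """
    a0, am, la, h0, hm, lh = _unpack(p)
    n_steps = cfg.n_steps
    dt = cfg.dt
    depletion = cfg.depletion
    n0 = float(offered)

    def rhs(state):
        n, a, h = state
        if depletion:
            na = max(n0 - n, 0.0)
            dn = a * na / (1.0 + a * h * na)
        else:
            dn = a * n0 / (1.0 + a * h * n0)
        return np.array([dn, la * (am - a) * dn, -lh * (h - hm) * dn])

    state = np.array([0.0, a0, h0])
    n_hist = np.empty(n_steps + 1)
    a_hist = np.empty(n_steps + 1)
    h_hist = np.empty(n_steps + 1)
    n_hist[0], a_hist[0], h_hist[0] = state
    for step in range(n_steps):
        k1 = rhs(state)
        k2 = rhs(state + 0.5 * dt * k1)
        k3 = rhs(state + 0.5 * dt * k2)
        k4 = rhs(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2.0 * (k2 + k3) + k4)
        if not np.all(np.isfinite(state)):
            raise NumericalError(f"non-finite state at step {step + 1}")
        if depletion and state[0] - n0 > _DEPLETION_TOL:
            raise NumericalError(
                f"remaining prey fell below zero at step {step + 1}"
            )
        n_hist[step + 1], a_hist[step + 1], h_hist[step + 1] = state

    t = np.linspace(0.0, cfg.t_max, n_steps + 1)
    return Trajectory(
        t=t,
        n_consumed=n_hist,
        attack=a_hist,
        handling=h_hist,
        n_available=(n0 - n_hist) if depletion else None,
    )


def _simulate(
    p: PredatorParams,
    offered: float,
    cfg: SimulationConfig,
    formulation: Formulation,
) -> Trajectory:
    if formulation == "substitution":
        return _rk4_trajectory_substitution(p, offered, cfg)
    if formulation == "coupled":
        return _rk4_trajectory_coupled(p, offered, cfg)
    raise ParameterError(f"unknown formulation {formulation!r}")


def simulate_fixed_density(
    p: PredatorParams,
    density: float,
    cfg: SimulationConfig | None = None,
    formulation: Formulation = "substitution",
) -> Trajectory:
    """Simulate one constant-density (Holling) feeding experiment.

    Returns the full trajectory; ``trajectory.final_consumed`` is the
    headline output (total prey consumed over the experiment).
    """
    cfg = cfg or SimulationConfig()
    if cfg.depletion:
        raise ParameterError("fixed-density simulation requires depletion=False")
    if density < 0:
        raise ParameterError("density must be nonnegative")
    return _simulate(p, density, cfg, formulation)


def simulate_depletion(
    p: PredatorParams,
    n0: float,
    cfg: SimulationConfig | None = None,
    formulation: Formulation = "substitution",
) -> Trajectory:
    """Simulate one prey-depletion (Rogers) experiment from an initial pool."""
    cfg = cfg or SimulationConfig(depletion=True)
    if not cfg.depletion:
        raise ParameterError("depletion simulation requires depletion=True")
    if n0 < 0:
        raise ParameterError("initial prey count must be nonnegative")
    return _simulate(p, n0, cfg, formulation)


def response_curve(
    p: PredatorParams,
    offered: np.ndarray,
    cfg: SimulationConfig | None = None,
) -> ResponseCurve:
    """Simulate one experiment per offered-prey value and collect the curve.

    ``offered`` must be a strictly increasing, uniformly spaced grid of at
    least 7 values (required by the downstream finite-difference scheme).
    Each offered value is an independent experiment; all of them are advanced
    in one vectorised RK4 pass.
    """
    cfg = cfg or SimulationConfig()
    offered = np.asarray(offered, dtype=float)
    if offered.ndim != 1:
        raise ParameterError("offered must be a 1-D grid")
    if np.any(offered < 0):
        raise ParameterError("offered values must be nonnegative")
    a0, am, la, h0, hm, lh = _unpack(p)
    consumed = _rk4_consumed(
        a0, am, la, h0, hm, lh, offered, cfg.t_max, cfg.n_steps, cfg.depletion
    )
    # RK4 round-off can leave consumption a hair below zero at offered = 0
    consumed = np.maximum(consumed, 0.0)
    return ResponseCurve(offered=offered, consumed=consumed, depletion=cfg.depletion)
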