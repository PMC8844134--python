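"""Exponential learning curves for attack rate and handling time.

A predator's per-capita attack rate ``a`` and handling time ``h`` are allowed
to improve with experience, measured as the cumulative number of consumed prey
``N``.  Both follow exponential learning curves toward an asymptote:

    a(N) = a_m - (a_m - a0) * exp(-l_a * N)      (monotone increasing)
    h(N) = h_m + (h0 - h_m) * exp(-l_h * N)      (monotone decreasing)

``l_a`` and ``l_h`` are per-consumed-prey learning rates; the distances
``a_m - a0`` and ``h0 - h_m`` between the initial and asymptotic values are
called learning amplitudes.  When a learning rate or an amplitude is zero the
corresponding parameter is constant and the intake reduces to the classical
type-II disk equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "AttackLearningParams",
    "HandlingLearningParams",
    "PredatorParams",
    "attack_rate",
    "handling_time",
    "intake_rate",
    "learning_amplitudes",
]


@dataclass(frozen=True)
class AttackLearningParams:
    """Learning-curve parameters for the attack rate.

    Parameters
    ----------
    a0 : float
        Initial (naive) attack rate, per time per unit prey density.
    am : float
        Asymptotic (fully learned) attack rate; ``0 < a0 <= am <= 1``.
    la : float
        Learning rate per consumed prey, in ``[0, 1]``.
    """

    a0: float
    am: float
    la: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a0 <= 1.0):
            raise ParameterError(f"a0 must be in (0, 1], got {self.a0}")
        if not (self.a0 <= self.am <= 1.0):
            raise ParameterError(
                f"am must satisfy a0 <= am <= 1, got a0={self.a0}, am={self.am}"
            )
        if not (0.0 <= self.la <= 1.0):
            raise ParameterError(f"la must be in [0, 1], got {self.la}")

    @property
    def amplitude(self) -> float:
        """Learning amplitude ``am - a0`` (how much can be learned)."""
        return self.am - self.a0


@dataclass(frozen=True)
class HandlingLearningParams:
    """Learning-curve parameters for the handling time.

    Parameters
    ----------
    h0 : float
        Initial (naive) handling time, time per prey.
    hm : float
        Minimum (fully learned) handling time; ``0 <= hm <= h0``.
    lh : float
        Learning rate per consumed prey, in ``[0, 1]``.
    """

    h0: float
    hm: float
    lh: float

    def __post_init__(self) -> None:
        if self.h0 < 0.0:
            raise ParameterError(f"h0 must be >= 0, got {self.h0}")
        if not (0.0 <= self.hm <= self.h0):
            raise ParameterError(
                f"hm must satisfy 0 <= hm <= h0, got h0={self.h0}, hm={self.hm}"
            )
        if not (0.0 <= self.lh <= 1.0):
            raise ParameterError(f"lh must be in [0, 1], got {self.lh}")

    @property
    def amplitude(self) -> float:
        """Learning amplitude ``h0 - hm``."""
        return self.h0 - self.hm


@dataclass(frozen=True)
class PredatorParams:
    """Full predator description: attack-rate and handling-time learning curves."""

    attack: AttackLearningParams
    handling: HandlingLearningParams

    @classmethod
    def from_values(
        cls,
        a0: float,
        am: float,
        la: float,
        h0: float,
        hm: float,
        lh: float,
    ) -> "PredatorParams":
        return cls(
            attack=AttackLearningParams(a0=a0, am=am, la=la),
            handling=HandlingLearningParams(h0=h0, hm=hm, lh=lh),
        )

    @classmethod
    def no_learning(cls, a: float, h: float) -> "PredatorParams":
        """Constant attack rate and handling time (plain disk equation)."""
        return cls.from_values(a0=a, am=a, la=0.0, h0=h, hm=h, lh=0.0)


def _check_nonneg_experience(n_consumed) -> np.ndarray:
    n = np.asarray(n_consumed, dtype=float)
    if np.any(n < 0.0):
        raise ParameterError("n_consumed must be nonnegative")
    return n


def attack_rate(p: AttackLearningParams, n_consumed):
    """Attack rate after ``n_consumed`` prey have been consumed.

    Evaluates ``a(N) = am - (am - a0) exp(-la N)``; accepts scalars or arrays.
    """
    n = _check_nonneg_experience(n_consumed)
    if p.la == 0.0 or p.am == p.a0:  # no learning: exactly constant
        out = np.full_like(n, p.a0)
    else:
        out = p.am - (p.am - p.a0) * np.exp(-p.la * n)
    return out if out.ndim else float(out)


def handling_time(p: HandlingLearningParams, n_consumed):
    """Handling time after ``n_consumed`` prey have been consumed.

    Evaluates ``h(N) = hm + (h0 - hm) exp(-lh N)``; accepts scalars or arrays.
    """
    n = _check_nonneg_experience(n_consumed)
    if p.lh == 0.0 or p.h0 == p.hm:  # no learning: exactly constant
        out = np.full_like(n, p.h0)
    else:
        out = p.hm + (p.h0 - p.hm) * np.exp(-p.lh * n)
    return out if out.ndim else float(out)


def intake_rate(a, h, density):
    """Instantaneous disk-equation intake rate ``a D / (1 + a h D)``.

    The rate saturates at ``1/h`` for ``h > 0`` and is linear in ``D`` for
    ``h = 0`` (type-I limit).
    """
    a = np.asarray(a, dtype=float)
    h = np.asarray(h, dtype=float)
    d = np.asarray(density, dtype=float)
    if np.any(a <= 0.0):
        raise ParameterError("attack rate must be positive")
    if np.any(h < 0.0):
        raise ParameterError("handling time must be nonnegative")
    if np.any(d < 0.0):
        raise ParameterError("prey density must be nonnegative")
    out = a * d / (1.0 + a * h * d)
    return out if out.ndim else float(out)


def learning_amplitudes(p: PredatorParams) -> tuple[float, float]:
    """Return ``(delta_a, delta_h)``; both zero means no learning at all."""
    return (p.attack.amplitude, p.handling.amplitude)
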