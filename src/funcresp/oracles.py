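"""Closed-form reference solutions for the no-learning limits.

With constant attack rate and handling time the dynamics admit analytic
solutions: the Holling disk equation in the constant-density setting, and the
Rogers random-predator implicit equation in the depletion setting.  These are
used throughout the test suite to validate the RK4 integrator.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

from .errors import NumericalError, ParameterError

__all__ = ["holling_closed_form", "rogers_closed_form"]


def _check_common(a: float, h: float, t: float) -> None:
    if a <= 0:
        raise ParameterError("attack rate must be positive")
    if h < 0:
        raise ParameterError("handling time must be nonnegative")
    if t <= 0:
        raise ParameterError("experiment length must be positive")


def holling_closed_form(a: float, h: float, density: float, t: float = 1.0) -> float:
    """Consumed prey at constant density: ``N = a D T / (1 + a h D)``."""
    _check_common(a, h, t)
    if density < 0:
        raise ParameterError("prey density must be nonnegative")
    return a * density * t / (1.0 + a * h * density)


def rogers_closed_form(
    a: float,
    h: float,
    n0: float,
    t: float = 1.0,
    method: str = "brentq",
) -> float:
    """Consumed prey under depletion: root of ``N = N0 (1 - exp(-a(T - hN)))``.

    The implicit random-predator equation follows from separating
    ``dNa/dt = -a Na / (1 + a h Na)``.  For ``h = 0`` the exponential
    depletion closed form ``N0 (1 - exp(-aT))`` is returned directly.

    ``method`` selects the solver: ``"brentq"`` (bracketed root finding on
    [0, N0], the default) or ``"lambertw"`` (the Lambert-W closed form);
    the two agree to better than 1e-10 and exist as mutual cross-checks.
    """
    _check_common(a, h, t)
    if n0 < 0:
        raise ParameterError("initial prey count must be nonnegative")
    if n0 == 0:
        return 0.0
    if h == 0:
        return n0 * (1.0 - np.exp(-a * t))

    if method == "lambertw":
        # N = N0 - W(a h N0 exp(-a (T - h N0))) / (a h)
        arg = a * h * n0 * np.exp(-a * (t - h * n0))
        w = lambertw(arg)
        if abs(w.imag) > 1e-12:
            raise NumericalError("Lambert-W returned a complex value")
        return float(n0 - w.real / (a * h))
    if method != "brentq":
        raise ParameterError(f"unknown method {method!r}")

    def f(n: float) -> float:
        return n - n0 * (1.0 - np.exp(-a * (t - h * n)))

    # f(0) < 0 and f(N0) = N0 exp(-a(T - h N0)) > 0: the root is bracketed
    try:
        root = brentq(f, 0.0, n0, xtol=1e-14, rtol=1e-15, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - bracketing holds
        raise NumericalError(f"root finding failed: {exc}") from exc
    if abs(f(root)) > 1e-12 * max(1.0, n0):
        raise NumericalError("implicit-equation residual too large")
    return float(root)
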