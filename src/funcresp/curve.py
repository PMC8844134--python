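"""The response-curve container: consumed prey versus offered prey.

A functional-response curve tabulates, for each offered prey level (constant
density in the Holling setting, initial pool size in the Rogers depletion
setting), the total prey consumed over one experiment.  The downstream
finite-difference machinery requires a uniform offered grid, so uniformity is
validated here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["ResponseCurve", "offered_grid"]

#: minimum number of grid points needed for interior second differences plus
#: a persistence window on each side
MIN_CURVE_LENGTH = 7

_UNIFORMITY_RTOL = 1e-9


def offered_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Uniform offered-prey grid including both endpoints.

    ``stop - start`` must be an integer multiple of ``step`` (to 1e-9
    relative); the grid is built with ``linspace`` so spacing is exact to
    rounding.
    """
    if step <= 0 or stop <= start:
        raise ParameterError("offered grid requires step > 0 and stop > start")
    n_intervals = (stop - start) / step
    if abs(n_intervals - round(n_intervals)) > 1e-9 * max(1.0, n_intervals):
        raise ParameterError(
            f"grid span {stop - start} is not an integer multiple of step {step}"
        )
    return np.linspace(start, stop, int(round(n_intervals)) + 1)


def _validate_uniform(offered: np.ndarray) -> float:
    diffs = np.diff(offered)
    if np.any(diffs <= 0):
        raise ParameterError("offered grid must be strictly increasing")
    spacing = float(diffs.mean())
    if np.max(np.abs(diffs - spacing)) > _UNIFORMITY_RTOL * spacing:
        raise ParameterError("offered grid must be uniformly spaced")
    return spacing


@dataclass
class ResponseCurve:
    """Consumed prey as a function of offered prey on a uniform grid.

    Attributes
    ----------
    offered : ndarray
        Strictly increasing, uniformly spaced prey densities (or initial
        prey counts when ``depletion`` is set).
    consumed : ndarray
        Total consumed prey per trial, aligned with ``offered``.
    depletion : bool
        Whether the curve came from the prey-depletion (Rogers) setting;
        used for labelling only.
    """

    offered: np.ndarray
    consumed: np.ndarray
    depletion: bool = False
    spacing: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.offered = np.asarray(self.offered, dtype=float)
        self.consumed = np.asarray(self.consumed, dtype=float)
        if self.offered.ndim != 1 or self.consumed.ndim != 1:
            raise ParameterError("offered and consumed must be 1-D arrays")
        if self.offered.size != self.consumed.size:
            raise ParameterError("offered and consumed must have equal length")
        if self.offered.size < MIN_CURVE_LENGTH:
            raise ParameterError(
                f"curve needs at least {MIN_CURVE_LENGTH} points, "
                f"got {self.offered.size}"
            )
        if not np.all(np.isfinite(self.offered)) or not np.all(
            np.isfinite(self.consumed)
        ):
            raise ParameterError("curve values must be finite")
        if np.any(self.consumed < 0):
            raise ParameterError("consumed values must be nonnegative")
        self.spacing = _validate_uniform(self.offered)

    def __len__(self) -> int:
        return int(self.offered.size)
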