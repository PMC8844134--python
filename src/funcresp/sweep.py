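"""Two-parameter sweeps mapping functional-response shape regions.

The model is explored along two one-parameter-pair experiments: an
attack-learning sweep over (a0, la) with handling fixed (h constant, no
handling learning), and a handling-learning sweep over (hm, lh) with the
attack rate fixed (no attack learning, h starting from 1).  Every grid cell
simulates a full response curve, diagnoses its shape, and records the
inflection location and the curvature maxima; the result maps out which
regions of learning-parameter space yield type I, II, or III responses.

Cells are independent, deterministic simulations; they are advanced in
vectorised chunks purely for speed, with results identical to sequential
evaluation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .curve import ResponseCurve, offered_grid
from .errors import NumericalError, ParameterError
from .integrate import SimulationConfig, _rk4_consumed
from .learning import PredatorParams
from .shape import (
    ClassificationThresholds,
    ShapeType,
    classify,
    finite_differences,
)

__all__ = [
    "GridSpec",
    "SweepResult",
    "sweep_attack_learning",
    "sweep_handling_learning",
    "threshold_scan",
]

#: offered grid used by default in sweeps — coarser than the per-curve
#: default (step 0.5 instead of 0.01) because classification is stable to
#: the offered step away from region boundaries
DEFAULT_SWEEP_OFFERED = (1.0, 200.0, 0.5)

_CHUNK_CELLS = 128


@dataclass(frozen=True)
class GridSpec:
    """A uniformly spaced, endpoint-inclusive axis of a parameter sweep."""

    name: str
    start: float
    stop: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ParameterError("grid count must be >= 1")
        if self.count == 1:
            if self.start != self.stop:
                raise ParameterError("count=1 requires start == stop")
        elif not (self.start < self.stop):
            raise ParameterError(
                f"grid {self.name}: start must be < stop, "
                f"got [{self.start}, {self.stop}]"
            )

    @property
    def values(self) -> np.ndarray:
        if self.count == 1:
            return np.array([self.start])
        return np.linspace(self.start, self.stop, self.count)


@dataclass
class SweepResult:
    """Per-cell shape diagnostics over a 2-D parameter grid.

    All cell arrays have shape ``(len(y_values), len(x_values))`` (rows vary
    the y parameter).  ``inflection`` is NaN where no inflection exists.
    """

    x_name: str
    y_name: str
    x_values: np.ndarray
    y_values: np.ndarray
    shape: np.ndarray  # dtype=object, ShapeType per cell
    inflection: np.ndarray
    max_d2: np.ndarray
    max_normalized_d2: np.ndarray
    final_consumed: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.x_values.size * self.y_values.size)

    def shape_counts(self) -> dict[str, int]:
        flat = self.shape.ravel()
        return {
            s.value: int(sum(1 for v in flat if v is s)) for s in ShapeType
        }

    def to_dataframe(self) -> pd.DataFrame:
        ny, nx = self.shape.shape
        xx, yy = np.meshgrid(self.x_values, self.y_values)
        return pd.DataFrame(
            {
                "x_name": self.x_name,
                "y_name": self.y_name,
                "x": xx.ravel(),
                "y": yy.ravel(),
                "shape": [s.value for s in self.shape.ravel()],
                "inflection_offered": self.inflection.ravel(),
                "max_d2": self.max_d2.ravel(),
                "max_normalized_d2": self.max_normalized_d2.ravel(),
                "final_consumed": self.final_consumed.ravel(),
            }
        )


def _default_offered() -> np.ndarray:
    return offered_grid(*DEFAULT_SWEEP_OFFERED)


def _classify_cells(
    consumed: np.ndarray,
    offered: np.ndarray,
    depletion: bool,
    thresholds: ClassificationThresholds,
):
    """Classify each row of a (cells, offered) consumed matrix."""
    shapes, inflections, max_d2s, max_gs = [], [], [], []
    for row in consumed:
        curve = ResponseCurve(
            offered=offered, consumed=np.maximum(row, 0.0), depletion=depletion
        )
        res = classify(finite_differences(curve), thresholds)
        shapes.append(res.shape)
        inflections.append(
            np.nan if res.inflection_offered is None else res.inflection_offered
        )
        max_d2s.append(res.max_d2)
        max_gs.append(res.max_normalized_d2)
    return shapes, inflections, max_d2s, max_gs


def _run_sweep(
    x_grid: GridSpec,
    y_grid: GridSpec,
    cell_params: Callable[[np.ndarray, np.ndarray], tuple],
    cfg: SimulationConfig,
    offered: np.ndarray,
    thresholds: ClassificationThresholds,
    metadata: dict,
    progress: Callable[[str], None] | None = None,
) -> SweepResult:
    xs = x_grid.values
    ys = y_grid.values
    nx, ny = xs.size, ys.size
    shape_arr = np.empty((ny, nx), dtype=object)
    infl = np.full((ny, nx), np.nan)
    max_d2 = np.full((ny, nx), np.nan)
    max_g = np.full((ny, nx), np.nan)
    final = np.full((ny, nx), np.nan)

    t0 = time.perf_counter()
    for j, yval in enumerate(ys):
        # one grid row at a time, vectorised over x cells and offered values
        for lo in range(0, nx, _CHUNK_CELLS):
            hi = min(lo + _CHUNK_CELLS, nx)
            xchunk = xs[lo:hi]
            a0, am, la, h0, hm, lh = cell_params(
                xchunk[:, None], np.full((xchunk.size, 1), yval)
            )
            try:
                consumed = _rk4_consumed(
                    a0, am, la, h0, hm, lh,
                    offered[None, :], cfg.t_max, cfg.n_steps, cfg.depletion,
                )
            except NumericalError as exc:
                raise NumericalError(
                    f"sweep cell failed in block {x_grid.name}="
                    f"[{xchunk[0]:g}, {xchunk[-1]:g}], {y_grid.name}={yval:g}: {exc}"
                ) from exc
            shapes, infls, d2s, gs = _classify_cells(
                consumed, offered, cfg.depletion, thresholds
            )
            shape_arr[j, lo:hi] = shapes
            infl[j, lo:hi] = infls
            max_d2[j, lo:hi] = d2s
            max_g[j, lo:hi] = gs
            final[j, lo:hi] = consumed[:, -1]
        if progress is not None:
            progress(
                f"{y_grid.name}={yval:g} row {j + 1}/{ny} done "
                f"({time.perf_counter() - t0:.1f}s elapsed)"
            )

    meta = {
        "x_name": x_grid.name,
        "y_name": y_grid.name,
        "x_range": [float(xs[0]), float(xs[-1]), int(nx)],
        "y_range": [float(ys[0]), float(ys[-1]), int(ny)],
        "offered_start": float(offered[0]),
        "offered_stop": float(offered[-1]),
        "offered_step": float(offered[1] - offered[0]),
        "t_max": cfg.t_max,
        "dt": cfg.dt,
        "depletion": cfg.depletion,
        "eps_lin": thresholds.eps_lin,
        "eps_pos": thresholds.eps_pos,
        "persistence": thresholds.persistence,
        **metadata,
    }
    return SweepResult(
        x_name=x_grid.name,
        y_name=y_grid.name,
        x_values=xs,
        y_values=ys,
        shape=shape_arr,
        inflection=infl,
        max_d2=max_d2,
        max_normalized_d2=max_g,
        final_consumed=final,
        metadata=meta,
    )


def sweep_attack_learning(
    a0_grid: GridSpec,
    la_grid: GridSpec,
    fixed_h: float = 0.1,
    cfg: SimulationConfig | None = None,
    offered: np.ndarray | None = None,
    thresholds: ClassificationThresholds | None = None,
    progress: Callable[[str], None] | None = None,
) -> SweepResult:
    """Shape map over initial attack rate (x) and attack learning rate (y).

    Per cell: ``am = 1``, handling constant at ``fixed_h`` (no handling
    learning).  Defaults follow the study design: ``fixed_h = 0.1``, offered
    prey 1-200.
    """
    cfg = cfg or SimulationConfig()
    offered = _default_offered() if offered is None else np.asarray(offered, float)
    thresholds = thresholds or ClassificationThresholds()
    if fixed_h < 0:
        raise ParameterError("fixed_h must be nonnegative")
    # validate the parameter corners once up front
    for a0 in (a0_grid.values[0], a0_grid.values[-1]):
        for la in (la_grid.values[0], la_grid.values[-1]):
            PredatorParams.from_values(a0, 1.0, la, fixed_h, fixed_h, 0.0)

    def cell_params(a0, la):
        return a0, 1.0, la, fixed_h, fixed_h, 0.0

    return _run_sweep(
        a0_grid, la_grid, cell_params, cfg, offered, thresholds,
        {"sweep": "attack_learning", "fixed_h": fixed_h, "am": 1.0},
        progress,
    )


def sweep_handling_learning(
    hm_grid: GridSpec,
    lh_grid: GridSpec,
    fixed_a: float = 0.1,
    cfg: SimulationConfig | None = None,
    offered: np.ndarray | None = None,
    thresholds: ClassificationThresholds | None = None,
    progress: Callable[[str], None] | None = None,
) -> SweepResult:
    """Shape map over minimum handling time (x) and handling learning rate (y).

    Per cell: attack rate constant at ``fixed_a`` (no attack learning),
    handling starts from ``h0 = 1`` and learns down to ``hm``.  Defaults
    follow the study design: ``fixed_a = 0.1``.
    """
    cfg = cfg or SimulationConfig()
    offered = _default_offered() if offered is None else np.asarray(offered, float)
    thresholds = thresholds or ClassificationThresholds()
    if not (0 < fixed_a <= 1):
        raise ParameterError("fixed_a must be in (0, 1]")
    for hm in (hm_grid.values[0], hm_grid.values[-1]):
        for lh in (lh_grid.values[0], lh_grid.values[-1]):
            PredatorParams.from_values(fixed_a, fixed_a, 0.0, 1.0, hm, lh)

    def cell_params(hm, lh):
        return fixed_a, fixed_a, 0.0, 1.0, hm, lh

    return _run_sweep(
        hm_grid, lh_grid, cell_params, cfg, offered, thresholds,
        {"sweep": "handling_learning", "fixed_a": fixed_a, "h0": 1.0},
        progress,
    )


_VARIABLE_FIELDS = ("a0", "am", "la", "h0", "hm", "lh")


def threshold_scan(
    axis: GridSpec,
    base: PredatorParams,
    predicate: ShapeType,
    cfg: SimulationConfig | None = None,
    offered: np.ndarray | None = None,
    thresholds: ClassificationThresholds | None = None,
    largest: bool = False,
) -> float | None:
    """Boundary of a shape region along one parameter axis.

    Varies the parameter named by ``axis.name`` (one of a0/am/la/h0/hm/lh)
    over the grid with all other parameters taken from ``base``, classifies
    the response curve at each value, and returns the smallest (or, with
    ``largest=True``, the largest) axis value whose class equals
    ``predicate``.  Returns ``None`` when the predicate class never occurs —
    an explicit not-found result, not an error.
    """
    if axis.name not in _VARIABLE_FIELDS:
        raise ParameterError(
            f"axis name must be one of {_VARIABLE_FIELDS}, got {axis.name!r}"
        )
    cfg = cfg or SimulationConfig()
    offered = _default_offered() if offered is None else np.asarray(offered, float)
    thresholds = thresholds or ClassificationThresholds()

    values = axis.values
    fields = {
        "a0": base.attack.a0,
        "am": base.attack.am,
        "la": base.attack.la,
        "h0": base.handling.h0,
        "hm": base.handling.hm,
        "lh": base.handling.lh,
    }
    for v in values:  # per-value parameter validation
        fields[axis.name] = float(v)
        PredatorParams.from_values(**fields)

    arrays = {k: (values[:, None] if k == axis.name else v)
              for k, v in fields.items()}
    consumed = _rk4_consumed(
        arrays["a0"], arrays["am"], arrays["la"],
        arrays["h0"], arrays["hm"], arrays["lh"],
        offered[None, :], cfg.t_max, cfg.n_steps, cfg.depletion,
    )
    shapes, _, _, _ = _classify_cells(consumed, offered, cfg.depletion, thresholds)
    matches = [float(v) for v, s in zip(values, shapes) if s is predicate]
    if not matches:
        return None
    return max(matches) if largest else min(matches)
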