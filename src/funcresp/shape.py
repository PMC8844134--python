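"""Curve-shape diagnosis: derivatives, inflection points, response types.

The shape of a functional-response curve is read off its second derivative:
type III curves are convex then concave (the second derivative crosses zero
from positive to negative at an inflection point), type II curves are concave
everywhere (second derivative always negative, approaching zero), and type I
curves are straight lines (second derivative identically zero).  Two
intermediate categories cover curvature signatures that exist but are too
small to be visually distinguishable: *near-type II* (a positive region that
is barely there) and *near-type I* (a nearly straight curve whose tiny
curvature turns positive at high prey levels without a genuine sigmoid
signature).

Derivatives are taken by second-order central differences on the uniform
offered grid; curves are noiseless ODE output, so no smoothing is applied by
default (an optional moving-average smoother exists for empirical curves).
For classification the curve is first rescaled so that offered and consumed
each span [0, 1]: thresholds on the normalised second derivative are then
scale-free.  The raw second derivative is reported alongside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .curve import ResponseCurve
from .errors import ParameterError

__all__ = [
    "ShapeType",
    "ClassificationThresholds",
    "DerivativeProfile",
    "ClassificationResult",
    "finite_differences",
    "find_inflection",
    "classify",
    "classify_curve",
]


class ShapeType(str, enum.Enum):
    """The five functional-response shape categories."""

    TYPE_I = "TYPE_I"
    NEAR_TYPE_I = "NEAR_TYPE_I"
    TYPE_II = "TYPE_II"
    NEAR_TYPE_II = "NEAR_TYPE_II"
    TYPE_III = "TYPE_III"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision thresholds on the normalised second derivative.

    ``eps_lin`` bounds what counts as "no curvature" (type I); ``eps_pos``
    is the minimum positive curvature for a full type III call — between the
    two, a curve with an inflection is only *near*-type II.  ``persistence``
    is the number of consecutive grid points the second derivative must keep
    its sign on each side of a crossing for the crossing to count, which
    suppresses single-point floating-point sign flips.
    """

    eps_lin: float = 0.02
    eps_pos: float = 0.05
    persistence: int = 5

    def __post_init__(self) -> None:
        if not (self.eps_lin > 0 and self.eps_pos > 0):
            raise ParameterError("thresholds must be positive")
        if self.eps_pos <= self.eps_lin:
            raise ParameterError(
                f"eps_pos ({self.eps_pos}) must exceed eps_lin ({self.eps_lin})"
            )
        if self.persistence < 1:
            raise ParameterError("persistence must be >= 1")


@dataclass
class DerivativeProfile:
    """First and second derivatives of a response curve on the interior grid.

    ``normalized_d2`` is the second derivative of the curve after affinely
    rescaling offered and consumed each to [0, 1]; ``offered_interior`` keeps
    the original offered units for locating features.
    """

    offered_interior: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    normalized_d2: np.ndarray

    def __post_init__(self) -> None:
        n = self.offered_interior.size
        if not (self.d1.size == self.d2.size == self.normalized_d2.size == n):
            raise ParameterError("derivative arrays must have equal length")
        for arr in (self.d1, self.d2, self.normalized_d2):
            if not np.all(np.isfinite(arr)):
                raise ParameterError("derivative values must be finite")


@dataclass
class ClassificationResult:
    """Outcome of shape diagnosis for one response curve."""

    shape: ShapeType
    inflection_offered: float | None
    max_d2: float
    max_normalized_d2: float
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )

    def to_dict(self) -> dict:
        return {
            "shape": self.shape.value,
            "inflection_offered": self.inflection_offered,
            "max_d2": self.max_d2,
            "max_normalized_d2": self.max_normalized_d2,
            "eps_lin": self.thresholds.eps_lin,
            "eps_pos": self.thresholds.eps_pos,
            "persistence": self.thresholds.persistence,
        }


def _central_d2(y: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    d1 = (y[2:] - y[:-2]) / (2.0 * spacing)
    d2 = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / spacing**2
    return d1, d2


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ParameterError("smoothing window must be a positive odd integer")
    if window == 1:
        return y
    kernel = np.full(window, 1.0 / window)
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def finite_differences(
    curve: ResponseCurve, smooth_window: int | None = None
) -> DerivativeProfile:
    """Central-difference derivative profile of a response curve.

    Endpoints are excluded (interior-point convention).  ``smooth_window``
    applies a moving-average filter to the consumed values first; intended
    for noisy empirical curves, never needed for ODE output.
    """
    x = curve.offered
    y = curve.consumed
    if smooth_window is not None:
        y = _smooth(y, smooth_window)
    d1, d2 = _central_d2(y, curve.spacing)

    x_span = x[-1] - x[0]
    y_span = y.max() - y.min()
    if y_span > 0:
        # d2 of the [0,1]x[0,1]-rescaled curve is d2 * x_span^2 / y_span
        normalized_d2 = d2 * (x_span**2 / y_span)
    else:
        normalized_d2 = np.zeros_like(d2)  # flat curve: no curvature by definition

    return DerivativeProfile(
        offered_interior=x[1:-1], d1=d1, d2=d2, normalized_d2=normalized_d2
    )


def _persistent_crossings(d2: np.ndarray, k: int) -> list[int]:
    """Indices i where d2 crosses + -> - between i and i+1 and the sign
    persists for k points on each side (windows truncated at the array
    edges are allowed to be shorter, but must contain at least one point)."""
    out = []
    n = d2.size
    for i in range(n - 1):
        if not (d2[i] > 0 and d2[i + 1] <= 0):
            continue
        left = d2[max(0, i - k + 1) : i + 1]
        right = d2[i + 1 : i + 1 + k]
        if np.all(left > 0) and np.all(right <= 0):
            out.append(i)
    return out


def find_inflection(
    profile: DerivativeProfile, persistence: int = 5
) -> float | None:
    """Offered value of the first persistent positive-to-negative zero
    crossing of the second derivative, linearly interpolated between grid
    points; ``None`` when no such crossing exists (a valid outcome: the
    type II signature)."""
    idx = _persistent_crossings(profile.d2, persistence)
    if not idx:
        return None
    i = idx[0]
    x = profile.offered_interior
    y0, y1 = profile.d2[i], profile.d2[i + 1]
    if y0 == y1:  # pragma: no cover - guarded by the crossing condition
        return float(x[i])
    frac = y0 / (y0 - y1)
    return float(x[i] + frac * (x[i + 1] - x[i]))


def classify(
    profile: DerivativeProfile,
    thresholds: ClassificationThresholds | None = None,
) -> ClassificationResult:
    """Classify a derivative profile into one of the five shape categories.

    The decision runs on the normalised second derivative ``g``:

    1. ``max |g| < eps_lin`` — straight line, **type I**;
    2. a persistent positive-to-negative crossing with ``max g >= eps_pos``
       — genuine sigmoid, **type III**;
    3. a persistent crossing with ``0 < max g < eps_pos`` — attenuated
       sigmoid, **near-type II**;
    4. ``g <= 0`` everywhere (within ``eps_lin/10``) with
       ``min g < -eps_lin`` — concave everywhere, **type II**;
    5. otherwise — small curvature turning positive at high prey levels
       without a sigmoid signature, **near-type I**.
    """
    th = thresholds or ClassificationThresholds()
    g = profile.normalized_d2
    max_g = float(g.max())
    min_g = float(g.min())
    max_abs = max(abs(max_g), abs(min_g))
    inflection = find_inflection(profile, th.persistence)
    # crossing location from the normalised profile equals the raw one: the
    # rescaling is affine, so zero crossings of d2 are preserved
    crossing = inflection is not None

    if max_abs < th.eps_lin:
        shape = ShapeType.TYPE_I
    elif crossing and max_g >= th.eps_pos:
        shape = ShapeType.TYPE_III
    elif crossing and 0.0 < max_g < th.eps_pos:
        shape = ShapeType.NEAR_TYPE_II
    elif max_g <= th.eps_lin / 10.0 and min_g < -th.eps_lin:
        shape = ShapeType.TYPE_II
    else:
        shape = ShapeType.NEAR_TYPE_I

    return ClassificationResult(
        shape=shape,
        inflection_offered=inflection if crossing else None,
        max_d2=float(profile.d2.max()),
        max_normalized_d2=max_g,
        thresholds=th,
    )


def classify_curve(
    curve: ResponseCurve,
    thresholds: ClassificationThresholds | None = None,
    smooth_window: int | None = None,
) -> ClassificationResult:
    """Convenience wrapper: derivatives plus classification in one call."""
    return classify(finite_differences(curve, smooth_window), thresholds)
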