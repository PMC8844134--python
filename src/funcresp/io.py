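"""CSV/JSON readers and writers for curves, trajectories, and sweeps.

CSV dialect: comma-separated, ``.`` decimal, one header row, no index
column, LF line endings; floats are written with 17 significant digits so
values round-trip bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .curve import ResponseCurve
from .errors import ParameterError
from .integrate import Trajectory
from .shape import ClassificationResult
from .sweep import SweepResult

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_trajectory_csv",
    "write_classification_json",
    "write_sweep_csv",
    "read_config",
]

_FLOAT_FMT = "%.17g"


def write_curve_csv(curve: ResponseCurve, path: str | Path) -> None:
    df = pd.DataFrame({"offered": curve.offered, "consumed": curve.consumed})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_curve_csv(path: str | Path, depletion: bool = False) -> ResponseCurve:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParameterError(f"could not parse curve CSV {path}: {exc}") from exc
    for col in ("offered", "consumed"):
        if col not in df.columns:
            raise ParameterError(f"curve CSV must have a {col!r} column")
    return ResponseCurve(
        offered=df["offered"].to_numpy(dtype=float),
        consumed=df["consumed"].to_numpy(dtype=float),
        depletion=depletion,
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    cols = {
        "t": traj.t,
        "n_consumed": traj.n_consumed,
        "attack": traj.attack,
        "handling": traj.handling,
    }
    if traj.n_available is not None:
        cols["n_available"] = traj.n_available
    pd.DataFrame(cols).to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )


def write_classification_json(
    result: ClassificationResult, path: str | Path, extra: dict | None = None
) -> None:
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_sweep_csv(result: SweepResult, path: str | Path) -> None:
    """Long-format sweep CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    result.to_dataframe().to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    sidecar = Path(str(path) + ".meta.json")
    sidecar.write_text(json.dumps(result.metadata, indent=2) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}"
            )
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ParameterError(f"{path}:{lineno}: empty key")
        out[key] = value
    return out
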