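"""Parameter sweeps and response surfaces of YAP/TAZ activity.

Reproduces the published sweep protocol: the feedback strength ``v_Y`` and
the initial α-catenin level are each varied from 0.1 to 1.0 in 10 steps
(endpoints included), and the initial autophagy/YAP levels from 0.1 to 2.0.
Each grid cell integrates one trajectory; the derived scales v_C and C_max
are re-derived per cell from that cell's C(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .model_core import InitialState, ModelParameters, Trajectory, integrate

__all__ = [
    "SweepSpec",
    "ResponseSurface",
    "axis_values",
    "run_sweep",
    "relative_accumulation",
]

#: Sweepable quantity -> ("params" | "init", field name)
_AXES = {
    "v_Y": ("params", "v_Y"),
    "alpha_cat": ("init", "alpha_cat_init"),
    "A_init": ("init", "A_init"),
    "Y_init": ("init", "Y_init"),
}

# tie tolerance for the increase/decrease/unchanged label (relative)
_TIE_EPS = 1e-6


def axis_values(lo: float, hi: float, n_steps: int) -> np.ndarray:
    """Inclusive evenly spaced axis, e.g. 0.1..1.0 in 10 steps -> 0.1, 0.2, ..., 1.0."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps == 1:
        return np.array([lo], dtype=float)
    return np.linspace(lo, hi, n_steps)


@dataclass(frozen=True)
class SweepSpec:
    """A two-axis sweep over model quantities.

    Axis names must be one of ``v_Y``, ``alpha_cat``, ``A_init``, ``Y_init``.
    Non-swept quantities come from ``params``/``init``.
    """

    axis1_name: str = "v_Y"
    axis1_values: np.ndarray = field(default_factory=lambda: axis_values(0.1, 1.0, 10))
    axis2_name: str = "alpha_cat"
    axis2_values: np.ndarray = field(default_factory=lambda: axis_values(0.1, 1.0, 10))
    params: ModelParameters = field(default_factory=ModelParameters)
    init: InitialState = field(default_factory=InitialState)
    t_end: float = 2.0      # matches the regime-analysis horizon (response module)
    n_samples: int = 400

    def __post_init__(self) -> None:
        for name in (self.axis1_name, self.axis2_name):
            if name not in _AXES:
                raise ValueError(f"unknown sweep axis {name!r}; choose from {sorted(_AXES)}")
        if self.axis1_name == self.axis2_name:
            raise ValueError("the two sweep axes must differ")
        for label, vals in (("axis1", self.axis1_values), ("axis2", self.axis2_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or len(arr) < 1:
                raise ValueError(f"{label}_values must be a non-empty 1-D array")
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{label}_values must be strictly increasing and positive")
            object.__setattr__(self, f"{label}_values", arr)

    def cell_run(self, value1: float, value2: float) -> tuple[ModelParameters, InitialState]:
        """Parameters and initial state for one grid cell."""
        params, init = self.params, self.init
        for name, value in ((self.axis1_name, value1), (self.axis2_name, value2)):
            target, fld = _AXES[name]
            if target == "params":
                params = params.replace(**{fld: float(value)})
            else:
                init = init.replace(**{fld: float(value)})
        return params, init

    def cells(self) -> Iterator[tuple[float, float]]:
        for v1 in self.axis1_values:
            for v2 in self.axis2_values:
                yield float(v1), float(v2)


@dataclass
class ResponseSurface:
    """Per-cell summaries of the model response over a two-axis sweep.

    ``table`` is a long-format frame with one row per cell:
    ``axis1, axis2, A_T, Y_T, Y_rel, C_T, C_rel, direction`` where
    ``Y_rel = Y(T)/Y_init`` (the published normalisation) and
    ``C_rel = C(T)/C(0)`` (NaN where C(0) = 0).
    """

    spec: SweepSpec
    table: pd.DataFrame

    def cell(self, value1: float, value2: float) -> pd.Series:
        t = self.table
        match = t[(np.isclose(t["axis1"], value1)) & (np.isclose(t["axis2"], value2))]
        if len(match) != 1:
            raise KeyError(f"no unique cell at ({value1}, {value2})")
        return match.iloc[0]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.12g")
        return path

    def pivot(self, value: str = "Y_rel") -> pd.DataFrame:
        return self.table.pivot(index="axis2", columns="axis1", values=value)


def _direction_label(y_T: float, y_init: float, tie_eps: float = _TIE_EPS) -> str:
    if y_T > y_init * (1.0 + tie_eps):
        return "increase"
    if y_T < y_init * (1.0 - tie_eps):
        return "decrease"
    return "unchanged"


def run_sweep(spec: SweepSpec) -> ResponseSurface:
    """Integrate one trajectory per grid cell and summarise it at t = T.

    Deterministic given the spec; a cell whose integration fails aborts the
    sweep with the failing coordinates attached.
    """
    rows = []
    for v1, v2 in spec.cells():
        params, init = spec.cell_run(v1, v2)
        try:
            traj: Trajectory = integrate(
                params, init, t_end=spec.t_end, n_samples=spec.n_samples
            )
        except Exception as exc:  # annotate with the failing cell
            raise type(exc)(
                f"integration failed at cell ({spec.axis1_name}={v1}, "
                f"{spec.axis2_name}={v2}): {exc}"
            ) from exc
        y_T = float(traj.Y[-1])
        c_T = float(traj.C[-1])
        c0 = init.alpha_cat_init
        rows.append(
            {
                "axis1": v1,
                "axis2": v2,
                "A_T": float(traj.A[-1]),
                "Y_T": y_T,
                "Y_rel": y_T / init.Y_init if init.Y_init > 0 else np.nan,
                "C_T": c_T,
                "C_rel": c_T / c0 if c0 > 0 else np.nan,
                "direction": _direction_label(y_T, init.Y_init),
            }
        )
    return ResponseSurface(spec=spec, table=pd.DataFrame(rows))


def relative_accumulation(surface: ResponseSurface) -> pd.DataFrame:
    """α-catenin fold-change table: C(T)/C(0) and C(T)−C(0) per cell.

    Cells with C(0) = 0 report an undefined fold-change (NaN) but a defined
    absolute increase.  The table is reported as computed; no monotonicity
    is assumed.
    """
    spec = surface.spec
    t = surface.table
    c0 = np.array(
        [spec.cell_run(r.axis1, r.axis2)[1].alpha_cat_init for r in t.itertuples()]
    )
    out = t[["axis1", "axis2", "C_T"]].copy()
    out["C_0"] = c0
    out["abs_increase"] = out["C_T"] - out["C_0"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = np.where(c0 > 0, out["C_T"] / c0, np.nan)
    return out
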