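"""Synthetic multi-cell-line experimental panels with known ground truth.

Emulates the statistical structure of the wet-lab readouts that motivate the
regime analysis: per-line basal CTNNA1 densitometry ratios (relative to an
MCF10A-like reference pinned at 1.0), CTNNA1 levels after autophagy
knockdown, and TEAD luciferase activity (a proxy for YAP/TAZ activity) —
each as n replicates with multiplicative lognormal noise.

Two α-catenin regimes mirror the published cell-line panel: "high" lines
(MCF10A-like; basal ratio in [0.5, 1.2]) and "low" lines (HepG2-like; ratio
in [0.05, 0.3]).  The knockdown condition is the model's default scenario
itself (the −cA depletion term *is* the knockdown); "autophagy induction"
readouts reuse the model with an elevated initial autophagy level, since the
model carries no explicit induction input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import InitialState, ModelParameters, integrate

__all__ = [
    "NoiseModel",
    "SyntheticCellLine",
    "SyntheticPanel",
    "generate_panel",
    "panel_summary",
    "REFERENCE_LINE",
]

REFERENCE_LINE = "MCF10A_like"

CONDITIONS = ("baseline", "knockdown", "induction")
READOUTS = ("ctnna1", "tead")

#: basal α-catenin ranges per regime (relative to the reference line)
REGIME_RANGES = {"high": (0.5, 1.2), "low": (0.05, 0.3)}

DEFAULT_INDUCTION_A_INIT = 1.5  # elevated initial autophagy for "induction"


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal replicate noise.

    Readouts are drawn as ``centre * exp(sigma * Z)`` with
    ``sigma^2 = ln(1 + CV^2)``, so the distribution is median-centred on the
    model value and its coefficient of variation equals ``cv``.  ``cv = 0``
    degenerates to noiseless replicates.
    """

    cv: float = 0.2
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        # 3-6 replicates matches the published experiment sizes; other counts
        # are allowed for convergence studies and degenerate-summary cases
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.cv**2))

    def draw(self, centre: float, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.full(self.n_replicates, centre, dtype=float)
        return centre * np.exp(self.sigma * rng.standard_normal(self.n_replicates))


@dataclass(frozen=True)
class SyntheticCellLine:
    """Ground truth for one simulated line."""

    name: str
    alpha_cat_init: float   # true basal CTNNA1 ratio vs the reference line
    v_Y: float              # true feedback strength
    regime: str             # "high" | "low"

    def __post_init__(self) -> None:
        if self.regime not in REGIME_RANGES:
            raise ValueError(f"regime must be one of {sorted(REGIME_RANGES)}")


@dataclass
class SyntheticPanel:
    """Replicate readouts per line/condition plus the generating ground truth.

    ``data`` is tidy: ``line, regime, condition, replicate, readout_type,
    value``.  ``truth`` maps line name -> :class:`SyntheticCellLine`.
    """

    data: pd.DataFrame
    truth: dict[str, SyntheticCellLine]
    noise: NoiseModel
    params: ModelParameters
    horizons: tuple[float, float]
    seed: int

    def lines(self) -> list[str]:
        return list(self.truth)

    def readouts(self, line: str, condition: str, readout_type: str) -> np.ndarray:
        d = self.data
        sel = d[
            (d["line"] == line)
            & (d["condition"] == condition)
            & (d["readout_type"] == readout_type)
        ]
        return sel["value"].to_numpy()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)  # full precision: the truth sidecar
        # plus this file must reproduce the panel exactly
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "noise": asdict(self.noise),
                    "params": asdict(self.params),
                    "horizons": list(self.horizons),
                    "lines": {n: asdict(t) for n, t in self.truth.items()},
                },
                indent=2,
            )
            + "\n"
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticPanel":
        path = Path(path)
        data = pd.read_csv(path, float_precision="round_trip")
        meta = json.loads(path.with_suffix(".truth.json").read_text())
        truth = {n: SyntheticCellLine(**t) for n, t in meta["lines"].items()}
        return cls(
            data=data,
            truth=truth,
            noise=NoiseModel(**meta["noise"]),
            params=ModelParameters(**meta["params"]),
            horizons=tuple(meta["horizons"]),
            seed=meta["seed"],
        )


@lru_cache(maxsize=4096)
def _centres(
    params: ModelParameters, alpha: float, T_kd: float, T_ind: float
) -> dict[str, tuple[float, float]]:
    """Model-predicted (CTNNA1, TEAD) readout centres per condition.

    Baseline centres are the initial levels; knockdown centres come from the
    default inhibition scenario at T_kd; induction centres from an elevated
    A_init run at T_ind.  Cached because panel generation across many seeds
    reuses the same deterministic forward maps.
    """
    init = InitialState(alpha_cat_init=alpha)
    kd = integrate(params, init, t_end=T_kd, n_samples=100)
    ind = integrate(
        params,
        init.replace(A_init=DEFAULT_INDUCTION_A_INIT),
        t_end=T_ind,
        n_samples=100,
    )
    return {
        "baseline": (alpha, init.Y_init),
        "knockdown": (float(kd.C[-1]), float(kd.Y[-1])),
        "induction": (float(ind.C[-1]), float(ind.Y[-1])),
    }


def _draw_lines(
    n_per_regime: int, rng: np.random.Generator, v_Y: float
) -> list[SyntheticCellLine]:
    lines: list[SyntheticCellLine] = [
        # the reference line is pinned at ratio 1.0 (relative-ratio convention)
        SyntheticCellLine(REFERENCE_LINE, 1.0, v_Y, "high")
    ]
    for regime in ("high", "low"):
        lo, hi = REGIME_RANGES[regime]
        n = n_per_regime - 1 if regime == "high" else n_per_regime
        for i in range(n):
            alpha = float(rng.uniform(lo, hi))
            lines.append(SyntheticCellLine(f"{regime}_{i + 1:02d}", alpha, v_Y, regime))
    return lines


def generate_panel(
    n_lines_per_regime: int = 10,
    noise: NoiseModel | None = None,
    params: ModelParameters | None = None,
    horizons: tuple[float, float] = (2.0, 2.0),
    lines: list[SyntheticCellLine] | None = None,
) -> SyntheticPanel:
    """Generate a seeded synthetic panel of replicate readouts.

    Per line and condition, ``noise.n_replicates`` CTNNA1 and TEAD readouts
    are drawn around the model-predicted centres.  Passing explicit
    ``lines`` fixes the ground truth and leaves only the replicate noise to
    the seed.  Regeneration with the same arguments is bit-identical.
    """
    noise = noise or NoiseModel()
    params = params or ModelParameters()
    if n_lines_per_regime < 1:
        raise ValueError("n_lines_per_regime must be >= 1")
    rng = np.random.default_rng(noise.seed)
    if lines is None:
        lines = _draw_lines(n_lines_per_regime, rng, params.v_Y)

    rows = []
    for line in lines:
        centres = _centres(params, line.alpha_cat_init, *horizons)
        for condition in CONDITIONS:
            c_centre, y_centre = centres[condition]
            for readout_type, centre in zip(READOUTS, (c_centre, y_centre)):
                values = noise.draw(centre, rng)
                for rep, value in enumerate(values, start=1):
                    rows.append(
                        {
                            "line": line.name,
                            "regime": line.regime,
                            "condition": condition,
                            "replicate": rep,
                            "readout_type": readout_type,
                            "value": float(value),
                        }
                    )
    return SyntheticPanel(
        data=pd.DataFrame(rows),
        truth={line.name: line for line in lines},
        noise=noise,
        params=params,
        horizons=horizons,
        seed=noise.seed,
    )


def panel_summary(panel: SyntheticPanel) -> pd.DataFrame:
    """Per line/condition/readout mean ± s.d. table (with s.e.m. and n).

    Mirrors a "mean ± s.d. (n independent experiments)" report; the s.d. of
    a single replicate is undefined (NaN).
    """
    g = panel.data.groupby(["line", "regime", "condition", "readout_type"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
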