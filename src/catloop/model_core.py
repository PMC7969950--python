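"""Three-ODE model of the autophagy–α-catenin–YAP/TAZ feedback loop.

The state is a triple of dimensionless levels:

* ``A`` — autophagy activity, primarily depleted at rate ``c`` (the
  genetic/chemical inhibition) and further reduced when YAP/TAZ activity
  drops (the feedback term, strength ``v_Y``),
* ``Y`` — YAP/TAZ transcriptional activity, grown by an autophagy-dependent
  logistic-like term (ceiling ``Y_max``) and sequestered into the cytosol by
  α-catenin at rate ``r1``,
* ``C`` — α-catenin protein level, which accumulates upon autophagy
  perturbation towards a ceiling ``C_max`` (protein synthesis neglected).

.. math::

    dA/dt &= -cA - v_Y (1 - e^{-\\delta_A Y}) A \\\\
    dY/dt &= -r_1 Y C + r_2 (1 - e^{-\\delta_Y A})(1 - Y/Y_{max}) Y \\\\
    dC/dt &= r_3 v_C v_Y (1 - e^{-\\delta_C A})(1 - C/C_{max}) C

with the derived scales :math:`v_C = k\\,C(0)`, :math:`C_{max} = k_C\\,C(0)`
and :math:`Y_{max} = k_Y\\,Y(0)`.  The saturation factors
:math:`1 - e^{-\\delta x}` bound each feedback effect (plateau behaviour).
All quantities are dimensionless, including model time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "InitialState",
    "DerivedScales",
    "Trajectory",
    "SteadyStateReport",
    "InvalidStateError",
    "DegenerateScaleError",
    "IntegrationError",
    "rhs",
    "integrate",
    "steady_state_check",
]


class InvalidStateError(ValueError):
    """Raised when a state vector contains non-finite or negative entries."""


class DegenerateScaleError(ValueError):
    """Raised when a zero saturation ceiling meets a nonzero state component."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, saturation scales and feedback strength of the model.

    Defaults are the published constants of the model.  ``v_Y`` is the
    feedback-loop strength (how strongly YAP/TAZ activity sustains
    autophagy); it is the main swept parameter together with the initial
    α-catenin level.
    """

    c: float = 0.1          # primary autophagy depletion rate
    r1: float = 1.0         # YAP sequestration rate by α-catenin
    r2: float = 1.2         # YAP accumulation rate
    r3: float = 3.0         # α-catenin accumulation rate
    k: float = 1.0          # scale for v_C = k*C(0)
    k_C: float = 3.0        # scale for C_max = k_C*C(0)
    k_Y: float = 4.0        # scale for Y_max = k_Y*Y(0)
    delta_A: float = 1.0    # saturation exponent, feedback on autophagy
    delta_Y: float = 1.0    # saturation exponent, YAP growth
    delta_C: float = 1.0    # saturation exponent, α-catenin accumulation
    v_Y: float = 0.5        # feedback-loop strength

    def __post_init__(self) -> None:
        # zero rates are meaningful limits (e.g. v_Y = 0: no feedback;
        # r1 = 0: no sequestration) and are used by the closed-form checks
        for name, value in asdict(self).items():
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"parameter {name!r} must be non-negative, got {value}")

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InitialState:
    """Initial levels at t = 0: autophagy, YAP/TAZ activity and α-catenin.

    ``alpha_cat_init`` is the "α-cat" of the regime analysis: the basal
    α-catenin level relative to a reference cell line.
    """

    A_init: float = 1.0
    Y_init: float = 1.0
    alpha_cat_init: float = 0.5

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"initial value {name!r} must be non-negative, got {value}")

    def replace(self, **kwargs) -> "InitialState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedScales:
    """Per-run scales derived from the initial state: v_C, C_max, Y_max."""

    v_C: float
    C_max: float
    Y_max: float

    @classmethod
    def from_run(cls, params: ModelParameters, init: InitialState) -> "DerivedScales":
        return cls(
            v_C=params.k * init.alpha_cat_init,
            C_max=params.k_C * init.alpha_cat_init,
            Y_max=params.k_Y * init.Y_init,
        )


def rhs(
    state: Sequence[float],
    params: ModelParameters,
    scales: DerivedScales,
) -> tuple[float, float, float]:
    """Evaluate the right-hand side (dA, dY, dC) at a state (A, Y, C).

    The degenerate ceilings are handled explicitly: a zero ``C_max`` (i.e.
    C(0) = 0) with C = 0 gives dC = 0 rather than a 0/0, and likewise for
    ``Y_max``; a zero ceiling with a *nonzero* component is a contradiction
    in the run setup and raises :class:`DegenerateScaleError`.
    """
    A, Y, C = (float(x) for x in state)
    if not all(math.isfinite(x) for x in (A, Y, C)):
        raise InvalidStateError(f"non-finite state ({A}, {Y}, {C})")
    if A < 0 or Y < 0 or C < 0:
        raise InvalidStateError(f"negative state component in ({A}, {Y}, {C})")

    dA = -params.c * A - params.v_Y * (1.0 - math.exp(-params.delta_A * Y)) * A

    if scales.Y_max == 0.0:
        if Y != 0.0:
            raise DegenerateScaleError("Y_max = 0 with nonzero Y")
        dY = 0.0
    else:
        dY = (
            -params.r1 * Y * C
            + params.r2
            * (1.0 - math.exp(-params.delta_Y * A))
            * (1.0 - Y / scales.Y_max)
            * Y
        )

    if scales.C_max == 0.0:
        if C != 0.0:
            raise DegenerateScaleError("C_max = 0 with nonzero C")
        dC = 0.0
    else:
        dC = (
            params.r3
            * scales.v_C
            * params.v_Y
            * (1.0 - math.exp(-params.delta_C * A))
            * (1.0 - C / scales.C_max)
            * C
        )

    return dA, dY, dC


@dataclass
class Trajectory:
    """A solved trajectory on an equally spaced time grid, with provenance."""

    times: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    C: np.ndarray
    params: ModelParameters = field(default_factory=ModelParameters)
    init: InitialState = field(default_factory=InitialState)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.times)
        if not (len(self.A) == len(self.Y) == len(self.C) == n):
            raise ValueError("times, A, Y, C must have equal lengths")

    @property
    def scales(self) -> DerivedScales:
        return DerivedScales.from_run(self.params, self.init)

    def index_at(self, t: float) -> int:
        """Index of the grid sample nearest to ``t`` (must lie in the span)."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"t={t} outside trajectory span [{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))

    def value_at(self, t: float, component: str = "Y") -> float:
        return float(getattr(self, component)[self.index_at(t)])

    def to_csv(self, path: str | Path) -> Path:
        """Write `t,A,Y,C` CSV plus a JSON sidecar with parameters and init."""
        path = Path(path)
        lines = ["t,A,Y,C"]
        for t, a, y, c in zip(self.times, self.A, self.Y, self.C):
            lines.append(f"{t:.12g},{a:.12g},{y:.12g},{c:.12g}")
        path.write_text("\n".join(lines) + "\n")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"params": asdict(self.params), "init": asdict(self.init)}, indent=2)
            + "\n"
        )
        return path


def integrate(
    params: ModelParameters | None = None,
    init: InitialState | None = None,
    t_end: float = 10.0,
    n_samples: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model with an adaptive Runge–Kutta (Dormand–Prince) solver.

    Output is sampled on an equally spaced grid of ``n_samples`` points over
    ``[0, t_end]``, independent of the internal steps, so that downstream
    windowed analyses are well defined.
    """
    params = params or ModelParameters()
    init = init or InitialState()
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if n_samples < 2:
        raise ValueError(f"n_samples must be at least 2, got {n_samples}")

    scales = DerivedScales.from_run(params, init)
    y0 = np.array([init.A_init, init.Y_init, init.alpha_cat_init], dtype=float)
    t_eval = np.linspace(0.0, t_end, n_samples)

    def f(_t: float, y: np.ndarray) -> list[float]:
        # clip tiny negative overshoots from the solver before evaluating
        return list(rhs(np.maximum(y, 0.0), params, scales))

    sol = solve_ivp(
        f, (0.0, t_end), y0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else 0.0
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_time=last)

    A, Y, C = (np.maximum(sol.y[i], 0.0) for i in range(3))
    return Trajectory(times=t_eval, A=A, Y=Y, C=C, params=params, init=init)


@dataclass(frozen=True)
class SteadyStateReport:
    """Horizon-validation summary used by the response analyses."""

    autophagy_decayed: bool
    terminal_dY_sign: int          # sign of the last finite difference of Y
    terminal_monotone: bool        # last quarter of Y samples monotone
    final_A: float
    insufficient_samples: bool = False


def steady_state_check(traj: Trajectory, epsilon: float = 1e-4) -> SteadyStateReport:
    """Report whether A has decayed below ``epsilon`` and whether Y is in a
    terminal monotone phase (a sanity check on analysis-horizon choices)."""
    if len(traj.times) < 4:
        return SteadyStateReport(
            autophagy_decayed=bool(traj.A[-1] < epsilon),
            terminal_dY_sign=0,
            terminal_monotone=False,
            final_A=float(traj.A[-1]),
            insufficient_samples=True,
        )
    dY = np.diff(traj.Y)
    tail = dY[-max(1, len(dY) // 4):]
    sign = int(np.sign(dY[-1]))
    monotone = bool(np.all(tail <= 0) or np.all(tail >= 0))
    return SteadyStateReport(
        autophagy_decayed=bool(traj.A[-1] < epsilon),
        terminal_dY_sign=sign,
        terminal_monotone=monotone,
        final_A=float(traj.A[-1]),
    )
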