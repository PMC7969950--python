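"""Independent oracles used by the tests.

These deliberately re-state the model equations inline (not via
``catloop.model_core.rhs``) so that agreement checks compare two
independent code paths.
"""

from __future__ import annotations

import math

import numpy as np


def rhs_inline(A, Y, C, *, c, r1, r2, r3, v_Y, v_C, C_max, Y_max,
               dA_exp=1.0, dY_exp=1.0, dC_exp=1.0):
    """Hand-transcribed right-hand side of the three ODEs."""
    dA = -c * A - v_Y * (1.0 - math.exp(-dA_exp * Y)) * A
    growth = r2 * (1.0 - math.exp(-dY_exp * A)) * (1.0 - Y / Y_max) * Y if Y_max > 0 else 0.0
    dY = -r1 * Y * C + growth
    accum = (
        r3 * v_C * v_Y * (1.0 - math.exp(-dC_exp * A)) * (1.0 - C / C_max) * C
        if C_max > 0
        else 0.0
    )
    return dA, dY, accum


def rk4_trajectory(params, init, t_end: float, step: float = 1e-4,
                   sample_times: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Fixed-step classical RK4 integration of the model.

    Returns the state sampled at ``sample_times`` (default: every integer
    multiple of 0.5) via linear interpolation between the bracketing steps.
    """
    kw = dict(
        c=params.c, r1=params.r1, r2=params.r2, r3=params.r3, v_Y=params.v_Y,
        v_C=params.k * init.alpha_cat_init,
        C_max=params.k_C * init.alpha_cat_init,
        Y_max=params.k_Y * init.Y_init,
        dA_exp=params.delta_A, dY_exp=params.delta_Y, dC_exp=params.delta_C,
    )
    if sample_times is None:
        sample_times = np.arange(0.0, t_end + 1e-12, 0.5)
    n_steps = int(round(t_end / step))
    A, Y, C = init.A_init, init.Y_init, init.alpha_cat_init
    ts, states = [0.0], [(A, Y, C)]
    f = rhs_inline
    for i in range(n_steps):
        k1 = f(A, Y, C, **kw)
        k2 = f(A + 0.5 * step * k1[0], Y + 0.5 * step * k1[1], C + 0.5 * step * k1[2], **kw)
        k3 = f(A + 0.5 * step * k2[0], Y + 0.5 * step * k2[1], C + 0.5 * step * k2[2], **kw)
        k4 = f(A + step * k3[0], Y + step * k3[1], C + step * k3[2], **kw)
        A += step / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        Y += step / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        C += step / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        ts.append((i + 1) * step)
        states.append((A, Y, C))
    ts = np.array(ts)
    arr = np.array(states)
    out = {"t": np.asarray(sample_times, dtype=float)}
    for j, name in enumerate(("A", "Y", "C")):
        out[name] = np.interp(out["t"], ts, arr[:, j])
    return out


def brute_force_lir_scan(residues: str) -> list[tuple[int, str]]:
    """Position-by-position core-consensus scan: (1-based aromatic pos, core)."""
    hits = []
    for i in range(len(residues) - 3):
        window = residues[i : i + 4]
        if window[0] in "WFY" and window[3] in "ILV":
            hits.append((i + 1, window))
    return hits
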