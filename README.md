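# catloop

**catloop** models the feedback loop between macroautophagy, α-catenin and
the Hippo-pathway co-activators YAP/TAZ, and asks the question that loop
raises for cell biologists: *why does inhibiting autophagy raise YAP/TAZ
activity in some cell lines and lower it in others?*

The answer the model encodes: α-catenin is an autophagy substrate that
sequesters YAP/TAZ in the cytosol, and YAP/TAZ in turn sustain autophagy.
When autophagy is inhibited, α-catenin accumulates — but how much, and how
fast it overtakes the simultaneous loss of autophagic YAP/TAZ degradation,
depends on the cell's *basal* α-catenin level. High-α-catenin cells
(MCF10A-like) respond with a net YAP/TAZ decrease; low-α-catenin cells
(HepG2-like) respond with a net increase.

## The model

Three coupled dimensionless ODEs for autophagy *A*, YAP/TAZ activity *Y*
and α-catenin level *C*:

```
dA/dt = −cA − v_Y (1 − e^(−δ_A Y)) A
dY/dt = −r₁YC + r₂ (1 − e^(−δ_Y A)) (1 − Y/Y_max) Y
dC/dt = r₃ v_C v_Y (1 − e^(−δ_C A)) (1 − C/C_max) C
```

with `v_C = k·C(0)`, `C_max = k_C·C(0)`, `Y_max = k_Y·Y(0)` and default
constants `c=0.1, r₁=1.0, r₂=1.2, r₃=3.0, k=1.0, k_C=3.0, k_Y=4.0, δ=1.0`,
`A(0)=Y(0)=1`. The `−cA` term is the primary (genetic/chemical) autophagy
inhibition; `v_Y` is the strength of the YAP/TAZ→autophagy feedback;
`C(0)` ("α-cat") is the basal α-catenin level relative to a reference line.

On top of the integrator the package provides

* **sweeps** — response surfaces over (v_Y × α-cat) and (A_init × Y_init)
  grids,
* **regime analysis** — direction classification of the YAP/TAZ response,
  bisection for the α-catenin *flip boundary*, and windowed Pearson
  correlations between Y and A around the YAP peak,
* **synthetic panels** — seeded multi-cell-line CTNNA1/TEAD replicate
  readouts with lognormal noise and known ground truth,
* **inference** — basal-ratio estimation, time-course fits of
  (α-cat, v_Y), and per-line direction prediction,
* **lirscan** — an LC3-interacting-region scanner for the core consensus
  `[WFY]xx[ILV]` on protein FASTA.

## Worked example

```python
from catloop import (ModelParameters, InitialState, integrate,
                     find_flip_boundary, windowed_correlation)

# where does the response flip direction?
print(find_flip_boundary(v_Y=0.5, T=2.0))        # 0.3544418334960938

# biphasic YAP response of a low-α-catenin cell
traj = integrate(ModelParameters(v_Y=0.5), InitialState(alpha_cat_init=0.1),
                 t_end=10.0, n_samples=400)
res = windowed_correlation(traj)
print(round(res.t_peak, 2))                      # 3.36
print(round(res.R_early, 3), round(res.R_late, 3))   # -0.995 0.88
```

A cell with basal α-catenin at 0.1 (10% of the reference line) raises its
YAP/TAZ activity for ~3.4 time units after autophagy inhibition while
autophagy falls (Pearson R = −0.995 between Y and A), then α-catenin
sequestration takes over and Y falls alongside A (R = 0.88). The direction
flip across cell lines sits at basal α-catenin ≈ 0.354 — between the
regime thresholds 0.3 and 0.5 used to classify real lines.

The same analyses are packaged as numbered drivers under `analysis/`
(`01_simulate_trajectories.py` … `07_lir_scan.py`), each writing its tables
to `results/`, and as a CLI:

```
catloop boundary --v-y 0.5
catloop correlate --alpha-cat 0.1 --t-end 10
catloop lirscan proteins.fasta
```

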