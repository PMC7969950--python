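# Methods

## Model

The system state is three non-negative dimensionless levels: autophagy
activity `A`, YAP/TAZ transcriptional activity `Y`, and α-catenin protein
level `C` (basal value relative to a reference cell line). Each term of
the ODE system represents a single mechanism:

* `−cA` — primary autophagy inhibition (siRNA/chemical), rate `c`;
* `−v_Y(1−e^(−δ_A Y))A` — loss of YAP/TAZ-driven autophagy support. The
  saturation factor bounds the feedback (plateau effect): only a strong
  YAP/TAZ drop meaningfully lowers autophagy. `v_Y` is the feedback
  strength and varies between cell types;
* `−r₁YC` — cytosolic sequestration of YAP/TAZ by α-catenin (the
  LIR-dependent mechanism);
* `+r₂(1−e^(−δ_Y A))(1−Y/Y_max)Y` — autophagy-dependent YAP/TAZ gain with
  logistic ceiling `Y_max = k_Y·Y(0)`;
* `+r₃v_C v_Y(1−e^(−δ_C A))(1−C/C_max)C` — α-catenin accumulation upon
  autophagy perturbation, proportional to the basal level through
  `v_C = k·C(0)` and capped at `C_max = k_C·C(0)`. Protein synthesis is
  neglected.

Model time is dimensionless; no mapping to wall-clock hours is asserted
anywhere. The published constants (`c=0.1, r₁=1.0, r₂=1.2, r₃=3.0, k=1.0,
k_C=3.0, k_Y=4.0, δ_A=δ_Y=δ_C=1.0`, `A(0)=Y(0)=1`) are the defaults of
`ModelParameters`/`InitialState`. `Y_max` is read as `k_Y·Y(0)` (the
source formula prints an apparent typo omitting Y(0)). Zero rates are
accepted as meaningful limits (`v_Y=0`: no feedback; `r₁=0`: no
sequestration); they back the closed-form checks.

Structural consequences used as test invariants: `A` is strictly
decreasing whenever `A(0)>0` (both terms are ≤ −cA ≤ 0); `C` is
non-decreasing and bounded by `C_max`; `Y ≤ Y_max`; all components stay
non-negative; for `C(0)>0, v_Y>0`, `Y → 0` at long horizons because the
sequestration term eventually dominates.

### Numerics

Integration uses `scipy.integrate.solve_ivp` with the Dormand–Prince RK45
pair at `rtol=1e-8, atol=1e-10`; the system is non-stiff over the
parameter ranges swept. Output is sampled on an equally spaced grid
(default 400 points) independent of the internal steps so that windowed
statistics are well defined. Tiny negative solver overshoots are clipped
to zero before evaluating the right-hand side and in the stored
trajectory. A degenerate `C(0)=0` gives `v_C=C_max=0`; the `C` equation
then returns exactly zero rather than evaluating `0/0`; a zero ceiling
combined with a *nonzero* component is rejected as a contradictory run
setup. Tests verify agreement with an independently coded fixed-step RK4
oracle to 1e-6 in sup norm, and closed-form limits (`A(t)=e^(−ct)` with
`v_Y=0, C(0)=0`; `Y(t)=Y₀e^(−r₁C₀t)` with `A=0`).

## Sweeps and regime analysis

The published sweep protocol is the default `SweepSpec`: `v_Y` and the
initial α-catenin from 0.1 to 1.0 in 10 steps (endpoints included, step
0.1), `A_init`/`Y_init` from 0.1 to 2.0 in 20 steps. Sweeping the initial
α-catenin re-derives `v_C` and `C_max` per cell, since both are defined
from that cell's `C(0)`. Surfaces record `Y(T)`, `Y(T)/Y(0)`, `C(T)`,
`C(T)/C(0)` and a direction label per cell; both `Y(T)` and the
normalised `Y(T)/Y(0)` are emitted because either could be the plotted
quantity in the source material.

**Direction** is classified by comparing `Y(T)` with `Y(0)` at a relative
tie band `tie_eps = 1e-6` — far below visible integrator error, so
"unchanged" effectively only fires for structurally frozen `Y`.

**Flip boundary.** The initial-α-catenin level at which the finite-horizon
response flips from increase to decrease is found by bisection on
`Y(T) − Y(0)` over the bracket [0.05, 1.0] to a tolerance of 1e-4. It is
a finite-horizon classification boundary, not a fixed-point bifurcation;
non-bracketing setups (e.g. `r₁=0`) return `None` with a diagnostic
rather than raising.

**Evaluation horizon.** The regime claims (basal α-catenin > 0.5 →
decrease, < 0.3 → increase) pin the boundary to the band [0.3, 0.5] but
the horizon behind them is not stated, so it is a calibrated parameter of
this package. The boundary moves with the horizon — 0.393 at T=1.5, 0.354
at T=2, 0.292 at T=3, 0.207 at T=5 at v_Y=0.5 — so the default is set to
**T = 2.0**, where the boundary (0.354) sits inside the band with margin
on both sides; beyond T ≈ 2.8 it exits the band. The default is exposed
(`DEFAULT_HORIZON`, CLI `--t-end`) and `analysis/03_flip_boundary.py`
writes a (T, v_Y) sensitivity table.

**Windowed correlations.** The time-dependency claim — in low-α-catenin
cells YAP first rises as autophagy falls, then both fall — is quantified
by Pearson correlations of the sampled (Y, A) pairs on two windows split
at the sampled Y maximum (both windows include the peak sample; ties break
to the earliest sample). The Y peak is the model's unique qualitative
changepoint, making it the natural split. Correlations are computed on
the equally spaced sample grid without weighting. Degenerate windows
(endpoint peak, < 10 samples, zero variance) report an undefined
coefficient for that window only.

## Synthetic panels

`generate_panel` emulates the measurement design of the cell-line
experiments: per line, per condition (baseline / autophagy knockdown /
autophagy induction), n replicate scalar readouts of CTNNA1 densitometry
(centred on model `C`) and TEAD luciferase activity (centred on model
`Y`), with known ground truth stored alongside.

* **Regimes:** "high" lines draw basal α-catenin from [0.5, 1.2], "low"
  lines from [0.05, 0.3], mirroring the observed cell-line split; one
  high-regime reference line is pinned at exactly 1.0 (the relative-ratio
  convention against MCF10A-like cells).
* **Conditions:** the knockdown condition is the default model scenario
  itself — the `−cA` term *is* the knockdown — read out at horizon
  `T_kd = 2.0` (the regime horizon). The model has no induction input, so
  induction readouts reuse the model with an elevated initial autophagy
  level (`A_init = 1.5`); this is the A_init-sweep route and the model's
  only handle on induction.
* **Noise:** multiplicative lognormal, `readout = centre·exp(σZ)` with
  `σ² = ln(1+CV²)`, default CV = 0.2 and n = 4 replicates (the published
  experiments report mean ± s.d./s.e.m. over n = 3–6). The distribution
  is *median*-centred on the model value, which makes the geometric-mean
  estimator below unbiased on the log scale and keeps readouts positive.
  CV = 0 degenerates to exact forward-model values. All draws flow from a
  single seed; regeneration is bit-identical.

What the generator does **not** emulate: blot imaging and saturation,
loading-control error, between-day batch effects, correlated replicates,
or any real cell line's actual parameters. Passing inference tests on
these panels therefore shows self-consistency of the pipeline under the
stated noise family, not validity on real densitometry.

## Inference

* **Basal ratio:** geometric mean of a line's baseline CTNNA1 replicates
  divided by the reference line's — the right location estimator under
  multiplicative noise. Monte-Carlo at CV=0.2, n=4 puts the median
  relative error at ≈ 0.10; the test suite freezes 0.15 as the bound.
  `v_Y` is reported as not identifiable from baseline data alone.
* **Time-course fits:** bounded least squares on log-residuals between
  model `Y(t)` and TEAD observations over (α-cat, v_Y) ∈ [0.01, 2] ×
  [0.05, 1.5], multi-started because the log-residual surface develops a
  steep, valley-shaped geometry when `Y` decays through many decades.
  Estimates within 1e-3 of a search bound are flagged. Noiseless series
  are recovered to < 1e-3 in both parameters.
* **Direction prediction** runs the forward model at the estimate and
  classifies at the regime horizon. Estimates inside the unresolved band
  (0.3–0.5) are called "indeterminate" rather than forced into a regime.
  On default panels (10 lines/regime, CV=0.2, n=4) direction prediction
  matches the ground-truth regime for ≥ 90% of unambiguous lines
  (Monte-Carlo over seeds: minimum 95%, mean ~99.8%).

## LIR scanning

The scanner reports every occurrence of the LC3-interacting-region core
consensus `[WFY]xx[ILV]` (overlaps included), in the field's reporting
convention: a hexamer of the 4-residue core plus two upstream flanking
residues, 1-based inclusive coordinates, aromatic residue at hexamer
position 3 and hydrophobic at position 6. Cores within two residues of
the N-terminus report truncated flanks with unchanged core coordinates.
Only the core consensus is implemented — no position-specific scoring,
disorder filtering, or structural (surface-accessibility) filtering — so
a full-length protein scan deliberately returns more raw hits than a
curated candidate list.

## Problem sizes

Default analyses are desk-scale: 400-sample trajectories, 10×10 and 20×20
sweep grids, bisection to 1e-4, panels of 20 lines × 3 conditions × 4
replicates, and Monte-Carlo checks over a few hundred seeds. The full
test suite and the acceptance script each run in well under a minute on
one CPU.

## Known limitations

* The horizon T is a free calibrated parameter; regime labels at other
  horizons differ (sensitivity table in `results/boundary_sensitivity.csv`).
* The model has no autophagy-induction term; induction is approximated by
  raising `A_init`.
* No fitting to real experimental data is attempted anywhere; inference
  is exercised on synthetic panels only.
* The flip boundary is horizon-dependent classification, not a bifurcation
  of the long-run dynamics (for any `C(0)>0, v_Y>0` the long-run `Y` is 0).
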