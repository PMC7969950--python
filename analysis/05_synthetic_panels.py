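#!/usr/bin/env python
"""Generate the synthetic multi-cell-line panel and its summary table.

Emulates the experimental readout design: per line (10 per α-catenin
regime, the MCF10A-like reference pinned at basal ratio 1.0), n = 4
replicate CTNNA1 densitometry and TEAD luciferase readouts under baseline,
autophagy-knockdown and autophagy-induction conditions, with CV = 0.2
lognormal replicate noise.
"""

from pathlib import Path

from catloop import NoiseModel, generate_panel, panel_summary

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

panel = generate_panel(10, NoiseModel(cv=0.2, n_replicates=4, seed=42))
panel.to_csv(OUT / "panel.csv")
summary = panel_summary(panel)
summary.to_csv(OUT / "panel_summary.csv", index=False, float_format="%.6g")

kd = summary[(summary["condition"] == "knockdown") & (summary["readout_type"] == "ctnna1")]
by_regime = kd.groupby("regime")["mean"].mean()
print(f"panel: {len(panel.lines())} lines, {len(panel.data)} readouts -> panel.csv")
print(
    "mean CTNNA1 readout after knockdown by regime: "
    f"low={by_regime['low']:.3f}, high={by_regime['high']:.3f} "
    "(low-α-cat lines accumulate less, as the model predicts)"
)
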