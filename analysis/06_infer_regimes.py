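#!/usr/bin/env python
"""Recover basal α-catenin ratios from the noisy panel and predict each
line's direction of YAP/TAZ response.

The regime logic under test: lines whose estimated basal ratio exceeds 0.5
should respond to autophagy inhibition with decreased YAP/TAZ activity,
lines below 0.3 with increased activity; estimates inside the 0.3–0.5 band
are called indeterminate.
"""

import json
from dataclasses import asdict
from pathlib import Path

from catloop import NoiseModel, generate_panel, panel_estimates
from catloop.inference import AMBIGUOUS_BAND

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

panel = generate_panel(10, NoiseModel(cv=0.2, n_replicates=4, seed=42))
estimates = panel_estimates(panel)

lo, hi = AMBIGUOUS_BAND
ok = total = 0
for name, est in estimates.items():
    truth = panel.truth[name]
    if lo <= truth.alpha_cat_init <= hi:
        continue
    total += 1
    expected = "decrease" if truth.regime == "high" else "increase"
    ok += est.direction == expected

report = {
    "recovery_rate": ok / total,
    "n_unambiguous": total,
    "lines": {name: asdict(est) for name, est in estimates.items()},
}
(OUT / "regime_inference.json").write_text(json.dumps(report, indent=2) + "\n")
print(
    f"direction prediction matched the ground-truth regime for {ok}/{total} "
    f"lines outside the {lo}-{hi} band ({ok / total:.0%}) -> regime_inference.json"
)
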