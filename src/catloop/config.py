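"""Run configuration: flat JSON/YAML blocks mirroring the module surfaces.

Unspecified fields resolve to the published defaults; a fully resolved copy
is written beside every artifact so that any output can be reproduced
exactly from its sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .model_core import InitialState, ModelParameters
from .response import DEFAULT_HORIZON, DEFAULT_TIE_EPS
from .synthetic import NoiseModel

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration for a command-line run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    init: InitialState = field(default_factory=InitialState)
    t_end: float = 10.0
    n_samples: int = 400
    horizon: float = DEFAULT_HORIZON
    tie_eps: float = DEFAULT_TIE_EPS
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_lines_per_regime: int = 10
    seed: int = 0
    outdir: Path = Path(".")

    def resolved(self) -> dict[str, Any]:
        d = {
            "params": asdict(self.params),
            "init": asdict(self.init),
            "t_end": self.t_end,
            "n_samples": self.n_samples,
            "horizon": self.horizon,
            "tie_eps": self.tie_eps,
            "noise": asdict(self.noise),
            "n_lines_per_regime": self.n_lines_per_regime,
            "seed": self.seed,
            "outdir": str(self.outdir),
        }
        return d

    def write_resolved(self, stem: str) -> Path:
        """Write the resolved config sidecar next to an artifact."""
        from . import __version__

        path = Path(self.outdir) / f"{stem}.config.json"
        payload = {"package_version": __version__, **self.resolved()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load a JSON or YAML config file; missing fields take the defaults.

    Keyword overrides (e.g. from CLI flags) win over the file.  Unknown
    keys raise, to catch typos early.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    if "params" in raw:
        kwargs["params"] = ModelParameters(**raw["params"])
    if "init" in raw:
        kwargs["init"] = InitialState(**raw["init"])
    if "noise" in raw:
        kwargs["noise"] = (
            raw["noise"] if isinstance(raw["noise"], NoiseModel) else NoiseModel(**raw["noise"])
        )
    for key in ("t_end", "n_samples", "horizon", "tie_eps", "n_lines_per_regime", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "outdir" in raw:
        kwargs["outdir"] = Path(raw["outdir"])
    return RunConfig(**kwargs)
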