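"""Run configuration: YAML/JSON files with design/observer/analysis sections."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiment_design import DesignConfig
from .model_selection import DEFAULT_CANDIDATES
from .synthetic_observer import ObserverParams


@dataclass(frozen=True)
class RunConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    observer: ObserverParams = field(default_factory=ObserverParams)
    n_subjects: int = 11
    candidates: tuple[tuple[str, ...], ...] = DEFAULT_CANDIDATES
    n_blocks: int = 4
    fit_set: tuple[str, ...] = ("SQ5", "D")

    def to_dict(self) -> dict:
        return {
            "design": {
                "discrepancy_deg": self.design.discrepancy_deg,
                "reps_per_type": self.design.reps_per_type,
                "areas": [list(a) for a in self.design.areas],
                "visual_limit_deg": self.design.visual_limit_deg,
                "auditory_limit_deg": self.design.auditory_limit_deg,
                "seed": self.design.seed,
            },
            "observer": {
                "sigma_V": self.observer.sigma_V,
                "sigma_A": self.observer.sigma_A,
                "capture_fraction": self.observer.capture_fraction,
                "baseline_shift": self.observer.baseline_shift,
                "w_SQ5": self.observer.w_SQ5,
                "w_D": self.observer.w_D,
                "quantize": self.observer.quantize,
            },
            "analysis": {
                "n_subjects": self.n_subjects,
                "candidates": [list(c) for c in self.candidates],
                "n_blocks": self.n_blocks,
                "fit_set": list(self.fit_set),
            },
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML or JSON file; None gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    design_raw = dict(raw.get("design", {}))
    if "areas" in design_raw:
        design_raw["areas"] = tuple(tuple(a) for a in design_raw["areas"])
    analysis = raw.get("analysis", {})
    return RunConfig(
        design=DesignConfig(**design_raw),
        observer=ObserverParams(**raw.get("observer", {})),
        n_subjects=int(analysis.get("n_subjects", 11)),
        candidates=tuple(
            tuple(c) for c in analysis.get("candidates", DEFAULT_CANDIDATES)
        ),
        n_blocks=int(analysis.get("n_blocks", 4)),
        fit_set=tuple(analysis.get("fit_set", ("SQ5", "D"))),
    )
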