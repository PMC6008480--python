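"""Experiment configuration: defaults, validation, YAML round-trip.

Every run resolves to one flat, fully explicit configuration echoing the
model constants (neuron and plasticity tables), the integration step,
the seed and the experiment-specific options, so that any output file
can be reproduced from its config echo alone.  Unspecified model
parameters default to the calibrated table values; unknown keys are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .neuron import NeuronParams
from .plasticity import PlasticityParams

__all__ = ["ExperimentConfig", "load_config", "save_config", "EXPERIMENT_IDS"]

EXPERIMENT_IDS = (
    "voltage_clamp",
    "stdp_window",
    "pair_frequency",
    "net9_rate",
    "net9_temporal",
    "ca3_train_recall",
    "ca3_sequence",
)

_TOP_KEYS = {"experiment", "seed", "dt_ms", "out", "neuron", "plasticity", "options"}


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int = 0
    dt_ms: float = 0.05
    out: str | None = None
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENT_IDS}"
            )
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "dt_ms": self.dt_ms,
            "out": self.out,
            "neuron": self.neuron.to_dict(),
            "plasticity": self.plasticity.to_dict(),
            "options": dict(self.options),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "experiment" not in d:
            raise ValueError("config must name an experiment")
        return cls(
            experiment=d["experiment"],
            seed=int(d.get("seed", 0)),
            dt_ms=float(d.get("dt_ms", 0.05)),
            out=d.get("out"),
            neuron=NeuronParams.from_dict(d.get("neuron") or {}),
            plasticity=PlasticityParams.from_dict(d.get("plasticity") or {}),
            options=dict(d.get("options") or {}),
        )


def load_config(path=None, overrides: dict | None = None) -> ExperimentConfig:
    """Load a YAML config file and/or apply flat override mappings."""
    d: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        d.update(loaded)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if "." in key:  # e.g. "plasticity.kappa"
            section, sub = key.split(".", 1)
            d.setdefault(section, {})[sub] = val
        else:
            d[key] = val
    return ExperimentConfig.from_dict(d)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
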