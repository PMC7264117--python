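"""Experiment configuration: flat YAML files, strict keys, seed expansion.

A single flat mapping covers both models; fields that default differently
per model (sigmoid slope/threshold, peak activation, eye-tuning width) are
``None`` until resolved.  Precedence is CLI flag > file value > default.
Every run writes back a frozen copy of the fully resolved configuration,
and result files carry its hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ExperimentConfig", "config_hash", "spawn_streams"]

EXPERIMENTS = (
    "fig2_curves",
    "fig3_rho_sweep",
    "fig4_multiplicativity",
    "selforg_train",
    "fig7_rho_sweep",
    "fig9_multiplicativity",
)

# model-dependent defaults applied at resolve time
_HARDWIRED = dict(phi_slope=1.9, theta=0.99, h_max=0.485, rho=20.0)
_SELFORG = dict(phi_slope=4.5, theta=0.0, h_max=2.0, rho=15.0)


@dataclass
class ExperimentConfig:
    experiment: str = "fig2_curves"
    outdir: str = "results"
    seed: int = 1
    seeds: tuple = (1, 2, 3)  # for multi-seed stochastic experiments
    # shared tuning parameters (None -> model default)
    sigma: float = 6.0
    rho: float | None = None
    h_max: float | None = None
    phi_slope: float | None = None
    theta: float | None = None
    # sweep lists
    rho_values: tuple = (2.5, 5.0, 10.0, 15.0, 20.0, 25.0)
    # self-organizing network
    n_outputs: int = 100
    tau: float = 0.1
    dt: float | None = None
    learning_rate: float = 0.05
    sparseness_percentile: float = 90.0
    connectivity: float = 10.0
    epochs: int = 10
    schedule_mode: str = "fixation_defined"
    fixation_duration: float = 0.3
    fixations_per_period: int = 15
    saccade_speed: float = 400.0
    learn_during_saccades: bool = True
    # analysis
    multiplicativity_tolerance: float = 0.05
    activity_min: float = 0.1
    range_min: float = 0.05
    plot: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; one of {EXPERIMENTS}"
            )
        if isinstance(self.seeds, list):
            self.seeds = tuple(self.seeds)
        if isinstance(self.rho_values, list):
            self.rho_values = tuple(self.rho_values)

    @property
    def model(self) -> str:
        return (
            "selforg"
            if self.experiment in ("selforg_train", "fig7_rho_sweep",
                                   "fig9_multiplicativity")
            else "hardwired"
        )

    def resolved(self) -> "ExperimentConfig":
        """Fill model-dependent ``None`` fields with that model's defaults."""
        defaults = dict(_SELFORG if self.model == "selforg" else _HARDWIRED)
        # the multiplicativity experiments use their own eye-tuning widths
        if self.experiment == "fig4_multiplicativity":
            defaults["rho"] = 15.0
        elif self.experiment == "fig9_multiplicativity":
            defaults["rho"] = 17.0
        updates = {
            k: defaults[k]
            for k in ("phi_slope", "theta", "h_max", "rho")
            if getattr(self, k) is None
        }
        if self.dt is None:
            updates["dt"] = self.tau / 10.0
        return dataclasses.replace(self, **updates)

    # --- I/O --------------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict, **overrides) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(data)
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat mapping")
        return cls.from_dict(data, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_jsonify(self.to_dict()), sort_keys=True)
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: ExperimentConfig) -> str:
    """Short stable hash of the resolved configuration, for provenance.

    Covers the scientific parameters only: where results are written (and
    whether plots are drawn) does not change what was computed.
    """
    payload = config.resolved().to_dict()
    payload.pop("outdir")
    payload.pop("plot")
    payload = json.dumps(_jsonify(payload), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def spawn_streams(seed: int) -> dict:
    """Expand one global seed into named independent sub-streams.

    The order (connectivity, weights, fixations) is fixed so that changing
    one consumer never perturbs the others.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    return dict(zip(("connectivity", "weights", "fixations"), children))
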