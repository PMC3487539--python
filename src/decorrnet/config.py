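"""Experiment configuration: schema, validation, defaults, hashing.

YAML files with sections ``network / neuron / synapse / drive /
simulation / analysis`` plus a ``scenario`` tag.  Unknown keys are
rejected; missing keys are filled with the package defaults (a
Brunel-type excitatory-inhibitory network).  Every result bundle embeds
the configuration hash so that artifacts are reproducible from
``(config, seed)`` alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigurationError
from .netsim import ExternalDrive, NeuronParams, SynapseSpec

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash",
           "INHIBITORY_DEFAULTS", "EI_DEFAULTS"]

SCENARIOS = ("feedback", "openloop:poissH", "openloop:poissI",
             "openloop:shuff1d", "openloop:shuff2d", "openloop:retype")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSection(_Strict):
    N: int = 4000
    gamma: float = 0.25
    K_E: int = 320
    K_I: int = 80
    topology_seed: int | None = None


class NeuronSection(_Strict):
    tau_m: float = 20.0
    V_th: float = 20.0
    V_r: float = 0.0
    tau_ref: float = 2.0

    @model_validator(mode="after")
    def _check(self):
        NeuronParams(**self.model_dump())   # reuse domain validation
        return self


class SynapseSection(_Strict):
    kernel: Literal["delta", "alpha"] = "delta"
    J: float = 0.2
    g: float = 8.0
    delay: float = 1.0
    tau_s: float | None = None

    @model_validator(mode="after")
    def _check(self):
        SynapseSpec(**self.model_dump())
        return self


class DriveSection(_Strict):
    mu_ext: float = 28.0
    sigma_ext: float = 4.0


class SimulationSection(_Strict):
    duration: float = 52000.0     # ms, includes warmup
    warmup: float = 2000.0        # ms discarded before analysis
    dt: float = 0.1


class AnalysisSection(_Strict):
    bin: float = 0.5              # ms, spectral binning
    frame: float = 1.0            # Hz, moving-average smoothing
    band: tuple[float, float] = (1.0, 10.0)   # Hz, low-frequency band
    window: float = 100.0         # ms, count window for correlations
    n_pairs: int | None = 2000    # pairs per class (None = all pairs)


class ExperimentConfig(_Strict):
    scenario: Literal[SCENARIOS] = "feedback"
    seed: int = 1
    network: NetworkSection = NetworkSection()
    neuron: NeuronSection = NeuronSection()
    synapse: SynapseSection = SynapseSection()
    drive: DriveSection = DriveSection()
    simulation: SimulationSection = SimulationSection()
    analysis: AnalysisSection = AnalysisSection()

    # domain-object accessors -------------------------------------------
    def neuron_params(self) -> NeuronParams:
        return NeuronParams(**self.neuron.model_dump())

    def synapse_spec(self) -> SynapseSpec:
        return SynapseSpec(**self.synapse.model_dump())

    def external_drive(self) -> ExternalDrive:
        return ExternalDrive(**self.drive.model_dump())


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the canonical JSON form."""
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML configuration file.

    Missing keys are filled with defaults; unknown keys and invalid
    values are rejected with a list of all schema violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig(**raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                 for err in exc.errors()]
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(lines)) from None


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


# Frozen default study conditions -------------------------------------------

#: Purely inhibitory random network (strong recurrent inhibition; the
#: low-frequency feedback/feedforward power ratio exceeds three decades).
INHIBITORY_DEFAULTS = dict(
    scenario="feedback",
    network=dict(N=1000, gamma=1.0, K_E=0, K_I=100),
    synapse=dict(kernel="delta", J=1.5, g=1.0, delay=1.0),
    drive=dict(mu_ext=45.0, sigma_ext=2.5),
)

#: Inhibition-dominated excitatory-inhibitory network (Brunel-type).
EI_DEFAULTS = dict(
    scenario="feedback",
    network=dict(N=4000, gamma=0.25, K_E=320, K_I=80),
    synapse=dict(kernel="delta", J=0.2, g=8.0, delay=1.0),
    drive=dict(mu_ext=28.0, sigma_ext=4.0),
)


def make_config(kind: str = "ei", **overrides) -> ExperimentConfig:
    """Build one of the frozen default configurations ('ei' or
    'inhibitory'), optionally overriding top-level sections."""
    base = {"ei": EI_DEFAULTS, "inhibitory": INHIBITORY_DEFAULTS}[kind]
    merged = {**{k: (dict(v) if isinstance(v, dict) else v)
                 for k, v in base.items()}}
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return ExperimentConfig(**merged)
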