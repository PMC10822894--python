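"""Pipeline configuration: nested dataclasses with strict YAML round-tripping.

Unknown keys are rejected so a typo in a config file fails loudly instead
of silently running defaults.  ``config_hash`` gives a short stable digest
used in output paths for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class SimSection:
    n_patients: int = 36
    n_controls: int = 40
    n_timepoints: int = 170
    n_components: int = 12
    noise_sd: float = 1.0
    stay_patient: list = field(default_factory=lambda: [0.99, 0.97])
    stay_control: list = field(default_factory=lambda: [0.97, 0.97])
    effect_attenuation: float = 0.5
    clinical_coupling: float = 10.0


@dataclass
class WindowSection:
    width: int = 18
    step: int = 2


@dataclass
class MVARSection:
    order: int = 1
    ridge: float = 0.1
    mode: str = "coef"


@dataclass
class ClusterSection:
    k: int = 2
    metric: str = "l2"
    n_init: int = 10
    zscore: bool = False


@dataclass
class InferenceSection:
    n_perm: int = 1000
    primary_t: float = 3.0
    alpha: float = 0.05
    clinical_vars: list = field(default_factory=lambda: ["HbA1c", "MoCA", "DBP", "education"])


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run from (config, seed)."""

    seed: int = 0
    outdir: str = "out"
    input_dir: str | None = None  # when set, ingest TSV cohort instead of simulating
    run_reliability: bool = True
    reliability_windows: list = field(default_factory=lambda: [[30, 1], [12, 3]])
    use_abs_degree: bool = True
    sim: SimSection = field(default_factory=SimSection)
    window: WindowSection = field(default_factory=WindowSection)
    mvar: MVARSection = field(default_factory=MVARSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    inference: InferenceSection = field(default_factory=InferenceSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


_SECTIONS = {
    "sim": SimSection,
    "window": WindowSection,
    "mvar": MVARSection,
    "cluster": ClusterSection,
    "inference": InferenceSection,
}


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for key, cls in _SECTIONS.items():
        section = data.pop(key, None)
        if section is not None:
            if not isinstance(section, dict):
                raise ParameterError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build(cls, section, key)
    top = _build(PipelineConfig, {**data, **kwargs}, "top level")
    return top


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError("config file must contain a YAML mapping")
    return config_from_dict(raw)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the config (seed included)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:8]
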