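"""Pipeline configuration: schema, defaults and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class SyntheticSettings:
    n_diseases: int = 10
    n_studies_per_disease: int = 3
    n_genes: int = 500
    n_case: int = 20
    n_control: int = 20
    n_signal_genes: int = 50
    effect_size: float = 1.0
    tau2: float = 0.05
    n_pathway_sets: int = 10
    n_tf_sets: int = 6
    n_mirna_sets: int = 6
    set_size: int = 25
    n_celltypes: int = 5
    panel_size: int = 30


@dataclass
class FilterSettings:
    min_patients: int = 4
    baseline_only: bool = True
    untreated_only: bool = True


@dataclass
class FeatureSettings:
    alpha: float = 0.25
    min_overlap: int = 5


@dataclass
class MetaSettings:
    fdr_threshold: float = 0.05
    min_studies: int = 1


@dataclass
class ModuleSettings:
    k: int = 15
    linkage: str = "ward"
    n_perturbations: int = 30
    n_null: int = 19
    noise_sd_fraction: float = 0.1


@dataclass
class ValidationSettings:
    n_perm: int = 200


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticSettings = field(default_factory=SyntheticSettings)
    filters: FilterSettings = field(default_factory=FilterSettings)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    meta: MetaSettings = field(default_factory=MetaSettings)
    modules: ModuleSettings = field(default_factory=ModuleSettings)
    validation: ValidationSettings = field(default_factory=ValidationSettings)

    def validate(self) -> None:
        s = self.synthetic
        if s.n_diseases < 2:
            raise ConfigError("synthetic.n_diseases must be >= 2")
        if s.n_studies_per_disease < 1:
            raise ConfigError("synthetic.n_studies_per_disease must be >= 1")
        if s.n_case < 2 or s.n_control < 2:
            raise ConfigError("synthetic group sizes must be >= 2")
        if not 0 <= s.n_signal_genes <= s.n_genes:
            raise ConfigError("synthetic.n_signal_genes must lie in [0, n_genes]")
        if s.tau2 < 0:
            raise ConfigError("synthetic.tau2 must be >= 0")
        if self.modules.k < 1:
            raise ConfigError("modules.k must be >= 1")
        if self.modules.linkage not in ("average", "complete", "ward", "single"):
            raise ConfigError(f"unknown linkage {self.modules.linkage!r}")
        if not 0 < self.meta.fdr_threshold < 1:
            raise ConfigError("meta.fdr_threshold must lie in (0, 1)")
        if self.validation.n_perm < 100:
            raise ConfigError("validation.n_perm must be >= 100")
        if not 0 <= self.features.alpha:
            raise ConfigError("features.alpha must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "synthetic": SyntheticSettings,
    "filters": FilterSettings,
    "features": FeatureSettings,
    "meta": MetaSettings,
    "modules": ModuleSettings,
    "validation": ValidationSettings,
}


def config_from_dict(payload: dict) -> PipelineConfig:
    payload = dict(payload or {})
    kwargs = {}
    unknown = set(payload) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for name, cls in _SECTIONS.items():
        section = payload.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(section) - valid
        if bad:
            raise ConfigError(f"unknown keys in config section {name!r}: {sorted(bad)}")
        kwargs[name] = cls(**section)
    config = PipelineConfig(seed=int(payload.get("seed", 0)), **kwargs)
    config.validate()
    return config


def load_config(path) -> PipelineConfig:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config_from_dict(payload)
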