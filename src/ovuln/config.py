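"""Shipped defaults and YAML configuration.

Every decision constant in the pipeline lives here with its shipped
default; a YAML config with matching sections overrides any subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class TruthConfig:
    hrd_cutoff: int = 63
    sig3_cutoff: float = 0.25
    methylation_cutoff: float = 0.7


@dataclass
class VariantConfig:
    min_callers: int = 2
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.05
    exome_size_mb: float = 30.0
    weak_rank: float = 2.0
    strong_rank: float = 0.5


@dataclass
class ClassifierConfig:
    top_k: int = 50
    min_votes: int = 2
    rfe_step: float = 0.2
    n_folds: int = 10
    n_estimators: int = 200
    bulk_cutoff: float = 0.5266
    cell_cutoff: float = 0.45


@dataclass
class VulnerabilityConfig:
    c2c_location: float = 0.301
    c2c_scale: float = 0.0433
    w_brca: float = 2.597
    w_c2c: float = 1.166


@dataclass
class Config:
    truth: TruthConfig = field(default_factory=TruthConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    vulnerability: VulnerabilityConfig = field(default_factory=VulnerabilityConfig)


def load_config(path: str | None) -> Config:
    """Load a YAML config; missing sections/keys keep their defaults."""
    cfg = Config()
    if path is None:
        return cfg
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for section_field in fields(cfg):
        section = getattr(cfg, section_field.name)
        overrides = raw.get(section_field.name) or {}
        known = {f.name for f in fields(section)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(
                f"unknown keys in config section {section_field.name!r}: {sorted(unknown)}"
            )
        for k, v in overrides.items():
            setattr(section, k, type(getattr(section, k))(v))
    return cfg
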