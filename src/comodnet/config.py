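"""Pipeline configuration: one flat mapping drives every stage.

Defaults are the reference analytical settings (4 replicate spots per
feature, 5% fold-change pivot, soft-power grid 1..20, cut height 0.995,
deep split 2, minimum module size 5, PPI confidence 0.15, top-20 trait
features). Unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

from .errors import ParameterError
from .io import load_yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    region: str = "CTX"

    # study design / simulation
    n_per_group: int = 7
    n_mirna_features: int = 500
    n_protein_features: int = 250
    noise_sd: float = 0.6
    replicate_noise_sd: float = 0.3
    n_replicates: int = 4
    flag_rate: float = 0.02
    n_decoy_targets: int = 50
    ppi_density: float = 0.01

    # optional external inputs (simulation used when unset)
    mirna_tsv: str | None = None
    protein_tsv: str | None = None
    design_tsv: str | None = None
    targets_tsv: str | None = None
    ppi_tsv: str | None = None

    # preprocessing
    max_missing_fraction: float = 0.25

    # differential expression
    fc_threshold: float = 0.05
    p_threshold: float = 0.05

    # coexpression
    beta: int | None = None  # None = automatic soft-power selection
    beta_min: int = 1
    beta_max: int = 20
    cut_height: float = 0.995
    deep_split: int = 2
    min_module_size: int = 5
    dissimilarity: str = "tom"

    # integration
    trait_p_max: float = 0.05
    trait_r_min: float = 0.5
    top_k: int = 20
    r_screen: float = 0.5

    # network
    ppi_min: float = 0.15
    hub_k: int = 10

    def __post_init__(self) -> None:
        if self.region not in ("CTX", "MB"):
            raise ParameterError("region must be CTX or MB")
        if self.beta_min < 1 or self.beta_max < self.beta_min:
            raise ParameterError("invalid soft-power grid")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(load_yaml(path))

    def to_dict(self) -> dict:
        return asdict(self)

    def override(self, **kwargs) -> "PipelineConfig":
        data = self.to_dict()
        for key, value in kwargs.items():
            if value is None:
                continue
            if key not in data:
                raise ParameterError(f"unknown config key: {key}")
            data[key] = value
        return PipelineConfig.from_dict(data)
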