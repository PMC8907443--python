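"""Pipeline configuration: one serializable object driving every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .bed import DEFAULT_TARGET_LEVELS
from .preprocessing import NormalizationParams
from .radiomics.texture import DiscretizationParams
from .synthetic_cohort import CohortConfig, DecayParams


@dataclass(frozen=True)
class BedConfig:
    dose_per_fraction: float = 2.2
    n_fractions_total: int = 25
    alpha_beta: float = 10.0
    target_levels: tuple[float, ...] = DEFAULT_TARGET_LEVELS
    rule: str = "nearest"


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    n_boot: int = 2000
    seed: int = 0
    pair_mode: str = "anchored"
    pair_top_k: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bed: BedConfig = field(default_factory=BedConfig)
    preprocessing: NormalizationParams = field(default_factory=NormalizationParams)
    discretization: DiscretizationParams = field(default_factory=DiscretizationParams)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, block: dict):
            names = {f.name for f in fields(klass)}
            unknown = set(block) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**block)

        cohort_block = dict(d.get("cohort", {}))
        if "responder_decay" in cohort_block:
            cohort_block["responder_decay"] = build(
                DecayParams, dict(cohort_block["responder_decay"])
            )
        for tup_key in ("voxel_spacing", "image_shape"):
            if tup_key in cohort_block:
                cohort_block[tup_key] = tuple(cohort_block[tup_key])
        bed_block = dict(d.get("bed", {}))
        if "target_levels" in bed_block:
            bed_block["target_levels"] = tuple(bed_block["target_levels"])
        return cls(
            cohort=build(CohortConfig, cohort_block),
            bed=build(BedConfig, bed_block),
            preprocessing=build(NormalizationParams, dict(d.get("preprocessing", {}))),
            discretization=build(DiscretizationParams, dict(d.get("discretization", {}))),
            stats=build(StatsConfig, dict(d.get("stats", {}))),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "PipelineConfig":
        from dataclasses import replace

        return replace(
            self,
            cohort=replace(self.cohort, rng_seed=seed),
            stats=replace(self.stats, seed=seed),
        )
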