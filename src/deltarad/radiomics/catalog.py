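"""The versioned feature catalog: which features are extracted, in order.

The default catalog has exactly 97 features (15 morphological, 22 first-order,
60 textural), so a 6-timepoint series yields 582 basal values and the 5
post-baseline timepoints yield 485 delta values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .firstorder import FIRSTORDER_FEATURES
from .morphology import MORPHOLOGY_FEATURES
from .texture import GLCM_FEATURES, GLRLM_FEATURES

DEFAULT_GLCM_DISTANCES = (1, 2)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str  # 'morphology' | 'firstorder' | 'texture'
    params: tuple = ()


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, unique feature descriptors; defaults to the 97-feature set."""

    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.descriptors)

    @property
    def size(self) -> int:
        return len(self.descriptors)

    def subset(self, families: set[str]) -> "FeatureCatalog":
        return FeatureCatalog(
            tuple(d for d in self.descriptors if d.family in families)
        )

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"name": d.name, "family": d.family, "params": list(d.params)}
            for d in self.descriptors
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(
                FeatureDescriptor(d["name"], d["family"], tuple(d["params"]))
                for d in payload
            )
        )


def default_catalog() -> FeatureCatalog:
    """The default 97-feature catalog (15 + 22 + 25x2 GLCM + 10 GLRLM)."""
    desc: list[FeatureDescriptor] = []
    for name in MORPHOLOGY_FEATURES:
        desc.append(FeatureDescriptor(name, "morphology"))
    for name in FIRSTORDER_FEATURES:
        desc.append(FeatureDescriptor(name, "firstorder"))
    for dist in DEFAULT_GLCM_DISTANCES:
        for name in GLCM_FEATURES:
            desc.append(
                FeatureDescriptor(f"GLCM_d{dist}_{name}", "texture", ("glcm", dist))
            )
    for name in GLRLM_FEATURES:
        desc.append(FeatureDescriptor(f"GLRLM_{name}", "texture", ("glrlm",)))
    return FeatureCatalog(tuple(desc))
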