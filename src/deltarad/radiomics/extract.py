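"""Per-timepoint feature extraction for a patient series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..preprocessing import NormalizationParams, normalize
from ..series import PatientSeries
from .catalog import FeatureCatalog, default_catalog
from .firstorder import firstorder_features
from .morphology import morphology_features
from .texture import DiscretizationParams, glcm_features, glrlm_features


@dataclass
class FeatureVector:
    """All catalog feature values for one (patient, timepoint)."""

    patient_id: str
    bed_gy: float
    values: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _glcm_distances(catalog: FeatureCatalog) -> tuple[int, ...]:
    return tuple(
        sorted({d.params[1] for d in catalog.descriptors if d.params[:1] == ("glcm",)})
    )


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing,
    catalog: FeatureCatalog | None = None,
    norm: NormalizationParams = NormalizationParams(),
    disc: DiscretizationParams = DiscretizationParams(),
) -> dict[str, float]:
    """Extract every catalog feature for one (image, mask) pair.

    The image is normalized first; intensity features are computed inside the
    ROI only. Per-feature failures surface as NaN rather than aborting.
    """
    catalog = catalog or default_catalog()
    families = {d.family for d in catalog.descriptors}
    pool: dict[str, float] = {}

    if "morphology" in families:
        pool.update(morphology_features(mask, spacing))

    if "firstorder" in families or "texture" in families:
        vol = normalize(volume, norm, mask=mask)
        if "firstorder" in families:
            pool.update(
                firstorder_features(vol, mask, disc, voxel_volume=float(np.prod(spacing)))
            )
        if "texture" in families:
            for dist in _glcm_distances(catalog):
                try:
                    g = glcm_features(vol, mask, disc, distance=dist)
                except ValueError:
                    g = {}
                pool.update({f"GLCM_d{dist}_{k}": v for k, v in g.items()})
            pool.update(
                {f"GLRLM_{k}": v for k, v in glrlm_features(vol, mask, disc).items()}
            )

    return {name: pool.get(name, np.nan) for name in catalog.names}


def extract_catalog(
    series: PatientSeries,
    catalog: FeatureCatalog | None = None,
    norm: NormalizationParams = NormalizationParams(),
    disc: DiscretizationParams = DiscretizationParams(),
) -> list[FeatureVector]:
    """One complete FeatureVector per timepoint of the series."""
    catalog = catalog or default_catalog()
    prov = {
        "normalization": norm.method,
        "discretization": disc.strategy,
        "n_bins": disc.n_bins,
        "catalog_size": catalog.size,
    }
    out = []
    for volume, mask, bed in zip(series.volumes, series.masks, series.bed_levels):
        values = extract_features(volume, mask, series.spacing, catalog, norm, disc)
        out.append(
            FeatureVector(
                patient_id=series.patient_id,
                bed_gy=float(bed),
                values=values,
                provenance=dict(prov),
            )
        )
    return out
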