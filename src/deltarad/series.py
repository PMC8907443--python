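"""Core longitudinal data container: one patient's image/mask series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PatientSeries:
    """Co-registered volumes and GTV masks over the BED-aligned timepoints.

    ``bed_levels`` is aligned to ``volumes``/``masks``; the first entry is 0
    (simulation). Masks are binary (nonzero = ROI) and every mask must be
    nonempty.
    """

    patient_id: str
    volumes: list[np.ndarray]
    masks: list[np.ndarray]
    bed_levels: list[float]
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.volumes) == len(self.masks) == len(self.bed_levels)):
            raise ValueError(
                f"{self.patient_id}: volumes/masks/bed_levels lengths differ "
                f"({len(self.volumes)}/{len(self.masks)}/{len(self.bed_levels)})"
            )
        if len(self.volumes) == 0:
            raise ValueError(f"{self.patient_id}: empty series")
        beds = np.asarray(self.bed_levels, dtype=float)
        if np.any(np.diff(beds) <= 0):
            raise ValueError(f"{self.patient_id}: bed_levels not strictly increasing")
        shape = self.volumes[0].shape
        for t, (v, m) in enumerate(zip(self.volumes, self.masks)):
            if v.shape != shape or m.shape != shape:
                raise ValueError(
                    f"{self.patient_id}: timepoint {t} shape mismatch "
                    f"(volume {v.shape}, mask {m.shape}, expected {shape})"
                )
            if not np.any(m):
                raise ValueError(f"{self.patient_id}: timepoint {t} has empty mask")

    @property
    def n_timepoints(self) -> int:
        return len(self.volumes)

    def mask_volumes_mm3(self) -> list[float]:
        """GTV volume per timepoint (voxel count times voxel volume)."""
        vv = float(np.prod(self.spacing))
        return [float(np.count_nonzero(m)) * vv for m in self.masks]
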