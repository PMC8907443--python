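"""NIfTI + manifest I/O: persist and reload cohorts as plain artifacts."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .series import PatientSeries

MANIFEST_COLUMNS = ("patient_id", "timepoint", "bed_gy", "image_path", "mask_path")


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Checks: required columns, unique (patient_id, timepoint), and a BED=0
    (simulation) row for every patient. Paths are kept relative; they are
    resolved against the manifest location at load time.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (patient_id, timepoint) rows in manifest")
    for pid, grp in df.groupby("patient_id"):
        if not (grp["bed_gy"] == 0).any():
            raise ValueError(f"{pid}: no BED=0 timepoint in manifest")
    df.attrs["manifest_dir"] = str(path.parent)
    return df


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_series(manifest: pd.DataFrame, patient_id: str) -> PatientSeries:
    """Assemble one patient's series from a loaded manifest.

    Masks are binarized (nonzero -> 1); timepoints are sorted by BED.
    Geometry mismatches raise errors naming the offending timepoint.
    """
    rows = manifest[manifest["patient_id"] == patient_id]
    if rows.empty:
        raise ValueError(f"{patient_id}: not present in manifest")
    base = Path(manifest.attrs.get("manifest_dir", "."))
    rows = rows.sort_values("bed_gy")

    volumes, masks, beds = [], [], []
    spacing = None
    for _, row in rows.iterrows():
        t = int(row["timepoint"])
        vol, sp_v = _read_nifti(base / row["image_path"])
        msk, sp_m = _read_nifti(base / row["mask_path"])
        if vol.shape != msk.shape:
            raise ValueError(
                f"{patient_id} timepoint {t}: image shape {vol.shape} != mask shape {msk.shape}"
            )
        if not np.allclose(sp_v, sp_m, atol=1e-5):
            raise ValueError(
                f"{patient_id} timepoint {t}: image spacing {sp_v} != mask spacing {sp_m}"
            )
        if spacing is None:
            spacing = sp_v
        elif not np.allclose(spacing, sp_v, atol=1e-5):
            raise ValueError(f"{patient_id} timepoint {t}: spacing differs across timepoints")
        binary = (msk != 0).astype(np.uint8)
        if not binary.any():
            raise ValueError(f"{patient_id} timepoint {t}: empty mask")
        volumes.append(vol)
        masks.append(binary)
        beds.append(float(row["bed_gy"]))
    return PatientSeries(
        patient_id=str(patient_id),
        volumes=volumes,
        masks=masks,
        bed_levels=beds,
        spacing=spacing,  # type: ignore[arg-type]
    )


def write_series(
    series: PatientSeries, outdir: str | Path, compress: bool = True
) -> list[dict]:
    """Write one series as NIfTI pairs; returns its manifest rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(series.spacing) + [1.0])
    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for t, (vol, msk, bed) in enumerate(
        zip(series.volumes, series.masks, series.bed_levels)
    ):
        img_name = f"{series.patient_id}_t{t}_img{ext}"
        msk_name = f"{series.patient_id}_t{t}_msk{ext}"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(outdir / img_name))
        nib.save(nib.Nifti1Image(np.asarray(msk, dtype=np.uint8), affine), str(outdir / msk_name))
        rows.append(
            {
                "patient_id": series.patient_id,
                "timepoint": t,
                "bed_gy": float(bed),
                "image_path": img_name,
                "mask_path": msk_name,
            }
        )
    return rows


def write_cohort(
    series_list: list[PatientSeries], outdir: str | Path, compress: bool = True
) -> Path:
    """Write a cohort of series plus ``manifest.csv``; returns the manifest path."""
    outdir = Path(outdir)
    rows: list[dict] = []
    for s in series_list:
        rows.extend(write_series(s, outdir, compress=compress))
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)
    return manifest_path
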