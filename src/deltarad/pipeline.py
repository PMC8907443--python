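"""Stage orchestration: simulate -> extract -> delta -> screen -> fit -> report.

Every stage reads/writes plain artifacts (CSV + NIfTI) under one output
directory and embeds the run's config hash as a ``# config_sha256=...``
comment line, so any stage can be inspected or replaced.
"""

from __future__ import annotations

import json
import logging
import re
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import delta as delta_mod
from . import eri as eri_mod
from . import imaging_io, stats_model
from .config import PipelineConfig
from .radiomics import default_catalog
from .radiomics.extract import FeatureVector, extract_catalog
from .synthetic_cohort import clinical_frame, simulate_cohort, summarize_cohort

log = logging.getLogger("deltarad")

STAGES = ("simulate", "extract", "delta", "screen", "fit", "report", "all")

_UPSTREAM = {
    "extract": ("cohort/manifest.csv", "simulate"),
    "delta": ("features_basal.csv", "extract"),
    "screen": ("features_delta.csv", "delta"),
    "fit": ("features_delta.csv", "delta"),
    "report": ("models_table2.csv", "fit"),
}


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(f"# config_sha256={cfg_hash}\n")
        df.to_csv(fh, index=index)
    tmp.replace(path)


def _read_csv(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def _require(out: Path, stage: str) -> None:
    artifact, producer = _UPSTREAM[stage]
    if not (out / artifact).exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {artifact}; run stage '{producer}' first"
        )


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    t0 = time.perf_counter()
    series_list, records = simulate_cohort(config.cohort)
    h = config.config_hash()
    imaging_io.write_cohort(series_list, out / "cohort")
    _write_csv(clinical_frame(records, encoded=True), out / "clinical.csv", h)
    _write_csv(clinical_frame(records, encoded=False), out / "clinical_raw.csv", h)
    _write_csv(summarize_cohort(records), out / "cohort_summary.csv", h, index=False)
    n_events = sum(1 - r.outcome_2ydfs for r in records)
    log.info(
        "simulate: %d patients, %d events, %.1fs",
        len(records), n_events, time.perf_counter() - t0,
    )


def stage_extract(config: PipelineConfig, out: Path) -> None:
    _require(out, "extract")
    t0 = time.perf_counter()
    manifest = imaging_io.load_manifest(out / "cohort" / "manifest.csv")
    catalog = default_catalog()
    rows_long = []
    basal: dict[str, list[FeatureVector]] = {}
    for pid in manifest["patient_id"].unique():
        series = imaging_io.load_series(manifest, pid)
        fvs = extract_catalog(
            series, catalog, norm=config.preprocessing, disc=config.discretization
        )
        basal[pid] = fvs
        for fv in fvs:
            for name, value in fv.values.items():
                rows_long.append((pid, fv.bed_gy, name, value))
    h = config.config_hash()
    _write_csv(delta_mod.basal_frame(basal), out / "features_basal.csv", h)
    _write_csv(
        pd.DataFrame(rows_long, columns=["patient_id", "bed_gy", "feature", "value"]),
        out / "features_long.csv", h, index=False,
    )
    log.info(
        "extract: %d patients x %d features, %.1fs",
        len(basal), catalog.size, time.perf_counter() - t0,
    )


_BASAL_RE = re.compile(r"^(?P<name>.+)@bed(?P<level>\d+)$")


def basal_wide_to_vectors(df: pd.DataFrame) -> dict[str, list[FeatureVector]]:
    """Reconstruct per-timepoint FeatureVectors from the wide basal CSV."""
    parsed = []
    for col in df.columns:
        m = _BASAL_RE.match(col)
        if m:
            parsed.append((col, m.group("name"), float(m.group("level"))))
    out: dict[str, list[FeatureVector]] = {}
    for pid, row in df.iterrows():
        by_level: dict[float, dict[str, float]] = {}
        for col, name, level in parsed:
            by_level.setdefault(level, {})[name] = row[col]
        out[str(pid)] = [
            FeatureVector(patient_id=str(pid), bed_gy=lv, values=vals)
            for lv, vals in sorted(by_level.items())
        ]
    return out


def stage_delta(config: PipelineConfig, out: Path) -> None:
    _require(out, "delta")
    basal = basal_wide_to_vectors(_read_csv(out / "features_basal.csv"))
    deltas = {pid: delta_mod.delta_features(fvs) for pid, fvs in basal.items()}
    df = pd.DataFrame.from_dict(
        {pid: dv.values for pid, dv in deltas.items()}, orient="index"
    )
    _write_csv(df, out / "features_delta.csv", config.config_hash())
    log.info("delta: %d patients x %d delta features", *df.shape)


def _load_table(out: Path) -> delta_mod.FeatureTable:
    basal = basal_wide_to_vectors(_read_csv(out / "features_basal.csv"))
    deltas = {pid: delta_mod.delta_features(fvs) for pid, fvs in basal.items()}
    clinical = _read_csv(out / "clinical.csv")
    clinical.index = clinical.index.astype(str)
    return delta_mod.assemble_variable_table(basal, deltas, clinical)


def stage_screen(config: PipelineConfig, out: Path) -> None:
    _require(out, "screen")
    table = _load_table(out)
    sr = stats_model.screen(table, alpha=config.stats.alpha)
    h = config.config_hash()
    _write_csv(sr.table, out / "screening.csv", h)
    _write_csv(sr.pcc_matrix, out / "screening_pcc.csv", h)
    log.info(
        "screen: %d tested, %d significant (expected false positives %.1f)",
        sr.n_tested, len(sr.significant), sr.expected_false_positives,
    )


def stage_fit(config: PipelineConfig, out: Path) -> None:
    _require(out, "fit")
    table = _load_table(out)
    st = config.stats
    reports = stats_model.build_models(
        table, alpha=st.alpha, n_boot=st.n_boot, seed=st.seed
    )
    h = config.config_hash()
    _write_csv(stats_model.model_reports_to_frame(reports), out / "models_table2.csv", h)
    payload = {
        "config_sha256": h,
        "models": [
            {
                "model_id": r.model_id,
                "variables": r.variables,
                "coefficients": r.coefficients,
                "auc": r.auc,
                "ci": [r.ci_low, r.ci_high],
                "threshold": r.threshold,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "youden_j": r.youden_j,
                "n_boot": r.n_boot,
                "flags": r.flags,
                "roc": {"fpr": r.fpr.tolist(), "tpr": r.tpr.tolist()},
            }
            for r in reports
        ],
    }
    (out / "models.json").write_text(json.dumps(payload, indent=1))
    log.info("fit: %d models, best AUCs %s",
             len(reports), [round(r.auc, 3) for r in reports])


def stage_report(config: PipelineConfig, out: Path) -> None:
    _require(out, "report")
    # ERI per level from the basal Volume columns
    basal = _read_csv(out / "features_basal.csv")
    clinical = _read_csv(out / "clinical.csv")
    clinical.index = clinical.index.astype(str)
    basal.index = basal.index.astype(str)
    vol_cols = {
        float(m.group("level")): c
        for c in basal.columns
        if (m := _BASAL_RE.match(c)) and m.group("name") == "Volume"
    }
    levels = sorted(vol_cols)
    eri_vals = pd.DataFrame(index=basal.index, dtype=float)
    v0 = basal[vol_cols[levels[0]]]
    for lv in levels[1:]:
        eri_vals[lv] = [
            eri_mod.eri_tcp(a, b) for a, b in zip(v0, basal[vol_cols[lv]])
        ]
    pvals = eri_mod.eri_screen(eri_vals, clinical["dfs2y"])
    h = config.config_hash()
    _write_csv(eri_vals, out / "eri.csv", h)
    _write_csv(pvals.to_frame(), out / "eri_pvalues.csv", h)
    best = pvals.idxmin() if pvals.notna().any() else None
    log.info("report: ERI best level %s (p=%s)", best,
             None if best is None else round(float(pvals[best]), 4))


def run(stage: str, config: PipelineConfig, out: str | Path) -> None:
    """Run one pipeline stage (or ``all``) against the output directory."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    chain = (
        ["simulate", "extract", "delta", "screen", "fit", "report"]
        if stage == "all"
        else [stage]
    )
    for st in chain:
        {
            "simulate": stage_simulate,
            "extract": stage_extract,
            "delta": stage_delta,
            "screen": stage_screen,
            "fit": stage_fit,
            "report": stage_report,
        }[st](config, out)
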