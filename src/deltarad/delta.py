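"""Delta features (per-timepoint / simulation ratios) and the variable table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiomics.extract import FeatureVector

#: Features whose values can legitimately cross zero; their ratios are
#: computed as defined but tagged unstable in reports.
RATIO_UNSTABLE = frozenset(
    {
        "Mean",
        "Minimum",
        "Maximum",
        "P10",
        "P25",
        "Median",
        "P75",
        "P90",
        "Skewness",
        "CoeffVariation",
    }
)

#: |baseline| below this is treated as zero: the ratio is flagged missing.
ZERO_TOL = 1e-9

OUTCOME_COLUMN = "dfs2y"


def is_ratio_unstable(feature_name: str) -> bool:
    base = feature_name.split("_")[-1]
    return feature_name in RATIO_UNSTABLE or base in {"ClusterShade", "InfoMeasureCorr1", "Correlation"}


def delta_name(feature: str, k: int) -> str:
    """Column name for the delta of ``feature`` at the k-th post-baseline level."""
    return f"{feature}(d{k})"


def basal_name(feature: str, bed_gy: float) -> str:
    level = int(round(bed_gy))
    return f"{feature}@bed{level}"


@dataclass
class DeltaFeatureVector:
    """Per-patient delta ratios, keyed ``<feature>(d<k>)`` for k = 1..T-1."""

    patient_id: str
    values: dict[str, float]
    bed_levels: list[float] = field(default_factory=list)
    unstable: frozenset[str] = frozenset()

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def delta_features(basal: list[FeatureVector]) -> DeltaFeatureVector:
    """Ratios of each post-baseline timepoint's features to the simulation values.

    The simulation timepoint is the one with BED 0 (required). Ratios with a
    near-zero baseline are flagged missing (NaN), never +/-inf.
    """
    if not basal:
        raise ValueError("no feature vectors given")
    ordered = sorted(basal, key=lambda fv: fv.bed_gy)
    if abs(ordered[0].bed_gy) > ZERO_TOL:
        raise ValueError(
            f"{ordered[0].patient_id}: missing simulation (BED=0) timepoint"
        )
    sim = ordered[0]
    values: dict[str, float] = {}
    unstable = set()
    for k, fv in enumerate(ordered[1:], start=1):
        for name, v in fv.values.items():
            v0 = sim.values.get(name, np.nan)
            col = delta_name(name, k)
            if not np.isfinite(v) or not np.isfinite(v0) or abs(v0) < ZERO_TOL:
                values[col] = np.nan
            else:
                values[col] = v / v0
            if is_ratio_unstable(name):
                unstable.add(col)
    return DeltaFeatureVector(
        patient_id=sim.patient_id,
        values=values,
        bed_levels=[fv.bed_gy for fv in ordered],
        unstable=frozenset(unstable),
    )


@dataclass
class FeatureTable:
    """Patients x variables matrix with per-column provenance.

    ``column_classes`` maps each predictor column to 'basal', 'delta' or
    'clinical'; the outcome column (``dfs2y``) is separate.
    """

    data: pd.DataFrame
    column_classes: dict[str, str]
    outcome: str = OUTCOME_COLUMN

    def __post_init__(self) -> None:
        missing = set(self.column_classes) - set(self.data.columns)
        if missing:
            raise ValueError(f"tagged columns absent from table: {sorted(missing)}")

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c in self.column_classes]

    def columns_of_class(self, cls: str) -> list[str]:
        return [c for c in self.predictors if self.column_classes[c] == cls]

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy()


def basal_frame(basal: dict[str, list[FeatureVector]]) -> pd.DataFrame:
    """Wide per-patient frame of basal features, columns ``<feature>@bed<level>``."""
    rows = {}
    for pid, fvs in basal.items():
        row = {}
        for fv in sorted(fvs, key=lambda f: f.bed_gy):
            for name, v in fv.values.items():
                row[basal_name(name, fv.bed_gy)] = v
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def assemble_variable_table(
    basal: dict[str, list[FeatureVector]],
    delta: dict[str, DeltaFeatureVector],
    clinical: pd.DataFrame,
    outcome: pd.Series | None = None,
) -> FeatureTable:
    """Combine basal RF, delta RF and clinical covariates into one table.

    ``clinical`` is indexed by patient id; ``outcome`` (binary, 1 =
    disease-free) may instead be a ``dfs2y`` column of ``clinical``.
    Every patient must be present in all blocks.
    """
    bf = basal_frame(basal)
    df_delta = pd.DataFrame.from_dict(
        {pid: dv.values for pid, dv in delta.items()}, orient="index"
    )
    clin = clinical.copy()
    if outcome is None:
        if OUTCOME_COLUMN not in clin.columns:
            raise ValueError("no outcome given and clinical table lacks 'dfs2y'")
        outcome = clin.pop(OUTCOME_COLUMN)

    ids = list(bf.index)
    for block_name, block in (("delta", df_delta), ("clinical", clin), ("outcome", outcome.to_frame())):
        missing = sorted(set(ids) - set(block.index))
        if missing:
            raise ValueError(f"patients missing from {block_name} block: {missing}")

    table = pd.concat(
        [bf, df_delta.loc[ids], clin.loc[ids]], axis=1
    )
    table[OUTCOME_COLUMN] = outcome.loc[ids].astype(int)
    classes = {c: "basal" for c in bf.columns}
    classes.update({c: "delta" for c in df_delta.columns})
    classes.update({c: "clinical" for c in clin.columns})
    return FeatureTable(data=table, column_classes=classes)
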