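"""Early regression index (ERI) from GTV volumes, and its per-level screening."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .series import PatientSeries
from .stats_model import wmw_test


def _neg_log_regression(v0: float, vt: float) -> float:
    dv = v0 - vt
    if dv <= 0:  # no regression or growth: undefined by convention
        return np.nan
    return float(-np.log(dv / v0))


#: Named ERI formula variants; the default maps complete regression to 0 and
#: increases as the regressed fraction shrinks.
ERI_FORMS: dict[str, Callable[[float, float], float]] = {
    "neg_log_regression": _neg_log_regression,
}


def eri_tcp(v0: float, vt: float, form: str = "neg_log_regression") -> float:
    """Early regression index for baseline volume ``v0`` and volume ``vt``.

    Default form: ``-ln((v0 - vt) / v0)``; complete regression (vt = 0)
    gives 0, and the index increases as regression decreases. ``vt >= v0``
    is flagged missing (NaN).
    """
    if v0 <= 0:
        raise ValueError(f"v0 must be > 0, got {v0}")
    if vt < 0:
        raise ValueError(f"vt must be >= 0, got {vt}")
    return ERI_FORMS[form](float(v0), float(vt))


@dataclass
class EriResult:
    """Per-patient per-level ERI values plus cohort-level screening p-values."""

    values: pd.DataFrame      # patients x BED levels
    volumes: pd.DataFrame     # patients x (0 + BED levels), mm^3
    p_values: pd.Series | None = None


def eri_table(series_list: list[PatientSeries], form: str = "neg_log_regression") -> EriResult:
    """ERI at every post-baseline BED level of every patient (from mask volumes)."""
    vol_rows, eri_rows = {}, {}
    for s in series_list:
        vols = s.mask_volumes_mm3()
        levels = [float(b) for b in s.bed_levels]
        vol_rows[s.patient_id] = dict(zip(levels, vols))
        v0 = vols[0]
        eri_rows[s.patient_id] = {
            lv: eri_tcp(v0, vt, form=form) for lv, vt in zip(levels[1:], vols[1:])
        }
    return EriResult(
        values=pd.DataFrame.from_dict(eri_rows, orient="index").sort_index(axis=1),
        volumes=pd.DataFrame.from_dict(vol_rows, orient="index").sort_index(axis=1),
    )


def eri_screen(eri_values: pd.DataFrame, outcome: pd.Series) -> pd.Series:
    """WMW p-value of ERI vs the binary outcome at each BED level.

    ``outcome`` is the disease-free indicator (1 = disease-free); patients
    with undefined ERI at a level are dropped for that level. Constant ERI
    at a level is flagged (NaN p-value).
    """
    y = outcome.loc[eri_values.index].astype(bool)
    if y.all() or (~y).all():
        raise ValueError("outcome has a single class")
    out = {}
    for level in eri_values.columns:
        x = eri_values[level].to_numpy(dtype=np.float64)
        ok = np.isfinite(x)
        ev = (~y.to_numpy())[ok]
        xs = x[ok]
        if xs.size == 0 or ev.all() or (~ev).all() or np.unique(xs).size < 2:
            out[level] = np.nan
            continue
        out[level] = wmw_test(xs[ev], xs[~ev])
    return pd.Series(out, name="p_value")
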