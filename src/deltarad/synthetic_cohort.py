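"""Synthetic longitudinal tumor cohorts with a controllable outcome signal.

Each patient gets a lobulated ellipsoidal tumor that shrinks over six
BED-aligned timepoints. The outcome signal is localized at a configurable
timepoint (default the 4th post-baseline level, 54 Gy): a per-patient latent
"regression aptitude" drives both the volume loss at that step and a surface
lobulation increase, so the surface-to-volume-ratio delta at that timepoint
is the best single discriminator of outcome. Outcome labels are drawn from a
logistic model on that embedded predictor plus a chemotherapy covariate,
with the intercept solved numerically for the requested event prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .bed import DEFAULT_TARGET_LEVELS
from .series import PatientSeries

#: weight of the lobe-amplitude change in the embedded predictor, matching
#: the (1/3) * log volume-ratio scale of the size term
SHAPE_WEIGHT = 1.0


@dataclass(frozen=True)
class DecayParams:
    """Distribution of per-timepoint fractional volume loss."""

    base: float = 0.14          # mean fractional loss per step
    noise_sd: float = 0.02      # step-to-step between-patient noise
    signal_gain: float = 0.12   # extra loss per unit latent at the signal step
    post_noise_sd: float = 0.08     # extra decay noise after the signal step
    lobe_base: float = 0.12     # baseline lobe amplitude (mean)
    lobe_signal_gain: float = 1.1   # log-amplitude per unit latent at signal step
    lobe_noise_sd: float = 0.1      # log-amplitude noise at pre-signal steps
    lobe_post_noise_sd: float = 1.1  # log-amplitude noise after the signal step
    shape_noise_sd: float = 0.0     # extra latent dilution in the shape channel


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 48
    event_prevalence: float = 1.0 / 6.0
    effect_size: float = 5.0      # log-odds per SD of the embedded predictor
    n_timepoints: int = 6
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    image_shape: tuple[int, int, int] = (40, 40, 40)
    noise_sd: float = 4.0
    responder_decay: DecayParams = field(default_factory=DecayParams)
    signal_timepoint: int = 4     # 1-based post-baseline index carrying the signal
    chemo_logodds: float = -0.7   # oxaliplatin effect on event log-odds
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.event_prevalence < 1.0:
            raise ValueError("event_prevalence must be in (0, 1)")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("spacing components must be > 0")
        if not 1 <= self.signal_timepoint <= self.n_timepoints - 1:
            raise ValueError("signal_timepoint out of range")

    def bed_levels(self) -> list[float]:
        levels = [0.0] + list(DEFAULT_TARGET_LEVELS)
        if self.n_timepoints <= len(levels):
            return levels[: self.n_timepoints]
        # extend past the printed levels with the mean increment
        step = levels[-1] - levels[-2]
        while len(levels) < self.n_timepoints:
            levels.append(levels[-1] + step)
        return levels


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates and outcome.

    ``outcome_2ydfs`` is 1 when the patient is disease-free at 2 years.
    ``truth_*`` fields expose the generator's ground truth for testing and
    are not part of the emulated clinical data.
    """

    patient_id: str
    sex: str                  # 'M' | 'F'
    age: float
    cT: int                   # 2 | 3 | 4
    cN: int                   # 0 | 1
    rt_dose: float
    surgery: str              # 'AR' | 'APR' | 'TEM' | 'none'
    chemo_type: str           # 'with_oxa' | 'without_oxa' | 'none'
    hemoglobin: float
    wbc: float
    neutrophils: float
    platelets: float
    nlr: float
    complete_response: int
    outcome_2ydfs: int
    truth_latent: float = np.nan
    truth_predictor: float = np.nan

    def __post_init__(self) -> None:
        if self.age <= 0 or self.nlr <= 0:
            raise ValueError(f"{self.patient_id}: invalid age/nlr")
        if self.cT not in (2, 3, 4) or self.cN not in (0, 1):
            raise ValueError(f"{self.patient_id}: invalid staging")
        if self.sex not in ("M", "F") or self.surgery not in ("AR", "APR", "TEM", "none"):
            raise ValueError(f"{self.patient_id}: invalid category")
        if self.chemo_type not in ("with_oxa", "without_oxa", "none"):
            raise ValueError(f"{self.patient_id}: invalid chemo_type")
        if self.outcome_2ydfs not in (0, 1) or self.complete_response not in (0, 1):
            raise ValueError(f"{self.patient_id}: outcome must be binary")


def regression_trajectory(v0: float, decay, t: int) -> float:
    """Volume at timepoint ``t``: ``v0 * prod(1 - decay_k)`` for k <= t."""
    if v0 <= 0:
        raise ValueError("v0 must be > 0")
    d = np.asarray(decay, dtype=np.float64)
    if np.any((d < 0) | (d >= 1)):
        raise ValueError("decay fractions must be in [0, 1)")
    if t < 0 or t > d.size:
        raise ValueError(f"timepoint {t} out of range")
    return float(v0 * np.prod(1.0 - d[:t]))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class _TumorGeometry:
    center: np.ndarray           # mm
    semi_axes: np.ndarray        # mm, baseline
    lobe_dirs: np.ndarray        # (k, 3) unit vectors
    lobe_widths: np.ndarray      # (k,)


def _fibonacci_sphere(n: int = 1024) -> np.ndarray:
    """Deterministic quasi-uniform directions for spherical quadrature."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


_QUAD_U = _fibonacci_sphere(1024)


class _StarShape:
    """Spherical-quadrature view of one patient's lobe field.

    For a star-shaped region ``r(u) = R (1 + a P(u))`` this provides the
    scale compensation that keeps the enclosed volume independent of the
    lobe amplitude ``a``, and the analytic log surface-to-volume shape
    factor used as the generator's embedded predictor.
    """

    def __init__(self, geom: _TumorGeometry):
        u = _QUAD_U
        P = np.zeros(len(u))
        G = np.zeros((len(u), 3))
        for d, w in zip(geom.lobe_dirs, geom.lobe_widths):
            e = np.exp((u @ d - 1.0) / w)
            P += e
            tang = d[None, :] - (u @ d)[:, None] * u
            G += e[:, None] * tang / w
        self._P = P
        self._G2 = np.sum(G ** 2, axis=1)

    def volume_factor(self, a: float) -> float:
        return float(np.mean((1.0 + a * self._P) ** 3))

    def compensation(self, a: float) -> float:
        """Radial scale keeping volume equal to the lobe-free ellipsoid's."""
        return self.volume_factor(a) ** (-1.0 / 3.0)

    def log_av_shape(self, a: float) -> float:
        """ln(AV(a) / AV(0)) at constant volume (first-fundamental-form area)."""
        r = 1.0 + a * self._P
        area = float(np.mean(r ** 2 * np.sqrt(1.0 + a ** 2 * self._G2 / r ** 2)))
        return float(np.log(area) + 2.0 * np.log(self.compensation(a)))


def _rasterize(
    geom: _TumorGeometry,
    scale: float,
    lobe_amp: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Binary mask of the star-shaped region r(u) <= scale * (1 + a * P(u))."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    y = np.stack([(g - c) / ax for g, c, ax in zip(grids, geom.center, geom.semi_axes)])
    rho = np.sqrt(np.sum(y ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(rho > 0, y / rho, 0.0)
    lobes = np.zeros(shape)
    for d, w in zip(geom.lobe_dirs, geom.lobe_widths):
        cos = np.tensordot(d, u, axes=1)
        lobes += np.exp((cos - 1.0) / w)
    return rho <= scale * (1.0 + lobe_amp * lobes)


def _unit_vectors(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _patient_draw(rng: np.random.Generator, config: CohortConfig) -> dict:
    """All latent quantities for one patient (geometry, decay, shape, labs)."""
    dp = config.responder_decay
    T = config.n_timepoints
    sig = config.signal_timepoint

    # two independent latent channels: volume regression and surface change.
    # only their combination (what the surface-to-volume delta measures)
    # fully determines the outcome.
    z_size = float(rng.normal())
    z_shape_raw = float(rng.normal())
    r0 = float(rng.uniform(8.0, 13.0))
    f = rng.uniform(0.85, 1.2, size=3)
    f /= np.prod(f) ** (1.0 / 3.0)
    n_lobes = int(rng.integers(6, 11))
    geom = _TumorGeometry(
        center=np.asarray(config.image_shape) * np.asarray(config.voxel_spacing) / 2.0
        + rng.uniform(-2.0, 2.0, size=3),
        semi_axes=r0 * f,
        lobe_dirs=_unit_vectors(rng, n_lobes),
        lobe_widths=rng.uniform(0.07, 0.12, size=n_lobes),
    )

    decay = np.empty(T - 1)
    for k in range(1, T):
        if k == sig:
            decay[k - 1] = dp.base + dp.signal_gain * z_size + 0.02 * rng.normal()
        elif k < sig:
            decay[k - 1] = dp.base + dp.noise_sd * rng.normal()
        else:  # post-signal: extra noise dilutes the carried-over size signal
            decay[k - 1] = dp.base + dp.post_noise_sd * rng.normal()
    decay = np.clip(decay, 0.02, 0.7)

    z_shape = z_shape_raw + dp.shape_noise_sd * rng.normal()
    a0 = dp.lobe_base * float(np.exp(0.3 * rng.normal()))
    lobe_amp = np.empty(T)
    lobe_amp[0] = a0
    for t in range(1, T):
        if t == sig:
            lobe_amp[t] = a0 * np.exp(dp.lobe_signal_gain * z_shape + 0.05 * rng.normal())
        elif t < sig:
            lobe_amp[t] = a0 * np.exp(dp.lobe_noise_sd * rng.normal())
        else:  # after the signal step: independent noise dilutes the shape signal
            lobe_amp[t] = a0 * np.exp(dp.lobe_post_noise_sd * rng.normal())
    lobe_amp = np.clip(lobe_amp, 0.0, 0.7)

    chemo = str(rng.choice(["with_oxa", "without_oxa", "none"], p=[0.354, 0.042, 0.604]))
    u_outcome = float(rng.uniform())
    u_cr = float(rng.uniform())

    lymphocytes = max(float(rng.normal(1.8, 0.5)), 0.4)
    neutrophils = max(float(rng.normal(4.2, 1.2)), 0.8)
    labs = {
        "hemoglobin": float(rng.normal(13.2, 1.5)),
        "wbc": max(float(rng.normal(6.5, 1.5)), 1.5),
        "neutrophils": neutrophils,
        "platelets": max(float(rng.normal(250.0, 60.0)), 60.0),
        "nlr": neutrophils / lymphocytes,
    }
    clin = {
        "sex": "M" if rng.uniform() < 0.688 else "F",
        "age": float(np.clip(rng.normal(62.0, 11.0), 30.0, 90.0)),
        "cT": int(rng.choice([2, 3, 4], p=[0.146, 0.583, 0.271])),
        "cN": int(rng.uniform() < 0.729),
        "rt_dose": float(rng.choice([55.0, 50.4], p=[0.875, 0.125])),
        "surgery": str(rng.choice(["APR", "AR", "TEM", "none"], p=[0.083, 0.667, 0.042, 0.208])),
        **labs,
    }
    return {
        "z": (z_size + z_shape_raw) / np.sqrt(2.0),
        "geom": geom,
        "star": _StarShape(geom),
        "r0": r0,
        "decay": decay,
        "lobe_amp": lobe_amp,
        "chemo": chemo,
        "u_outcome": u_outcome,
        "u_cr": u_cr,
        "clin": clin,
    }


def _embedded_predictor(draw: dict, sig: int) -> float:
    """The generator's analytic log delta-AV at the signal timepoint."""
    v_ratio = float(np.prod(1.0 - draw["decay"][:sig]))
    size_term = -np.log(v_ratio) / 3.0
    star: _StarShape = draw["star"]
    shape_term = SHAPE_WEIGHT * (
        star.log_av_shape(float(draw["lobe_amp"][sig]))
        - star.log_av_shape(float(draw["lobe_amp"][0]))
    )
    return float(size_term + shape_term)


def _solve_intercept(eta_rest: np.ndarray, prevalence: float) -> float:
    def gap(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_rest)))) - prevalence)

    return float(optimize.brentq(gap, -30.0, 30.0))


def _draw_cohort(config: CohortConfig):
    """Per-patient latent draws plus calibrated event probabilities."""
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(config.n_patients)
    draws = [_patient_draw(np.random.default_rng(c), config) for c in children]
    sig = config.signal_timepoint

    pred = np.array([_embedded_predictor(d, sig) for d in draws])
    sd = pred.std()
    pred_std = (pred - pred.mean()) / sd if sd > 0 else np.zeros_like(pred)
    chemo_oxa = np.array([d["chemo"] == "with_oxa" for d in draws], dtype=float)

    eta_rest = -config.effect_size * pred_std + config.chemo_logodds * chemo_oxa
    b0 = _solve_intercept(eta_rest, config.event_prevalence)
    p_event = 1.0 / (1.0 + np.exp(-(b0 + eta_rest)))
    return children, draws, pred, p_event


def _record_for(pid: str, d: dict, pred_i: float, p_event_i: float) -> ClinicalRecord:
    event = d["u_outcome"] < p_event_i
    cr_prob = 1.0 / (1.0 + np.exp(-(-0.75 + 1.0 * d["z"])))
    return ClinicalRecord(
        patient_id=pid,
        chemo_type=d["chemo"],
        complete_response=int(d["u_cr"] < cr_prob),
        outcome_2ydfs=int(not event),
        truth_latent=d["z"],
        truth_predictor=pred_i,
        **d["clin"],
    )


def simulate_labels(
    config: CohortConfig,
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """Clinical records plus analytic ground truth, without rasterizing images.

    The truth frame (indexed by patient id) holds the nominal GTV volume
    trajectory ``volume_t<k>`` (mm^3) and the analytic log delta-AV proxy
    ``log_delta_av_t<k>`` per post-baseline timepoint. Identical labels to
    :func:`simulate_cohort` for the same config.
    """
    _, draws, pred, p_event = _draw_cohort(config)
    records, rows = [], {}
    for i, d in enumerate(draws):
        pid = f"P{i:03d}"
        records.append(_record_for(pid, d, float(pred[i]), float(p_event[i])))
        v0 = 4.0 / 3.0 * np.pi * float(np.prod(d["geom"].semi_axes))
        star: _StarShape = d["star"]
        base_shape = star.log_av_shape(float(d["lobe_amp"][0]))
        row = {}
        for t in range(config.n_timepoints):
            v_ratio = float(np.prod(1.0 - d["decay"][:t]))
            row[f"volume_t{t}"] = v0 * v_ratio
            if t > 0:
                row[f"log_delta_av_t{t}"] = (
                    -np.log(v_ratio) / 3.0
                    + star.log_av_shape(float(d["lobe_amp"][t])) - base_shape
                )
        rows[pid] = row
    truth = pd.DataFrame.from_dict(rows, orient="index")
    return records, truth


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientSeries], list[ClinicalRecord]]:
    """Generate a full synthetic cohort (image series + clinical records).

    Deterministic for a fixed config: one RNG stream per patient is derived
    from the master seed, so growing ``n_patients`` leaves earlier patients
    unchanged. If shrinkage would empty a mask, the ROI is clamped to a
    single voxel and flagged in the series metadata.
    """
    children, draws, pred, p_event = _draw_cohort(config)
    levels = config.bed_levels()
    series_list: list[PatientSeries] = []
    records: list[ClinicalRecord] = []
    for i, d in enumerate(draws):
        pid = f"P{i:03d}"
        rng_tex = np.random.default_rng(children[i].spawn(1)[0])
        volumes, masks = [], []
        clamped = False
        for t in range(config.n_timepoints):
            v_ratio = float(np.prod(1.0 - d["decay"][:t]))
            amp = float(d["lobe_amp"][t])
            # compensate the lobe volume so size follows the decay trajectory
            scale = v_ratio ** (1.0 / 3.0) * d["star"].compensation(amp)
            mask = _rasterize(
                d["geom"], scale, amp,
                config.image_shape, config.voxel_spacing,
            )
            if not mask.any():
                mask = np.zeros(config.image_shape, dtype=bool)
                c = tuple(
                    int(round(x / s))
                    for x, s in zip(d["geom"].center, config.voxel_spacing)
                )
                mask[c] = True
                clamped = True
            texture = ndimage.gaussian_filter(
                rng_tex.normal(size=config.image_shape), sigma=1.5
            )
            img = (
                100.0
                + 15.0 * texture / max(texture.std(), 1e-12)
                + 25.0 * ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.0)
                + config.noise_sd * rng_tex.normal(size=config.image_shape)
            )
            volumes.append(img.astype(np.float32))
            masks.append(mask.astype(np.uint8))
        if clamped:
            warnings.warn(f"{pid}: shrinkage emptied a mask; clamped to 1 voxel")
        series_list.append(
            PatientSeries(
                patient_id=pid,
                volumes=volumes,
                masks=masks,
                bed_levels=list(levels),
                spacing=config.voxel_spacing,
                meta={"clamped": clamped},
            )
        )

        records.append(_record_for(pid, d, float(pred[i]), float(p_event[i])))
    return series_list, records


def clinical_frame(records: list[ClinicalRecord], encoded: bool = True) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by patient id.

    With ``encoded=True`` categorical covariates are expanded to numeric
    columns suitable for screening/modeling (sex_male, chemo_oxa, surgery
    dummies), truth columns are dropped, and the outcome stays as ``dfs2y``.
    """
    df = pd.DataFrame([asdict(r) for r in records]).set_index("patient_id")
    if not encoded:
        return df
    out = pd.DataFrame(index=df.index)
    out["sex_male"] = (df["sex"] == "M").astype(float)
    out["age"] = df["age"]
    out["cT"] = df["cT"].astype(float)
    out["cN"] = df["cN"].astype(float)
    out["rt_dose"] = df["rt_dose"]
    for s in ("AR", "APR", "TEM"):
        out[f"surgery_{s}"] = (df["surgery"] == s).astype(float)
    out["chemo_oxa"] = (df["chemo_type"] == "with_oxa").astype(float)
    out["chemo_any"] = (df["chemo_type"] != "none").astype(float)
    for lab in ("hemoglobin", "wbc", "neutrophils", "platelets", "nlr"):
        out[lab] = df[lab]
    out["dfs2y"] = df["outcome_2ydfs"].astype(int)
    return out


def summarize_cohort(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Cohort characteristics table: counts and percentages (one decimal)
    per categorical level, median and range for continuous variables."""
    if not records:
        raise ValueError("empty cohort")
    df = pd.DataFrame([asdict(r) for r in records])
    n = len(df)
    rows: list[dict] = []

    def cat(variable: str, series: pd.Series, levels: list) -> None:
        for lv in levels:
            count = int((series == lv).sum())
            rows.append(
                {
                    "variable": variable,
                    "level": str(lv),
                    "n": count,
                    "percent": round(100.0 * count / n, 1),
                    "summary": f"{count} ({round(100.0 * count / n, 1)}%)",
                }
            )

    def cont(variable: str, series: pd.Series) -> None:
        med, lo, hi = series.median(), series.min(), series.max()
        rows.append(
            {
                "variable": variable,
                "level": "median (range)",
                "n": n,
                "percent": np.nan,
                "summary": f"{med:g} ({lo:g}–{hi:g})",
            }
        )

    cont("Age", df["age"])
    cat("Sex", df["sex"], ["M", "F"])
    cat("cT", df["cT"], [2, 3, 4])
    cat("cN", df["cN"], [0, 1])
    cont("RT dose", df["rt_dose"])
    cat("Surgical procedure", df["surgery"], ["APR", "AR", "TEM", "none"])
    cat("pCR/cCR", df["complete_response"].map({1: "Yes", 0: "No"}), ["Yes", "No"])
    cat("CT type", df["chemo_type"], ["with_oxa", "without_oxa", "none"])
    cat("2yDFS", df["outcome_2ydfs"].map({1: "Yes", 0: "No"}), ["Yes", "No"])
    return pd.DataFrame(rows)
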