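"""Univariate screening, logistic models and bootstrap ROC analysis.

The cascade: Wilcoxon-Mann-Whitney screening of every candidate variable
against the binary outcome, per-variable AUC, Pearson-correlation redundancy
analysis among significant variables, logistic models on the selected
predictors, and an ROC summary (AUC with percentile-bootstrap CI, Youden
operating point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# univariate primitives
# ---------------------------------------------------------------------------

def wmw_test(x_event: np.ndarray, x_noevent: np.ndarray, mode: str = "auto") -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    ``auto`` uses exact enumeration for small untied samples
    (n1 + n2 <= 12) and the tie-corrected normal approximation otherwise.
    Identical values across both groups give p = 1.
    """
    x = np.asarray(x_event, dtype=np.float64)
    y = np.asarray(x_noevent, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 12 and not has_ties) else "normal_approx_tie_corrected"
    if mode == "exact":
        method = "exact"
    elif mode == "normal_approx_tie_corrected":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class AucResult:
    """Orientation-corrected AUC: ``auc = max(raw, 1 - raw)``."""

    auc: float
    raw: float
    flipped: bool


def _pair_auc(values: np.ndarray, positives: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 P(equal), via midranks (exact with ties)."""
    v = np.asarray(values, dtype=np.float64)
    pos = np.asarray(positives).astype(bool)
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(v)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def feature_auc(values: np.ndarray, labels: np.ndarray) -> AucResult:
    """Discrimination of a feature for a binary label, orientation-corrected.

    ``labels`` marks the positive class; the raw AUC is the probability that
    a random positive value exceeds a random negative one (ties count 1/2,
    i.e. U / (n1 * n0)). Since a delta feature may predict in either
    direction, ``auc`` is ``max(raw, 1 - raw)`` with ``flipped`` set when the
    orientation was reversed.
    """
    raw = _pair_auc(values, labels)
    return AucResult(auc=max(raw, 1.0 - raw), raw=raw, flipped=raw < 0.5)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Per-variable WMW p / AUC ranking plus PCC among significant variables.

    ``table`` is indexed by variable with columns ``p_value``, ``auc``,
    ``auc_raw``, ``flipped``, ``class``, ``significant``, ``rank`` (NaN for
    excluded variables) and ``excluded`` (reason string or '').
    """

    table: pd.DataFrame
    pcc_matrix: pd.DataFrame
    alpha: float
    n_tested: int

    @property
    def significant(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"].fillna(False)])

    def significant_of_class(self, cls: str) -> list[str]:
        t = self.table
        keep = t["significant"].fillna(False) & (t["class"] == cls)
        return list(t.index[keep])

    @property
    def expected_false_positives(self) -> float:
        """Expected chance findings given no multiplicity correction."""
        return self.alpha * self.n_tested

    def top(self, cls: str | None = None) -> str:
        t = self.table.dropna(subset=["rank"]).sort_values("rank")
        if cls is not None:
            t = t[t["class"] == cls]
        if t.empty:
            raise ValueError("no ranked variables")
        return str(t.index[0])


def screen(table, alpha: float = 0.05, max_missing: float = 0.2) -> ScreeningResult:
    """Univariate WMW + AUC screening of every predictor column.

    Variables missing in more than ``max_missing`` of patients, or constant
    on the observed values, are excluded from ranking. Ranking is by p
    ascending, ties broken by oriented AUC descending, then column order.
    No multiplicity correction is applied.
    """
    df = table.data
    y = table.y.astype(bool)
    event = ~y  # positive class = patients without 2-year disease-free survival
    if event.all() or (~event).all():
        raise ValueError("outcome has a single class")
    cols = table.predictors
    if not cols:
        raise ValueError("empty table")

    records = []
    for col in cols:
        x = df[col].to_numpy(dtype=np.float64)
        ok = np.isfinite(x)
        frac_missing = 1.0 - ok.mean()
        cls = table.column_classes[col]
        if frac_missing > max_missing:
            records.append((col, cls, np.nan, np.nan, np.nan, False, "missing"))
            continue
        xs, es = x[ok], event[ok]
        if np.unique(xs).size < 2 or es.all() or (~es).all():
            records.append((col, cls, np.nan, np.nan, np.nan, False, "constant"))
            continue
        p = wmw_test(xs[es], xs[~es])
        a = feature_auc(xs, es)
        records.append((col, cls, p, a.auc, a.raw, a.flipped, ""))

    res = pd.DataFrame(
        records,
        columns=["variable", "class", "p_value", "auc", "auc_raw", "flipped", "excluded"],
    ).set_index("variable")
    res["significant"] = (res["p_value"] < alpha) & (res["excluded"] == "")

    ranked = res[res["excluded"] == ""].copy()
    ranked["_order"] = np.arange(len(ranked))
    ranked = ranked.sort_values(
        ["p_value", "auc", "_order"], ascending=[True, False, True]
    )
    res["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1, dtype=float), index=ranked.index
    )

    sig = list(res.index[res["significant"]])
    if len(sig) >= 2:
        sub = df[sig].astype(float)
        pcc_matrix = sub.corr(method="pearson")
    else:
        pcc_matrix = pd.DataFrame(np.ones((len(sig), len(sig))), index=sig, columns=sig)

    return ScreeningResult(
        table=res, pcc_matrix=pcc_matrix, alpha=alpha, n_tested=len(ranked)
    )


def select_pair(
    sr: ScreeningResult, mode: str = "anchored", top_k: int = 10
) -> tuple[str, str | None]:
    """Two significant delta features with the lowest mutual |PCC|.

    ``anchored`` (default) keeps the single most significant delta feature
    and picks the partner minimizing |PCC| with it; ``global`` searches all
    pairs among the ``top_k`` most significant delta features. Ties break by
    screening rank. With fewer than two significant delta features, returns
    ``(best, None)`` with a warning (single-feature fallback).
    """
    sig = sr.significant_of_class("delta")
    ranked = sorted(sig, key=lambda c: sr.table.loc[c, "rank"])
    if not ranked:
        raise ValueError("no significant delta features")
    if len(ranked) < 2:
        warnings.warn("fewer than 2 significant delta features; single-feature fallback")
        return ranked[0], None

    if mode == "anchored":
        anchor = ranked[0]
        best, best_val = None, np.inf
        for cand in ranked[1:]:
            val = abs(float(sr.pcc_matrix.loc[anchor, cand]))
            if val < best_val - 1e-15:
                best, best_val = cand, val
        return anchor, best
    if mode == "global":
        cands = ranked[: max(2, top_k)]
        best_pair, best_val = (cands[0], cands[1]), np.inf
        for i, a in enumerate(cands):
            for b in cands[i + 1:]:
                val = abs(float(sr.pcc_matrix.loc[a, b]))
                if val < best_val - 1e-15:
                    best_pair, best_val = (a, b), val
        return best_pair
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# logistic model
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (IRLS), optionally ridge-stabilized."""

    variables: list[str]
    coef_standardized: np.ndarray  # [intercept, slopes...] on z-scored X
    coef_original: np.ndarray      # [intercept, slopes...] on input scale
    fitted: np.ndarray
    converged: bool
    penalized: bool
    x_mean: np.ndarray
    x_sd: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        eta = self.coef_original[0] + X @ self.coef_original[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 200):
    n, p = Z.shape
    beta = np.zeros(p)
    pen = np.eye(p) * ridge
    pen[0, 0] = 0.0  # never penalize the intercept
    converged = False
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Z.T @ (y - mu) - pen @ beta
        hess = (Z * w[:, None]).T @ Z + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    return beta, converged


def fit_logistic(X, y: np.ndarray, variables: list[str] | None = None) -> LogisticFit:
    """Fit ``P(y=1) = sigmoid(b0 + X b)`` by IRLS.

    Predictors are standardized internally; coefficients are reported on
    both the standardized and the original scale. On detected separation
    (diverging standardized coefficients or non-convergence), the model is
    refit with a small ridge penalty and flagged ``penalized``.
    """
    if isinstance(X, pd.DataFrame):
        variables = variables or list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    variables = variables or [f"x{i}" for i in range(p)]
    if n <= p + 1:
        raise ValueError(f"need n > #predictors + 1 (n={n}, p={p})")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [variables[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant predictor(s): {bad}")
    mean = X.mean(axis=0)
    Z = np.column_stack([np.ones(n), (X - mean) / sd])

    beta, converged = _irls(Z, y, ridge=0.0)
    penalized = False
    if not converged or (p > 0 and np.max(np.abs(beta[1:])) > 15.0):
        beta, converged = _irls(Z, y, ridge=0.1)
        penalized = True
        if not converged:
            raise RuntimeError(
                f"logistic fit failed to converge for {variables} even with ridge"
            )

    slopes = beta[1:] / sd
    intercept = beta[0] - float(np.sum(beta[1:] * mean / sd))
    coef_orig = np.concatenate([[intercept], slopes])
    eta = Z @ beta
    fitted = 1.0 / (1.0 + np.exp(-eta))
    return LogisticFit(
        variables=list(variables),
        coef_standardized=beta,
        coef_original=coef_orig,
        fitted=fitted,
        converged=converged,
        penalized=penalized,
        x_mean=mean,
        x_sd=sd,
    )


# ---------------------------------------------------------------------------
# ROC / bootstrap / Youden
# ---------------------------------------------------------------------------

def _roc_points(score: np.ndarray, pos: np.ndarray):
    """Empirical ROC: thresholds descending, predict positive if score >= t."""
    order = np.argsort(-score, kind="stable")
    s, p = score[order], pos[order]
    # group tied scores
    thresholds = []
    tps, fps = [0], [0]
    i = 0
    n = len(s)
    tp = fp = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            tp += int(p[j])
            fp += int(not p[j])
            j += 1
        thresholds.append(s[i])
        tps.append(tp)
        fps.append(fp)
        i = j
    n1, n0 = int(pos.sum()), int((~pos).sum())
    tpr = np.asarray(tps, dtype=np.float64) / n1
    fpr = np.asarray(fps, dtype=np.float64) / n0
    return fpr, tpr, np.asarray([np.inf] + thresholds, dtype=np.float64)


def bootstrap_auc_ci(
    score: np.ndarray,
    pos: np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the pair-counting AUC.

    Resampling is stratified by class (events and non-events resampled
    separately), which guarantees both classes in every replicate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(score, dtype=np.float64)
    pos = np.asarray(pos).astype(bool)
    se, sn = s[pos], s[~pos]
    n1, n0 = se.size, sn.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    aucs = np.empty(n_boot)
    # chunk replicates to bound the (B, n1, n0) comparison tensor
    chunk = max(1, int(2e7 // max(1, n1 * n0)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        e = se[rng.integers(0, n1, size=(b, n1))]
        m = sn[rng.integers(0, n0, size=(b, n0))]
        diff = e[:, :, None] - m[:, None, :]
        aucs[done:done + b] = (
            (diff > 0).mean(axis=(1, 2)) + 0.5 * (diff == 0).mean(axis=(1, 2))
        )
        done += b
    lo, hi = np.percentile(aucs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


@dataclass
class ModelReport:
    """One row of the performance table plus the full ROC."""

    model_id: str
    variables: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    auc: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    threshold: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    youden_j: float = np.nan
    n_boot: int = 0
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict[str, float]:
        return {
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Threshold": self.threshold,
            "J_index": self.youden_j,
            "AUC": self.auc,
            "AUC_Low": self.ci_low,
            "AUC_High": self.ci_high,
        }


def roc_analysis(
    score: np.ndarray,
    y_pos: np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    model_id: str = "model",
    variables: list[str] | None = None,
) -> ModelReport:
    """ROC, trapezoid AUC, stratified-bootstrap 95% CI and Youden threshold.

    ``y_pos`` marks the positive class. The trapezoid AUC over the empirical
    ROC equals the pair-counting AUC (exact, including ties). The operating
    threshold maximizes ``J = sensitivity + specificity - 1``; ties are
    broken toward higher specificity.
    """
    s = np.asarray(score, dtype=np.float64)
    pos = np.asarray(y_pos).astype(bool)
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    fpr, tpr, thresholds = _roc_points(s, pos)
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    # argmax with ties toward higher specificity (lower fpr), then higher threshold
    best = max(range(len(j)), key=lambda i: (j[i], -fpr[i], thresholds[i]))
    ci_lo, ci_hi = bootstrap_auc_ci(s, pos, n_boot=n_boot, seed=seed)

    return ModelReport(
        model_id=model_id,
        variables=variables or [],
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        ci_low=ci_lo,
        ci_high=ci_hi,
        threshold=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden_j=float(j[best]),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# model table
# ---------------------------------------------------------------------------

def _find_chemo_column(table) -> str | None:
    cands = [c for c in table.columns_of_class("clinical") if "chemo" in c.lower()]
    return cands[0] if cands else None


def build_models(
    table,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
    chemo_column: str | None = None,
    screening: ScreeningResult | None = None,
) -> list[ModelReport]:
    """The three performance-table models: chemo-only, best delta RF, combined.

    The single-feature model uses the most significant delta feature from
    screening (top-ranked delta if none reaches significance); the combined
    model adds the chemotherapy covariate to it. A constant chemo column
    skips the clinical-only and combined models with a warning flag.
    """
    sr = screening if screening is not None else screen(table, alpha=alpha)
    df = table.data
    event = (~table.y.astype(bool)).astype(float)

    try:
        best = sr.top(cls="delta")
    except ValueError:
        raise ValueError("no rankable delta features") from None

    chemo = chemo_column or _find_chemo_column(table)
    rng = np.random.default_rng(seed)
    reports: list[ModelReport] = []

    def _one(model_id: str, cols: list[str]) -> ModelReport | None:
        sub = df[cols].to_numpy(dtype=np.float64)
        ok = np.all(np.isfinite(sub), axis=1)
        X, yv = sub[ok], event[ok]
        if np.unique(yv).size < 2:
            return None
        try:
            fit = fit_logistic(X, yv, variables=cols)
        except ValueError as exc:
            warnings.warn(f"{model_id}: {exc}")
            return None
        rep = roc_analysis(
            fit.fitted, yv.astype(bool), n_boot=n_boot, seed=rng,
            model_id=model_id, variables=cols,
        )
        rep.coefficients = dict(zip(["(intercept)"] + cols, fit.coef_original))
        if fit.penalized:
            rep.flags.append("penalized")
        return rep

    if chemo is not None:
        rep = _one("Chemo", [chemo])
        if rep is not None:
            reports.append(rep)
        else:
            warnings.warn("chemo column constant or degenerate; clinical-only model skipped")

    rep = _one(best, [best])
    if rep is None:
        raise ValueError(f"single-feature model on {best} is degenerate")
    reports.append(rep)

    if chemo is not None:
        rep = _one(f"Chemo+{best}", [chemo, best])
        if rep is not None:
            reports.append(rep)

    return reports


def model_reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Performance table (Sensitivity/Specificity/Threshold/J_index/AUC/CI)."""
    return pd.DataFrame(
        {r.model_id: r.to_row() for r in reports}
    ).T[["Sensitivity", "Specificity", "Threshold", "J_index", "AUC", "AUC_Low", "AUC_High"]]
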