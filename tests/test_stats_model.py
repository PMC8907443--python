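import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltarad.delta import FeatureTable
from deltarad.stats_model import (
    bootstrap_auc_ci,
    build_models,
    feature_auc,
    fit_logistic,
    model_reports_to_frame,
    pcc,
    roc_analysis,
    screen,
    select_pair,
    wmw_test,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_auc(values, positives):
    """O(n^2) pair counting: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = [v for v, p in zip(values, positives) if p]
    neg = [v for v, p in zip(values, positives) if not p]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def enumerate_wmw_p(x, y):
    """Exact two-sided WMW p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = brute_force_auc(pooled, [True] * n1 + [False] * len(y)) * n1 * len(y)
    center = n1 * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = [i in idx for i in range(len(pooled))]
        u = brute_force_auc(pooled, mask) * n1 * len(y)
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_force_youden(score, pos):
    """Enumerate all thresholds; maximize J, break ties toward specificity."""
    thresholds = [np.inf] + sorted(set(score), reverse=True)
    best = None
    for t in thresholds:
        predicted = score >= t
        sens = np.mean(predicted[pos]) if pos.any() else 0.0
        spec = np.mean(~predicted[~pos])
        j = sens + spec - 1.0
        key = (j, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec, j)
    return best[1], best[2], best[3], best[4]


# ---------------------------------------------------------------------------
# wmw_test
# ---------------------------------------------------------------------------


class TestWmw:
    def test_toy_exact_one_third(self):
        assert wmw_test(np.array([1, 2]), np.array([3, 4])) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert wmw_test(x, x) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            assert wmw_test(x, y, mode="exact") == pytest.approx(
                enumerate_wmw_p(x, y), abs=1e-12
            )

    def test_null_calibration_large_sample(self):
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            rejections += wmw_test(x, y) < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wmw_test(np.array([]), np.array([1.0]))


# ---------------------------------------------------------------------------
# feature_auc / pcc
# ---------------------------------------------------------------------------


class TestFeatureAuc:
    def test_perfect_separation(self):
        res = feature_auc(np.array([1, 2, 3]), np.array([0, 0, 1], dtype=bool))
        assert res.auc == 1.0 and not res.flipped

    def test_all_ties(self):
        res = feature_auc(np.ones(10), np.array([1] * 4 + [0] * 6, dtype=bool))
        assert res.raw == pytest.approx(0.5)

    def test_orientation_flip(self):
        res = feature_auc(np.array([3, 2, 1]), np.array([0, 0, 1], dtype=bool))
        assert res.raw == 0.0 and res.auc == 1.0 and res.flipped

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            v = rng.integers(0, 6, size=20).astype(float)  # heavy ties
            lab = rng.integers(0, 2, size=20).astype(bool)
            if lab.sum() in (0, 20):
                continue
            assert feature_auc(v, lab).raw == pytest.approx(
                brute_force_auc(v, lab), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            feature_auc(np.arange(4.0), np.ones(4, dtype=bool))

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_auc_u_duality(self, seed):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(seed)
        v = rng.integers(0, 8, size=15).astype(float)
        lab = np.zeros(15, dtype=bool)
        lab[: rng.integers(1, 14)] = True
        rng.shuffle(lab)
        n1, n0 = int(lab.sum()), int((~lab).sum())
        u = mannwhitneyu(v[lab], v[~lab], alternative="two-sided").statistic
        assert feature_auc(v, lab).raw * n1 * n0 == pytest.approx(u, abs=1e-9)


class TestPcc:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pcc(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pcc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pcc(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# screening / pair selection
# ---------------------------------------------------------------------------


def make_table(X: pd.DataFrame, y, classes=None) -> FeatureTable:
    df = X.copy()
    df["dfs2y"] = np.asarray(y, dtype=int)
    classes = classes or {c: "delta" for c in X.columns}
    return FeatureTable(data=df, column_classes=classes)


class TestScreen:
    def test_perfect_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.array([0] * 10 + [1] * 30)
        X = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"f{i}" for i in range(20)])
        X["winner"] = 1.0 - y  # perfectly separates the event class
        sr = screen(make_table(X, y))
        assert sr.top() == "winner"
        assert "winner" in sr.significant

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 5 + [1] * 15)
        X = pd.DataFrame({"const": np.ones(20), "ok": rng.normal(size=20)})
        sr = screen(make_table(X, y))
        assert sr.table.loc["const", "excluded"] == "constant"
        assert np.isnan(sr.table.loc["const", "rank"])

    def test_missing_heavy_column_excluded(self):
        rng = np.random.default_rng(2)
        y = np.array([0] * 5 + [1] * 15)
        x = rng.normal(size=20)
        x[:10] = np.nan
        X = pd.DataFrame({"holey": x, "ok": rng.normal(size=20)})
        sr = screen(make_table(X, y))
        assert sr.table.loc["holey", "excluded"] == "missing"

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(10):
            y = np.array([0] * 16 + [1] * 32)
            X = pd.DataFrame(
                rng.normal(size=(48, 300)), columns=[f"f{i}" for i in range(300)]
            )
            sr = screen(make_table(X, y))
            fracs.append(len(sr.significant) / sr.n_tested)
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_pcc_matrix_structure(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 15 + [1] * 25)
        base = rng.normal(size=40)
        X = pd.DataFrame(
            {
                "a": base + (1 - y) * 2.0,
                "b": base + (1 - y) * 2.0 + rng.normal(size=40) * 0.1,
                "c": rng.normal(size=40),
            }
        )
        sr = screen(make_table(X, y))
        m = sr.pcc_matrix
        assert (m.columns == m.index).all()
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T, atol=1e-12)

    def test_single_class_outcome_errors(self):
        X = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError):
            screen(make_table(X, np.ones(5)))


class TestSelectPair:
    def _screening(self, X, y):
        return screen(make_table(X, y))

    def test_forced_orthogonal_partner(self):
        rng = np.random.default_rng(5)
        n = 60
        y = np.array([0] * 20 + [1] * 40)
        sig = (1 - y) + rng.normal(size=n) * 0.3
        indep = (1 - y) * 0.9 + rng.normal(size=n) * 0.4 + rng.normal(size=n)
        X = pd.DataFrame(
            {"top": sig, "twin": sig + rng.normal(size=n) * 0.01, "other": indep}
        )
        sr = self._screening(X, y)
        a, b = select_pair(sr)
        assert a == sr.top()
        assert b == "other"

    def test_two_significant_returns_them(self):
        rng = np.random.default_rng(6)
        y = np.array([0] * 20 + [1] * 40)
        X = pd.DataFrame(
            {
                "a": (1 - y) + rng.normal(size=60) * 0.3,
                "b": (1 - y) + rng.normal(size=60) * 0.35,
            }
        )
        sr = self._screening(X, y)
        assert set(select_pair(sr)) == {"a", "b"}

    def test_anchored_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 25 + [1] * 35)
        X = pd.DataFrame(
            {f"f{i}": (1 - y) * 0.8 + rng.normal(size=60) * 0.6 for i in range(8)}
        )
        sr = self._screening(X, y)
        sig = sr.significant_of_class("delta")
        if len(sig) >= 2:
            anchor, partner = select_pair(sr)
            others = [c for c in sig if c != anchor]
            best = min(others, key=lambda c: (abs(sr.pcc_matrix.loc[anchor, c]), sr.table.loc[c, "rank"]))
            assert abs(sr.pcc_matrix.loc[anchor, partner]) == pytest.approx(
                abs(sr.pcc_matrix.loc[anchor, best])
            )

    def test_single_significant_falls_back(self):
        rng = np.random.default_rng(8)
        y = np.array([0] * 20 + [1] * 40)
        X = pd.DataFrame(
            {"strong": (1 - y) * 3 + rng.normal(size=60) * 0.1, "noise": rng.normal(size=60)}
        )
        sr = self._screening(X, y)
        with pytest.warns(UserWarning):
            a, b = select_pair(sr)
        assert a == "strong" and b is None


# ---------------------------------------------------------------------------
# logistic model
# ---------------------------------------------------------------------------


class TestFitLogistic:
    def test_intercept_only_gives_prevalence(self):
        y = np.array([1] * 3 + [0] * 9, dtype=float)
        fit = fit_logistic(np.empty((12, 0)), y)
        np.testing.assert_allclose(fit.fitted, 0.25, atol=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.normal(size=n)
        beta0, beta1 = -1.0, 2.0
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.uniform(size=n) < p).astype(float)
        fit = fit_logistic(x[:, None], y)
        assert fit.coef_original[0] == pytest.approx(beta0, rel=0.05, abs=0.1)
        assert fit.coef_original[1] == pytest.approx(beta1, rel=0.05)
        assert fit.converged and not fit.penalized

    def test_separation_penalized_and_finite(self):
        y = np.array([0] * 10 + [1] * 10, dtype=float)
        x = y * 2.0 - 1.0 + np.linspace(0, 0.1, 20)  # perfectly separating
        fit = fit_logistic(x[:, None], y)
        assert fit.penalized
        assert np.all(np.isfinite(fit.coef_original))

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((10, 1)), np.array([0, 1] * 5, dtype=float))

    def test_too_few_observations_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.random.default_rng(0).normal(size=(3, 2)), np.array([0.0, 1.0, 0.0]))

    def test_predict_matches_fitted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 2))
        y = (rng.uniform(size=50) < 0.4).astype(float)
        fit = fit_logistic(x, y)
        np.testing.assert_allclose(fit.predict(x), fit.fitted, atol=1e-8)


# ---------------------------------------------------------------------------
# ROC / bootstrap
# ---------------------------------------------------------------------------


class TestRocAnalysis:
    def test_perfect_score(self):
        score = np.array([0.9, 0.8, 0.2, 0.1])
        pos = np.array([1, 1, 0, 0], dtype=bool)
        rep = roc_analysis(score, pos, n_boot=100, seed=0)
        assert rep.auc == 1.0
        assert rep.ci_low == 1.0 and rep.ci_high == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.youden_j == pytest.approx(1.0)

    def test_trapezoid_equals_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(6, 40)
            score = rng.integers(0, 10, size=n).astype(float)
            pos = np.zeros(n, dtype=bool)
            pos[: rng.integers(1, n - 1)] = True
            rng.shuffle(pos)
            rep = roc_analysis(score, pos, n_boot=1, seed=0)
            assert rep.auc == pytest.approx(brute_force_auc(score, pos), abs=1e-12)

    def test_youden_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            score = rng.integers(0, 6, size=12).astype(float)
            pos = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0, 1, 0], dtype=bool)
            rep = roc_analysis(score, pos, n_boot=1, seed=0)
            t, sens, spec, j = brute_force_youden(score, pos)
            assert rep.youden_j == pytest.approx(j, abs=1e-12)
            assert rep.sensitivity == pytest.approx(sens, abs=1e-12)
            assert rep.specificity == pytest.approx(spec, abs=1e-12)
            assert rep.threshold == pytest.approx(t)

    def test_anti_predictive_symmetry(self):
        score = np.array([0.1, 0.2, 0.8, 0.9])
        pos = np.array([1, 1, 0, 0], dtype=bool)
        rep = roc_analysis(score, pos, n_boot=10, seed=0)
        assert rep.auc == pytest.approx(0.0)
        flipped = roc_analysis(-score, pos, n_boot=10, seed=0)
        assert flipped.auc == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(4.0), np.ones(4, dtype=bool), n_boot=10)

    def test_ci_contains_point_estimate_typically(self):
        rng = np.random.default_rng(2)
        score = np.concatenate([rng.normal(1, 1, 15), rng.normal(0, 1, 25)])
        pos = np.array([True] * 15 + [False] * 25)
        rep = roc_analysis(score, pos, n_boot=2000, seed=3)
        assert rep.ci_low <= rep.auc <= rep.ci_high


class TestBootstrapCi:
    def test_stratification_keeps_both_classes(self):
        score = np.array([1.0, 0.0, 0.5, 0.2, 0.9])
        pos = np.array([1, 0, 0, 0, 0], dtype=bool)  # single event
        lo, hi = bootstrap_auc_ci(score, pos, n_boot=200, seed=0)
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        score = rng.normal(size=30)
        pos = np.array([True] * 10 + [False] * 20)
        assert bootstrap_auc_ci(score, pos, 500, seed=42) == bootstrap_auc_ci(
            score, pos, 500, seed=42
        )


# ---------------------------------------------------------------------------
# build_models
# ---------------------------------------------------------------------------


class TestBuildModels:
    def _table(self, rng, n=48, chemo_constant=False):
        y = np.array([0] * 12 + [1] * 36)  # dfs2y
        event = 1 - y
        av = event * 1.5 + rng.normal(size=n) * 0.5
        X = pd.DataFrame(
            {
                "AV(d4)": av,
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        chemo = np.zeros(n) if chemo_constant else rng.integers(0, 2, size=n).astype(float)
        X["chemo_oxa"] = chemo
        classes = {"AV(d4)": "delta", "noise1": "delta", "noise2": "delta", "chemo_oxa": "clinical"}
        return make_table(X, y, classes)

    def test_three_model_rows(self):
        table = self._table(np.random.default_rng(0))
        reports = build_models(table, n_boot=100, seed=0)
        assert [r.model_id for r in reports] == ["Chemo", "AV(d4)", "Chemo+AV(d4)"]
        frame = model_reports_to_frame(reports)
        assert list(frame.columns) == [
            "Sensitivity", "Specificity", "Threshold", "J_index", "AUC", "AUC_Low", "AUC_High",
        ]
        for r in reports:
            assert r.ci_low <= r.auc <= r.ci_high
            assert r.youden_j == pytest.approx(r.sensitivity + r.specificity - 1.0)

    def test_single_feature_model_beats_chemo(self):
        table = self._table(np.random.default_rng(1))
        reports = build_models(table, n_boot=100, seed=0)
        by_id = {r.model_id: r for r in reports}
        assert by_id["AV(d4)"].auc > by_id["Chemo"].auc

    def test_constant_chemo_skipped_with_warning(self):
        table = self._table(np.random.default_rng(2), chemo_constant=True)
        with pytest.warns(UserWarning, match="(?i)chemo"):
            reports = build_models(table, n_boot=50, seed=0)
        assert [r.model_id for r in reports] == ["AV(d4)"]
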