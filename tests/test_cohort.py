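"""Cohort statistics: Pearson, logistic MLE, ROC/AUC, summaries."""

import numpy as np
import pandas as pd
import pytest

from aortamech import (fit_logistic, gen_cohort, optimal_threshold,
                       pearson_r, quadrant_summary, roc_auc)
from aortamech.cohort import _youden_threshold_raw


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_table_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r, p = pearson_r(x, y)
        cx, cy = x - x.mean(), y - y.mean()
        brute = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert r == pytest.approx(brute, abs=1e-12)
        assert 0.0 < p < 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 30))
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r(3.0 * x + 2.0, 0.5 * y - 7.0)
        assert r1 == pytest.approx(r0, abs=1e-12)
        r2, _ = pearson_r(-x, y)
        assert r2 == pytest.approx(-r0, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogistic:
    def test_intercept_only_balanced(self):
        df = pd.DataFrame({"label": [0.0, 1.0] * 10})
        model = fit_logistic(df, [], log_scale=False)
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_within_wald_intervals(self):
        rng = np.random.default_rng(0)
        beta0, beta1 = -2.0, 1.5
        x = rng.normal(0.0, 2.0, 2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-(beta0 + beta1 * x))))
        df = pd.DataFrame({"x": x, "label": y.astype(float)})
        model = fit_logistic(df, ["x"], log_scale=False)
        assert model.converged and not model.separated
        # Wald 95 % intervals from the observed information
        t = np.column_stack([np.ones(2000), x]) @ model.coefficients
        p = 1 / (1 + np.exp(-t))
        w = p * (1 - p)
        xmat = np.column_stack([np.ones(2000), x])
        se = np.sqrt(np.diag(np.linalg.inv(xmat.T @ (xmat * w[:, None]))))
        for est, s, true in zip(model.coefficients, se, (beta0, beta1)):
            assert abs(est - true) < 1.96 * s

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 + 0.8 * x))))
        df = pd.DataFrame({"x": x, "label": y.astype(float)})
        ours = fit_logistic(df, ["x"], log_scale=False)
        ref = sm.Logit(y.astype(float),
                       sm.add_constant(x)).fit(disp=0)
        assert np.allclose(ours.coefficients, ref.params, atol=1e-6)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_detected_with_auc_one(self):
        df = pd.DataFrame({
            "case_id": [f"c{i}" for i in range(8)],
            "group": ["healthy"] * 4 + ["aneurysm"] * 4,
            "diameter_mm": 20.0, "quadrant": "A",
            "SSI": [1, 2, 3, 4, 40, 50, 60, 70],
            "dSSI": [1, 2, 3, 4, 40, 50, 60, 70]})
        model = fit_logistic(df, ["SSI"])
        assert model.separated and not model.converged
        assert model.auc == 1.0

    def test_log_likelihood_non_decreasing(self):
        t = gen_cohort(5, 8, gap=3.0, seed=2)
        model = fit_logistic(t, ["SSI", "dSSI"])
        ll = np.asarray(model.ll_history)
        assert np.all(np.diff(ll) >= -1e-10)

    def test_single_class_raises(self):
        df = pd.DataFrame({"label": [1.0] * 5, "x": np.arange(5.0)})
        with pytest.raises(ValueError, match="class"):
            fit_logistic(df, ["x"], log_scale=False)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc([1, 2, 3, 4], y)[0] == 1.0
        assert roc_auc([4, 3, 2, 1], y)[0] == 0.0

    def test_ties_match_exhaustive_pair_count(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.7, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        total = 0.0
        for p in pos:
            for n in neg:
                total += 1.0 if p > n else (0.5 if p == n else 0.0)
        assert auc == pytest.approx(total / (pos.size * neg.size), abs=1e-12)

    def test_sklearn_oracle_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels)[0] == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_roc_points_span_unit_square(self):
        rng = np.random.default_rng(7)
        auc, pts = roc_auc(rng.normal(size=50), rng.integers(0, 2, 50))
        assert pts[0, 1] == 0.0 and pts[0, 2] == 0.0
        assert pts[-1, 1] == 1.0 and pts[-1, 2] == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestThreshold:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        scores = rng.random(10)
        labels = rng.integers(0, 2, 10)
        if labels.sum() in (0, 10):
            labels[0] = 1 - labels[0]
        best = _youden_threshold_raw(scores, labels)
        # brute force over all candidate thresholds
        pos, neg = labels == 1, labels == 0
        js = {}
        for th in scores:
            pred = scores >= th
            js[th] = (pred & pos).sum() / pos.sum() \
                + (~pred & neg).sum() / neg.sum() - 1.0
        jmax = max(js.values())
        winners = sorted(t for t, j in js.items() if j == jmax)
        assert best == winners[0]          # ties -> lower threshold

    def test_probability_threshold_in_unit_interval(self):
        t = gen_cohort(4, 6, gap=8.0, seed=3)
        model = fit_logistic(t, ["SSI"])
        th = optimal_threshold(model, t)
        assert 0.0 < th < 1.0
        assert 0.0 < model.optimal_threshold < 1.0


class TestQuadrantSummary:
    def _table(self, values):
        rows = []
        for i, v in enumerate(values):
            rows.append({"case_id": f"c{i}", "group": "healthy",
                         "diameter_mm": 20.0, "quadrant": "A",
                         "SSI": v, "dSSI": v})
        # aneurysm filler so validation passes
        rows.append({"case_id": "x", "group": "aneurysm",
                     "diameter_mm": 50.0, "quadrant": "A", "SSI": 1.0,
                     "dSSI": 1.0})
        return pd.DataFrame(rows)

    def test_single_value_cell(self):
        s = quadrant_summary(self._table([2.5]))
        row = s[(s.group == "healthy") & (s.quadrant == "A")].iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 2.5
        assert row["whisker_lo"] == row["whisker_hi"] == 2.5

    def test_one_to_nine_quartiles(self):
        # linear-interpolation (type-7) rule: quartiles 3 and 7
        s = quadrant_summary(self._table(list(range(1, 10))))
        row = s[(s.group == "healthy") & (s.quadrant == "A")].iloc[0]
        assert row["median"] == 5.0
        assert row["q1"] == 3.0 and row["q3"] == 7.0

    def test_gap10_cohort_median_ratio(self):
        t = gen_cohort(40, 40, gap=10.0, seed=5)
        s = quadrant_summary(t, "SSI")
        for q in "ALPR":
            h = s[(s.group == "healthy") & (s.quadrant == q)].iloc[0]
            a = s[(s.group == "aneurysm") & (s.quadrant == q)].iloc[0]
            assert a["median"] / h["median"] == pytest.approx(10.0, rel=0.35)

    def test_empty_cell_reported_missing(self):
        t = self._table([1.0, 2.0])
        s = quadrant_summary(t)
        row = s[(s.group == "healthy") & (s.quadrant == "L")].iloc[0]
        assert row["n"] == 0 and np.isnan(row["median"])
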