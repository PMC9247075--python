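"""Group-level operations: normalization, NB differential expression,
Kaplan-Meier / log-rank, and centroid classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survnet.group_level import (
    CentroidModel,
    NormalizationError,
    centroid_classify,
    classify_direction,
    differential_expression,
    km_estimate,
    logrank_survival,
    logrank_test,
    normalize_log,
    size_factors,
)
from survnet.simulate import generate_cohort
from survnet.types import ClinicalTable, ExpressionMatrix, RunConfig

from conftest import null_cohort_config


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = ExpressionMatrix(["G1", "G2"], ["S1", "S2", "S3"],
                             np.array([[5, 5, 5], [9, 9, 9]]))
        np.testing.assert_allclose(size_factors(m), 1.0)

    def test_scaled_column_scale_equivariance(self):
        base = np.array([[4, 4, 8], [10, 10, 20], [6, 6, 12]])
        m = ExpressionMatrix(["G1", "G2", "G3"], ["S1", "S2", "S3"], base)
        sf = size_factors(m)
        assert np.isclose(sf[2] / sf[0], 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_median_of_ratios_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.negative_binomial(10, 0.1, size=(500, 10)) + 1
        m = ExpressionMatrix([f"G{i}" for i in range(500)],
                             [f"S{j}" for j in range(10)], vals)
        sf = size_factors(m)
        # brute-force oracle: per-gene ratio to the geometric mean, median per sample
        geo = np.exp(np.mean(np.log(vals), axis=1))
        oracle = np.median(vals / geo[:, None], axis=0)
        np.testing.assert_allclose(sf, oracle, atol=1e-12)

    def test_all_zero_rows_need_fallback(self):
        m = ExpressionMatrix(["G1", "G2"], ["S1", "S2"],
                             np.array([[0, 5], [3, 0]]))
        with pytest.raises(NormalizationError, match="pseudo_reference"):
            size_factors(m)
        assert (size_factors(m, pseudo_reference=True) > 0).all()


class TestNormalizeLog:
    def test_closed_forms(self):
        m = ExpressionMatrix(["G1", "G2"], ["S1"], np.array([[0], [7]]))
        out = normalize_log(m, np.array([1.0]))
        assert out.values[0, 0] == 0.0
        out2 = normalize_log(m, np.array([2.0]))
        assert np.isclose(out2.values[1, 0], np.log2(4.5))
        assert out.scale_tag == "lognorm"

    def test_monotone_within_column(self, rng):
        vals = rng.integers(0, 500, (50, 4))
        m = ExpressionMatrix([f"G{i}" for i in range(50)], list("ABCD"), vals)
        out = normalize_log(m, np.array([0.5, 1.0, 1.5, 2.0]))
        for j in range(4):
            order_raw = np.argsort(vals[:, j], kind="stable")
            order_log = np.argsort(out.values[:, j], kind="stable")
            np.testing.assert_array_equal(order_raw, order_log)

    def test_nonpositive_factor_rejected(self):
        m = ExpressionMatrix(["G1"], ["S1"], np.array([[1]]))
        with pytest.raises(NormalizationError):
            normalize_log(m, np.array([0.0]))


class TestDifferentialExpression:
    @given(
        lfc=st.floats(-6, 6, allow_nan=False),
        p=st.floats(0, 1, allow_nan=False, exclude_min=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_direction_is_pure_threshold_rule(self, lfc, p):
        d = classify_direction(np.array([lfc]), np.array([p]))[0]
        if lfc >= 2 and p < 0.05:
            assert d == "up"
        elif lfc <= -2 and p < 0.05:
            assert d == "down"
        else:
            assert d == "ns"

    def test_classification_examples(self):
        """log2FC 2.5 is 'up' only when also significant at p < 0.05."""
        assert classify_direction(np.array([2.5]), np.array([0.01]))[0] == "up"
        assert classify_direction(np.array([2.5]), np.array([0.2]))[0] == "ns"
        assert classify_direction(np.array([-2.5]), np.array([0.01]))[0] == "down"

    def test_null_type_one_rate_in_oracle_band(self):
        """With no planted effects the fraction of unadjusted p < 0.05 stays
        inside the pre-registered simulation band [0.035, 0.063]."""
        rates = []
        for seed in range(5):
            counts, clinical, _ = generate_cohort(null_cohort_config(seed + 40))
            deg = differential_expression(counts, clinical, RunConfig())
            rates.append((deg.table["p"] < 0.05).mean())
        assert 0.035 <= np.mean(rates) <= 0.063

    def test_planted_degs_recovered(self, small_cohort):
        counts, clinical, truth = small_cohort
        deg = differential_expression(counts, clinical, RunConfig())
        found = set(deg.deg_genes)
        tp = len(found & set(truth.deg_signs))
        assert tp / len(truth.deg_signs) >= 0.9
        # planted signs match the reported direction
        for g, sign in truth.deg_signs.items():
            d = deg.table.loc[g, "direction"]
            if d != "ns":
                assert d == ("up" if sign > 0 else "down")

    def test_constant_zero_gene_is_ns(self):
        counts, clinical, _ = generate_cohort(null_cohort_config(8, n_genes=200))
        vals = counts.values.copy()
        vals[0, :] = 0
        m = ExpressionMatrix(counts.gene_ids, counts.sample_ids, vals)
        deg = differential_expression(m, clinical, RunConfig())
        assert deg.table.iloc[0]["direction"] == "ns"
        assert deg.table.iloc[0]["p"] == 1.0


class TestKaplanMeier:
    def test_two_deaths_hand_computation(self):
        km = km_estimate([5.0, 10.0], [1, 1])
        assert km.loc[km["time"] == 5.0, "survival"].item() == 0.5
        assert km.loc[km["time"] == 10.0, "survival"].item() == 0.0
        assert km.loc[km["time"] == 0.0, "survival"].item() == 1.0

    def test_all_censored_flat_curve(self):
        km = km_estimate([3.0, 8.0, 12.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_event_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.uniform(1, 50, 50).round(1)
        events = rng.integers(0, 2, 50)
        km = km_estimate(times, events)
        # naive oracle: walk event times, multiply survival factors
        s = 1.0
        for t in sorted(set(times[events == 1])):
            at_risk = (times >= t).sum()
            d = ((times == t) & (events == 1)).sum()
            s *= 1 - d / at_risk
            assert km.loc[km["time"] == t, "survival"].item() == pytest.approx(s, abs=0)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        times = rng.uniform(1, 40, 60).round(1)
        events = rng.integers(0, 2, 60)
        km = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for _, row in km.iterrows():
            assert np.isclose(
                kmf.predict(row["time"]), row["survival"], atol=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times = [5.0, 8.0, 5.0, 8.0]
        events = [1, 1, 1, 1]
        chi2, p = logrank_test(times, events, [0, 0, 1, 1])
        assert chi2 == 0.0 and p == 1.0

    def test_textbook_oe_oracle(self):
        """Statistic equals the hand observed-minus-expected computation."""
        times = np.array([6, 7, 10, 15, 19, 25, 1, 3, 4, 8, 11, 16], dtype=float)
        events = np.array([1, 0, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1])
        group = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        chi2, p = logrank_test(times, events, group)
        o_minus_e, var = 0.0, 0.0
        for t in sorted(set(times[events == 1])):
            at = times >= t
            n, n1 = at.sum(), (at & (group == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (group == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert np.isclose(chi2, o_minus_e**2 / var, atol=1e-10)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        times = rng.uniform(1, 30, 40)
        events = rng.integers(0, 2, 40)
        group = rng.integers(0, 2, 40)
        chi2, p = logrank_test(times, events, group)
        ref = ll_logrank(times[group == 0], times[group == 1],
                         events[group == 0], events[group == 1])
        assert np.isclose(chi2, ref.test_statistic, atol=1e-8)
        assert np.isclose(p, ref.p_value, atol=1e-8)

    def test_median_split_ties_low_19_samples(self):
        """19 distinct values split 10 low / 9 high with ties to the low group."""
        x = np.arange(19.0)
        res = logrank_survival(x, np.arange(1.0, 20.0), np.ones(19, dtype=int))
        assert res["n_low"] == 10 and res["n_high"] == 9

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        times = rng.uniform(1, 30, 20)
        events = rng.integers(0, 2, 20)
        a = logrank_survival(x, times, events)
        b = logrank_survival(np.exp(x), times, events)
        assert a["chi2"] == b["chi2"]

    def test_degenerate_split_flagged(self):
        res = logrank_survival(np.ones(10), np.arange(1.0, 11.0), np.ones(10, int))
        assert res["testable"] is False and np.isnan(res["p"])


class TestCentroidClassify:
    def _model(self, rng, n_genes=30):
        genes = [f"G{i}" for i in range(n_genes)]
        return CentroidModel(
            ["typeA", "typeB", "typeC"], genes, rng.normal(size=(n_genes, 3))
        )

    def test_exact_centroid_scores_one(self, rng):
        model = self._model(rng)
        expr = ExpressionMatrix(model.gene_ids, ["S1"],
                                model.centroids[:, [1]], "lognorm")
        out = centroid_classify(expr, model)
        assert out.loc["S1", "best_subtype"] == "typeB"
        assert np.isclose(out.loc["S1", "typeB"], 1.0)

    def test_negated_centroid_scores_minus_one(self, rng):
        model = self._model(rng)
        expr = ExpressionMatrix(model.gene_ids, ["S1"],
                                -model.centroids[:, [0]], "lognorm")
        out = centroid_classify(expr, model)
        assert np.isclose(out.loc["S1", "typeA"], -1.0)

    def test_scores_match_correlation_oracle(self, rng):
        model = self._model(rng, n_genes=40)
        x = rng.normal(size=(40, 1))
        expr = ExpressionMatrix(model.gene_ids, ["S1"], x, "lognorm")
        out = centroid_classify(expr, model)
        for k, name in enumerate(model.subtypes):
            xm, cm = x[:, 0], model.centroids[:, k]
            oracle = np.sum((xm - xm.mean()) * (cm - cm.mean())) / (
                np.sqrt(np.sum((xm - xm.mean()) ** 2) * np.sum((cm - cm.mean()) ** 2))
            )
            assert np.isclose(out.loc["S1", name], oracle, atol=1e-12)

    def test_small_intersection_rejected(self, rng):
        model = self._model(rng, n_genes=5)
        expr = ExpressionMatrix(model.gene_ids, ["S1"],
                                rng.normal(size=(5, 1)), "lognorm")
        with pytest.raises(ValueError, match="genes shared"):
            centroid_classify(expr, model)
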