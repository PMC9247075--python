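"""Co-expression core: soft threshold, TOM, module detection, eigengenes,
merging, and module-trait association."""
import numpy as np
import pandas as pd
import pytest

from survnet.coexpression import (
    detect_modules,
    merge_modules,
    module_eigengenes,
    module_significance,
    module_trait_association,
    pick_soft_threshold,
    tom_from_expression,
)
from survnet.group_level import normalize_log, size_factors
from survnet.simulate import generate_cohort
from survnet.types import ClinicalTable, ExpressionMatrix

from conftest import module_cohort_config


def _expr(vals, tag="lognorm"):
    vals = np.asarray(vals, float)
    return ExpressionMatrix(
        [f"G{i}" for i in range(vals.shape[0])],
        [f"S{j}" for j in range(vals.shape[1])],
        vals,
        tag,
    )


class TestSoftThreshold:
    def test_selection_rule_smallest_power_reaching_target(self, rng):
        """On a cohort with planted modules the chosen power is the smallest
        candidate whose signed fit reaches the target."""
        counts, _, _ = generate_cohort(module_cohort_config(0))
        ln = normalize_log(counts, size_factors(counts))
        res = pick_soft_threshold(ln, r2_target=0.85)
        assert res.chosen in res.powers
        if res.reached_target:
            below = [p for p, r in zip(res.powers, res.r2) if p < res.chosen]
            assert all(
                r < 0.85 for p, r in zip(res.powers, res.r2) if p < res.chosen
            )
            assert res.r2[res.powers.index(res.chosen)] >= 0.85

    def test_fallback_argmax_with_warning_flag(self, rng):
        # pure noise never reaches the target; argmax is returned, flagged
        x = _expr(rng.normal(size=(60, 19)))
        res = pick_soft_threshold(x, powers=(1, 2), r2_target=0.999)
        assert res.reached_target is False
        assert res.chosen == res.powers[int(np.argmax(res.r2))]

    def test_scale_free_connectivities_score_high(self, rng):
        """Connectivities drawn from a power law (configuration-model style)
        give a signed fit above 0.8; anti-scale-free increasing-density
        degrees score negative."""
        from survnet.coexpression import _scale_free_fit

        k = (1.0 - rng.uniform(size=3000)) ** (-1.0 / 1.5)  # Pareto tail, alpha=2.5
        assert _scale_free_fit(k) >= 0.8
        # mass concentrated at high k: density increases with k -> negative sign
        k_bad = 100.0 - (1.0 - rng.uniform(size=3000)) ** (-1.0 / 1.5)
        assert _scale_free_fit(k_bad[k_bad > 0]) < 0

    def test_mean_connectivity_decreasing_in_power(self):
        counts, _, _ = generate_cohort(module_cohort_config(1))
        ln = normalize_log(counts, size_factors(counts))
        res = pick_soft_threshold(ln)
        assert (np.diff(res.mean_connectivity) < 0).all()


class TestTom:
    def test_two_gene_closed_form(self, rng):
        """For two genes, TOM equals the adjacency |cor|^beta itself."""
        x = rng.normal(size=(2, 15))
        beta = 6
        tom = tom_from_expression(_expr(x), beta)
        a = abs(np.corrcoef(x)[0, 1]) ** beta
        assert np.isclose(tom[0, 1], a, atol=1e-12)
        assert tom[0, 0] == 1.0

    def test_orthogonal_genes_give_zero_overlap(self):
        # exactly orthogonal patterns: correlation 0 everywhere off-diagonal
        x = np.array([[1.0, 1, -1, -1], [1.0, -1, 1, -1], [1.0, -1, -1, 1]])
        tom = tom_from_expression(_expr(x), 2)
        off = tom[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 12))
        beta = 5
        tom = tom_from_expression(_expr(x), beta)
        a = np.abs(np.corrcoef(x)) ** beta
        np.fill_diagonal(a, 0.0)
        n = 20
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expect = (l + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert np.isclose(tom[i, j], expect, atol=1e-10)

    def test_bounds_symmetry_unit_diagonal(self, rng):
        x = rng.normal(size=(30, 19))
        tom = tom_from_expression(_expr(x), 7)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_constant_gene_rejected(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            tom_from_expression(_expr(x), 2)


class TestDetectModules:
    def test_perfect_blocks_recovered(self):
        """A block-diagonal dissimilarity (0.1 within, 0.9 between) yields
        exactly the three planted modules."""
        n = 90
        d = np.full((n, n), 0.9)
        for b in range(3):
            sl = slice(30 * b, 30 * (b + 1))
            d[sl, sl] = 0.1
        np.fill_diagonal(d, 0.0)
        ms = detect_modules(d, [f"G{i}" for i in range(n)], min_module_size=10)
        assert len(ms.module_ids) == 3
        for b in range(3):
            block = ms.labels[30 * b : 30 * (b + 1)]
            assert len(set(block)) == 1 and block[0] != 0

    def test_min_size_filters_everything(self):
        n = 30
        d = np.full((n, n), 0.9)
        for b in range(3):
            sl = slice(10 * b, 10 * (b + 1))
            d[sl, sl] = 0.1
        np.fill_diagonal(d, 0.0)
        ms = detect_modules(d, [f"G{i}" for i in range(n)], min_module_size=50)
        assert (ms.labels == 0).all()

    def test_gene_order_permutation_equivariance(self):
        counts, _, truth = generate_cohort(module_cohort_config(3))
        ln = normalize_log(counts, size_factors(counts))
        tom = tom_from_expression(ln, 6)
        ms = detect_modules(1 - tom, ln.gene_ids)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ln.n_genes)
        tom_p = tom[np.ix_(perm, perm)]
        ms_p = detect_modules(1 - tom_p, [ln.gene_ids[i] for i in perm])
        # same partition up to relabeling
        from sklearn.metrics import adjusted_rand_score

        lab = dict(zip(ms.gene_ids, ms.labels))
        lab_p = dict(zip(ms_p.gene_ids, ms_p.labels))
        genes = ln.gene_ids
        assert adjusted_rand_score(
            [lab[g] for g in genes], [lab_p[g] for g in genes]
        ) == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_genes_give_common_profile(self, rng):
        prof = rng.normal(size=12)
        x = np.tile(prof, (5, 1))
        mes, expl = module_eigengenes(_expr(x), np.ones(5, int))
        z = (prof - prof.mean()) / prof.std(ddof=1)
        np.testing.assert_allclose(mes["ME1"].to_numpy(), z, atol=1e-8)
        assert expl[1] == pytest.approx(1.0)

    def test_perfectly_correlated_pair_explains_everything(self, rng):
        g = rng.normal(size=10)
        x = np.vstack([g, 3 * g + 5])
        _, expl = module_eigengenes(_expr(x), np.ones(2, int))
        assert expl[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(25, 19))
        mes, _ = module_eigengenes(_expr(x), np.ones(25, int))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        pc1 = u[:, 0]
        pc1 = (pc1 - pc1.mean()) / pc1.std(ddof=1)
        me = mes["ME1"].to_numpy()
        assert np.allclose(me, pc1, atol=1e-8) or np.allclose(me, -pc1, atol=1e-8)

    def test_standardized_and_oriented(self, rng):
        x = rng.normal(size=(40, 19)) + rng.normal(size=19)
        mes, _ = module_eigengenes(_expr(x), np.ones(40, int))
        me = mes["ME1"].to_numpy()
        assert np.isclose(me.mean(), 0, atol=1e-10)
        assert np.isclose(me.std(ddof=1), 1, atol=1e-10)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        assert np.corrcoef(me, z.mean(axis=0))[0, 1] >= 0


class TestMergeModules:
    def test_highly_correlated_modules_merged(self, rng):
        """Two modules sharing a latent profile (eigengene cor ~ 0.9) merge
        at the 0.25 dissimilarity cut."""
        f = rng.normal(size=19)
        a = f[None, :] + 0.25 * rng.normal(size=(30, 19))
        b = f[None, :] + 0.25 * rng.normal(size=(30, 19))
        x = np.vstack([a, b])
        labels = np.array([1] * 30 + [2] * 30)
        expr = _expr(x)
        ms = merge_modules(expr, _module_set(expr.gene_ids, labels), 0.25)
        assert len(ms.module_ids) == 1

    def test_orthogonal_modules_untouched(self, rng):
        counts, _, truth = generate_cohort(module_cohort_config(5))
        ln = normalize_log(counts, size_factors(counts))
        labels = np.array([truth.module_labels.get(g, 0) for g in ln.gene_ids])
        ms = merge_modules(ln, _module_set(ln.gene_ids, labels), 0.25)
        assert len(ms.module_ids) == 5

    def test_idempotent(self, rng):
        counts, _, truth = generate_cohort(module_cohort_config(6))
        ln = normalize_log(counts, size_factors(counts))
        labels = np.array([truth.module_labels.get(g, 0) for g in ln.gene_ids])
        once = merge_modules(ln, _module_set(ln.gene_ids, labels), 0.25)
        twice = merge_modules(ln, once, 0.25)
        np.testing.assert_array_equal(once.labels, twice.labels)


def _module_set(gene_ids, labels):
    from survnet.coexpression import ModuleSet

    return ModuleSet(list(gene_ids), labels)


class TestModuleTrait:
    def _clinical(self, traits, trait_types, n=19):
        ids = [f"S{j}" for j in range(n)]
        return ClinicalTable(
            ids,
            ["ST"] * 10 + ["LT"] * (n - 10),
            np.concatenate([np.linspace(3, 12, 10), np.linspace(36, 60, n - 10)]),
            np.ones(n, int),
            pd.DataFrame(traits, index=ids),
            trait_types,
        )

    def test_perfect_correlation_significant(self, rng):
        me = rng.normal(size=19)
        clin = self._clinical({"t": me}, {"t": "continuous"})
        mes = pd.DataFrame({"ME1": me}, index=clin.sample_ids)
        out = module_trait_association(mes, clin)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-10 and row["significant"]

    def test_bonferroni_factor_is_pair_count(self, rng):
        mes = pd.DataFrame(rng.normal(size=(19, 35)),
                           columns=[f"ME{i+1}" for i in range(35)])
        clin = self._clinical(
            {"a": rng.normal(size=19), "b": rng.integers(0, 3, 19)},
            {"a": "continuous", "b": "categorical"},
        )
        mes.index = clin.sample_ids
        out = module_trait_association(mes, clin)
        assert len(out) == 70
        finite = out.dropna(subset=["p"])
        np.testing.assert_allclose(
            finite["p_bonferroni"], np.minimum(1.0, finite["p"] * 70)
        )

    def test_spearman_used_for_categorical(self, rng):
        me = np.arange(19.0)
        clin = self._clinical({"grade": (me > 9).astype(int)}, {"grade": "categorical"})
        mes = pd.DataFrame({"ME1": me}, index=clin.sample_ids)
        out = module_trait_association(mes, clin)
        assert out.iloc[0]["method"] == "spearman"

    def test_too_few_complete_cases_flagged(self, rng):
        t = np.full(19, np.nan)
        t[:3] = [1.0, 2.0, 3.0]
        clin = self._clinical({"t": t}, {"t": "continuous"})
        mes = pd.DataFrame({"ME1": rng.normal(size=19)}, index=clin.sample_ids)
        out = module_trait_association(mes, clin)
        assert np.isnan(out.iloc[0]["p"])

    def test_module_significance_perfect_and_null(self, rng):
        trait = rng.normal(size=19)
        clin = self._clinical({"t": trait}, {"t": "continuous"})
        x = np.vstack([trait + 1e-9 * rng.normal(size=19) for _ in range(5)]
                      + [rng.normal(size=19) for _ in range(40)])
        expr = ExpressionMatrix([f"G{i}" for i in range(45)], clin.sample_ids, x, "lognorm")
        labels = np.array([1] * 5 + [2] * 40)
        ms = module_significance(expr, labels, clin, "t")
        assert ms[1] == pytest.approx(1.0, abs=1e-6)
        # null modules: mean |r| for n=19 is ~ sqrt(2/pi)/sqrt(n-1) ~ 0.19
        assert 0.08 <= ms[2] <= 0.35
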