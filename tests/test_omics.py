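import numpy as np
import pytest
from scipy import stats

from gliaquant.errors import DesignError, GliaquantError
from gliaquant.omics import (
    AssayTable,
    compare_groups,
    filter_flags,
    normalize_75th,
    pca_conditions,
    select_degs,
)
from gliaquant.synth import AssaySpec, ConditionEffect, generate_assay_matrix


def _table(values, flags=None, conditions=None):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    conditions = conditions or [f"c{j}" for j in range(ns)]
    return AssayTable(
        values=values,
        feature_ids=[f"f{i}" for i in range(nf)],
        sample_labels=[f"s{j}" for j in range(ns)],
        conditions=conditions,
        replicates=[1] * ns,
        flags=None if flags is None else np.asarray(flags),
    )


class TestFilterFlags:
    def test_no_flags_unchanged(self):
        t = _table(np.ones((10, 4)), flags=np.ones((10, 4), dtype=int))
        filtered, removed = filter_flags(t)
        assert filtered.n_features == 10
        assert removed == []

    def test_one_flagged_entry_drops_feature(self):
        flags = np.ones((10, 4), dtype=int)
        flags[3, 2] = 0
        filtered, removed = filter_flags(_table(np.ones((10, 4)), flags=flags))
        assert filtered.n_features == 9
        assert removed == ["f3"]

    def test_generator_flags_match_recount_oracle(self):
        table = generate_assay_matrix(AssaySpec(n_features=300, flag_fraction=0.2, seed=7))
        filtered, removed = filter_flags(table)
        brute = int(np.sum(~(table.flags == 0).any(axis=1)))
        assert filtered.n_features == brute
        assert len(removed) == 300 - brute

    def test_missing_flags_error(self):
        with pytest.raises(GliaquantError):
            filter_flags(_table(np.ones((5, 3))))

    def test_alternative_policies(self):
        flags = np.ones((4, 4), dtype=int)
        flags[0, :] = 0      # below background everywhere
        flags[1, :3] = 0     # majority
        flags[2, 0] = 0      # single sample
        t = _table(np.ones((4, 4)), flags=flags)
        assert filter_flags(t, "any")[0].n_features == 1
        assert filter_flags(t, "all")[0].n_features == 3
        assert filter_flags(t, "majority")[0].n_features == 2


class TestNormalize75:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(2, 1, 50)
        t = _table(np.column_stack([col] * 4))
        normed = normalize_75th(t)
        assert np.allclose(normed.values, t.values)

    def test_scaled_sample_restored(self):
        rng = np.random.default_rng(1)
        col = rng.lognormal(2, 1, 50)
        values = np.column_stack([col, col * 2.0, col])
        normed = normalize_75th(_table(values))
        assert np.allclose(normed.values[:, 0], normed.values[:, 1])

    def test_percentiles_equal_post_normalization(self):
        rng = np.random.default_rng(2)
        t = _table(rng.lognormal(3, 1, (200, 6)))
        normed = normalize_75th(t)
        q = np.percentile(normed.values, 75, axis=0)
        assert np.max(np.abs(q - q[0])) < 1e-9

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        t = _table(rng.lognormal(3, 1, (100, 5)))
        once = normalize_75th(t)
        twice = normalize_75th(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_zero_percentile_error(self):
        values = np.zeros((10, 3))
        values[0, :] = 1.0  # 75th percentile of mostly-zero sample is 0
        with pytest.raises(GliaquantError):
            normalize_75th(_table(values))


def _two_group_table(effects, n_features=20, n_reps=3, cv=0.05, seed=0):
    eff = np.ones(n_features)
    for i, e in effects.items():
        eff[i] = e
    spec = AssaySpec(
        n_features=n_features, n_replicates=n_reps, noise_cv=cv, seed=seed,
        conditions=(ConditionEffect("b", 1.0), ConditionEffect("a", tuple(eff))),
    )
    return generate_assay_matrix(spec)


class TestSelectDegs:
    def test_identical_groups_nothing_selected(self):
        t = _two_group_table({}, cv=0.05, seed=1)
        res = select_degs(t, "a", "b", shrinkage_weight=0.0)
        assert not res.selected.any()
        assert np.max(np.abs(res.log2_fc)) < 0.5

    def test_planted_fourfold_selected(self):
        t = _two_group_table({0: 4.0}, cv=0.05, seed=2)
        res = select_degs(t, "a", "b")
        assert res.selected[0]
        assert res.log2_fc[0] == pytest.approx(2.0, abs=0.2)

    def test_planted_1p5fold_never_selected(self):
        # |log2 1.5| = 0.585 < 1: the fold-change gate blocks selection
        for seed in range(5):
            t = _two_group_table({0: 1.5}, cv=0.02, seed=seed)
            res = select_degs(t, "a", "b")
            assert not res.selected[0]

    def test_selected_implies_both_thresholds(self):
        t = _two_group_table({0: 4.0, 1: 3.0, 2: 0.2}, cv=0.1, seed=3)
        res = select_degs(t, "a", "b")
        for i in np.nonzero(res.selected)[0]:
            assert res.p_values[i] < res.p_threshold
            assert abs(res.log2_fc[i]) > res.fc_threshold_log2

    def test_shrinkage_zero_matches_ordinary_t(self):
        t = _two_group_table({0: 2.0}, seed=4)
        res = select_degs(t, "a", "b", shrinkage_weight=0.0)
        a = np.log2(t.values[:, t.columns_for("a")])
        b = np.log2(t.values[:, t.columns_for("b")])
        oracle = stats.ttest_ind(a.T, b.T)
        assert np.allclose(res.p_values, oracle.pvalue, atol=1e-12)

    def test_too_few_replicates_error(self):
        spec = AssaySpec(n_replicates=2, seed=0)
        t = generate_assay_matrix(spec)
        t.conditions[1] = "other"  # leaves 1 replicate in "control"... and 2 in treated
        with pytest.raises(DesignError):
            select_degs(t, "control", "treated")


class TestPCA:
    def test_duplicated_profiles_coincide(self):
        rng = np.random.default_rng(5)
        profiles = rng.lognormal(2, 1, (30, 3))
        values = np.column_stack([profiles[:, [0, 0, 1, 1, 2, 2]]])
        res = pca_conditions(_table(values))
        assert np.allclose(res.scores[0], res.scores[1], atol=1e-9)
        assert np.allclose(res.scores[2], res.scores[3], atol=1e-9)

    def test_pov_sums_to_one(self):
        rng = np.random.default_rng(6)
        res = pca_conditions(_table(rng.lognormal(2, 1, (25, 5))))
        assert res.pov.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.pov) <= 1e-12)
        assert np.all((res.pov >= 0) & (res.pov <= 1))

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(10, 3, (6, 4))
        res = pca_conditions(_table(values))
        # oracle: eigen-decompose the sample covariance directly
        x = values.T - values.T.mean(axis=0)
        cov = x.T @ x / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores_oracle = x @ v
        k = min(res.scores.shape[1], 3)
        for c in range(k):
            assert np.allclose(
                np.abs(res.scores[:, c]), np.abs(scores_oracle[:, c]), atol=1e-8
            )
        pov_oracle = w[w > 1e-12] / w[w > 1e-12].sum()
        assert np.allclose(res.pov, pov_oracle, atol=1e-8)

    def test_too_few_samples_error(self):
        with pytest.raises(DesignError):
            pca_conditions(_table(np.ones((5, 2))))

    def test_rank_zero_error(self):
        with pytest.raises(GliaquantError):
            pca_conditions(_table(np.ones((5, 4))))


class TestCompareGroups:
    def test_identical_groups_t0_p1(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "unpaired")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_paired_constant_shift_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        res = compare_groups({"a": x, "b": x + 1.0}, "paired")
        assert res.degenerate

    def test_anova_matches_f_oracle(self):
        rng = np.random.default_rng(8)
        g = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0.5, 1, 10),
            "c": rng.normal(1.0, 1, 10),
        }
        res = compare_groups(g, "anova_bonferroni")
        # oracle: explicit between/within mean squares + F CDF
        allv = np.concatenate(list(g.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in g.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in g.values())
        dfb, dfw = len(g) - 1, allv.size - len(g)
        f = (ssb / dfb) / (ssw / dfw)
        p = stats.f.sf(f, dfb, dfw)
        assert res.statistic == pytest.approx(f, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-6)
        assert len(res.pairwise) == 3
        assert all(0 <= v <= 1 for v in res.pairwise.values())

    def test_bonferroni_capped_at_one(self):
        g = {k: np.array([1.0, 2.0, 3.0]) + 0.001 * i for i, k in enumerate("abcd")}
        res = compare_groups(g, "anova_bonferroni")
        assert all(p <= 1.0 for p in res.pairwise.values())

    def test_ks_design(self):
        rng = np.random.default_rng(9)
        res = compare_groups(
            {"a": rng.normal(0, 1, 50), "b": rng.normal(2, 1, 50)}, "ks"
        )
        assert res.p_value < 0.001

    def test_design_mismatch_errors(self):
        with pytest.raises(DesignError):
            compare_groups({"a": [1.0, 2.0]}, "unpaired")
        with pytest.raises(DesignError):
            compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0]}, "paired")
        with pytest.raises(DesignError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]}, "unpaired")
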