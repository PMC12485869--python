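"""Screen statistics: normalisation, tests, enrichment, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccmkit.screenstats import (
    ScreenDesign,
    dunnett_vs_control,
    knockdown_effects,
    normalize_to_control,
    osm_effect_enrichment,
    phenotype_pca,
    screen_ttests,
    ttest_vs_control,
)
from ccmkit.simkit import simulate_phenotype_table


def long_table(values_by_knockdown, treatment="OSM", metric="m"):
    rows = [
        (kd, treatment, metric, r + 1, v)
        for kd, vals in values_by_knockdown.items()
        for r, v in enumerate(vals)
    ]
    return pd.DataFrame(rows, columns=["knockdown", "treatment", "metric",
                                       "replicate", "value"])


class TestNormalize:
    def test_arithmetic_example(self):
        tab = long_table({"siSCR": [2.0, 4.0], "kd": [6.0]})
        out = normalize_to_control(tab, ScreenDesign())
        by_kd = out.groupby("knockdown")["value"].apply(list)
        assert by_kd["kd"] == [2.0]
        assert by_kd["siSCR"] == pytest.approx([2 / 3, 4 / 3])

    def test_all_equal_table_normalises_to_one(self):
        tab = long_table({"siSCR": [5.0, 5.0], "a": [5.0, 5.0], "b": [5.0, 5.0]})
        out = normalize_to_control(tab, ScreenDesign())
        assert (out["value"] == 1.0).all()

    def test_missing_control_stratum_is_named(self):
        tab = long_table({"kd": [1.0, 2.0]})
        with pytest.raises(ValueError, match="OSM"):
            normalize_to_control(tab, ScreenDesign())

    def test_simulated_30_percent_effect_recovered(self):
        eff = {("siKD01", "OSM", "msd_slope"): 0.3}
        tab = simulate_phenotype_table(n_knockdowns=2, effect_matrix=eff,
                                       noise_sd=0.02, n_replicates=20, seed=0)
        out = normalize_to_control(tab, ScreenDesign())
        sub = out[(out["knockdown"] == "siKD01") & (out["treatment"] == "OSM")
                  & (out["metric"] == "msd_slope")]
        assert sub["value"].mean() == pytest.approx(1.3, abs=0.03)


class TestDunnett:
    def test_single_comparison_reduces_to_t_test(self):
        groups = {"EGF": [0.1, -0.1, 0.05], "OSM": [0.5, 0.3, 0.25]}
        res = dunnett_vs_control(groups, ScreenDesign())
        t = stats.ttest_ind(groups["OSM"], groups["EGF"], equal_var=True).pvalue
        assert res[0].p_value == pytest.approx(t, rel=0.05)

    def test_strong_separation_is_significant(self):
        groups = {"EGF": [0.0, 0.1, -0.1], "OSM": [5.0, 5.1, 4.9]}
        res = dunnett_vs_control(groups, ScreenDesign())
        assert res[0].p_value < 0.001
        assert res[0].estimate == pytest.approx(5.0)

    def test_degenerate_identical_groups_raise(self):
        groups = {"EGF": [1.0, 1.0], "OSM": [2.0, 2.0]}
        with pytest.raises(ValueError, match="variance"):
            dunnett_vs_control(groups, ScreenDesign())

    def test_single_replicate_raises(self):
        with pytest.raises(ValueError, match="replicate"):
            dunnett_vs_control({"EGF": [1.0], "OSM": [2.0]}, ScreenDesign())

    def test_adjusted_p_dominates_unadjusted(self):
        # reference: the same pooled-variance per-contrast t without the
        # multiplicity adjustment
        from conftest import pooled_marginal_p

        rng = np.random.default_rng(0)
        for _ in range(25):
            groups = {"EGF": rng.normal(size=4),
                      "OSM": rng.normal(0.5, size=4),
                      "IFNG": rng.normal(1.0, size=4)}
            adj = dunnett_vs_control(groups, ScreenDesign())
            unadj = pooled_marginal_p(groups, "EGF")
            for a in adj:
                assert a.p_value >= unadj[a.contrast[0]] * 0.999


class TestTtest:
    def test_hand_computed_pooled_t(self):
        res = ttest_vs_control({"siSCR": [1, 2, 3], "kd": [11, 12, 13]},
                               ScreenDesign())
        assert res[0].estimate == pytest.approx(10.0)
        assert res[0].p_value == pytest.approx(2.552e-4, rel=1e-3)
        assert not res[0].adjusted

    def test_identical_groups_give_p_one(self):
        res = ttest_vs_control({"siSCR": [1.0, 2.0], "kd": [1.0, 2.0]},
                               ScreenDesign())
        assert res[0].p_value == pytest.approx(1.0)

    def test_swapping_groups_negates_estimate_keeps_p(self):
        a = ttest_vs_control({"siSCR": [1, 2, 3], "kd": [2, 3, 5]}, ScreenDesign())
        b = ttest_vs_control({"siSCR": [2, 3, 5], "kd": [1, 2, 3]}, ScreenDesign())
        assert a[0].p_value == pytest.approx(b[0].p_value)
        assert a[0].estimate == pytest.approx(-b[0].estimate)

    def test_zero_variance_unequal_means_warns_p_zero(self):
        with pytest.warns(UserWarning):
            res = ttest_vs_control({"siSCR": [1.0, 1.0], "kd": [2.0, 2.0]},
                                   ScreenDesign())
        assert res[0].p_value == 0.0

    def test_screen_ttests_cover_every_stratum(self):
        tab = simulate_phenotype_table(n_knockdowns=3, noise_sd=0.05, seed=1)
        results = screen_ttests(tab, ScreenDesign())
        # 3 knockdowns x 3 treatments x 4 metrics
        assert len(results) == 36


class TestEnrichment:
    def test_seven_of_fourteen(self):
        idx = [f"k{i}" for i in range(14)]
        osm = pd.Series([2.0] * 7 + [0.5] * 7, index=idx)
        ifng = pd.Series(1.0, index=idx)
        res = osm_effect_enrichment(osm, ifng)
        assert res.n_successes == 7
        assert res.p_value == pytest.approx(0.6047, abs=1e-4)

    def test_all_fourteen_closed_form(self):
        idx = [f"k{i}" for i in range(14)]
        res = osm_effect_enrichment(pd.Series(2.0, index=idx),
                                    pd.Series(1.0, index=idx))
        assert res.p_value == pytest.approx(0.5 ** 14)

    def test_zero_ifng_effect_dropped_with_warning(self):
        idx = ["a", "b"]
        with pytest.warns(UserWarning):
            res = osm_effect_enrichment(pd.Series([1.0, 1.0], index=idx),
                                        pd.Series([0.0, 0.5], index=idx))
        assert res.n_used == 1 and res.n_dropped == 1

    def test_effect_aggregation_rules(self):
        eff = {("siKD01", "OSM", "msd_slope"): 0.4,
               ("siKD01", "OSM", "cosine_similarity"): -0.3}
        tab = simulate_phenotype_table(n_knockdowns=1, effect_matrix=eff,
                                       noise_sd=0.0, seed=0)
        norm = normalize_to_control(tab, ScreenDesign())
        eu = knockdown_effects(norm, ScreenDesign(), aggregate="euclidean")
        mx = knockdown_effects(norm, ScreenDesign(), aggregate="max")
        assert eu.loc["siKD01", "OSM"] == pytest.approx(0.5)
        assert mx.loc["siKD01", "OSM"] == pytest.approx(0.4)


class TestPca:
    def test_loadings_orthonormal_variance_non_increasing(self):
        tab = simulate_phenotype_table(n_knockdowns=6, noise_sd=0.1, seed=2)
        res = phenotype_pca(normalize_to_control(tab, ScreenDesign()))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        assert (np.diff(res.variance_explained) <= 1e-12).all()
        assert res.variance_explained.sum() <= 1 + 1e-9

    def test_correlated_bivariate_pc1_is_diagonal(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=300)
        rows = [(f"k{i}", "T", m, 1, z[i, j])
                for i in range(300) for j, m in enumerate(["a", "b"])]
        tab = pd.DataFrame(rows, columns=["knockdown", "treatment", "metric",
                                          "replicate", "value"])
        res = phenotype_pca(tab)
        np.testing.assert_allclose(res.loadings["PC1"], [2 ** -0.5, 2 ** -0.5],
                                   atol=0.02)

    def test_duplicating_rows_leaves_loadings_unchanged(self):
        tab = simulate_phenotype_table(n_knockdowns=5, noise_sd=0.1, seed=4)
        norm = normalize_to_control(tab, ScreenDesign())
        doubled = pd.concat([norm, norm.assign(treatment=norm["treatment"] + "_b")],
                            ignore_index=True)
        a = phenotype_pca(norm)
        b = phenotype_pca(doubled)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-8)

    def test_fewer_than_two_rows_raises(self):
        tab = long_table({"siSCR": [1.0, 1.0]})
        with pytest.raises(ValueError):
            phenotype_pca(tab)
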