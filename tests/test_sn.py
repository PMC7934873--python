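"""Single-nucleus pseudo-bulk selection, regression contrasts, pseudobulk tracks."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from enhancerkit.sn import (
    adjust_bonferroni,
    diff_accessibility,
    diff_expression,
    pseudobulk_profile,
    select_nuclei,
)
from enhancerkit.synthetic import NucleusSimConfig, simulate_nucleus_table


@pytest.fixture(scope="module")
def labeled_table():
    cfg = NucleusSimConfig(seed=42, n_nuclei_per_group=600)
    table, _ = simulate_nucleus_table(cfg)
    rng = np.random.default_rng(0)
    table = table.copy()
    table["cell_type"] = rng.choice(["secretory", "ciliated", "basal"], size=len(table))
    return table


class TestSelectNuclei:
    def test_cell_type_filter(self, labeled_table):
        sub = select_nuclei(labeled_table, cell_types=["secretory"])
        assert set(sub["cell_type"]) == {"secretory"}

    def test_set_difference_arithmetic(self, labeled_table):
        epithelial = select_nuclei(labeled_table, cell_types=["secretory", "ciliated", "basal"])
        nonsecretory = select_nuclei(labeled_table, cell_types=["ciliated", "basal"])
        secretory = select_nuclei(labeled_table, cell_types=["secretory"])
        assert len(epithelial) == len(nonsecretory) + len(secretory)

    def test_unknown_label_lists_available(self, labeled_table):
        with pytest.raises(ValueError, match="available"):
            select_nuclei(labeled_table, cell_types=["goblet"])

    def test_combined_filters(self, labeled_table):
        sub = select_nuclei(labeled_table, cell_types=["basal"], disease="IPF")
        assert set(sub["disease"]) == {"IPF"} and set(sub["cell_type"]) == {"basal"}


class TestBonferroni:
    def test_scaling_cap_and_identity(self):
        from enhancerkit.sn import RegressionResult

        def res(p):
            return RegressionResult("f", "c", "a", "b", 1.0, 1.0, 1.0, p, 10, 10, "m")

        out = adjust_bonferroni([res(0.01), res(0.2)], n_tests=10)
        assert out[0].p_adj == pytest.approx(0.1)
        assert out[1].p_adj == 1.0
        single = adjust_bonferroni([res(0.03)])
        assert single[0].p_adj == pytest.approx(0.03)
        with pytest.raises(ValueError, match="n_tests"):
            adjust_bonferroni([res(0.1), res(0.1)], n_tests=1)


class TestDiffAccessibility:
    def test_null_fold_change_near_one(self):
        cfg = NucleusSimConfig(seed=11, access_fold_change=1.0, expr_fold_change=1.0)
        table, _ = simulate_nucleus_table(cfg)
        res = diff_accessibility(table, cfg.access_feature, "disease", groups=["control", "IPF"])
        assert 0.9 <= res.fold_change <= 1.1
        assert res.p > 1e-3  # no planted effect

    def test_recovery_of_planted_ratio(self):
        cfg = NucleusSimConfig(seed=7, access_fold_change=1.5)
        table, _ = simulate_nucleus_table(cfg)
        res = diff_accessibility(table, cfg.access_feature, "disease", groups=["control", "IPF"])
        assert 1.35 <= res.fold_change <= 1.65
        assert res.p < 1e-6

    def test_all_zero_group_flagged_finite(self):
        cfg = NucleusSimConfig(seed=3, n_nuclei_per_group=200)
        table, _ = simulate_nucleus_table(cfg)
        table.loc[table.disease == "control", cfg.access_feature] = 0
        res = diff_accessibility(table, cfg.access_feature, "disease", groups=["control", "IPF"])
        assert np.isfinite(res.fold_change) and res.fold_change > 0
        assert "zero_group_mean_offset" in res.flags

    def test_reciprocal_fold_changes(self):
        cfg = NucleusSimConfig(seed=5, n_nuclei_per_group=400)
        table, _ = simulate_nucleus_table(cfg)
        fwd = diff_accessibility(table, cfg.access_feature, "disease", groups=["control", "IPF"])
        rev = diff_accessibility(table, cfg.access_feature, "disease", groups=["IPF", "control"])
        assert fwd.fold_change * rev.fold_change == pytest.approx(1.0)


class TestDiffExpression:
    def test_null_fold_change_near_one(self):
        cfg = NucleusSimConfig(seed=13, access_fold_change=1.0, expr_fold_change=1.0)
        table, _ = simulate_nucleus_table(cfg)
        res = diff_expression(table, cfg.expr_feature, "disease", groups=["control", "IPF"])
        assert 0.9 <= res.fold_change <= 1.1

    def test_recovery_of_planted_ratio(self):
        cfg = NucleusSimConfig(seed=17, expr_fold_change=1.91, nb_dispersion=0.5)
        table, _ = simulate_nucleus_table(cfg)
        res = diff_expression(table, cfg.expr_feature, "disease", groups=["control", "IPF"])
        assert abs(res.fold_change - 1.91) / 1.91 <= 0.1
        assert res.method == "negative_binomial_lrt"

    def test_depth_offset_absorbs_depth_scaling(self):
        cfg = NucleusSimConfig(seed=19, n_nuclei_per_group=400)
        table, _ = simulate_nucleus_table(cfg)
        res1 = diff_expression(table, cfg.expr_feature, "disease", groups=["control", "IPF"])
        doubled = table.assign(total_counts=table.total_counts * 2)
        res2 = diff_expression(doubled, cfg.expr_feature, "disease", groups=["control", "IPF"])
        assert res2.fold_change == pytest.approx(res1.fold_change, rel=1e-4)

    def test_genotype_contrast_variable(self):
        cfg = NucleusSimConfig(
            seed=23, group_variable="genotype", group_labels=("GG", "TT"), expr_fold_change=1.36
        )
        table, _ = simulate_nucleus_table(cfg)
        res = diff_expression(table, cfg.expr_feature, "genotype", groups=["GG", "TT"])
        assert abs(res.fold_change - 1.36) / 1.36 <= 0.12


class TestPermutationNull:
    def test_pvalues_uniform_under_label_permutation(self):
        """Permuting disease labels must give uniform p-values in both tests."""
        cfg = NucleusSimConfig(seed=29, n_nuclei_per_group=250)
        table, _ = simulate_nucleus_table(cfg)
        rng = np.random.default_rng(29)
        p_acc, p_expr = [], []
        for _ in range(120):
            perm = table.assign(disease=rng.permutation(table.disease.to_numpy()))
            p_acc.append(
                diff_accessibility(perm, cfg.access_feature, "disease", groups=["control", "IPF"]).p
            )
            p_expr.append(
                diff_expression(perm, cfg.expr_feature, "disease", groups=["control", "IPF"]).p
            )
        assert kstest(p_acc, "uniform").pvalue > 0.01
        assert kstest(p_expr, "uniform").pvalue > 0.01


class TestPseudobulk:
    FRAGS = pd.DataFrame(
        {
            "nucleus_id": ["n1", "n1", "n2"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [100, 400, 100],
            "end": [200, 450, 200],
        }
    )

    def _subset(self, ids):
        return pd.DataFrame(
            {
                "nucleus_id": ids,
                "sample_id": "s",
                "disease": "IPF",
                "genotype": "GG",
                "cell_type": "secretory",
                "total_counts": 1000,
            }
        )

    def test_single_fragment_scaled_coverage(self):
        track = pseudobulk_profile(self._subset(["n1"]), self.FRAGS, ("chr1", 0, 500))
        assert np.all(track.raw[100:200] == 1) and track.raw[99] == 0 and track.raw[200] == 0
        assert np.all(track.normalized[100:200] == 1e4)

    def test_duplicate_nucleus_doubles_raw_not_normalized(self):
        one = pseudobulk_profile(self._subset(["n1"]), self.FRAGS, ("chr1", 0, 500))
        n1_frags = self.FRAGS[self.FRAGS.nucleus_id == "n1"]
        frags2 = pd.concat([self.FRAGS, n1_frags.assign(nucleus_id="n1b")], ignore_index=True)
        two = pseudobulk_profile(self._subset(["n1", "n1b"]), frags2, ("chr1", 0, 500))
        np.testing.assert_array_equal(two.raw, 2 * one.raw)
        np.testing.assert_array_equal(two.normalized, one.normalized)

    def test_empty_subset_flagged_zero_track(self):
        track = pseudobulk_profile(self._subset([]), self.FRAGS, ("chr1", 0, 500))
        assert track.empty and track.raw.sum() == 0

    def test_region_outside_chromosome_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            pseudobulk_profile(
                self._subset(["n1"]), self.FRAGS, ("chr1", 0, 5000), chrom_sizes={"chr1": 1000}
            )
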