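"""Fold changes, Student's t test, volcano tables, clustering, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from conftest import make_quant_matrix
from plexquant.diffstats import (
    hierarchical_cluster,
    log2_fold_change,
    pca_scores,
    student_t_test,
    volcano_table,
)


class TestLog2FoldChange:
    def test_identical_groups_zero(self):
        lfc, _ = log2_fold_change([5.0, 5.0], [5.0, 5.0])
        assert lfc == 0.0

    def test_fourfold_means(self):
        lfc, _ = log2_fold_change([400.0, 400.0], [100.0, 100.0])
        assert lfc == pytest.approx(2.0)

    def test_zero_variance_zero_se(self):
        lfc, se = log2_fold_change([100.0] * 3, [50.0] * 3)
        assert lfc == pytest.approx(1.0) and se == 0.0

    def test_delta_method_se(self):
        a, b = [90.0, 100.0, 110.0], [45.0, 50.0, 55.0]
        _, se = log2_fold_change(a, b)
        expected = math.sqrt(
            np.var(a, ddof=1) / (3 * 100.0**2) + np.var(b, ddof=1) / (3 * 50.0**2)
        ) / math.log(2)
        assert se == pytest.approx(expected, rel=1e-12)

    def test_floor_replaces_zeros(self):
        lfc, _ = log2_fold_change([4.0, 4.0], [0.0, 0.0], floor=1.0)
        assert lfc == pytest.approx(2.0)

    def test_all_zero_groups_rejected(self):
        with pytest.raises(ZeroDivisionError):
            log2_fold_change([0.0], [0.0], floor=0.0)


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_pooled_example(self):
        # pooled variance 4, se = 2*sqrt(2/3), df = 4
        t, p = student_t_test([10, 12, 14], [20, 22, 24])
        assert t == pytest.approx(-6.123724, abs=1e-5)
        assert p == pytest.approx(2 * stats.t.sf(6.123724, 4), rel=1e-4)
        assert p == pytest.approx(0.00356, abs=2e-4)

    def test_swap_symmetry(self):
        t1, p1 = student_t_test([1, 2, 4], [5, 6, 9])
        t2, p2 = student_t_test([5, 6, 9], [1, 2, 4])
        assert t1 == -t2 and p1 == p2

    def test_degenerate_zero_variance(self):
        _, p_same = student_t_test([3.0, 3.0], [3.0, 3.0])
        _, p_diff = student_t_test([3.0, 3.0], [4.0, 4.0])
        assert p_same == 1.0 and p_diff == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [2.0, 3.0])


class TestVolcano:
    def matrix(self):
        rng = np.random.default_rng(17)
        vals = rng.lognormal(5, 0.1, size=(30, 6))
        vals[0, 3:] *= 2.0  # planted 2x in the KO half
        return make_quant_matrix(vals)

    def test_row_per_protein_and_flags(self):
        qm = self.matrix()
        out = volcano_table(qm, ("KO", "WT"))
        assert len(out) == 30
        assert (out["significant"] == (out["p_value"] < 0.05)).all()

    def test_noiseless_planted_ratio_exact(self):
        vals = np.tile([100.0, 100.0, 100.0, 200.0, 200.0, 200.0], (3, 1))
        qm = make_quant_matrix(vals)
        out = volcano_table(qm, ("KO", "WT"))
        assert np.allclose(out["log2_ratio"], 1.0)

    def test_significance_invariant_to_global_rescale(self):
        qm = self.matrix()
        scaled = make_quant_matrix(qm.values.to_numpy() * 7.3)
        a = volcano_table(qm, ("KO", "WT")).set_index("protein")["significant"]
        b = volcano_table(scaled, ("KO", "WT")).set_index("protein")["significant"]
        assert (a == b.loc[a.index]).all()

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            volcano_table(self.matrix(), ("KO", "HET"))

    def test_sorted_by_p_then_effect(self):
        out = volcano_table(self.matrix(), ("KO", "WT"))
        assert out["p_value"].is_monotonic_increasing


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        vals = np.column_stack([np.arange(5.0)] * 2 + [np.arange(5.0) * 3 + 1])
        qm = make_quant_matrix(vals, genotypes=["WT", "WT", "KO"])
        Z, labels = hierarchical_cluster(qm, axis="samples", zscore=False)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_upgma_hand_example(self):
        # 1-D points 0, 1, 10: merge (0,1) at height 1, then at (10+9)/2 = 9.5
        qm = make_quant_matrix([[0.0, 1.0, 10.0]], genotypes=["WT", "WT", "KO"])
        Z, _ = hierarchical_cluster(qm, axis="samples", zscore=False)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(9.5)

    def test_strong_effects_split_genotypes(self):
        rng = np.random.default_rng(17)
        vals = rng.lognormal(5, 0.05, size=(100, 6))
        vals[:30, 3:] *= 4.0
        qm = make_quant_matrix(vals)
        Z, labels = hierarchical_cluster(qm, axis="samples")
        cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        groups = {}
        for lab, c in zip(labels, cut):
            groups.setdefault(c, set()).add(str(qm.design.loc[lab, "genotype"]))
        assert all(len(g) == 1 for g in groups.values())  # pure split: Rand = 1

    def test_constant_rows_dropped_and_logged(self):
        vals = np.vstack(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]]
        )
        qm = make_quant_matrix(vals)
        Z, labels = hierarchical_cluster(qm, axis="proteins")
        assert len(labels) == 2  # constant row removed
        assert any(
            "dropped_constant_rows" in p["step"] for p in qm.provenance
        )

    def test_single_item_axis_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(
                make_quant_matrix([[1.0, 2.0, 3.0, 4.0]]), axis="proteins"
            )


class TestPca:
    def test_two_samples_rank_one(self):
        rng = np.random.default_rng(1)
        qm = make_quant_matrix(rng.lognormal(3, 0.5, (20, 2)), genotypes=["WT", "KO"])
        scores, frac = pca_scores(qm)
        assert frac[0] == pytest.approx(1.0)

    def test_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(3, 0.5, (20, 1))
        vals = np.column_stack([base, base, rng.lognormal(3, 0.5, (20, 2))])
        qm = make_quant_matrix(vals, genotypes=["WT", "WT", "KO", "KO"])
        scores, _ = pca_scores(qm)
        assert np.allclose(scores.iloc[0], scores.iloc[1], atol=1e-8)

    def test_planted_groups_separate_on_pc1(self):
        rng = np.random.default_rng(17)
        vals = rng.lognormal(5, 0.05, size=(200, 6))
        vals[:50, 3:] *= 1.5
        qm = make_quant_matrix(vals)
        scores, frac = pca_scores(qm)
        wt = scores.iloc[:3, 0]
        ko = scores.iloc[3:, 0]
        assert (wt.max() < ko.min()) or (ko.max() < wt.min())

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(3)
        qm = make_quant_matrix(rng.lognormal(3, 0.5, (30, 5)),
                               genotypes=["WT", "WT", "WT", "KO", "KO"])
        s1, _ = pca_scores(qm)
        s2, _ = pca_scores(qm)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_variance_fractions_bounded(self):
        rng = np.random.default_rng(4)
        qm = make_quant_matrix(rng.lognormal(3, 0.5, (30, 6)))
        _, frac = pca_scores(qm)
        assert frac.sum() <= 1.0 + 1e-9
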