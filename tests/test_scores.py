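"""Hand-computed examples, oracle equivalence and invariants of the nine
time-course scores."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import naive_score_all, random_tensor, tensor_from_rows

from vaccsig import GroupAssignment, score_all
from vaccsig.scores import (
    score_absfc,
    score_diff26,
    score_numsigneg,
    score_numsigpos,
    score_sim,
    score_signif,
    score_tscore,
)

NAN = float("nan")


class TestSimilarityScore:
    def test_equal_group_means_give_zero(self):
        g = np.array([[1.0] * 5, [2.0] * 5, [1.5] * 5])
        assert score_sim(g, [0, 1], [2]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        g = np.array([[1.0] * 5, [2.0] * 5, [2.5] * 5])
        assert score_sim(g, [0, 1], [2]) == pytest.approx(1.0)

    def test_group_swap_symmetry(self):
        g = np.array([[1.3] * 5, [0.4] * 5, [2.2] * 5])
        assert score_sim(g, [0, 1], [2]) == score_sim(g, [2], [0, 1])

    def test_missing_baseline_names_group(self):
        g = np.array([[NAN, 1, 1, 1, 1], [1.0] * 5])
        with pytest.raises(ValueError, match="group R"):
            score_sim(g, [0], [1])


class TestTrajectoryDistance:
    def test_identical_series_give_zero(self):
        g = np.array([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]], dtype=float)
        assert score_diff26(g, [0], [1]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        g = np.array([[1, 1, 1, 1, 4], [1, 1, 1, 1, 1]], dtype=float)
        assert score_diff26(g, [0], [1]) == pytest.approx(3.0)

    def test_metric_symmetry(self):
        g = np.array([[1, 2, 0.5, 4, 1], [2, 1, 1, 1, 3]], dtype=float)
        assert score_diff26(g, [0], [1]) == pytest.approx(
            score_diff26(g, [1], [0]))


class TestSignSum:
    def test_all_unit_fold_changes_give_zero(self):
        g = np.ones((3, 5))
        assert score_tscore(g, [0, 1, 2]) == 0

    def test_enumeration_example(self):
        # late fold changes (2,3) and (0.5,4): +1 +1 -1 +1 = 2
        g = np.array([[1, 1, 1, 2, 3], [1, 1, 1, 0.5, 4]], dtype=float)
        assert score_tscore(g, [0, 1]) == 2

    def test_maximum_attained(self):
        g = np.full((7, 5), 3.0)
        assert score_tscore(g, range(7)) == 14


class TestSignificantCount:
    def test_window_values_do_not_count(self):
        g = np.array([[0.5, 1.0, 1.5, 2.0, 0.7]])
        assert score_signif(g, [0]) == 0

    def test_enumeration_example(self):
        g = np.array([[2.5, 0.4, 1.0, 1.9, NAN]])
        assert score_signif(g, [0]) == 2

    def test_boundary_two_is_strict(self):
        g = np.array([[2.0, 2.0001, 1, 1, 1]])
        assert score_signif(g, [0]) == 1


class TestAbsLogFoldChange:
    def test_unit_fold_changes_give_zero(self):
        assert score_absfc(np.ones((2, 5)), [0, 1]) == pytest.approx(0.0)

    def test_natural_log_hand_arithmetic(self):
        g = np.array([[math.e, math.e ** 2, NAN, NAN, NAN]])
        assert score_absfc(g, [0]) == pytest.approx(3.0)

    def test_reciprocal_invariance(self):
        rng = np.random.default_rng(2)
        g = np.exp(rng.normal(0, 1, size=(3, 5)))
        assert score_absfc(g, [0, 1, 2]) == pytest.approx(
            score_absfc(1.0 / g, [0, 1, 2]))

    def test_log_base_switch(self):
        g = np.array([[4.0, 1, 1, 1, 1]])
        assert score_absfc(g, [0], log_base=2) == pytest.approx(2.0)
        assert score_absfc(g, [0], log_base=10) == pytest.approx(math.log10(4))


class TestResponderCounts:
    def test_no_upregulation(self):
        assert score_numsigpos(np.ones((3, 5)), [0, 1, 2]) == 0

    def test_per_patient_maxima(self):
        g = np.array([[2.5, 1, 1, 1, 1], [1.8, 1, 1, 1, 1],
                      [1, 1, 3.0, 1, 1]])
        assert score_numsigpos(g, [0, 1, 2]) == 2

    def test_sentinel_means_no_downregulation(self):
        assert score_numsigneg(np.ones((4, 5)), range(4)) == -1

    def test_one_downregulated_patient(self):
        g = np.ones((3, 5))
        g[1, 3] = 0.4
        assert score_numsigneg(g, [0, 1, 2]) == -2


class TestScoreAll:
    def test_all_ones_tensor_is_the_null_vector(self):
        tensor, groups = tensor_from_rows([[1.0] * 5] * 3, [[1.0] * 5] * 2)
        row = score_all(tensor, groups).iloc[0]
        assert row["sim"] == 0 and row["diff26"] == 0
        assert row["tscoreR"] == 0 and row["tscoreN"] == 0
        assert row["SignifR"] == 0 and row["SignifN"] == 0
        assert row["absFCR"] == 0 and row["absFCN"] == 0
        assert row["NumSigPos"] == 0 and row["NumSigNeg"] == -1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tensor, groups = random_tensor(rng, n_genes=6)
        got = score_all(tensor, groups)
        expected = naive_score_all(tensor, groups)
        pd.testing.assert_frame_equal(
            got[expected.columns].astype(float), expected.astype(float),
            check_exact=False, atol=1e-12, rtol=0, check_names=False)

    def test_group_scores_depend_only_on_own_group(self):
        rng = np.random.default_rng(42)
        tensor, groups = random_tensor(rng, n_genes=4)
        base = score_all(tensor, groups)
        # perturb non-responder cells only
        n_idx = tensor.patient_indices(groups.non_responders)
        perturbed = tensor.values.copy()
        perturbed[:, n_idx, :] *= 1.7
        from vaccsig.core import FoldChangeTensor
        t2 = FoldChangeTensor(tensor.gene_ids, tensor.patient_ids, perturbed,
                              tensor.mask)
        after = score_all(t2, groups)
        for col in ("tscoreR", "SignifR", "absFCR", "NumSigPos", "NumSigNeg"):
            pd.testing.assert_series_equal(base[col], after[col])

    def test_masking_a_cell_preserves_other_scores(self):
        rng = np.random.default_rng(9)
        tensor, groups = random_tensor(rng, n_genes=5, missing_frac=0.0)
        from vaccsig.core import FoldChangeTensor
        mask2 = tensor.mask.copy()
        mask2[0, 2] = False  # drop one responder mid-course cell
        v2 = tensor.values.copy()
        v2[:, 0, 2] = np.nan
        t2 = FoldChangeTensor(tensor.gene_ids, tensor.patient_ids, v2, mask2)
        base = score_all(tensor, groups)
        after = score_all(t2, groups)
        # scores built only from late cells or the other group are unchanged
        for col in ("tscoreR", "tscoreN", "SignifN", "absFCN"):
            pd.testing.assert_series_equal(base[col], after[col])

    def test_score_bounds(self):
        rng = np.random.default_rng(17)
        tensor, groups = random_tensor(rng, n_genes=10)
        table = score_all(tensor, groups)
        r_idx = tensor.patient_indices(groups.responders)
        late_r = int(tensor.mask[r_idx][:, (3, 4)].sum())
        assert (table["tscoreR"].abs() <= late_r).all()
        assert (table["SignifR"] <= tensor.mask[r_idx].sum()).all()
        assert (table["NumSigPos"] <= len(groups.responders)).all()
        assert (table["NumSigNeg"] <= -1).all()

    def test_empty_group_rejected(self):
        tensor, _ = tensor_from_rows([[1.0] * 5], [[1.0] * 5])
        with pytest.raises(ValueError, match="responder"):
            score_all(tensor, GroupAssignment(["R0"], ["nobody"]))
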