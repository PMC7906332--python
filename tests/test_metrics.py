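"""Evaluation measures against naive oracles and worked examples."""

import numpy as np
import pytest

from pfpwgan.annotations import AnnotationMatrix
from pfpwgan.go_dag import propagate_true_path
from pfpwgan.metrics import (cooccurrence_heatmap, f1_by_height,
                             f1_by_sample_count, fmax, heatmap_mse, micro_f1,
                             protein_prf, term_auc_mcc, term_aupr, term_f1,
                             threshold_grid, tpr_score)

from conftest import annotation, make_dag
from oracles import naive_fmax, naive_term_aupr, naive_term_f1, naive_tpr, random_dag

R, A, B = "GO:0000001", "GO:0000002", "GO:0000003"


class TestThresholdGrid:
    def test_shape_and_endpoints(self):
        g = threshold_grid()
        assert len(g) == 100 and g[0] == 0.0 and g[-1] == 1.0
        assert (np.diff(g) > 0).all()


class TestProteinPrf:
    def test_direct_counts(self):
        truth = [1, 1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.1, 0.2]
        prec, rec, tp, fp, fn = protein_prf(truth, scores, 0.5)
        assert (tp, fp, fn) == (2, 1, 1)
        assert prec == pytest.approx(2 / 3) and rec == pytest.approx(2 / 3)

    def test_perfect(self):
        prec, rec, *_ = protein_prf([1, 0, 1], [1.0, 0.0, 1.0], 0.5)
        assert prec == 1.0 and rec == 1.0

    def test_no_predictions_convention(self):
        prec, rec, *_ = protein_prf([1, 1], [0.1, 0.2], 0.9)
        assert prec == 0.0 and rec == 0.0


class TestFmax:
    def test_perfect_scores(self, rng):
        truth = rng.integers(0, 2, size=(6, 5))
        truth[:, 0] = 1  # no empty proteins
        f, t = fmax(truth, truth.astype(float))
        assert f == pytest.approx(1.0)
        assert 0 < t <= 1

    def test_single_protein_worked_example(self):
        f, t = fmax(np.array([[1, 0]]), np.array([[0.9, 0.4]]))
        assert f == pytest.approx(1.0)
        assert 0.4 < t <= 0.9

    def test_inverted_scores_match_oracle(self, rng):
        truth = rng.integers(0, 2, size=(3, 4))
        scores = 1.0 - truth.astype(float)
        grid = threshold_grid()
        assert fmax(truth, scores, grid)[0] == pytest.approx(
            naive_fmax(truth, scores, grid), abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        grid = threshold_grid()
        for _ in range(5):
            truth = rng.integers(0, 2, size=(20, 15))
            scores = rng.random((20, 15))
            assert fmax(truth, scores, grid)[0] == pytest.approx(
                naive_fmax(truth, scores, grid), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fmax(np.zeros((0, 3)), np.zeros((0, 3)))


class TestTermF1:
    def test_perfectly_ranked(self):
        assert term_f1([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8]) == pytest.approx(1.0)

    def test_constant_half_scores_balanced(self):
        # all-positive prediction at t <= 0.5: F1 = 2p/(p+1), prevalence 1/2 -> 2/3
        v = term_f1([1, 1, 0, 0], [0.5] * 4)
        assert v == pytest.approx(2 / 3)

    def test_no_positives_undefined(self):
        assert np.isnan(term_f1([0, 0, 0], [0.2, 0.3, 0.4]))

    def test_oracle_equivalence_random(self, rng):
        grid = threshold_grid()
        for _ in range(10):
            truth = rng.integers(0, 2, size=30)
            scores = rng.random(30)
            got = term_f1(truth, scores, grid)
            want = naive_term_f1(truth, scores, grid)
            assert got == pytest.approx(want, abs=1e-12)


class TestTermAupr:
    def test_perfect_ranking(self):
        assert term_aupr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_reversed_ranking_matches_enumeration(self):
        truth = [1, 1, 0, 0]
        scores = [0.1, 0.2, 0.8, 0.9]
        assert term_aupr(truth, scores) == pytest.approx(
            naive_term_aupr(truth, scores), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        n = 10000
        truth = (rng.random(n) < 0.3).astype(int)
        scores = rng.random(n)
        assert term_aupr(truth, scores) == pytest.approx(0.3, abs=0.02)

    def test_no_positives_undefined(self):
        assert np.isnan(term_aupr([0, 0], [0.1, 0.9]))

    def test_oracle_equivalence_with_ties(self, rng):
        for _ in range(10):
            truth = rng.integers(0, 2, size=25)
            truth[0] = 1
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=25)
            assert term_aupr(truth, scores) == pytest.approx(
                naive_term_aupr(truth, scores), abs=1e-12)


class TestAucMcc:
    def test_perfect_separation(self):
        auc, mcc = term_auc_mcc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 0.5)
        assert auc == 1.0 and mcc == pytest.approx(1.0)

    def test_independent_scores_auc_half(self, rng):
        n = 10000
        truth = rng.integers(0, 2, size=n)
        auc, _ = term_auc_mcc(truth, rng.random(n), 0.5)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_balanced_confusion_gives_zero_mcc(self):
        _, mcc = term_auc_mcc([1, 1, 0, 0], [0.9, 0.1, 0.9, 0.1], 0.5)
        assert mcc == 0.0

    def test_degenerate_column_auc_undefined(self):
        auc, _ = term_auc_mcc([1, 1], [0.5, 0.6], 0.5)
        assert np.isnan(auc)


class TestTprScore:
    def _chain(self):
        return make_dag({R: set(), A: {R}, B: {A}})

    def test_deep_term_alone_counts_both_ancestors(self):
        dag = self._chain()
        assert tpr_score(dag, annotation(dag, [{B}])) == 2.0

    def test_two_terms_missing_root(self):
        dag = self._chain()
        assert tpr_score(dag, annotation(dag, [{A, B}])) == 2.0

    def test_closed_set_has_no_conflicts(self):
        dag = self._chain()
        assert tpr_score(dag, annotation(dag, [{R, A, B}])) == 0.0

    def test_averages_over_proteins(self):
        dag = self._chain()
        m = annotation(dag, [{B}, {R, A, B}])
        assert tpr_score(dag, m) == 1.0

    def test_oracle_equivalence_random_dags(self, rng):
        for _ in range(10):
            terms, parents = random_dag(rng, int(rng.integers(5, 40)))
            dag = make_dag(parents)
            values = rng.integers(0, 2, size=(8, len(terms)))
            m = AnnotationMatrix([f"P{i}" for i in range(8)], terms, values)
            assert tpr_score(dag, m) == pytest.approx(
                naive_tpr(parents, terms, values), abs=1e-12)


class TestHeatmap:
    def test_pair_definition(self):
        m = np.array([[1, 1, 0], [0, 1, 1]])
        h = cooccurrence_heatmap(m)
        assert h[0, 1] == 1 and h[1, 2] == 1 and h[0, 2] == 0
        assert (h == h.T).all()
        assert h[2, 2] == 1  # column nonemptiness on the diagonal

    def test_empty_matrix(self):
        assert cooccurrence_heatmap(np.zeros((3, 4))).sum() == 0

    def test_invariant_under_row_duplication(self, rng):
        m = rng.integers(0, 2, size=(6, 5))
        np.testing.assert_array_equal(
            cooccurrence_heatmap(m), cooccurrence_heatmap(np.vstack([m, m])))

    def test_mse_worked_examples(self):
        a = np.eye(2)
        assert heatmap_mse(a, a) == 0.0
        assert heatmap_mse(a, 1 - a) == 1.0
        x = np.zeros((3, 3))
        y = np.zeros((3, 3))
        y[0, 1] = y[1, 0] = 1
        assert heatmap_mse(x, y) == pytest.approx(2 / 9)

    def test_mse_symmetric_and_bounded(self, rng):
        a = rng.integers(0, 2, size=(4, 4))
        b = rng.integers(0, 2, size=(4, 4))
        assert heatmap_mse(a, b) == heatmap_mse(b, a)
        assert 0.0 <= heatmap_mse(a, b) <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            heatmap_mse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBreakdowns:
    def test_heights_grouping(self):
        dag = make_dag({R: set(), A: {R}, B: {A}})
        out = f1_by_height(dag, [R, A, B], [0.5, 0.7, float("nan")])
        assert out == {0: 0.5, 1: 0.7}

    def test_flat_dag_single_group(self):
        dag = make_dag({R: set(), A: set()})
        out = f1_by_height(dag, [R, A], [0.2, 0.4])
        assert out == {0: pytest.approx(0.3)}

    def test_group_means_match_naive(self, rng):
        terms, parents = random_dag(rng, 20)
        dag = make_dag(parents)
        f1s = rng.random(20)
        out = f1_by_height(dag, terms, f1s)
        for h, mean in out.items():
            vals = [f for t, f in zip(terms, f1s) if dag.term_height(t) == h]
            assert mean == pytest.approx(sum(vals) / len(vals))

    def test_sample_count_pairs(self):
        truth = np.array([[1, 0], [1, 0], [0, 0]])
        out = f1_by_sample_count(truth, [0.8, float("nan")])
        assert out == [(2, 0.8)]


class TestMicroF1:
    def test_pooled_counts(self):
        truth = np.array([[1, 0], [0, 1]])
        scores = np.array([[0.9, 0.9], [0.1, 0.1]])
        # at 0.5: tp=1 (term0), fp=1, fn=1 -> F1 = 2/4
        assert micro_f1(truth, scores, 0.5) == pytest.approx(0.5)
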