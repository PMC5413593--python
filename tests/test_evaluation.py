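"""k-NN, ROC metrics, holdout evaluation and the experiment grid."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from gammase import (
    grid_pivot,
    grid_to_frame,
    holdout_evaluate,
    knn_classify,
    roc_auc,
    run_grid,
    stratified_split,
)
from gammase.errors import DegenerateSamplesError, ParameterError, SizeError

from conftest import make_features

A, C = "alcoholic", "control"


def brute_force_knn(train_x, train_y, test_x, k):
    """Exhaustive oracle: sort every (distance, index) pair explicitly."""
    preds, scores = [], []
    for q in test_x:
        pairs = sorted(
            (float(np.sqrt(np.sum((q - t) ** 2))), i)
            for i, t in enumerate(train_x)
        )
        idx = [i for _, i in pairs[:k]]
        labs = [train_y[i] for i in idx]
        score = labs.count(A) / k
        if score > 0.5:
            pred = A
        elif score < 0.5:
            pred = C
        else:
            pred = labs[0]
        preds.append(pred)
        scores.append(score)
    return np.asarray(preds, dtype=object), np.asarray(scores)


class TestKnn:
    def test_coincident_training_point(self):
        train = np.asarray([[0.0], [1.0]])
        y = np.asarray([C, A], dtype=object)
        pred, score = knn_classify(train, y, np.asarray([[1.0]]), k=1)
        assert pred[0] == A and score[0] == 1.0

    def test_nearest_point_wins_at_k1(self):
        train = np.asarray([[0.0], [1.0]])
        y = np.asarray([C, A], dtype=object)
        pred, _ = knn_classify(train, y, np.asarray([[0.4]]), k=1)
        assert pred[0] == C

    def test_distance_tie_breaks_to_lower_index(self):
        train = np.asarray([[-1.0], [1.0]])
        for y0, y1 in ((A, C), (C, A)):
            y = np.asarray([y0, y1], dtype=object)
            pred, _ = knn_classify(train, y, np.asarray([[0.0]]), k=1)
            assert pred[0] == y0

    def test_vote_tie_breaks_to_nearest_neighbor(self):
        train = np.asarray([[0.0], [1.0]])
        y = np.asarray([A, C], dtype=object)
        pred, score = knn_classify(train, y, np.asarray([[0.3]]), k=2)
        assert score[0] == 0.5 and pred[0] == A

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n_train = int(rng.integers(3, 50))
            n_test = int(rng.integers(1, 10))
            dim = int(rng.integers(1, 4))
            k = int(rng.integers(1, n_train + 1))
            train = rng.integers(-3, 4, size=(n_train, dim)).astype(float)
            test = rng.integers(-3, 4, size=(n_test, dim)).astype(float)
            y = np.asarray([A if b else C for b in rng.integers(0, 2, n_train)],
                           dtype=object)
            pred, score = knn_classify(train, y, test, k=k)
            pred_o, score_o = brute_force_knn(train, y, test, k)
            assert np.array_equal(pred, pred_o)
            np.testing.assert_allclose(score, score_o, atol=1e-12)

    def test_k1_resubstitution_is_perfect(self, rng):
        X = rng.standard_normal((30, 3))  # distinct points a.s.
        y = np.asarray([A if b else C for b in rng.integers(0, 2, 30)],
                       dtype=object)
        pred, _ = knn_classify(X, y, X, k=1)
        assert np.array_equal(pred, y)

    def test_parameter_errors(self):
        X = np.zeros((3, 2))
        y = np.asarray([A, C, A], dtype=object)
        with pytest.raises(SizeError):
            knn_classify(np.zeros((0, 2)), np.asarray([], dtype=object), X, k=1)
        with pytest.raises(ParameterError):
            knn_classify(X, y, X, k=4)
        with pytest.raises(ParameterError):
            knn_classify(X, y, X, k=1, metric="cosine")


class TestRoc:
    def test_perfect_separation(self):
        roc, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [A, A, C, C])
        assert auc == 1.0
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)

    def test_uninformative_scores(self):
        _, auc = roc_auc([0.5] * 6, [A, C, A, C, A, C])
        assert auc == 0.5

    def test_three_point_hand_case(self):
        # both +/- pairs concordant: (0.9 > 0.8) and (0.9 > 0.3)
        _, auc = roc_auc([0.9, 0.8, 0.3], [A, C, C])
        assert auc == pytest.approx(1.0)

    def test_monotone_curve(self, rng):
        scores = rng.integers(0, 4, 20) / 3.0
        truth = [A if b else C for b in rng.integers(0, 2, 20)]
        if A not in truth or C not in truth:
            truth[0], truth[1] = A, C
        roc, _ = roc_auc(scores, truth)
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)

    def test_auc_equals_concordance_and_reference(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 5, 30) / 4.0  # heavy ties, like k-NN votes
            truth = np.asarray([A if b else C for b in rng.integers(0, 2, 30)],
                               dtype=object)
            if A not in truth or C not in truth:
                continue
            _, auc = roc_auc(scores, truth)
            pos = scores[truth == A]
            neg = scores[truth == C]
            conc = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert auc == pytest.approx(conc, abs=1e-9)
            assert auc == pytest.approx(
                roc_auc_score((truth == A).astype(int), scores), abs=1e-9
            )

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateSamplesError):
            roc_auc([0.1, 0.9], [A, A])


class TestSplitAndHoldout:
    def test_stratified_split_contract(self):
        labels = np.asarray([A] * 10 + [C] * 6, dtype=object)
        train, test = stratified_split(labels, 0.5, seed=4)
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == 16
        assert sum(labels[i] == A for i in train) == 5
        assert sum(labels[i] == C for i in train) == 3
        t2, _ = stratified_split(labels, 0.5, seed=4)
        assert np.array_equal(train, t2)

    def test_split_fraction_validated(self):
        with pytest.raises(ParameterError):
            stratified_split(np.asarray([A, C], dtype=object), 1.0, 0)

    @staticmethod
    def separable_features(n_per_group=40, n_channels=6, seed=0):
        gen = np.random.default_rng(seed)
        values = gen.standard_normal((2 * n_per_group, n_channels)) * 0.05 + 0.4
        values[:n_per_group, -2:] += 0.3  # informative channels last
        labels = [A] * n_per_group + [C] * n_per_group
        return make_features(np.clip(values, 0, 1), labels)

    def test_ranked_mode_finds_out_of_prefix_channels(self):
        fm = self.separable_features()
        ranked = holdout_evaluate(fm, 2, 2, ranked=True, k=3, seed=1)
        plain = holdout_evaluate(fm, 2, 2, ranked=False, k=3, seed=1)
        assert ranked.efficiency > plain.efficiency
        assert ranked.efficiency > 0.9

    def test_report_counts_are_consistent(self):
        fm = self.separable_features()
        rep = holdout_evaluate(fm, 6, 3, ranked=True, k=3, seed=2)
        assert rep.n_test == 40
        assert rep.efficiency == (rep.tp + rep.tn) / rep.n_test
        assert rep.sensitivity == rep.tp / (rep.tp + rep.fn)
        assert rep.specificity == rep.tn / (rep.tn + rep.fp)

    def test_parameter_errors(self):
        fm = self.separable_features()
        with pytest.raises(ParameterError):
            holdout_evaluate(fm, 7, 2)
        with pytest.raises(ParameterError):
            holdout_evaluate(fm, 4, 5)
        with pytest.raises(ParameterError):
            holdout_evaluate(fm, 4, 2, rank_scope="all")

    def test_full_channel_set_is_ranking_invariant(self):
        """Selecting all channels makes ranking a pure permutation; PCA and
        k-NN are permutation invariant, so the reports must be identical."""
        fm = self.separable_features()
        r = holdout_evaluate(fm, 6, 4, ranked=True, k=3, seed=5)
        n = holdout_evaluate(fm, 6, 4, ranked=False, k=3, seed=5)
        assert (r.tp, r.fp, r.tn, r.fn) == (n.tp, n.fp, n.tn, n.fn)
        assert r.auc == pytest.approx(n.auc, abs=1e-12)

    def test_channel_relabeling_invariance(self):
        """Consistently permuting the channel order leaves reports unchanged."""
        fm = self.separable_features()
        gen = np.random.default_rng(9)
        perm = gen.permutation(fm.n_channels)
        fm_p = make_features(fm.values[:, perm], fm.labels)
        r = holdout_evaluate(fm, fm.n_channels, 3, ranked=True, k=3, seed=3)
        r_p = holdout_evaluate(fm_p, fm.n_channels, 3, ranked=True, k=3, seed=3)
        assert (r.tp, r.fp, r.tn, r.fn) == (r_p.tp, r_p.fp, r_p.tn, r_p.fn)


def test_null_data_classifies_at_chance():
    """With no planted effect the full pipeline stays at chance: mean
    holdout efficiency over 50 seeded splits within the binomial spread."""
    from gammase import SynthConfig, gamma_se_features, generate_epochs

    cfg = SynthConfig(n_per_group=300, n_channels=16, effect=0.0, seed=31)
    fm = gamma_se_features(generate_epochs(cfg))
    effs = [holdout_evaluate(fm, 16, 8, ranked=False, k=3, seed=s).efficiency
            for s in range(50)]
    assert 0.42 <= np.mean(effs) <= 0.58


class TestGrid:
    def test_row_counting_and_determinism(self):
        fm = TestSplitAndHoldout.separable_features()
        pcs = {6: [2, 4, 6], 4: [2, 4], 2: [2]}
        rows = run_grid(fm, pcs, seeds=(0, 1))
        assert len(rows) == 2 * (3 + 2 + 1) * 2
        again = run_grid(fm, pcs, seeds=(0, 1))
        assert grid_to_frame(rows).equals(grid_to_frame(again))

    def test_pivot_shape(self):
        fm = TestSplitAndHoldout.separable_features()
        rows = run_grid(fm, {4: [2, 4]}, seeds=(0, 1, 2))
        pivot = grid_pivot(rows)
        assert len(pivot) == 2
        assert "efficiency_pct_ranked" in pivot.columns
        assert "efficiency_pct_nonranked" in pivot.columns

    def test_invalid_grid_cell_rejected(self):
        fm = TestSplitAndHoldout.separable_features()
        with pytest.raises(ParameterError):
            run_grid(fm, {4: [5]})
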