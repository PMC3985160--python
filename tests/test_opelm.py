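"""OP-ELM: MRSR neuron ranking, PRESS leave-one-out error, and pruning.

The keystone check is PRESS against the explicit retrain-per-sample
leave-one-out oracle: the closed form must reproduce it exactly.
"""

import numpy as np
import pytest

from protelm.elm import encode_targets, hidden_output, init_hidden, train_elm
from protelm.opelm import (
    NeuronRanking,
    PressCurve,
    RidgeContext,
    mrsr_rank,
    press_loo_error,
    select_neuron_count,
    train_opelm,
)

from conftest import random_classification
from protelm.elm import Dataset


def explicit_loo(H, T):
    """Retrain N times with one sample held out; mean squared prediction error."""
    N = H.shape[0]
    errors = []
    for i in range(N):
        mask = np.arange(N) != i
        beta, *_ = np.linalg.lstsq(H[mask], T[mask], rcond=None)
        errors.append((T[i] - H[i] @ beta) ** 2)
    return float(np.mean(errors))


class TestPress:
    def test_matches_explicit_loo_oracle(self, rng):
        """The module's decisive correctness property."""
        H = rng.normal(size=(20, 3))
        T = rng.normal(size=(20, 2))
        assert press_loo_error(H, T) == pytest.approx(explicit_loo(H, T), rel=1e-6)

    def test_constant_column_closed_form(self, rng):
        """A single constant regressor fits the mean; its LOO residuals are
        (t_i - mean) * N / (N - 1)."""
        N = 15
        H = np.ones((N, 1))
        t = rng.normal(size=(N, 1))
        expected = np.mean(((t - t.mean()) * N / (N - 1)) ** 2)
        assert press_loo_error(H, t) == pytest.approx(expected, rel=1e-10)

    def test_consistent_system_gives_zero(self, rng):
        H = rng.normal(size=(12, 4))
        T = H @ rng.normal(size=(4, 2))
        assert press_loo_error(H, T) == pytest.approx(0.0, abs=1e-18)

    def test_ridge_engages_only_when_singular(self, rng):
        H = rng.normal(size=(10, 2))
        H_sing = np.column_stack([H, H[:, 0]])  # exactly collinear
        value = press_loo_error(H_sing, rng.normal(size=(10, 1)), RidgeContext())
        assert np.isfinite(value)


class TestMrsrRank:
    def test_single_best_regressor_ranked_first(self, rng):
        H = rng.normal(size=(30, 6))
        T = H[:, [4]] + 1e-4 * rng.normal(size=(30, 1))
        order = mrsr_rank(H, T).order
        # brute force: the single column with the best LS fit to T
        best = min(range(6), key=lambda j: np.linalg.norm(
            T - H[:, [j]] @ np.linalg.lstsq(H[:, [j]], T, rcond=None)[0]))
        assert order[0] == best == 4

    def test_single_column_trivial_permutation(self, rng):
        assert np.array_equal(mrsr_rank(rng.normal(size=(5, 1)), rng.normal(size=(5, 1))).order, [0])

    def test_orthonormal_design_sorts_by_correlation(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(40, 5)))
        t = rng.normal(size=(40, 1))
        order = mrsr_rank(Q, t).order
        expected = np.argsort(-np.abs(Q.T @ t).ravel())
        assert np.array_equal(order, expected)

    def test_zero_variance_column_ranked_last(self, rng):
        H = rng.normal(size=(20, 4))
        H[:, 1] = 2.5
        order = mrsr_rank(H, rng.normal(size=(20, 2))).order
        assert order[-1] == 1

    def test_invariant_to_row_duplication(self, rng):
        H = rng.normal(size=(15, 6))
        T = rng.normal(size=(15, 2))
        doubled = mrsr_rank(np.vstack([H, H]), np.vstack([T, T])).order
        assert np.array_equal(mrsr_rank(H, T).order, doubled)

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            NeuronRanking(order=np.array([0, 0, 1]))


class TestSelectNeuronCount:
    def test_tie_resolves_to_smallest_k(self):
        assert PressCurve.from_errors([3.0, 1.0, 1.0, 2.0]).selected_k == 2

    def test_single_candidate(self):
        assert PressCurve.from_errors([0.7]).selected_k == 1

    def test_fast_path_matches_per_prefix_press(self, rng):
        H = rng.normal(size=(25, 8))
        T = rng.normal(size=(25, 3))
        curve = select_neuron_count(H, T)
        explicit = [press_loo_error(H[:, :k], T) for k in range(1, 9)]
        assert curve.loo_error == pytest.approx(explicit, rel=1e-8)

    def test_recovers_number_of_informative_neurons(self, rng):
        """Data built from 5 informative columns plus pure-noise columns:
        the PRESS argmin should land near 5 in most runs."""
        hits = 0
        for trial in range(50):
            trial_rng = np.random.default_rng(1000 + trial)
            H = trial_rng.normal(size=(60, 15))
            beta = np.zeros((15, 2))
            beta[:5] = trial_rng.normal(size=(5, 2))
            T = H @ beta + 0.05 * trial_rng.normal(size=(60, 2))
            curve = select_neuron_count(H, T)
            if abs(curve.selected_k - 5) <= 2:
                hits += 1
        assert hits >= 40  # >= 80% of seeds

    def test_curve_csv_export(self, rng, tmp_path):
        curve = select_neuron_count(rng.normal(size=(12, 4)), rng.normal(size=(12, 1)))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame["k"]) == [1, 2, 3, 4]
        assert frame["loo_error"].to_numpy() == pytest.approx(curve.loo_error)


class TestTrainOpelm:
    def test_pruned_size_bounded_and_deterministic(self, small_dataset):
        a = train_opelm(small_dataset, J_max=40, seed=2)
        b = train_opelm(small_dataset, J_max=40, seed=2)
        assert a.n_nodes <= 40
        assert a.extras["selected_k"] == b.extras["selected_k"]
        assert np.array_equal(a.W, b.W)

    def test_pruned_training_residual_not_below_full(self, small_dataset):
        T = encode_targets(small_dataset)
        model = train_opelm(small_dataset, J_max=40, seed=3)
        layer_full = init_hidden(40, small_dataset.n_features, "sigmoid", seed=3)
        H_full = hidden_output(small_dataset.X, layer_full)
        W_full, *_ = np.linalg.lstsq(H_full, T, rcond=None)
        res_full = np.linalg.norm(H_full @ W_full - T)
        H_kept = hidden_output(small_dataset.X, model.hidden)
        res_pruned = np.linalg.norm(H_kept @ model.W - T)
        assert res_pruned >= res_full - 1e-9

    def test_selected_k_minimizes_press_curve(self, small_dataset):
        model = train_opelm(small_dataset, J_max=30, seed=5)
        curve = model.extras["press_curve"]
        assert curve.loo_error[curve.selected_k - 1] == curve.loo_error.min()

    def test_permuted_labels_inflate_press_beyond_small_k(self):
        """With pure-noise targets the LOO curve should rise with k (adding
        neurons only overfits) in most seeds."""
        rising = 0
        for trial in range(20):
            rng = np.random.default_rng(2000 + trial)
            X, labels = random_classification(rng, 50, 6, 2)
            ds = Dataset.from_arrays(X, rng.permutation(labels))
            model = train_opelm(ds, J_max=30, seed=trial)
            curve = model.extras["press_curve"].loo_error
            if curve[-1] > curve[:10].min():
                rising += 1
        assert rising >= 16  # >= 80%

    def test_generalizes_at_least_as_well_as_elm_usually(self):
        """Pruning should not hurt held-out accuracy in most seeds."""
        from protelm.elm import accuracy
        from protelm.features import FeatureScaler, feature_matrix
        from protelm.synthetic import generate_dataset, make_profiles

        profiles = make_profiles(4, separation=0.35, seed=3)
        train = generate_dataset(profiles, [40] * 4, seed=3)
        test = generate_dataset(profiles, [40] * 4, seed=4)
        scaler = FeatureScaler().fit(feature_matrix(train.records))
        ds = Dataset.from_arrays(
            scaler.transform(feature_matrix(train.records)),
            np.asarray(train.labels, dtype=object),
        )
        X_test = scaler.transform(feature_matrix(test.records))
        wins = 0
        for seed in range(10):
            acc_op = accuracy(train_opelm(ds, J_max=120, seed=seed), X_test, test.labels)
            acc_elm = accuracy(train_elm(ds, 120, seed=seed), X_test, test.labels)
            if acc_op >= acc_elm - 1e-12:
                wins += 1
        assert wins >= 7
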