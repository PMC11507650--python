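"""Wavelength selectors: schedules, stability logic, planted-band recovery."""

import numpy as np
import pytest

from crabspec import (
    band_enrichment_pvalue,
    boss_select,
    cars_select,
    encode_labels,
    fit_msc_reference,
    msc,
    spxy_split,
    uve_select,
)
from crabspec.select import cars_decay_schedule


@pytest.fixture(scope="module")
def planted_training_data(study_dataset):
    """MSC-corrected training block of the calibrated study dataset."""
    part = spxy_split(study_dataset.absorbance, study_dataset.labels, 310)
    ref = fit_msc_reference(study_dataset.absorbance[part.train_idx])
    X = msc(study_dataset.absorbance, ref)
    y = encode_labels(study_dataset.labels, ("WL", "TL", "HL"))
    return X[part.train_idx], y[part.train_idx]


class TestEncodeLabels:
    def test_integer_codes_in_declared_order(self):
        codes = encode_labels(["HL", "WL", "TL"], ("WL", "TL", "HL"))
        assert codes.tolist() == [2.0, 0.0, 1.0]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            encode_labels(["XX"], ("WL", "TL"))


class TestCARS:
    def test_decay_schedule_endpoints(self):
        sched = cars_decay_schedule(3101, 100)
        assert sched[0] == 3101
        assert sched[-1] == 2
        assert np.all(np.diff(sched) <= 0)

    def test_retained_counts_match_closed_form(self):
        import math

        p, n_runs = 500, 50
        k = math.log(p / 2.0) / (n_runs - 1)
        expected = [math.ceil(math.exp(-k * i) * p) for i in range(n_runs)]
        assert cars_decay_schedule(p, n_runs).tolist() == expected

    def test_trajectory_u_shape_and_band_recovery(self, planted_training_data, band_indices, small_grid):
        X, y = planted_training_data
        res = cars_select(X, y, n_runs=100, folds=5, seed=3)
        traj = res.rmsecv_trajectory
        # dynamic decrease into a minimum away from the ends, then increase
        assert 0 < res.best_iteration < len(traj) - 1
        assert traj[-1] > traj.min() + 0.05
        assert traj[res.best_iteration] == traj.min()
        # selection concentrates in the two planted bands
        in_band = np.isin(res.selected_idx, band_indices).mean()
        null = band_indices.size / len(small_grid)
        assert in_band > 2 * null
        assert band_enrichment_pvalue(res.selected_idx, band_indices, len(small_grid)) < 0.01

    def test_deterministic_given_seed(self, planted_training_data):
        X, y = planted_training_data
        a = cars_select(X, y, n_runs=30, seed=5)
        b = cars_select(X, y, n_runs=30, seed=5)
        assert np.array_equal(a.selected_idx, b.selected_idx)
        assert np.allclose(a.rmsecv_trajectory, b.rmsecv_trajectory)

    def test_selected_indices_unique_and_in_bounds(self, planted_training_data):
        X, y = planted_training_data
        res = cars_select(X, y, n_runs=30, seed=1)
        assert np.unique(res.selected_idx).size == res.selected_idx.size
        assert res.selected_idx.min() >= 0
        assert res.selected_idx.max() < X.shape[1]


class TestUVE:
    def test_perfect_predictor_retained(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 20))
        y = X[:, 7].copy()
        res = uve_select(X, y, n_components=2, seed=0)
        assert 7 in res.selected_idx

    def test_duplicated_variable_gets_equal_stability(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 10))
        X[:, 4] = X[:, 2]
        y = X @ rng.standard_normal(10) + 0.1 * rng.standard_normal(50)
        res = uve_select(X, y, n_components=3, seed=1)
        stab = res.weights_history
        assert stab[2] == pytest.approx(stab[4], rel=1e-6)

    def test_pure_noise_false_keep_rate_small(self):
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(500 + seed)
            X = rng.standard_normal((80, 200))
            y = rng.standard_normal(80)
            res = uve_select(X, y, seed=seed)
            fracs.append(res.extras["n_survivors"] / 200)
        assert np.mean(fracs) <= 0.01

    def test_band_recovery_on_planted_data(self, planted_training_data, band_indices, small_grid):
        X, y = planted_training_data
        res = uve_select(X, y, seed=3)
        assert band_enrichment_pvalue(res.selected_idx, band_indices, len(small_grid)) < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 30))
        y = X[:, 3] + 0.5 * rng.standard_normal(40)
        a = uve_select(X, y, n_components=2, seed=9)
        b = uve_select(X, y, n_components=2, seed=9)
        assert np.array_equal(a.selected_idx, b.selected_idx)


class TestBOSS:
    def test_weights_normalized_each_iteration(self, planted_training_data):
        X, y = planted_training_data
        res = boss_select(X, y, n_bootstrap=40, max_iterations=4, seed=0)
        for w in res.weights_history:
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert (w >= 0).all()

    def test_trajectory_drops_then_rises_with_band_recovery(
        self, planted_training_data, band_indices, small_grid
    ):
        X, y = planted_training_data
        res = boss_select(X, y, n_bootstrap=150, max_iterations=40, seed=3)
        traj = res.rmsecv_trajectory
        assert traj[res.best_iteration] == traj.min()
        # rapid early decrease, later clearly above the minimum
        assert traj.min() < traj[0]
        assert traj[-1] > traj.min()
        assert band_enrichment_pvalue(res.selected_idx, band_indices, len(small_grid)) < 0.01

    def test_deterministic_given_seed(self, planted_training_data):
        X, y = planted_training_data
        a = boss_select(X, y, n_bootstrap=30, max_iterations=3, seed=7)
        b = boss_select(X, y, n_bootstrap=30, max_iterations=3, seed=7)
        assert np.array_equal(a.selected_idx, b.selected_idx)
        assert np.allclose(a.rmsecv_trajectory, b.rmsecv_trajectory)
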