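"""Generator: grid geometry, replicate averaging, planted class structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crabspec import (
    DEFAULT_GRID,
    SpectraSet,
    SyntheticConfig,
    WavenumberGrid,
    average_replicates,
    bayes_accuracy,
    calibrate_class_effects,
    generate_dataset,
    read_spectra_csv,
    write_spectra_csv,
)


class TestWavenumberGrid:
    def test_acquisition_grid_has_3101_points(self):
        assert len(DEFAULT_GRID) == 3101
        assert DEFAULT_GRID.values[0] == 10_000.0
        assert DEFAULT_GRID.values[-1] == 3_800.0

    @given(
        start=st.integers(100, 20_000),
        span_steps=st.integers(1, 4000),
        step=st.sampled_from([1, 2, 4, 5, 8, 10]),
    )
    @settings(max_examples=60, deadline=None)
    def test_length_formula(self, start, span_steps, step):
        end = start - span_steps * step
        grid = WavenumberGrid(float(start), float(end), float(step))
        assert len(grid) == (start - end) // step + 1
        assert np.all(np.diff(grid.values) == -step)

    def test_rejects_non_dividing_step(self):
        with pytest.raises(ValueError):
            WavenumberGrid(10_000, 3_800, 3.7)

    def test_rejects_ascending(self):
        with pytest.raises(ValueError):
            WavenumberGrid(3_800, 10_000, 2)


class TestGenerateDataset:
    def test_noise_free_effect_free_rows_identical(self, small_grid):
        cfg = SyntheticConfig(
            grid=small_grid,
            n_per_class=3,
            scatter_sd=0.0,
            baseline_sd=0.0,
            noise_sd=0.0,
            class_band_effects={c: (0.0, 0.0) for c in ("WL", "TL", "HL")},
            seed=0,
        )
        ds = generate_dataset(cfg)
        assert np.allclose(ds.absorbance, ds.absorbance[0])

    def test_point_count_matches_acquisition_grid(self):
        cfg = SyntheticConfig(n_per_class=1, seed=0)
        ds = generate_dataset(cfg)
        assert ds.absorbance.shape[1] == 3101

    def test_seed_determinism(self, small_grid):
        a = generate_dataset(SyntheticConfig(grid=small_grid, n_per_class=4, seed=42))
        b = generate_dataset(SyntheticConfig(grid=small_grid, n_per_class=4, seed=42))
        assert np.array_equal(a.absorbance, b.absorbance)
        assert np.array_equal(a.labels, b.labels)

    def test_per_class_counts_mirror_unbalanced_design(self, small_grid):
        ds = generate_dataset(
            SyntheticConfig(grid=small_grid, n_per_class=(5, 7, 6), seed=0)
        )
        counts = {c: int((ds.labels == c).sum()) for c in ("WL", "TL", "HL")}
        assert counts == {"WL": 5, "TL": 7, "HL": 6}

    def test_class_mean_differences_confined_to_planted_bands(
        self, small_grid, band_indices
    ):
        noise_sd = 0.05
        cfg = SyntheticConfig(
            grid=small_grid,
            n_per_class=100,
            scatter_sd=0.0,
            baseline_sd=0.0,
            noise_sd=noise_sd,
            seed=7,
        )
        ds = generate_dataset(cfg)
        outside = np.setdiff1d(np.arange(len(small_grid)), band_indices)
        means = [ds.absorbance[ds.labels == c].mean(axis=0) for c in ("WL", "TL", "HL")]
        for i in range(3):
            for j in range(i + 1, 3):
                gap = np.abs(means[i] - means[j])[outside].max()
                assert gap <= 3.0 * noise_sd / np.sqrt(100)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_per_class=0)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(site="claw")


class TestCalibration:
    def test_bayes_accuracy_limits(self):
        assert bayes_accuracy(0.0, 1.0) == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert bayes_accuracy(100.0, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_calibrated_effects_hit_target_empirically(self, small_grid):
        """Nearest-mean classification on the noise-only model reaches the target."""
        from crabspec.synthetic import DISCRIMINATIVE_BANDS, _band_profile

        target = 0.95
        eff = calibrate_class_effects(
            small_grid, noise_sd=0.1, n_replicates=3, target_accuracy=target
        )
        profiles = [_band_profile(small_grid, b) for b in DISCRIMINATIVE_BANDS]
        means = {k: a1 * profiles[0] + a2 * profiles[1] for k, (a1, a2) in eff.items()}
        rng = np.random.default_rng(0)
        sigma = 0.1 / np.sqrt(3)
        classes = list(means)
        hits = 0
        n_trials = 3000
        for t in range(n_trials):
            truth = classes[t % 3]
            x = means[truth] + sigma * rng.standard_normal(len(small_grid))
            guess = min(classes, key=lambda c: np.linalg.norm(x - means[c]))
            hits += guess == truth
        assert hits / n_trials == pytest.approx(target, abs=0.02)


class TestAverageReplicates:
    def test_idempotent_on_identical_replicates(self):
        s = np.linspace(0, 1, 10)
        assert np.array_equal(average_replicates([s, s, s]), s)

    def test_mean_of_constants(self):
        out = average_replicates([np.zeros(5), np.full(5, 2.0)])
        assert np.array_equal(out, np.ones(5))

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(1)
        reps = [rng.standard_normal(8) for _ in range(3)]
        expected = [sum(r[i] for r in reps) / 3 for i in range(8)]
        assert np.allclose(average_replicates(reps), expected, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            average_replicates([np.zeros(5), np.zeros(6)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])


class TestCsvRoundTrip:
    def test_round_trip_preserves_everything(self, small_grid, tmp_path):
        ds = generate_dataset(SyntheticConfig(grid=small_grid, n_per_class=3, seed=5))
        path = tmp_path / "spectra.csv"
        write_spectra_csv(ds, path)
        back = read_spectra_csv(path)
        assert back.grid == ds.grid
        assert np.allclose(back.absorbance, ds.absorbance)
        assert np.array_equal(back.labels, ds.labels)
        assert back.sample_ids == ds.sample_ids
        assert back.site == ds.site

    def test_duplicate_sample_ids_rejected(self, small_grid):
        with pytest.raises(ValueError, match="unique"):
            SpectraSet(
                grid=small_grid,
                absorbance=np.zeros((2, len(small_grid))),
                labels=np.array(["WL", "TL"]),
                site="abdomen",
                sample_ids=["a", "a"],
            )
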