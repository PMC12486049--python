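"""Fusion MLP: architecture, splits, weights, metrics, training behavior."""

import numpy as np
import pytest

from tfosim.estimator import (
    Dataset,
    MLPRegressor,
    TrainConfig,
    build_model,
    evaluate,
    random_split,
    round_weights,
    run_comparison,
    temporal_split,
    train,
)
from tfosim.optics_model import ConfigError


class TestArchitecture:
    def test_halving_schedule(self):
        assert TrainConfig(hidden=64).hidden_widths == (64, 32, 16, 8)
        assert TrainConfig(hidden=8).hidden_widths == (8,)

    def test_invalid_first_width_rejected(self):
        for bad in (12, 24, 7, 0):
            with pytest.raises(ConfigError):
                TrainConfig(hidden=bad)

    def test_parameter_count_closed_form(self):
        model = build_model(TrainConfig(hidden=64), input_width=10)
        # linear layers: (in+1)*out summed along 10-64-32-16-8-1, plus
        # gamma/beta per hidden stage
        linear = (10 + 1) * 64 + (64 + 1) * 32 + (32 + 1) * 16 + (16 + 1) * 8 + (8 + 1) * 1
        bn = 2 * (64 + 32 + 16 + 8)
        assert model.parameter_count == linear + bn

    def test_state_dict_roundtrip_preserves_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(64, 5))
        y = X @ rng.normal(size=5) * 3 + 50
        cfg = TrainConfig(hidden=16, max_epochs=5, seed=1)
        model = build_model(cfg, 5)
        model.fit(X, y, X, y)
        clone = MLPRegressor.from_state_dict(model.state_dict())
        np.testing.assert_allclose(clone.predict(X), model.predict(X))


class TestSplits:
    def test_random_split_per_group_proportions(self):
        groups = np.repeat([10.0, 20.0, 30.0], 100)
        tr, va = random_split(groups, frac=0.8, seed=4)
        for g in (10.0, 20.0, 30.0):
            assert (groups[tr] == g).sum() == 80
            assert (groups[va] == g).sum() == 20

    def test_random_split_disjoint_exhaustive_and_seeded(self):
        groups = np.repeat([1, 2], 50)
        tr1, va1 = random_split(groups, seed=7)
        tr2, va2 = random_split(groups, seed=7)
        np.testing.assert_array_equal(tr1, tr2)
        assert np.intersect1d(tr1, va1).size == 0
        assert np.union1d(tr1, va1).size == 100

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError):
            random_split(np.array([1, 1, 1, 2, 2, 2]), min_group=5)

    def test_temporal_split_contiguous_blocks(self):
        tr, va = temporal_split(10, k=5, fold=0)
        np.testing.assert_array_equal(va, [0, 1])
        np.testing.assert_array_equal(tr, np.arange(2, 10))
        # contiguity of every fold's validation block
        for fold in range(5):
            _, va = temporal_split(13, k=5, fold=fold)
            assert np.all(np.diff(va) == 1)

    def test_temporal_folds_partition_all_samples(self):
        seen = np.concatenate([temporal_split(13, 5, f)[1] for f in range(5)])
        np.testing.assert_array_equal(np.sort(seen), np.arange(13))
        sizes = [temporal_split(13, 5, f)[1].size for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_temporal_split_bounds(self):
        with pytest.raises(ConfigError):
            temporal_split(3, k=5, fold=0)
        with pytest.raises(ConfigError):
            temporal_split(10, k=5, fold=5)


class TestRoundWeights:
    def test_equal_rounds_unit_weights(self):
        np.testing.assert_allclose(round_weights(np.repeat([1, 2], 30)), 1.0)

    def test_normalisation_arithmetic(self):
        ids = np.array([0] * 100 + [1] * 50)
        w = round_weights(ids)
        np.testing.assert_allclose(w[:100], 0.75)
        np.testing.assert_allclose(w[100:], 1.5)
        assert w.sum() == pytest.approx(150.0)

    def test_per_round_total_weight_equal(self):
        ids = np.array([0] * 10 + [1] * 40 + [2] * 25)
        w = round_weights(ids)
        totals = [w[ids == r].sum() for r in (0, 1, 2)]
        np.testing.assert_allclose(totals, totals[0])


class TestEvaluate:
    def test_perfect_prediction(self):
        mae, std, r, p = evaluate(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert mae == 0.0 and std == 0.0
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_hand_arithmetic(self):
        mae, std, r, p = evaluate(np.array([12.0, 18.0, 33.0]),
                                  np.array([10.0, 20.0, 30.0]))
        assert mae == pytest.approx(7.0 / 3.0)

    def test_offset_changes_mae_not_correlation(self):
        rng = np.random.default_rng(2)
        y = rng.normal(50, 10, 100)
        pred = y + rng.normal(0, 1, 100)
        m1, _, r1, _ = evaluate(pred, y)
        m2, _, r2, _ = evaluate(pred + 5.0, y)
        assert m2 > m1
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_zero_variance_reports_nan_correlation(self):
        mae, std, r, p = evaluate(np.full(10, 3.0), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 100, 50)
        pred = y + rng.normal(0, 2, 50)
        perm = rng.permutation(50)
        assert evaluate(pred, y)[:3] == pytest.approx(evaluate(pred[perm], y[perm])[:3])


def linear_dataset(n=600, width=10, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, width))
    coef = rng.normal(size=width)
    y = X @ coef
    y = 50.0 + 20.0 * (y - y.mean()) / y.std()
    y = np.clip(y + noise * rng.normal(size=n), 0, 100)
    groups = np.repeat(np.arange(n // 100), 100)[:n]
    return Dataset(X=X, y=y, groups=groups)


class TestTraining:
    def test_constant_labels_are_fit_exactly(self):
        rng = np.random.default_rng(5)
        ds = Dataset(
            X=rng.normal(size=(200, 4)),
            y=np.full(200, 42.0),
            groups=np.zeros(200),
        )
        split = (np.arange(160), np.arange(160, 200))
        cfg = TrainConfig(hidden=16, max_epochs=60, seed=3)
        fit = train(ds, split, cfg)
        assert fit.mae < 1.0

    def test_noiseless_linear_map_recovered(self):
        # ample data: the deterministic map should be learned to a small
        # fraction of a percent
        ds = linear_dataset(n=5000, seed=1)
        split = random_split(ds.groups, seed=1)
        cfg = TrainConfig(hidden=32, seed=2)
        fit = train(ds, split, cfg)
        assert fit.mae < 0.5
        assert fit.pearson_r > 0.998

    def test_training_is_seed_deterministic(self):
        ds = linear_dataset(n=200, width=4, seed=2)
        split = (np.arange(160), np.arange(160, 200))
        cfg = TrainConfig(hidden=8, max_epochs=15, seed=9)
        f1 = train(ds, split, cfg)
        f2 = train(ds, split, cfg)
        np.testing.assert_array_equal(f1.val_predictions, f2.val_predictions)

    def test_early_stopping_and_best_restore(self):
        ds = linear_dataset(n=300, width=6, seed=3, noise=5.0)
        split = (np.arange(240), np.arange(240, 300))
        cfg = TrainConfig(hidden=8, max_epochs=300, patience=10, seed=4)
        fit = train(ds, split, cfg)
        n_epochs = len(fit.history["val_loss"])
        assert n_epochs <= 300
        best = np.argmin(fit.history["val_loss"])
        assert fit.best_epoch == best
        # stop happened no later than patience epochs after the best
        assert n_epochs - 1 - best <= cfg.patience + 1

    def test_equal_weights_match_unweighted(self):
        ds = linear_dataset(n=200, width=4, seed=6)
        split = (np.arange(160), np.arange(160, 200))
        cfg = TrainConfig(hidden=8, max_epochs=20, seed=5)
        unweighted = train(ds, split, cfg)
        weighted = train(ds, split, cfg, sample_weight=np.ones(200))
        np.testing.assert_allclose(
            weighted.val_predictions, unweighted.val_predictions, rtol=1e-10
        )


class TestComparison:
    def test_identical_feature_sets_tie_within_noise(self):
        ds = linear_dataset(n=400, width=6, seed=7, noise=3.0)
        twin = Dataset(X=ds.X.copy(), y=ds.y, groups=ds.groups)
        cfg = TrainConfig(hidden=16, max_epochs=60, seed=11)
        out = run_comparison(ds, twin, cfg, trials=2)
        assert out["improvement"]["mae_pct"] == pytest.approx(0.0, abs=10.0)

    def test_improvement_formula(self):
        # frozen arithmetic: (7.00 - 4.81) / 7.00 = 31.3 %
        assert 100 * (7.00 - 4.81) / 7.00 == pytest.approx(31.3, abs=0.05)

    def test_informative_features_beat_shuffled_ones(self):
        ds = linear_dataset(n=400, width=6, seed=8, noise=1.0)
        rng = np.random.default_rng(0)
        scrambled = Dataset(X=rng.permutation(ds.X, axis=0), y=ds.y, groups=ds.groups)
        cfg = TrainConfig(hidden=16, max_epochs=40, seed=12)
        out = run_comparison(ds, scrambled, cfg, trials=1)
        assert out["EPR"]["mae"] < out["RoR"]["mae"]

    def test_reproducible_given_seeds(self):
        ds = linear_dataset(n=200, width=4, seed=9, noise=2.0)
        twin = Dataset(X=ds.X * 2.0, y=ds.y, groups=ds.groups)
        cfg = TrainConfig(hidden=8, max_epochs=15, seed=13)
        a = run_comparison(ds, twin, cfg, trials=2)
        b = run_comparison(ds, twin, cfg, trials=2)
        assert a["EPR"]["mae"] == b["EPR"]["mae"]
        assert a["RoR"]["mae"] == b["RoR"]["mae"]

    def test_mismatched_datasets_rejected(self):
        ds = linear_dataset(n=200, width=4, seed=10)
        other = linear_dataset(n=100, width=4, seed=10)
        with pytest.raises(ConfigError):
            run_comparison(ds, other, TrainConfig(), trials=1)
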