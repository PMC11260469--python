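"""Losses, scheduler, training loop, search and size helpers."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from utrxfer.data import DataSplit
from utrxfer.model import ModelSpec, build_model, encode_batch
from utrxfer.train import (PlateauScheduler, SchedulerConfig, TrainConfig,
                           TrialPruned, hyperparameter_search, log_spaced_sizes,
                           lognormal_kl, mse_loss, train)


class TestMseLoss:
    def test_identical_vectors_zero(self):
        assert mse_loss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_worked_example(self):
        assert mse_loss([1.0, 5.0], [2.0, 4.0]) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert mse_loss(a, b) == pytest.approx(mse_loss(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])


def kl_by_quadrature(mu1, s1, mu2, s2):
    """Numerical-integration oracle for the KL between two log-normals
    (integrated on the log scale where both densities are normal)."""
    p = stats.norm(mu1, s1)
    q = stats.norm(mu2, s2)

    def integrand(x):
        px = p.pdf(x)
        return px * (p.logpdf(x) - q.logpdf(x)) if px > 0 else 0.0

    lo, hi = mu1 - 12 * s1, mu1 + 12 * s1
    value, _ = integrate.quad(integrand, lo, hi, limit=200)
    return value


class TestLognormalKL:
    def test_self_divergence_zero(self):
        assert lognormal_kl((2.0, 0.7), (2.0, 0.7)) == 0.0

    def test_unit_shift_worked_example(self):
        assert lognormal_kl((0.0, 1.0), (1.0, 1.0)) == pytest.approx(0.5)

    def test_matches_quadrature_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mu1, mu2 = rng.normal(0, 2, 2)
            s1, s2 = rng.uniform(0.2, 2.0, 2)
            closed = lognormal_kl((mu1, s1), (mu2, s2))
            assert closed == pytest.approx(
                kl_by_quadrature(mu1, s1, mu2, s2), abs=1e-6)
            assert closed >= 0.0

    def test_equal_sigmas_reduce_to_scaled_squared_error(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mu1, mu2 = rng.normal(0, 3, 2)
            s = rng.uniform(0.3, 1.5)
            assert lognormal_kl((mu1, s), (mu2, s)) == pytest.approx(
                0.5 * (mu1 - mu2) ** 2 / s ** 2)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            lognormal_kl((0.0, 0.0), (0.0, 1.0))


class TestPlateauScheduler:
    def test_four_bad_epochs_halve_the_rate(self):
        sched = PlateauScheduler(3e-5)
        sched.step(1.0)                    # establishes the best
        for _ in range(3):
            assert sched.step(1.0) == pytest.approx(3e-5)
        assert sched.step(1.0) == pytest.approx(1.5e-5)

    def test_floor_at_min_lr(self):
        sched = PlateauScheduler(2e-5)
        sched.step(1.0)
        for _ in range(40):
            sched.step(1.0)
        assert sched.lr == pytest.approx(1e-5)

    def test_sub_threshold_improvements_count_as_plateau(self):
        """Losses falling by < 1% per epoch: the first reduction comes
        after 4 consecutive non-improving epochs."""
        sched = PlateauScheduler(1e-3)
        trace = [1.0, 0.995, 0.994, 0.993, 0.992, 0.991]
        lrs = [sched.step(v) for v in trace]
        assert lrs[:4] == [1e-3] * 4
        assert lrs[4] == pytest.approx(5e-4)

    def test_improvement_resets_counter(self):
        sched = PlateauScheduler(1e-3)
        sched.step(1.0)
        sched.step(1.0)
        sched.step(1.0)
        sched.step(0.5)                    # > 1% improvement
        for _ in range(3):
            sched.step(0.5)
        assert sched.lr == pytest.approx(1e-3)
        sched.step(0.5)
        assert sched.lr == pytest.approx(5e-4)


TINY_SPEC = ModelSpec(backbone="CNN-LSTM", conv_blocks=((8, 3, "relu"),),
                      lstm_hidden=8, mlp_hidden=(16,), max_len=12)


def tiny_training_problem(n=60, seed=0):
    from helpers import make_dataset
    rng = np.random.default_rng(seed)
    ds = make_dataset(rng.normal(5, 1.5, n), seq_len=12, seed=seed)
    ids = ds.ids
    return ds, DataSplit(train_ids=ids[: int(0.8 * n)],
                         val_ids=ids[int(0.8 * n):], test_ids=[])


class TestTrain:
    def test_learns_a_constant_target(self):
        ds, split = tiny_training_problem(seed=3)
        ds.frame["mu"] = 4.0
        model = build_model(TINY_SPEC, seed=0)
        # a patient schedule so the rate is not floored before convergence
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=200,
                          early_stop_patience=200,
                          scheduler=SchedulerConfig(threshold=0.0, patience=10),
                          seed=0)
        model, hist = train(model, ds, split, cfg)
        held_out = ds.subset(split.val_ids)
        X = encode_batch(list(held_out.frame["sequence"]), 12)
        preds = model.predict_mu(X)
        assert float(np.mean((preds - 4.0) ** 2)) < 1e-2

    def test_early_stopping_invariant_and_best_weights(self):
        ds, split = tiny_training_problem(seed=4)
        model = build_model(TINY_SPEC, seed=1)
        cfg = TrainConfig(learning_rate=3e-3, max_epochs=40,
                          early_stop_patience=3, seed=1)
        model, hist = train(model, ds, split, cfg)
        n_epochs = len(hist.val_loss)
        assert hist.best_epoch == int(np.argmin(hist.val_loss))
        assert n_epochs - 1 - hist.best_epoch <= cfg.early_stop_patience
        # learning-rate trace non-increasing and floored
        lrs = hist.learning_rate
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert min(lrs) >= cfg.scheduler.min_lr

    def test_bitwise_reproducible_under_seed(self):
        ds, split = tiny_training_problem(seed=5)
        cfg = TrainConfig(max_epochs=5, seed=7)
        m1, h1 = train(build_model(TINY_SPEC, seed=2), ds, split, cfg)
        m2, h2 = train(build_model(TINY_SPEC, seed=2), ds, split, cfg)
        for a, b in zip(m1.get_state(), m2.get_state()):
            np.testing.assert_array_equal(a, b)
        assert h1.val_loss == h2.val_loss

    def test_empty_split_rejected(self):
        ds, split = tiny_training_problem()
        bad = DataSplit(train_ids=[], val_ids=split.val_ids, test_ids=[])
        with pytest.raises(ValueError):
            train(build_model(TINY_SPEC, seed=0), ds, bad, TrainConfig())

    def test_kl_loss_requires_sigma_head(self):
        ds, split = tiny_training_problem()
        ds.frame["sigma"] = 0.5
        with pytest.raises(ValueError, match="mean_and_sigma"):
            train(build_model(TINY_SPEC, seed=0), ds, split,
                  TrainConfig(loss="lognormal_kl", max_epochs=1))

    def test_kl_training_runs_and_returns_positive_sigma(self):
        ds, split = tiny_training_problem(seed=6)
        ds.frame["sigma"] = 0.5
        spec = ModelSpec(backbone="CNN-LSTM", conv_blocks=((8, 3, "relu"),),
                         lstm_hidden=8, mlp_hidden=(16,),
                         outputs="mean_and_sigma", max_len=12)
        model = build_model(spec, seed=3)
        model, hist = train(model, ds, split,
                            TrainConfig(loss="lognormal_kl", max_epochs=5,
                                        seed=3))
        X = encode_batch(list(ds.frame["sequence"]), 12)
        _, sigma = model.transform_outputs(model.forward(X))
        assert np.all(sigma > 0)
        assert len(hist.val_loss) >= 1


class TestHyperparameterSearch:
    SPACE = {"x": ("uniform", -5.0, 5.0)}

    def test_budget_one_returns_single_trial(self):
        params, value, trials = hyperparameter_search(
            self.SPACE, lambda p, r: (p["x"] - 1) ** 2, budget=1, seed=0)
        assert len(trials) == 1
        assert value == pytest.approx((params["x"] - 1) ** 2)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search({}, lambda p, r: 0.0, budget=1, seed=0)

    def test_beats_random_median_on_quadratic(self):
        """Best of 30 sampled trials is at or below the median of 30
        random draws of the same objective (repeated over seeds)."""
        wins = 0
        for seed in range(10):
            _, best, _ = hyperparameter_search(
                self.SPACE, lambda p, r: (p["x"] - 1) ** 2, budget=30,
                pruning=False, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            draws = (rng.uniform(-5, 5, 30) - 1) ** 2
            if best <= np.median(draws):
                wins += 1
        assert wins >= 8

    def test_pruning_keeps_best_and_saves_epochs(self):
        """With monotone, non-crossing learning curves, pruning changes
        the total epoch count but not the winner."""

        def objective(params, report):
            final = (params["x"] - 1) ** 2
            for epoch in range(5):
                report(epoch, final + (4 - epoch))
            return final

        p_on, v_on, t_on = hyperparameter_search(
            self.SPACE, objective, budget=20, pruning=True, seed=5)
        p_off, v_off, t_off = hyperparameter_search(
            self.SPACE, objective, budget=20, pruning=False, seed=5)
        assert v_on == pytest.approx(v_off)
        assert p_on == p_off
        epochs_on = sum(len(t.intermediate) for t in t_on)
        epochs_off = sum(len(t.intermediate) for t in t_off)
        assert epochs_on < epochs_off
        assert any(t.pruned for t in t_on)


class TestLogSpacedSizes:
    def test_geometric_interpolation(self):
        assert log_spaced_sizes(1000, 4) == [10, 46, 215, 1000]

    def test_deduplication(self):
        sizes = log_spaced_sizes(12, 10)
        assert sizes == sorted(set(sizes))
        assert sizes[0] == 10 and sizes[-1] == 12


def test_scheduler_config_validation():
    with pytest.raises(ValueError):
        SchedulerConfig(factor=1.5)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=1e-6)   # below min_lr
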