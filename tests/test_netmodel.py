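"""Architecture, training loop, MC-dropout posteriors and decision rules."""

import numpy as np
import pytest

from tumevol import nn
from tumevol.netmodel import (EvolutionCall, ModelSpec, PosteriorSummary,
                              TrainConfig, TrainingSet, build_network,
                              call_evolution, estimate_frequencies,
                              load_model, mc_draws, mc_predict, rebalance,
                              save_model, train)


def _toy_set(n=240, seed=0):
    """Linearly separable toy data: selection samples put mass in the
    subclonal band, neutral samples only in the tail bins."""
    rng = np.random.default_rng(seed)
    X = rng.poisson(2.0, size=(n, 192)).astype(float)
    y = rng.integers(0, 2, n)
    X[y == 1, 30:34] += 40
    X[y == 1, 64 + 60:64 + 68] += 40
    f1 = np.where(y == 1, 0.25, np.nan)
    return TrainingSet(X=X, y_sel=y, y_nsub=y.copy(), f1=f1,
                       f2=np.full(n, np.nan))


class TestModelSpec:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            build_network(ModelSpec(kernel=4))

    def test_out_of_range_channels_rejected(self):
        with pytest.raises(ValueError):
            build_network(ModelSpec(channels=64))
        with pytest.raises(ValueError):
            build_network(ModelSpec(n_conv_layers=0))

    def test_dropout_on_every_hidden_layer(self):
        m = build_network(ModelSpec())
        for trunk in m.trunks:
            drops = [l for l in trunk.layers if isinstance(l, nn.Dropout)]
            convs = [l for l in trunk.layers if isinstance(l, nn.Conv1d)]
            assert len(drops) == len(convs)
            assert all(d.p == 0.5 for d in drops)
        for head in m.heads.values():
            assert any(isinstance(l, nn.Dropout) and l.p == 0.5
                       for l in head.layers)

    def test_minimal_spec_parameter_count(self):
        """Closed-form count for 1 conv layer, 4 channels, kernel 3."""
        spec = ModelSpec(n_conv_layers=1, channels=4, kernel=3,
                         branch_hidden=64)
        m = build_network(spec)
        conv = 2 * (4 * 1 * 3 + 4)                   # two trunks
        merged = 4 * 32 + 4 * 64                     # lengths pooled once
        heads = ((merged * 64 + 64) + (64 * 1 + 1)) \
            + ((merged * 64 + 64) + (64 * 3 + 3))    # selection + nsub
        assert m.parameter_count() == conv + heads

    def test_random_search_space_respects_bounds(self):
        from tumevol.netmodel import sample_model_spec, sample_train_config
        rng = np.random.default_rng(0)
        for _ in range(50):
            spec = sample_model_spec(rng)
            spec.validate()          # kernel odd, channels 4-32, layers 1-20
            cfg = sample_train_config(rng)
            cfg.validate()
            assert 1e-7 <= cfg.learning_rate <= 1e-3

    def test_parameter_count_deterministic(self):
        a = build_network(ModelSpec(), seed=0).parameter_count()
        b = build_network(ModelSpec(), seed=99).parameter_count()
        assert a == b


class TestGradients:
    def test_conv_dense_backward_matches_numerical(self):
        rng = np.random.default_rng(3)
        conv = nn.Conv1d(2, 3, 5, rng)
        x = rng.normal(size=(4, 2, 16)).astype(nn.DTYPE)
        dy = rng.normal(size=(4, 3, 16)).astype(nn.DTYPE)
        conv.forward(x, False, rng)
        dx = conv.backward(dy)
        eps = 1e-3
        for idx in [(0, 0, 0), (2, 1, 9)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = ((conv.forward(xp, False, rng) * dy).sum()
                   - (conv.forward(xm, False, rng) * dy).sum()) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=2e-2, abs=1e-2)


class TestRebalance:
    def _set(self, counts):
        rows = []
        for vaf, n in counts.items():
            rows += [vaf] * n
        f1 = np.array(rows)
        n = f1.size
        return TrainingSet(X=np.zeros((n, 192)), y_sel=np.ones(n, int),
                           y_nsub=np.ones(n, int), f1=f1,
                           f2=np.full(n, np.nan))

    def test_downsample_to_uniform(self):
        data = self._set({0.20: 100, 0.30: 10})
        out = rebalance(data, seed=0)
        vals, cnt = np.unique(np.round(out.f1, 2), return_counts=True)
        assert list(vals) == [0.20, 0.30]
        assert list(cnt) == [10, 10]

    def test_two_subclone_gap_filter(self):
        n = 10
        data = TrainingSet(X=np.zeros((n, 192)), y_sel=np.ones(n, int),
                           y_nsub=np.full(n, 2),
                           f1=np.full(n, 0.30),
                           f2=np.r_[np.full(5, 0.26), np.full(5, 0.20)])
        out = rebalance(data, seed=0)
        # gap 0.04 rows are excluded (> 5% VAF separation required)
        assert out.n == 5
        assert np.all(out.f1 - out.f2 > 0.05)

    def test_all_neutral_unchanged(self):
        n = 30
        data = TrainingSet(X=np.zeros((n, 192)), y_sel=np.zeros(n, int),
                           y_nsub=np.zeros(n, int), f1=np.full(n, np.nan),
                           f2=np.full(n, np.nan))
        out = rebalance(data, seed=0)
        assert out.n == n


class TestTraining:
    def test_loss_decreases_on_separable_toy(self):
        data = _toy_set()
        m = build_network(ModelSpec(channels=8, branch_hidden=32), seed=1)
        hist = train(m, data, TrainConfig(max_epochs=6, sims_per_batch=512,
                                          patience=5, seed=2))
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert hist["config"]["batch_size"] == 256
        assert hist["config"]["optimizer"] == "adam"

    def test_extreme_positive_penalty_suppresses_false_positives(self):
        """As the positive-class penalty grows, the binary loss is dominated
        by the neutral class: the classifier stops mispredicting selection
        on training data it can fit."""
        data = _toy_set()
        m = build_network(ModelSpec(channels=8, branch_hidden=32), seed=3)
        train(m, data, TrainConfig(max_epochs=6, sims_per_batch=512,
                                   patience=5, positive_penalty=1e6, seed=4))
        d = mc_draws(m, data.X, T=20, seed=5)
        p = d["selection"].mean(axis=0)[:, 0]
        false_pos = ((p > 0.5) & (data.y_sel == 0)).sum()
        assert false_pos == 0

    def test_learning_rate_range_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=1e-2).validate()
        with pytest.raises(ValueError):
            TrainConfig(patience=10).validate()

    def test_reproducible_under_seed(self):
        data = _toy_set()
        runs = []
        for _ in range(2):
            m = build_network(ModelSpec(channels=8, branch_hidden=32), seed=7)
            train(m, data, TrainConfig(max_epochs=2, sims_per_batch=512,
                                       seed=8))
            runs.append(m.get_weights())
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)


class TestMCDropout:
    def test_draws_shape_and_simplex(self):
        m = build_network(ModelSpec(), seed=1)
        d = mc_draws(m, np.zeros((3, 192)), T=10, seed=2)
        assert d["selection"].shape == (10, 3, 1)
        assert d["nsub"].shape == (10, 3, 3)
        np.testing.assert_allclose(d["nsub"].sum(axis=2), 1.0, rtol=1e-5)

    def test_no_dropout_means_zero_width(self):
        m = build_network(ModelSpec(dropout=0.0), seed=1)
        s = mc_predict(m, np.zeros(192), T=20, seed=3)["selection"]
        assert s.eti_upper - s.eti_lower == pytest.approx(0.0, abs=1e-7)

    def test_quantile_oracle(self):
        # 11 equally spaced draws: interpolated 5.5% / 94.5% quantiles are
        # 0.055 and 0.945 exactly
        s = PosteriorSummary.from_draws(np.linspace(0, 1, 11))
        assert s.eti_lower == pytest.approx(0.055)
        assert s.eti_upper == pytest.approx(0.945)
        assert s.eti_lower <= s.mean <= s.eti_upper

    def test_t_minimum(self):
        m = build_network(ModelSpec(), seed=1)
        with pytest.raises(ValueError):
            mc_draws(m, np.zeros((1, 192)), T=1)

    def test_seeded_draws_reproducible(self):
        m = build_network(ModelSpec(), seed=1)
        x = np.random.default_rng(0).poisson(3.0, 192)
        a = mc_draws(m, x, T=10, seed=5)["selection"]
        b = mc_draws(m, x, T=10, seed=5)["selection"]
        np.testing.assert_array_equal(a, b)


def _summary(values):
    return PosteriorSummary.from_draws(np.asarray(values, dtype=float))


class TestCallEvolution:
    def test_low_selection_bound_forces_neutral(self):
        p_sel = _summary([0.49] * 50)
        p_n = [_summary([0.0] * 50), _summary([0.0] * 50),
               _summary([1.0] * 50)]
        call = call_evolution(p_sel, p_n)
        assert call.mode == "neutral"
        assert call.n_subclones == 0

    def test_certain_two_subclones(self):
        call = call_evolution(_summary([1.0] * 50),
                              [_summary([0.0] * 50), _summary([0.0] * 50),
                               _summary([1.0] * 50)])
        assert (call.mode, call.n_subclones) == ("selection", 2)

    def test_fallback_argmax_parsimony(self):
        call = call_evolution(_summary([0.9] * 50),
                              [_summary([0.2] * 50), _summary([0.40] * 50),
                               _summary([0.35] * 50)])
        assert call.n_subclones == 1
        assert not call.by_interval

    def test_both_classes_pass_prefers_fewer(self):
        call = call_evolution(_summary([0.9] * 50),
                              [_summary([0.0] * 50), _summary([0.6] * 50),
                               _summary([0.7] * 50)])
        assert call.n_subclones == 1


class TestEstimateFrequencies:
    def test_neutral_call_empty(self, toy_models):
        call = call_evolution(_summary([0.1] * 50),
                              [_summary([0.9] * 50), _summary([0.0] * 50),
                               _summary([0.0] * 50)])
        out = estimate_frequencies(toy_models["1s"], toy_models["2s"],
                                   np.zeros(192), call)
        assert out == []

    def test_two_subclone_output_sorted(self, toy_models):
        call = call_evolution(_summary([1.0] * 50),
                              [_summary([0.0] * 50), _summary([0.0] * 50),
                               _summary([1.0] * 50)])
        out = estimate_frequencies(toy_models["1s"], toy_models["2s"],
                                   np.random.default_rng(0).poisson(2.0, 192),
                                   call, T=10, seed=3)
        assert len(out) == 2
        assert out[0].mean >= out[1].mean


class TestCheckpoints:
    def test_round_trip_identical_predictions(self, tmp_path):
        m = build_network(ModelSpec(), seed=4)
        path = tmp_path / "model.npz"
        save_model(m, path, history={"best_val_loss": 1.0})
        m2 = load_model(path)
        x = np.random.default_rng(1).poisson(2.0, (4, 192))
        a = mc_draws(m, x, T=5, seed=9)
        b = mc_draws(m2, x, T=5, seed=9)
        for k in a:
            np.testing.assert_allclose(a[k], b[k], rtol=1e-6)
        assert m2.spec == m.spec
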