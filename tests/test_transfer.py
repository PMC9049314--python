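"""Deterministic-subclone simulator, viable-parameter GP, renovation and
mutation-rate calibration."""

import numpy as np
import pytest
from scipy.optimize import brentq

from tumevol.netmodel import ModelSpec, TrainConfig, build_network, train
from tumevol.transfer import (DeterministicSimParams, TransferLabels,
                              ViableParamSampler, calibrate_mu,
                              make_pilot_table, renovate,
                              simulate_deterministic, viable_param_sampler)

_SEEDMOD = 2**31 - 1


class TestSimulateDeterministic:
    def test_late_emergence_no_subclone(self):
        p = DeterministicSimParams(subclone_time=20.0, n_final=2000,
                                   mutation_rate=1.0, seed=1)
        truth, lab = simulate_deterministic(p)
        assert lab.subclone_cellular_fraction == 0.0
        assert truth.labels.n_subclones == 0

    def test_neutral_subclone_martingale_mean(self):
        """With fitness 1 the subclone lineage is one random cell among
        2^t_s, so its final fraction has mean 1 / 2^t_s (a martingale).
        Compared against a brute-force two-type birth-death oracle."""
        t_s, n_final, reps = 3.0, 256, 400
        fr = [simulate_deterministic(DeterministicSimParams(
            mutation_rate=0.0, subclone_fitness=1.0, subclone_time=t_s,
            n_final=n_final, n_clonal=0, seed=i))[1].subclone_cellular_fraction
            for i in range(reps)]
        oracle = _two_type_oracle(8, n_final, 1.0, 1.0, 0.2, reps=400, seed=9)
        fr = np.array(fr)
        sem = np.sqrt(fr.var(ddof=1) / reps + oracle.var(ddof=1) / reps)
        assert abs(fr.mean() - oracle.mean()) < 3 * sem + 1e-9
        # both agree with the martingale expectation
        assert abs(fr.mean() - 1.0 / 2**t_s) < 3 * fr.std(ddof=1) / np.sqrt(reps)

    def test_selected_subclone_matches_growth_ode(self):
        """High fitness, early emergence: the mean cellular fraction tracks
        the deterministic two-population exponential-growth solution."""
        w, t_s, n_final, reps = 3.0, 4.0, 2000, 200
        lam1 = 0.8            # birth 1 - death 0.2
        lam2 = 0.8 * w
        n0 = 2.0 ** t_s
        def total(dt):
            return (n0 - 1) * np.exp(lam1 * dt) + np.exp(lam2 * dt) - n_final
        dt = brentq(total, 0.0, 50.0)
        closed = np.exp(lam2 * dt) / n_final
        fr = np.array([simulate_deterministic(DeterministicSimParams(
            mutation_rate=0.0, subclone_fitness=w, subclone_time=t_s,
            n_final=n_final, n_clonal=0, seed=1000 + i))[1]
            .subclone_cellular_fraction for i in range(reps)])
        # stochastic founder dynamics broaden the distribution; the mean
        # agrees with the ODE fraction to within a modest absolute slack
        assert abs(fr.mean() - closed) < 0.10

    def test_mutation_accumulation(self):
        truth, lab = simulate_deterministic(DeterministicSimParams(
            mutation_rate=10.0, n_final=2000, n_clonal=100, seed=5))
        assert truth.n_clonal == 100
        assert truth.n_mutations > 100
        assert np.all(truth.true_vafs <= 0.5)

    def test_labels_validate(self):
        with pytest.raises(ValueError):
            TransferLabels(10.0, 2.0, 3.0, subclone_cellular_fraction=1.5)
        lab = TransferLabels(10.0, 2.0, 3.0, 0.5)
        assert lab.detectable          # VAF 0.25


def _two_type_oracle(n0, n_final, w, birth, death, reps, seed):
    """Brute-force two-type birth-death simulation tracking only counts."""
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    b2 = death + (birth - death) * w
    bmax = max(birth, b2)
    for r in range(reps):
        n_bg, n_sub = n0 - 1, 1
        while 0 < (n_bg + n_sub) < n_final:
            n = n_bg + n_sub
            is_sub = rng.random() < n_sub / n
            b = b2 if is_sub else birth
            u = rng.random() * (bmax + death)
            if u < b:
                if is_sub:
                    n_sub += 1
                else:
                    n_bg += 1
            elif u < b + death:
                if is_sub:
                    n_sub -= 1
                else:
                    n_bg -= 1
        out[r] = n_sub / n_final if (n_bg + n_sub) else 0.0
    return out


class TestViableParamSampler:
    @pytest.fixture(scope="class")
    def sampler(self):
        return viable_param_sampler(make_pilot_table(120, seed=3))

    def test_requires_enough_rows(self):
        with pytest.raises(ValueError):
            viable_param_sampler(np.zeros((10, 3)))

    def test_samples_within_bounds(self, sampler):
        rng = np.random.default_rng(0)
        pairs = sampler.sample(rng, 300)
        w, ts = pairs[:, 0], pairs[:, 1]
        assert np.all((w >= sampler.fitness_range[0])
                      & (w <= sampler.fitness_range[1]))
        assert np.all((ts >= sampler.t_s_range[0])
                      & (ts <= sampler.t_s_range[1]))

    def test_majority_of_samples_detectable(self, sampler):
        """At least half of the sampled (fitness, t_s) pairs should produce
        a detectable subclone when simulated."""
        rng = np.random.default_rng(1)
        pairs = sampler.sample(rng, 60)
        hits = 0
        for w, ts in pairs:
            _, lab = simulate_deterministic(DeterministicSimParams(
                mutation_rate=2.0, subclone_fitness=float(w),
                subclone_time=float(ts), n_clonal=0,
                seed=int(rng.integers(_SEEDMOD))))
            hits += lab.detectable
        assert hits / len(pairs) >= 0.5

    def test_noiseless_sampling_collapses_to_gp_mean(self, sampler):
        """Removing the noise component collapses repeated t_s draws at a
        fixed fitness onto the GP mean."""
        from dataclasses import replace
        quiet = replace(sampler, fitness_range=(3.0, 3.0), noisy=False)
        rng = np.random.default_rng(2)
        ts = quiet.sample(rng, 100)[:, 1]
        noisy = replace(sampler, fitness_range=(3.0, 3.0)).sample(
            rng, 100)[:, 1]
        assert ts.std() < 1e-9
        assert noisy.std() > 0.1


class TestRenovation:
    def _sources(self):
        ms = build_network(ModelSpec(task="ms"), seed=1)
        m1 = build_network(ModelSpec(task="1s"), seed=2)
        return ms, m1

    def test_four_heads_and_copied_trunks(self):
        ms, m1 = self._sources()
        tm = renovate(ms, m1, seed=3)
        assert set(tm.spec.heads) == {"mutation_rate", "fitness",
                                      "emergence_time", "cellular_fraction"}
        src = ms.trunk_params() + m1.trunk_params()
        for dst, s in zip(tm.trunk_params(), src):
            np.testing.assert_array_equal(dst[0], s[0])

    def test_featurization_mismatch_rejected(self):
        ms, _ = self._sources()
        other = build_network(ModelSpec(task="1s", normalized_input=True),
                              seed=2)
        with pytest.raises(ValueError):
            renovate(ms, other)

    def test_pretrained_trunks_beat_random_init(self, transfer_bundle,
                                                desk_models):
        """At a fixed small budget, renovated (pre-trained-trunk) models
        reach lower median validation loss than identically shaped randomly
        initialized models (paired over seeds)."""
        data = transfer_bundle["train_set"].subset(np.arange(1200))
        cfg = dict(max_epochs=2, sims_per_batch=1200, patience=5)
        pre, rnd = [], []
        for seed in range(10):
            m_pre = renovate(desk_models["ms"], desk_models["1s"], seed=seed)
            h = train(m_pre, data, TrainConfig(trunk_lr_mult=0.1,
                                               seed=100 + seed, **cfg))
            pre.append(h["best_val_loss"])
            m_rnd = build_network(m_pre.spec, seed=500 + seed)
            h = train(m_rnd, data, TrainConfig(trunk_lr_mult=0.1,
                                               seed=100 + seed, **cfg))
            rnd.append(h["best_val_loss"])
        assert np.median(pre) < np.median(rnd)


class TestCalibration:
    def test_systematic_halving_corrected(self):
        """Inject a known bias into the predicted rate: the fitted degree-2
        ridge map removes most of it on held-out data."""
        from sklearn.linear_model import Ridge
        from sklearn.preprocessing import PolynomialFeatures
        rng = np.random.default_rng(0)
        true = rng.uniform(5, 100, 1000)
        pred = true / 2.0 + rng.normal(0, 1.0, 1000)
        P = PolynomialFeatures(2, include_bias=False).fit_transform(
            pred[:, None])
        r = Ridge(alpha=1.0).fit(P, true)
        hold_true = rng.uniform(5, 100, 500)
        hold_pred = hold_true / 2.0 + rng.normal(0, 1.0, 500)
        Ph = PolynomialFeatures(2, include_bias=False).fit_transform(
            hold_pred[:, None])
        corrected = r.predict(Ph)
        mpe_raw = np.abs((hold_pred - hold_true) / hold_true).mean()
        mpe_cal = np.abs((corrected - hold_true) / hold_true).mean()
        assert mpe_cal < mpe_raw / 5

    def test_calibration_object_applies_polynomial(self, transfer_bundle):
        cal = transfer_bundle["calibration"]
        x = np.array([10.0, 50.0])
        expected = cal.coef[0] + cal.coef[1] * x + cal.coef[2] * x**2
        np.testing.assert_allclose(cal(x), expected)

    def test_degenerate_predictions_rejected(self):
        from tumevol.transfer import TransferSet
        ms = build_network(ModelSpec(task="ms", dropout=0.0), seed=1)
        m1 = build_network(ModelSpec(task="1s", dropout=0.0), seed=2)
        m = renovate(ms, m1, seed=3)
        n = 60
        flat = TransferSet(X=np.zeros((n, 192)), mutation_rate=np.ones(n),
                           fitness=np.ones(n), t_s=np.ones(n),
                           cellular_fraction=np.zeros(n),
                           detectable=np.zeros(n, bool))
        with pytest.raises(ValueError):
            calibrate_mu(m, flat, T=5)
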