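"""Purity correction, clonal-peak adjustment, clustering and rescaling."""

import numpy as np
import pytest

from tumevol.biopsy import SequencingParams, VAFSample, virtual_biopsy
from tumevol.postprocess import (clonal_peak_adjust, heuristic_cluster,
                                 purity_correct, rescale_estimates,
                                 tumour_age)


def _sample(vafs, depth=100.0):
    v = np.asarray(vafs, dtype=float)
    dep = np.full(v.size, 1000, np.int64)
    return VAFSample(alt_count=np.round(v * dep).astype(np.int64), depth=dep,
                     mean_depth=depth, vaf=v)


class TestPurityCorrect:
    def test_examples(self):
        s = purity_correct(_sample([0.30]), 0.6)
        assert s.vaf[0] == pytest.approx(0.50)
        s = purity_correct(_sample([0.2, 0.4]), 1.0)
        np.testing.assert_allclose(s.vaf, [0.2, 0.4])
        with pytest.raises(ValueError):
            purity_correct(_sample([0.2]), 0.0)

    def test_inverts_purity_dilution_in_expectation(self):
        """biopsy at purity 0.7 then correct with the exact purity: the
        clonal cluster returns to ~0.5."""
        seq = SequencingParams(mean_depth=200.0, purity=0.7, depth_pool=1000)
        obs = virtual_biopsy(np.full(3000, 0.5), seq, seed=1)
        corrected = purity_correct(obs, 0.7)
        assert corrected.vaf.mean() == pytest.approx(0.5, abs=0.01)


class TestClonalPeakAdjust:
    def _biopsied(self, center, n=2000, depth=150.0, seed=0):
        seq = SequencingParams(mean_depth=depth, depth_pool=1000)
        tail = np.random.default_rng(seed).uniform(0.03, 0.15, n // 4)
        v = np.concatenate([np.full(n, center), tail])
        return virtual_biopsy(v, seq, seed=seed)

    def test_centered_cluster_scale_near_one(self):
        res = clonal_peak_adjust(self._biopsied(0.5))
        assert res.adjusted
        assert res.scale == pytest.approx(1.0, abs=0.03)

    def test_misplaced_cluster_recentered(self):
        """A clonal cluster at 0.40 (25% purity error) moves to ~0.50."""
        res = clonal_peak_adjust(self._biopsied(0.40))
        assert res.adjusted
        sample = res.sample
        # the adjusted cluster mean sits within 0.02 of 0.5
        cluster = sample.vaf[np.abs(sample.vaf - 0.5) < 0.15]
        assert cluster.mean() == pytest.approx(0.50, abs=0.02)

    def test_low_peak_left_unchanged(self):
        """Closest peak at ~0.30 (<= 0.35): no adjustment, warning flag."""
        seq = SequencingParams(mean_depth=150.0, depth_pool=1000)
        obs = virtual_biopsy(np.full(2000, 0.30), seq, seed=3)
        res = clonal_peak_adjust(obs)
        assert not res.adjusted
        assert res.scale == 1.0
        np.testing.assert_array_equal(res.sample.vaf, obs.vaf)

    def test_too_few_mutations_flagged(self):
        res = clonal_peak_adjust(_sample([0.4] * 50))
        assert not res.adjusted
        assert "mutations" in res.note


class TestHeuristicCluster:
    def test_window_reference_value(self):
        # q = 0.2, c = 100, eps = 2 -> 0.2 +- 2 sqrt(0.2*0.8/100) = [0.12, 0.28]
        ca = heuristic_cluster(_sample([0.2]), [0.2], mean_depth=100.0)
        lo, hi = ca.bounds["subclone_1"]
        assert lo == pytest.approx(0.12)
        assert hi == pytest.approx(0.28)

    def test_eps_zero_degenerates(self):
        ca = heuristic_cluster(_sample([0.2]), [0.2], mean_depth=100.0,
                               eps=0.0)
        lo, hi = ca.bounds["subclone_1"]
        assert lo == hi == pytest.approx(0.2)

    def test_no_subclones_tail_clonal_split(self):
        ca = heuristic_cluster(_sample([0.05, 0.2, 0.44, 0.52]), [],
                               mean_depth=100.0)
        lo = 0.5 - 2 * np.sqrt(0.25 / 100.0)
        assert set(np.unique(ca.labels)) <= {"tail", "clonal"}
        v = np.array([0.05, 0.2, 0.44, 0.52])
        np.testing.assert_array_equal(ca.labels == "clonal", v >= lo)

    def test_every_mutation_labelled_once(self):
        rng = np.random.default_rng(0)
        s = _sample(rng.uniform(0.02, 0.7, 400))
        ca = heuristic_cluster(s, [0.18, 0.33], mean_depth=120.0)
        assert ca.labels.size == 400
        assert set(np.unique(ca.labels)) <= {"tail", "subclone_1",
                                             "subclone_2", "clonal"}
        # higher VAF mutations never get a lower cluster than lower VAF ones
        order = np.argsort(s.vaf)
        rank = {"tail": 0, "subclone_2": 1, "subclone_1": 2, "clonal": 3}
        ranks = np.array([rank[l] for l in ca.labels[order]])
        assert np.all(np.diff(ranks) >= 0)

    def test_windows_shrink_with_depth(self):
        widths = []
        for c in (50.0, 100.0, 400.0):
            ca = heuristic_cluster(_sample([0.2]), [0.2], mean_depth=c)
            lo, hi = ca.bounds["subclone_1"]
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_gmm_refinement_runs(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0.25, 0.02, 150),
                            rng.normal(0.5, 0.02, 150)])
        ca = heuristic_cluster(_sample(v), [0.25], mean_depth=150.0,
                               gmm_refine=True, seed=2)
        assert set(np.unique(ca.labels)) <= {"tail", "subclone_1", "clonal"}


class TestRescaling:
    def test_tumour_age_examples(self):
        assert tumour_age(0.0, 2**30) == pytest.approx(30.0)
        assert tumour_age(0.5, 2**10) == pytest.approx(9.0)
        assert tumour_age(0.5, 1e10) == pytest.approx(np.log2(5e9))
        with pytest.raises(ValueError):
            tumour_age(1.0, 1e10)

    def test_identity_when_sizes_match(self):
        r = rescale_estimates(w=2.5, t_s=4.0, f_sub=0.3, n_sim=1e4,
                              n_real=1e4)
        assert r.w_r == pytest.approx(2.5)
        assert r.t_s_r == pytest.approx(4.0)

    def test_neutral_fitness_invariant(self):
        r = rescale_estimates(w=1.0, t_s=5.0, f_sub=0.2, n_sim=1e4)
        assert r.w_r == pytest.approx(1.0)

    def test_against_independent_formula_evaluation(self):
        """Re-derive the four quantities step by step and compare."""
        w, t_s, f_sub, n_sim, n_real = 3.0, 6.0, 0.4, 1e4, 1e10
        t_s_r = t_s * np.log(n_real) / np.log(n_sim)          # 15.0
        t_end = np.log2((1 - f_sub) * n_sim)
        t_end_r = np.log2((1 - f_sub) * n_real)
        w_r = 1 + (w - 1) * (t_end - t_s) / (t_end_r - t_s_r)
        r = rescale_estimates(w, t_s, f_sub, n_sim, n_real)
        assert r.t_s_r == pytest.approx(15.0)
        assert r.t_end == pytest.approx(t_end)
        assert r.t_end_r == pytest.approx(t_end_r)
        assert r.w_r == pytest.approx(w_r)
        assert r.t_s_r < r.t_end_r

    def test_non_physical_rescale_rejected(self):
        # an emergence time at/after the biopsy cannot be rescaled
        with pytest.raises(ValueError):
            rescale_estimates(w=2.0, t_s=14.0, f_sub=0.0, n_sim=1e4,
                              n_real=100.0)
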