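"""Post-processing of empirical VAF distributions and evolutionary estimates.

Real biopsies differ from the training conditions in two ways the pipeline
must undo before featurization: tumour impurity dilutes every VAF
(corrected by ``VAF / purity``), and the *purity estimate itself* may be
wrong, leaving the heterozygous diploid clonal cluster away from 50% VAF.
The clonal-peak adjustment finds density peaks, takes the peak closest to
0.5, and -- when it lies above 35% VAF, where it can only plausibly be a
misplaced clonal cluster -- rescales all VAFs so the fitted cluster mean
returns to 0.5.

After model predictions, mutations are clustered outward from the estimated
subclone frequencies using binomial-variance windows (no mixture model is
fitted), and subclone fitness / emergence-time estimates made at the small
simulated population size are rescaled to a realistic tumour size using the
tumour-doublings clock ``t_end = log2((1 - f_sub) N_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, norm

from .biopsy import VAFSample
from .sim_selection import _check

__all__ = ["purity_correct", "clonal_peak_adjust", "heuristic_cluster",
           "ClusterAssignment", "tumour_age", "rescale_estimates",
           "RescaledEstimates", "PeakAdjustResult"]

CLUSTER_EPS = 2.0          # window half-width in binomial standard deviations
MISPLACED_PEAK_MIN = 0.35  # peaks above this are treated as clonal
_KDE_GRID = np.linspace(0.05, 1.0, 512)
_FIT_HALFWIDTH = 0.1       # VAF window around the peak used for the Gaussian fit
MIN_MUTATIONS = 100


def purity_correct(sample: VAFSample, purity: float) -> VAFSample:
    """Divide every VAF by tumour purity.  Values above 0.5 are retained;
    the fixed featurization range excludes them later."""
    _check(0.0 < purity <= 1.0, "purity must lie in (0, 1]")
    out = sample.replace_vafs(sample.vaf / purity)
    out.provenance = sample.provenance
    return out


@dataclass(frozen=True)
class PeakAdjustResult:
    sample: VAFSample
    scale: float
    adjusted: bool
    peak: float | None
    note: str = ""


def _density_peaks(v: np.ndarray) -> np.ndarray:
    """Locations of local maxima of a Gaussian KDE (Silverman bandwidth)
    evaluated on a fixed 512-point grid over [0.05, 1.0]."""
    kde = gaussian_kde(v, bw_method="silverman")
    dens = kde(_KDE_GRID)
    d1 = np.gradient(dens, _KDE_GRID)
    sign = np.sign(d1)
    idx = np.flatnonzero((sign[:-1] > 0) & (sign[1:] <= 0))
    return _KDE_GRID[idx]


def clonal_peak_adjust(sample: VAFSample) -> PeakAdjustResult:
    """Re-center a misplaced clonal cluster at 50% VAF.

    Density peaks of the (purity-corrected) VAF distribution are located;
    the peak closest to 0.5 (ties broken toward the higher VAF) is taken as
    the clonal-cluster candidate.  If it lies above 35% VAF a Gaussian is
    fitted to the VAFs within +-0.1 of the peak and every VAF is multiplied
    by ``0.5 / fitted mean``; otherwise the sample is returned unchanged
    with a warning flag, since a peak at or below 35% cannot be confidently
    identified as clonal.  Samples with fewer than 100 mutations are left
    unchanged and flagged.
    """
    v = sample.vaf
    if v.size < MIN_MUTATIONS:
        return PeakAdjustResult(sample, 1.0, False, None,
                                f"only {v.size} mutations (<{MIN_MUTATIONS})")
    peaks = _density_peaks(v)
    if peaks.size == 0:
        return PeakAdjustResult(sample, 1.0, False, None, "no density peaks")
    dist = np.abs(peaks - 0.5)
    best = dist.min()
    qstar = float(peaks[np.isclose(dist, best)].max())  # tie -> higher VAF
    if qstar <= MISPLACED_PEAK_MIN:
        return PeakAdjustResult(sample, 1.0, False, qstar,
                                f"closest peak {qstar:.3f} <= "
                                f"{MISPLACED_PEAK_MIN}; not adjusted")
    cluster = v[np.abs(v - qstar) <= _FIT_HALFWIDTH]
    mean, _ = norm.fit(cluster)
    scale = 0.5 / mean
    return PeakAdjustResult(sample.replace_vafs(v * scale), float(scale),
                            True, qstar)


@dataclass
class ClusterAssignment:
    """Per-mutation labels (tail / subclone_i / clonal) and window bounds."""

    labels: np.ndarray            # strings
    bounds: dict                  # cluster name -> (low, high)
    eps: float

    def counts(self) -> dict:
        names, n = np.unique(self.labels, return_counts=True)
        return dict(zip(names.tolist(), n.tolist()))


def _window(q: float, c: float, eps: float) -> tuple[float, float]:
    half = eps * np.sqrt(q * (1.0 - q) / c)
    return q - half, q + half


def heuristic_cluster(sample: VAFSample, subclone_freqs,
                      mean_depth: float | None = None,
                      eps: float = CLUSTER_EPS,
                      gmm_refine: bool = False,
                      seed: int = 0) -> ClusterAssignment:
    """Assign mutations to tail / subclone(s) / clonal clusters outward from
    the estimated subclone frequencies.

    Each subclone at frequency ``q`` claims the window
    ``q +- eps * sqrt(q (1 - q) / c)`` (binomial standard deviations at mean
    depth ``c``); the clonal cluster claims ``0.5 +- eps * sqrt(0.25 / c)``.
    Mutations between two windows split at the midpoint of the facing window
    edges (which is also the overlap midpoint when windows intersect);
    everything below the lowest subclone window is neutral tail.  Optional
    Gaussian-mixture refinement re-fits the non-tail mutations with means
    seeded at the subclone frequencies and 0.5.
    """
    c = mean_depth if mean_depth is not None else sample.mean_depth
    _check(c > 0, "mean depth must be > 0")
    _check(eps >= 0, "eps must be >= 0")
    qs = sorted(float(q) for q in subclone_freqs)   # ascending
    v = sample.vaf

    centers = qs + [0.5]
    # subclone_1 is the highest-frequency subclone by convention
    names = [f"subclone_{len(qs) - i}" for i in range(len(qs))] + ["clonal"]
    wins = [_window(q, c, eps) for q in qs] + [_window(0.5, c, eps)]

    # boundaries between adjacent clusters: midpoint of facing window edges
    cuts = [(wins[i][1] + wins[i + 1][0]) / 2.0 for i in range(len(wins) - 1)]
    tail_edge = wins[0][0]

    labels = np.empty(v.size, dtype=object)
    for i, vi in enumerate(v):
        if vi < tail_edge:
            labels[i] = "tail"
        else:
            j = int(np.searchsorted(cuts, vi))
            labels[i] = names[j]
    bounds = {"tail": (0.0, float(tail_edge))}
    for name, w in zip(names, wins):
        bounds[name] = (float(w[0]), float(w[1]))

    if gmm_refine and len(centers) >= 1:
        from sklearn.mixture import GaussianMixture
        mask = labels != "tail"
        pts = v[mask][:, None]
        if pts.shape[0] > len(centers):
            gm = GaussianMixture(n_components=len(centers),
                                 means_init=np.array(centers)[:, None],
                                 random_state=seed).fit(pts)
            comp = gm.predict(pts)
            order = np.argsort(gm.means_[:, 0])
            remap = {int(order[k]): names[k] for k in range(len(names))}
            labels[mask] = [remap[int(cc)] for cc in comp]
    return ClusterAssignment(labels=labels.astype(str), bounds=bounds, eps=eps)


def tumour_age(f_sub: float, n_end: float) -> float:
    """Tumour age at biopsy in population doublings:
    ``t_end = log2((1 - f_sub) * N_end)`` for subclone cellular fraction
    ``f_sub`` (the background population defines the doubling clock)."""
    _check(0.0 <= f_sub < 1.0, "f_sub must lie in [0, 1)")
    _check(n_end >= 1, "N_end must be >= 1")
    return float(np.log2((1.0 - f_sub) * n_end))


@dataclass(frozen=True)
class RescaledEstimates:
    w: float
    t_s: float
    f_sub: float
    n_sim: float
    n_real: float
    t_end: float
    t_end_r: float
    t_s_r: float
    w_r: float


def rescale_estimates(w: float, t_s: float, f_sub: float, n_sim: float,
                      n_real: float = 1e10) -> RescaledEstimates:
    """Rescale subclone fitness and emergence time from the simulated final
    population size to a realistic one.

    Emergence time scales linearly with log population size,
    ``t_s^R = t_s log(N_real) / log(N_sim)``, and fitness is rescaled so the
    subclone achieves the same frequency over the rescaled growth interval:
    ``w_R = 1 + (w - 1)(t_end - t_s) / (t_end^R - t_s^R)``.
    """
    _check(w >= 1.0, "fitness w must be >= 1")
    _check(t_s >= 0 and n_sim > 1 and n_real > 1, "inputs must be positive")
    _check(0.0 <= f_sub < 1.0, "f_sub must lie in [0, 1)")
    t_s_r = t_s * np.log(n_real) / np.log(n_sim)
    t_end = tumour_age(f_sub, n_sim)
    t_end_r = tumour_age(f_sub, n_real)
    _check(t_end_r > t_s_r, "non-physical rescale: t_end_R <= t_s_R")
    w_r = 1.0 + (w - 1.0) * (t_end - t_s) / (t_end_r - t_s_r)
    return RescaledEstimates(w=w, t_s=t_s, f_sub=f_sub, n_sim=n_sim,
                             n_real=n_real, t_end=float(t_end),
                             t_end_r=float(t_end_r), t_s_r=float(t_s_r),
                             w_r=float(w_r))
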