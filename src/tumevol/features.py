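"""Depth-conditioned VAF-histogram features and tumour site-frequency statistics.

The model input is the concatenation of a 64-bin and a 128-bin histogram of
observed VAFs over the fixed range [0.02, 0.50].  To condition the model on
sequencing depth, mutations below a depth-dependent lower cutoff are dropped:
with ``f_alt = min_alt_reads / mean_depth``, the cutoff is ``f_alt`` plus two
binomial standard deviations of a frequency estimated at ``mean_depth`` reads,
``f_alt + 2 sqrt(f_alt (1 - f_alt) / c)``.

Tajima's D and Fay & Wu's H are provided in a tumour-sequencing adaptation:
the effective number of sampled chromosomes is taken as ``round(mean depth)``,
and somatic VAFs are treated as derived-allele frequencies (the reference
genome is the ancestral state, so no folding or polarisation step applies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .biopsy import VAFSample
from .sim_selection import _check

__all__ = ["FeatureVector", "lower_cutoff", "featurize",
           "tajimas_d", "fay_wu_h", "VAF_RANGE", "DEFAULT_K"]

VAF_RANGE = (0.02, 0.50)
DEFAULT_K = (64, 128)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    cutoff: float
    k_list: tuple[int, ...]
    normalized: bool

    def __post_init__(self):
        _check(self.values.size == sum(self.k_list), "feature length mismatch")


def lower_cutoff(f_alt: float, c: float) -> float:
    """Frequency below which mutations are not counted into the histograms."""
    _check(0.0 <= f_alt <= 1.0, "f_alt must lie in [0, 1]")
    _check(c > 0, "mean depth must be > 0")
    return f_alt + 2.0 * np.sqrt(f_alt * (1.0 - f_alt) / c)


def featurize(sample: VAFSample, k_list: tuple[int, ...] = DEFAULT_K,
              normalize: bool = False) -> FeatureVector:
    """Bin a sample's VAFs into the concatenated fixed-range histograms.

    Mutations below the depth-conditioned :func:`lower_cutoff` or above 0.50
    contribute to no bin.  ``normalize=True`` divides each histogram by the
    total retained count (models record which convention they were trained
    with); the default is raw counts.
    """
    lo, hi = VAF_RANGE
    c = sample.mean_depth
    cut = lower_cutoff(min(sample.min_alt_reads / c, 1.0), c)
    v = sample.vaf
    v = v[(v >= cut) & (v <= hi)]
    parts = []
    for k in k_list:
        h, _ = np.histogram(v, bins=np.linspace(lo, hi, k + 1))
        h = h.astype(float)
        if normalize and h.sum() > 0:
            h = h / h.sum()
        parts.append(h)
    return FeatureVector(values=np.concatenate(parts), cutoff=float(cut),
                         k_list=tuple(k_list), normalized=normalize)


class SFSStat(NamedTuple):
    value: float
    degenerate: bool  # True when no segregating sites (value 0 by convention)


def _theta_pi(p: np.ndarray, n: int) -> float:
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))


def tajimas_d(sample: VAFSample) -> SFSStat:
    """Tajima's D from per-mutation VAFs with n = round(mean depth).

    D = (theta_pi - theta_W) / sqrt(e1 S + e2 S (S - 1)) with the standard
    Tajima (1989) variance constants.
    """
    n = int(round(sample.mean_depth))
    _check(n >= 2, "need effective sample size >= 2")
    p = sample.vaf
    S = p.size
    if S == 0:
        return SFSStat(0.0, True)
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = _theta_pi(p, n) - S / a1
    if var <= 0 or num == 0.0:
        return SFSStat(0.0, var <= 0)
    return SFSStat(float(num / np.sqrt(var)), False)


def fay_wu_h(sample: VAFSample) -> SFSStat:
    """Unnormalised Fay & Wu's H = theta_pi - theta_H with
    theta_H = sum(2 p_i^2) * n / (n - 1)."""
    n = int(round(sample.mean_depth))
    _check(n >= 2, "need effective sample size >= 2")
    p = sample.vaf
    if p.size == 0:
        return SFSStat(0.0, True)
    theta_h = float(np.sum(2.0 * p**2) * n / (n - 1))
    return SFSStat(_theta_pi(p, n) - theta_h, False)
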