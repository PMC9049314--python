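"""Virtual biopsy: true cellular frequencies -> observed read counts.

Sequencing noise follows a two-stage model.  Per-site depth is sampled as
``D_obs ~ Binomial(N, D/N)`` where ``D`` is the target mean depth and ``N``
the depth pool size (by default the simulated population size), and the
alt-read count as ``R_obs ~ BetaBinomial(D_obs, p, rho)`` where
``p = VAF_true * purity`` and ``rho`` is the intraclass-correlation
overdispersion.  The beta-binomial is parameterised so that
``a = p (1 - rho) / rho`` and ``b = (1 - p)(1 - rho) / rho``, giving
``Var(R) = n p (1 - p)(1 + (n - 1) rho)``; ``rho = 0`` degenerates exactly to
a binomial.  Mutations with fewer than ``min_alt_reads`` alt reads are not
callable and are dropped.  Tumour impurity dilutes frequencies before read
sampling: normal-cell DNA contributes reference reads only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .sim_selection import TumourTruth, _check

__all__ = ["SequencingParams", "VAFSample", "apply_purity", "virtual_biopsy"]


@dataclass(frozen=True)
class SequencingParams:
    mean_depth: float
    rho: float = 0.0
    min_alt_reads: int = 2
    purity: float = 1.0
    depth_pool: int | None = None   # binomial pool N; defaults to simulated N

    def validate(self) -> None:
        _check(np.isfinite(self.mean_depth) and self.mean_depth > 0,
               "mean_depth must be > 0")
        _check(0.0 <= self.rho < 1.0, "rho must lie in [0, 1)")
        _check(0.0 < self.purity <= 1.0, "purity must lie in (0, 1]")
        _check(self.min_alt_reads >= 0, "min_alt_reads must be >= 0")
        if self.depth_pool is not None:
            _check(self.mean_depth / self.depth_pool <= 1.0,
                   "mean_depth may not exceed the depth pool size")


@dataclass
class VAFSample:
    """An observed sample: per-mutation alt counts, depths and VAFs."""

    alt_count: np.ndarray
    depth: np.ndarray
    mean_depth: float
    purity: float = 1.0
    min_alt_reads: int = 2
    provenance: str = "synthetic"
    vaf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.vaf is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                self.vaf = np.where(self.depth > 0,
                                    self.alt_count / self.depth, 0.0)
        _check(self.alt_count.shape == self.depth.shape, "shape mismatch")
        _check(bool(np.all(self.alt_count >= 0)), "negative alt counts")
        _check(bool(np.all(self.alt_count <= self.depth)), "alt count > depth")

    @property
    def n_mutations(self) -> int:
        return int(self.alt_count.size)

    @property
    def effective_coverage(self) -> float:
        return self.mean_depth * self.purity

    def to_frame(self) -> pd.DataFrame:
        """Flat table with synthetic chrom/pos placeholders for simulated data."""
        n = self.n_mutations
        return pd.DataFrame({
            "chrom": np.repeat("chrS", n),
            "pos": np.arange(1, n + 1),
            "alt_count": self.alt_count,
            "depth": self.depth,
            "vaf": self.vaf,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def replace_vafs(self, vaf: np.ndarray, **meta) -> "VAFSample":
        out = VAFSample(alt_count=self.alt_count.copy(),
                        depth=self.depth.copy(),
                        mean_depth=self.mean_depth, purity=self.purity,
                        min_alt_reads=self.min_alt_reads,
                        provenance=self.provenance, vaf=np.asarray(vaf, float))
        for k, v in meta.items():
            setattr(out, k, v)
        return out


def apply_purity(vafs: np.ndarray, purity: float) -> np.ndarray:
    """Dilute true frequencies by tumour purity (pre-read-sampling)."""
    _check(0.0 < purity <= 1.0, "purity must lie in (0, 1]")
    return np.asarray(vafs, dtype=float) * purity


@njit(cache=True)
def _biopsy_kernel(p, pool, depth_p, rho, min_alt, seed):
    np.random.seed(seed)
    m = p.size
    alt = np.empty(m, np.int64)
    dep = np.empty(m, np.int64)
    k = 0
    c = (1.0 - rho) / rho if rho > 0.0 else 0.0
    for i in range(m):
        d = np.random.binomial(pool, depth_p)
        pi = p[i]
        if rho > 0.0 and 0.0 < pi < 1.0:
            pi = np.random.beta(pi * c, (1.0 - pi) * c)
        r = np.random.binomial(d, pi) if d > 0 else 0
        if r >= min_alt:
            alt[k] = r
            dep[k] = d
            k += 1
    return alt[:k], dep[:k]


def virtual_biopsy(truth, seq: SequencingParams, seed: int = 0,
                   min_true_vaf: float = 0.0) -> VAFSample:
    """Sample observed read counts for every mutation of a tumour.

    ``truth`` is a :class:`TumourTruth` or a 1-D array of true VAFs in
    ``(0, 0.5]``.  ``min_true_vaf`` is a detection floor on the purity-diluted
    frequency: mutations below it skip read sampling entirely.  The default 0
    is exact; bulk dataset generation raises it to a value far below the
    featurization cutoff, where the probability of a mutation ever entering
    the feature histograms is negligible (see the methods note).
    """
    seq.validate()
    if isinstance(truth, TumourTruth):
        pool = seq.depth_pool or (truth.n_final if truth.n_final > 0 else 1000)
        p = truth.group_vafs * seq.purity
        keep = p >= min_true_vaf
        p = np.repeat(p[keep], truth.group_counts[keep])
    else:
        vafs = np.asarray(truth, dtype=float)
        pool = seq.depth_pool or 1000
        p = vafs * seq.purity
        p = p[p >= min_true_vaf]
    _check(seq.mean_depth / pool <= 1.0,
           "mean_depth may not exceed the depth pool size")
    _check(p.size == 0 or float(p.max()) <= 1.0, "diluted VAF above 1")

    alt, dep = _biopsy_kernel(np.ascontiguousarray(p, dtype=np.float64),
                              int(pool), seq.mean_depth / pool, float(seq.rho),
                              int(seq.min_alt_reads), int(seed) % (2**31 - 1))
    return VAFSample(alt_count=alt, depth=dep, mean_depth=seq.mean_depth,
                     purity=seq.purity, min_alt_reads=seq.min_alt_reads,
                     provenance="synthetic")
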