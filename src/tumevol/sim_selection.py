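"""Stochastic branching-process simulation of exponentially growing tumours.

A tumour starts from a single founder cell carrying ``n_clonal`` heterozygous
diploid mutations and grows to ``n_final`` cells under a rejection-kinetic
Monte Carlo scheme: a cell is drawn uniformly at random and divides (or dies)
with probability proportional to its birth (death) rate, normalised by the
current maximum rate in the population.  At every division each daughter cell
acquires ``Poisson(mutation_rate)`` new mutations.  Each new mutation is a
driver with probability ``p_driver`` (until ``max_drivers`` driver events have
occurred); a driver receives a selection coefficient ``s ~ Exponential(s_mean)``
and multiplies the net growth rate ``b - d`` of its lineage by ``(1 + s)``,
so a cell's fitness is the product ``prod(1 + s_i)`` over its drivers.

Cells are stored as references into a genotype table (a genotype is created
whenever a daughter acquires at least one new mutation), which keeps memory
linear in the number of genotypes rather than the number of mutations.  The
true VAF of every mutation on a diploid heterozygous background is
``cells carrying it / (2 N)``; clonal founder mutations sit at exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SelectionParams",
    "DriverLineage",
    "SubcloneLabels",
    "TumourTruth",
    "simulate_tumour",
    "label_subclones",
    "DETECTION_WINDOW",
    "MERGE_GAP",
]

#: detectable subclone window on the VAF scale (20-80% cellular fraction)
DETECTION_WINDOW = (0.10, 0.40)
#: minimum VAF separation for two driver lineages to count as distinct subclones
MERGE_GAP = 0.05

_EXTINCTION_RETRIES = 100
_SEED_MOD = 2**31 - 1


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the stochastic selection simulator.

    ``birth_rate`` defaults to ``ln 2`` and ``death_rate`` to 0 so that, with
    ``n_final = 1000``, tumours grow in roughly ten population doublings --
    a small-population approximation that reproduces the shape of empirical
    VAF distributions at a fraction of the cost of realistic tumour sizes.
    """

    mutation_rate: float = 20.0
    p_driver: float = 1e-4
    s_mean: float = 1.0
    n_clonal: int = 500
    max_drivers: int = 3
    n_final: int = 1000
    birth_rate: float = float(np.log(2))
    death_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _check(np.isfinite(self.mutation_rate) and self.mutation_rate >= 0,
               "mutation_rate must be finite and >= 0")
        _check(0.0 <= self.p_driver <= 1.0, "p_driver must lie in [0, 1]")
        _check(self.s_mean > 0, "s_mean must be > 0")
        _check(self.n_clonal >= 0, "n_clonal must be >= 0")
        _check(self.max_drivers >= 0, "max_drivers must be >= 0")
        _check(self.n_final >= 2, "n_final must be >= 2")
        _check(np.isfinite(self.birth_rate) and np.isfinite(self.death_rate),
               "rates must be finite")
        _check(self.birth_rate > self.death_rate >= 0.0,
               "require birth_rate > death_rate >= 0")


@dataclass(frozen=True)
class DriverLineage:
    """One driver event: the genotype it created and its state at biopsy."""

    genotype: int
    s: float
    cellular_fraction: float  # fraction of tumour cells in the lineage
    fitness: float            # cumulative prod(1 + s) of the genotype

    @property
    def vaf(self) -> float:
        return 0.5 * self.cellular_fraction


@dataclass(frozen=True)
class SubcloneLabels:
    mode: str                 # "neutral" | "selection"
    n_subclones: int          # 0 | 1 | 2
    subclone_vafs: tuple[float, ...] = ()
    usable: bool = True       # False if >2 detectable subclones

    def __post_init__(self):
        _check(self.mode in ("neutral", "selection"), "bad mode")
        if self.usable:
            _check((self.mode == "neutral") == (self.n_subclones == 0),
                   "mode neutral iff zero subclones")
            _check(len(self.subclone_vafs) == self.n_subclones,
                   "subclone_vafs length mismatch")
        _check(all(self.subclone_vafs[i] >= self.subclone_vafs[i + 1]
                   for i in range(len(self.subclone_vafs) - 1)),
               "subclone_vafs must be sorted descending")


@dataclass
class TumourTruth:
    """A simulated tumour with per-mutation ground truth.

    Mutations are stored run-length compressed: ``group_vafs[i]`` is the true
    VAF shared by ``group_counts[i]`` mutations (all mutations born with the
    same genotype share the cell count of that genotype's subtree).  Driver
    mutations are singled out in ``driver_lineages``.
    """

    n_final: int
    n_clonal: int
    group_vafs: np.ndarray        # float, per mutation group
    group_counts: np.ndarray      # int, mutations per group
    driver_lineages: list[DriverLineage]
    labels: SubcloneLabels | None = None
    params: SelectionParams | None = None

    @property
    def n_mutations(self) -> int:
        return int(self.group_counts.sum())

    @property
    def true_vafs(self) -> np.ndarray:
        """Expanded per-mutation true VAFs (clonal mutations at exactly 0.5)."""
        return np.repeat(self.group_vafs, self.group_counts)

    def to_frame(self):
        """Flat per-mutation table (id, true VAF, driver flag, s)."""
        import pandas as pd
        vafs = self.true_vafs
        flags = self.is_driver_flags()
        s_col = np.zeros(vafs.size)
        if self.driver_lineages:
            starts = np.flatnonzero(flags)
            for i, lin in zip(starts, self.driver_lineages):
                s_col[i] = lin.s
        return pd.DataFrame({"mutation_id": np.arange(vafs.size),
                             "true_vaf": vafs, "is_driver": flags,
                             "s": s_col})

    def is_driver_flags(self) -> np.ndarray:
        """Expanded boolean mask aligned with :attr:`true_vafs`."""
        flags = np.zeros(self.n_mutations, dtype=bool)
        driver_groups = getattr(self, "_driver_group_idx", None)
        if driver_groups is not None:
            starts = np.concatenate(([0], np.cumsum(self.group_counts)[:-1]))
            flags[starts[driver_groups]] = True
        return flags


@njit(cache=True)
def _grow(seed, n_final, mu, p_driver, s_mean, birth, death, max_drivers, gen_cap):
    """Rejection-kinetic growth; returns genotype table arrays.

    Returns (status, ngen, parent, ncells, nmut, fit, drv_gen, drv_s, ndrv)
    with status 0 = ok, 1 = extinct, 2 = genotype capacity exceeded.
    """
    np.random.seed(seed)
    parent = np.full(gen_cap, -1, np.int64)
    ncells = np.zeros(gen_cap, np.int64)
    nmut = np.zeros(gen_cap, np.int64)      # new neutral mutations per genotype
    gbirth = np.empty(gen_cap, np.float64)
    gfit = np.empty(gen_cap, np.float64)    # cumulative prod(1+s)
    drv_gen = np.empty(max_drivers + 1, np.int64)
    drv_s = np.empty(max_drivers + 1, np.float64)

    cells = np.empty(n_final, np.int64)
    cells[0] = 0
    ncells[0] = 1
    gbirth[0] = birth
    gfit[0] = 1.0
    ngen = 1
    ndrv = 0
    n = 1
    bmax = birth
    total = bmax + death

    while n < n_final:
        j = int(np.random.random() * n)
        if j == n:
            j = n - 1
        g = cells[j]
        r = np.random.random() * total
        bg = gbirth[g]
        if r < bg:
            # division: parent replaced by two daughters
            ncells[g] -= 1
            for dtr in range(2):
                k = np.random.poisson(mu) if mu > 0.0 else 0
                nd = 0
                if k > 0 and p_driver > 0.0 and ndrv < max_drivers:
                    nd = np.random.binomial(k, p_driver)
                    rem = max_drivers - ndrv
                    if nd > rem:
                        nd = rem
                if k > 0:
                    if ngen >= gen_cap:
                        return 2, ngen, parent, ncells, nmut, gfit, drv_gen, drv_s, ndrv
                    gi = ngen
                    ngen += 1
                    parent[gi] = g
                    nmut[gi] = k - nd
                    gb = bg
                    gf = gfit[g]
                    for _ in range(nd):
                        s = np.random.exponential(s_mean)
                        drv_gen[ndrv] = gi
                        drv_s[ndrv] = s
                        ndrv += 1
                        gb = death + (gb - death) * (1.0 + s)
                        gf = gf * (1.0 + s)
                    gbirth[gi] = gb
                    gfit[gi] = gf
                    ncells[gi] = 1
                    if gb > bmax:
                        bmax = gb
                        total = bmax + death
                    newg = gi
                else:
                    ncells[g] += 1
                    newg = g
                if dtr == 0:
                    cells[j] = newg
                else:
                    cells[n] = newg
                    n += 1
        elif r < bg + death:
            ncells[g] -= 1
            n -= 1
            cells[j] = cells[n]
            if n == 0:
                return 1, ngen, parent, ncells, nmut, gfit, drv_gen, drv_s, ndrv
    return 0, ngen, parent, ncells, nmut, gfit, drv_gen, drv_s, ndrv


@njit(cache=True)
def _subtree_counts(ngen, parent, ncells):
    sub = ncells[:ngen].copy()
    for i in range(ngen - 1, 0, -1):
        sub[parent[i]] += sub[i]
    return sub


def simulate_tumour(params: SelectionParams) -> TumourTruth:
    """Grow one tumour to ``params.n_final`` cells and label its subclones.

    Deterministic under a fixed ``params.seed``.  With ``death_rate > 0`` an
    extinct population is retried (fresh RNG stream) up to 100 times.
    """
    params.validate()
    # each division creates at most 2 genotypes; expected divisions are
    # (n_final - 1) * b / (b - d), padded generously for stochastic overshoot
    ratio = params.birth_rate / (params.birth_rate - params.death_rate)
    gen_cap = int(8 * params.n_final * ratio) + 16

    status = 1
    for attempt in range(_EXTINCTION_RETRIES):
        seed = (params.seed + 1_000_003 * attempt) % _SEED_MOD
        out = _grow(seed, params.n_final, float(params.mutation_rate),
                    float(params.p_driver), float(params.s_mean),
                    float(params.birth_rate), float(params.death_rate),
                    int(params.max_drivers), gen_cap)
        status = out[0]
        if status == 0:
            break
        if status == 2:
            gen_cap *= 2
    if status == 1:
        raise RuntimeError(
            f"population went extinct in {_EXTINCTION_RETRIES} consecutive attempts")
    if status == 2:
        raise RuntimeError("genotype table capacity exceeded")

    _, ngen, parent, ncells, nmut, gfit, drv_gen, drv_s, ndrv = out
    sub = _subtree_counts(ngen, parent, ncells)
    n = params.n_final

    # mutation groups: clonal founder block, neutral per-genotype blocks,
    # and one singleton block per driver mutation
    gvafs = [np.array([0.5])] if params.n_clonal > 0 else []
    gcounts = [np.array([params.n_clonal])] if params.n_clonal > 0 else []
    alive = nmut[:ngen] > 0
    gvafs.append(sub[alive] / (2.0 * n))
    gcounts.append(nmut[:ngen][alive])
    driver_lineages = []
    driver_group_idx = []
    offset = sum(len(v) for v in gvafs)
    for i in range(ndrv):
        gi = int(drv_gen[i])
        driver_lineages.append(DriverLineage(
            genotype=gi, s=float(drv_s[i]),
            cellular_fraction=float(sub[gi]) / n,
            fitness=float(gfit[gi])))
        gvafs.append(np.array([sub[gi] / (2.0 * n)]))
        gcounts.append(np.array([1]))
        driver_group_idx.append(offset + i)

    truth = TumourTruth(
        n_final=n,
        n_clonal=params.n_clonal,
        group_vafs=np.concatenate(gvafs) if gvafs else np.empty(0),
        group_counts=np.concatenate(gcounts).astype(np.int64)
        if gcounts else np.empty(0, np.int64),
        driver_lineages=driver_lineages,
        params=params,
    )
    truth._driver_group_idx = np.asarray(driver_group_idx, dtype=np.int64)
    truth.labels = label_subclones(truth)
    return truth


def label_subclones(truth: TumourTruth,
                    window: tuple[float, float] = DETECTION_WINDOW,
                    merge_gap: float = MERGE_GAP) -> SubcloneLabels:
    """Assign the 0/1/2-subclone ground-truth label to a simulated tumour.

    A detectable subclone is a driver lineage whose VAF (cellular fraction / 2)
    lies inside ``window``.  Lineages separated by less than ``merge_gap`` on
    the VAF scale are indistinguishable in a one-dimensional VAF distribution
    and are merged (single linkage), reporting the largest lineage's VAF.
    More than two detectable subclones cannot be expressed in the 0/1/2 label
    scheme; such tumours are flagged ``usable=False`` rather than rejected.
    """
    lo, hi = window
    vafs = sorted({round(l.vaf, 12) for l in truth.driver_lineages
                   if lo <= l.vaf <= hi}, reverse=True)
    if not vafs:
        return SubcloneLabels(mode="neutral", n_subclones=0)
    # single-linkage merge on descending VAFs
    reps: list[float] = [vafs[0]]
    prev = vafs[0]
    for v in vafs[1:]:
        if prev - v >= merge_gap:
            reps.append(v)
        prev = v
    if len(reps) > 2:
        return SubcloneLabels(mode="selection", n_subclones=2,
                              subclone_vafs=tuple(reps[:2]), usable=False)
    return SubcloneLabels(mode="selection", n_subclones=len(reps),
                          subclone_vafs=tuple(reps))
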