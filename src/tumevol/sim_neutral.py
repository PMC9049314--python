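"""Generative sampling of neutral VAF distributions and paired datasets.

Neutrally evolving tumours have VAF distributions whose non-clonal part
follows a power law: the density of a mutation at frequency ``x`` is
``f(x | alpha, m) = alpha m^alpha x^-(alpha+1)`` (a Pareto distribution with
shape ``alpha`` and scale ``m``).  A neutral tumour is therefore sampled
directly -- Pareto tail plus a clonal cluster -- instead of run through the
branching simulator, which at small population sizes occasionally produces
spurious late subclones by drift.  Two perturbations emulate features of
real biopsies: with probability ``p_trim`` the tail below ``trim_f`` is
removed (many real samples lack a visible tail), and the clonal cluster is
shifted to 45-50% VAF (emulating modest purity mis-estimates).

Selected and neutral tumours are generated in *pairs* sharing the clonal
mutation count, the total mutation count, and the sequencing parameters, so
that a classifier cannot separate the two classes by mutational burden or
noise level alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .biopsy import SequencingParams, VAFSample, virtual_biopsy
from .sim_selection import (SelectionParams, SubcloneLabels, TumourTruth,
                            _check, simulate_tumour)

__all__ = [
    "NeutralParams",
    "sample_pareto",
    "sample_pareto_shape",
    "generate_neutral",
    "generate_pair",
    "PairedSample",
    "DatasetPriors",
]

_SEED_MOD = 2**31 - 1

#: scaled-down study conditions for the clean-sequencing model suite
#: (the conditions the held-out classification/regression checks use)
DESK_NARROW = dict(mean_depth=(100.0, 150.0), rho=(0.0, 0.003))
#: broad sequencing conditions covering low-depth, high-overdispersion and
#: impure samples after purity correction (robustness model)
DESK_BROAD = dict(mean_depth=(20.0, 250.0), rho=(0.0, 0.3))


@dataclass(frozen=True)
class NeutralParams:
    pareto_shape: float
    pareto_scale: float
    n_tail: int
    n_clonal: int
    p_trim: float = 0.1
    trim_f: float = 0.2
    clonal_center: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        _check(self.pareto_shape > 0, "pareto_shape must be > 0")
        _check(0.0 < self.pareto_scale < 0.5, "pareto_scale must lie in (0, 0.5)")
        _check(self.n_tail >= 0 and self.n_clonal >= 0, "counts must be >= 0")
        _check(0.0 <= self.p_trim <= 0.1, "p_trim must lie in [0, 0.1]")
        _check(0.10 <= self.trim_f <= 0.30, "trim_f must lie in [0.10, 0.30]")
        _check(0.45 <= self.clonal_center <= 0.50,
               "clonal_center must lie in [0.45, 0.50]")


def sample_pareto(shape: float, scale: float, n: int,
                  seed_or_rng) -> np.ndarray:
    """Draw ``n`` i.i.d. Pareto(shape, scale) VAFs; draws above 0.5 are
    resampled so the output respects the VAF support.

    The maximum-likelihood estimate of the scale given data is the minimum
    observed value, and the analytic quantile function is
    ``Q(q) = scale * (1 - q)^(-1/shape)``.
    """
    _check(shape > 0, "shape must be > 0")
    _check(0.0 < scale < 0.5, "scale must lie in (0, 0.5)")
    _check(n >= 0, "n must be >= 0")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    out = scale * (1.0 + rng.pareto(shape, size=n))
    bad = out > 0.5
    while bad.any():
        out[bad] = scale * (1.0 + rng.pareto(shape, size=int(bad.sum())))
        bad = out > 0.5
    return out


def sample_pareto_shape(rng: np.random.Generator) -> float:
    """Draw a Pareto shape from the package's default sampling distribution:
    log-normal with median 1.0 (sigma 0.5), truncated to [0.5, 3].

    This is a documented stand-in for shape distributions fit to patient
    cohorts; a user-supplied table of shapes can be passed to
    :class:`DatasetPriors` instead.
    """
    while True:
        a = float(rng.lognormal(mean=0.0, sigma=0.5))
        if 0.5 <= a <= 3.0:
            return a


def generate_neutral(params: NeutralParams) -> TumourTruth:
    """Sample one neutral tumour (pre-sequencing-noise true VAFs)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tail = sample_pareto(params.pareto_shape, params.pareto_scale,
                         params.n_tail, rng)
    if params.p_trim > 0 and rng.random() < params.p_trim:
        tail = tail[tail >= params.trim_f]
    groups = []
    counts = []
    if params.n_clonal > 0:
        groups.append(np.array([params.clonal_center]))
        counts.append(np.array([params.n_clonal]))
    groups.append(tail)
    counts.append(np.ones(tail.size, dtype=np.int64))
    truth = TumourTruth(
        n_final=0, n_clonal=params.n_clonal,
        group_vafs=np.concatenate(groups) if groups else np.empty(0),
        group_counts=np.concatenate(counts).astype(np.int64),
        driver_lineages=[],
        labels=SubcloneLabels(mode="neutral", n_subclones=0),
    )
    return truth


def _generate_neutral_above(params: NeutralParams,
                            floor: float) -> TumourTruth:
    """Neutral tumour with only the tail mutations above ``floor``
    instantiated (distributionally identical to filtering afterwards)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    if floor >= 0.5:
        tail = np.empty(0)
    else:
        p_keep = (params.pareto_scale / floor) ** params.pareto_shape
        k = int(rng.binomial(params.n_tail, min(p_keep, 1.0)))
        tail = sample_pareto(params.pareto_shape, floor, k, rng)
    if params.p_trim > 0 and rng.random() < params.p_trim:
        tail = tail[tail >= params.trim_f]
    groups, counts = [], []
    if params.n_clonal > 0:
        groups.append(np.array([params.clonal_center]))
        counts.append(np.array([params.n_clonal]))
    groups.append(tail)
    counts.append(np.ones(tail.size, dtype=np.int64))
    return TumourTruth(
        n_final=0, n_clonal=params.n_clonal,
        group_vafs=np.concatenate(groups),
        group_counts=np.concatenate(counts).astype(np.int64),
        driver_lineages=[],
        labels=SubcloneLabels(mode="neutral", n_subclones=0))


@dataclass
class PairedSample:
    """One selected/neutral pair after virtual biopsy."""

    selected: VAFSample
    selected_labels: SubcloneLabels
    neutral: VAFSample
    neutral_labels: SubcloneLabels
    pair_id: int = 0
    n_regenerated: int = 0
    # pre-noise bookkeeping (identical in both arms by construction)
    n_clonal: int = 0
    n_prenoise_selected: int = 0
    n_prenoise_neutral: int = 0


@dataclass(frozen=True)
class DatasetPriors:
    """Sampling ranges for the synthetic training conditions.

    Mutation rates are drawn log-uniformly over a range spanning typical
    whole-genome per-division burdens; driver probabilities and mean selection
    coefficients are chosen so that a substantial fraction of selection
    simulations carries a detectable subclone at the small simulated
    population size (see the methods note for the rationale of every range).
    """

    mutation_rate: tuple[float, float] = (5.0, 100.0)     # log-uniform
    p_driver: tuple[float, float] = (1e-5, 1e-3)          # log-uniform
    s_mean: tuple[float, float] = (0.5, 3.0)              # uniform
    n_clonal: tuple[int, int] = (200, 2000)               # uniform integer
    n_final: int = 1000
    mean_depth: tuple[float, float] = (50.0, 250.0)       # uniform
    rho: tuple[float, float] = (0.0, 0.003)               # uniform
    min_alt_reads: int = 2
    purity: float = 1.0
    pareto_shapes: tuple[float, ...] | None = None  # optional empirical table

    def sample_selection_params(self, rng: np.random.Generator) -> SelectionParams:
        lo, hi = self.mutation_rate
        mu = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lo, hi = self.p_driver
        pd_ = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return SelectionParams(
            mutation_rate=mu, p_driver=pd_,
            s_mean=float(rng.uniform(*self.s_mean)),
            n_clonal=int(rng.integers(self.n_clonal[0], self.n_clonal[1] + 1)),
            n_final=self.n_final,
            seed=int(rng.integers(_SEED_MOD)))

    def sample_sequencing_params(self, rng: np.random.Generator) -> SequencingParams:
        return SequencingParams(
            mean_depth=float(rng.uniform(*self.mean_depth)),
            rho=float(rng.uniform(*self.rho)),
            min_alt_reads=self.min_alt_reads,
            purity=self.purity)

    def sample_shape(self, rng: np.random.Generator) -> float:
        if self.pareto_shapes is not None:
            return float(rng.choice(np.asarray(self.pareto_shapes)))
        return sample_pareto_shape(rng)


def generate_pair(sel_params: SelectionParams, seq: SequencingParams,
                  seed: int = 0, *, pareto_shape: float | None = None,
                  min_true_vaf: float = 0.0, max_attempts: int = 25,
                  require_detectable: bool = False) -> PairedSample:
    """Simulate one selection tumour and its count-matched neutral twin.

    The neutral arm reuses the selection arm's clonal count, uses the total
    non-clonal mutation count as its Pareto tail size, sets the Pareto scale
    to the selection arm's minimum true frequency (the MLE convention), and
    is biopsied with the identical :class:`SequencingParams`.  Selection
    simulations flagged unusable (>2 detectable subclones) are regenerated,
    as are -- when ``require_detectable`` -- simulations with no detectable
    subclone (capped at ``max_attempts``).
    """
    rng = np.random.default_rng(seed)
    truth = None
    n_regen = 0
    for attempt in range(max_attempts):
        p = replace(sel_params, seed=int(rng.integers(_SEED_MOD)))
        cand = simulate_tumour(p)
        if cand.labels.usable and not (require_detectable
                                       and cand.labels.n_subclones == 0):
            truth = cand
            break
        n_regen += 1
    if truth is None:
        raise RuntimeError(
            f"no usable selection simulation in {max_attempts} attempts")

    nonclonal = truth.group_vafs[truth.group_vafs < 0.5]
    n_tail = truth.n_mutations - truth.n_clonal
    scale = float(nonclonal.min()) if nonclonal.size else 1.0 / (4 * truth.n_final)
    shape = pareto_shape if pareto_shape is not None else sample_pareto_shape(rng)
    neutral_params = NeutralParams(
        pareto_shape=shape, pareto_scale=scale, n_tail=n_tail,
        n_clonal=truth.n_clonal, p_trim=0.1,
        trim_f=float(rng.uniform(0.10, 0.30)),
        clonal_center=float(rng.uniform(0.45, 0.50)),
        seed=int(rng.integers(_SEED_MOD)))
    floor = min_true_vaf / seq.purity   # biopsy floors the diluted frequency
    if floor > scale:
        # equivalent fast path: a Pareto conditioned on exceeding the biopsy
        # detection floor is a Pareto with the floor as scale, so only the
        # Binomial(n_tail, P(X >= floor)) mutations that could ever be
        # observed are instantiated
        neutral = _generate_neutral_above(neutral_params, floor)
    else:
        neutral = generate_neutral(neutral_params)

    if seq.depth_pool is None:
        seq = replace(seq, depth_pool=truth.n_final)
    sel_obs = virtual_biopsy(truth, seq, seed=int(rng.integers(_SEED_MOD)),
                             min_true_vaf=min_true_vaf)
    neu_obs = virtual_biopsy(neutral, seq, seed=int(rng.integers(_SEED_MOD)),
                             min_true_vaf=min_true_vaf)
    return PairedSample(selected=sel_obs, selected_labels=truth.labels,
                        neutral=neu_obs, neutral_labels=neutral.labels,
                        pair_id=seed, n_regenerated=n_regen,
                        n_clonal=truth.n_clonal,
                        n_prenoise_selected=truth.n_mutations,
                        # assigned (pre-trim) count; random tail trimming may
                        # drop realised neutral mutations below trim_f
                        n_prenoise_neutral=neutral_params.n_tail
                        + neutral_params.n_clonal)
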