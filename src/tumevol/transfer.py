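"""Open-set domain adaptation: recycle trained trunks for new inference tasks.

The target domain is an alternative tumour simulator in which a single
subclone is initiated *deterministically*: growth is a birth-death branching
process (birth 1, death 0.2, final size 10^4) and at population-doubling time
``t_s`` one random cell founds a subclone whose net growth rate is multiplied
by a user-specified fitness ``w = 1 + s``.  The inference tasks become the
per-genome per-division mutation rate, the subclone fitness, its emergence
time (in tumour doublings) and its cellular fraction (subclone VAF * 2).

The input space -- the VAF histogram -- is unchanged, so pre-trained
convolutional trunks store reusable knowledge: *architecture renovation*
concatenates the trunks of the classification (M_ms) and single-subclone
regression (M_1s) models, replaces their task branches with four fresh
fully-connected branches, and fine-tunes on the new simulations.  Because
only fitness/emergence-time combinations inside a narrow band yield
detectable subclones (10-40% VAF), training parameters are drawn from a
noisy Gaussian-process regression of viable ``t_s`` on fitness fitted to a
small pilot grid.  A residual systematic bias in the mutation-rate output is
removed post hoc with a degree-2 polynomial ridge regression fitted on 1000
synthetic tumours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .biopsy import SequencingParams, virtual_biopsy
from .features import DEFAULT_K, featurize
from .netmodel import (ModelSpec, MultiTaskCNN, TrainConfig, build_network,
                       mc_draws, train)
from .sim_selection import (DriverLineage, SelectionParams, SubcloneLabels,
                            TumourTruth, _check, _grow, _subtree_counts)

__all__ = [
    "DeterministicSimParams", "TransferLabels", "simulate_deterministic",
    "make_pilot_table", "ViableParamSampler", "viable_param_sampler",
    "TransferSet", "make_transfer_set", "renovate", "finetune",
    "calibrate_mu", "MutationRateCalibration", "predict_transfer",
]

_SEED_MOD = 2**31 - 1
DETECTABLE = (0.10, 0.40)

#: default sequencing conditions of the transfer study (75-200x, light
#: beta-binomial overdispersion, pure tumours)
TRANSFER_DEPTHS = (75.0, 200.0)
TRANSFER_RHO = (0.0, 0.003)
TRANSFER_MU = (5.0, 100.0)


@dataclass(frozen=True)
class DeterministicSimParams:
    mutation_rate: float = 20.0
    subclone_fitness: float = 2.0     # growth-rate multiplier 1 + s
    subclone_time: float = 6.0        # emergence time in population doublings
    n_clonal: int = 500
    n_final: int = 10_000
    birth_rate: float = 1.0
    death_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _check(self.birth_rate > self.death_rate >= 0, "need birth > death >= 0")
        _check(self.subclone_time >= 0, "subclone_time must be >= 0")
        _check(self.subclone_fitness >= 1.0, "fitness must be >= 1")
        _check(self.mutation_rate >= 0 and self.n_final >= 2, "bad sizes")


@dataclass(frozen=True)
class TransferLabels:
    mutation_rate: float
    subclone_fitness: float
    subclone_time: float
    subclone_cellular_fraction: float   # subclone VAF * 2

    def __post_init__(self):
        _check(0.0 <= self.subclone_cellular_fraction <= 1.0,
               "cellular fraction must lie in [0, 1]")

    @property
    def detectable(self) -> bool:
        vaf = self.subclone_cellular_fraction / 2.0
        return DETECTABLE[0] <= vaf <= DETECTABLE[1]


def simulate_deterministic(params: DeterministicSimParams
                           ) -> tuple[TumourTruth, TransferLabels]:
    """Grow a tumour with one deterministically initiated subclone.

    The subclone is founded by one random cell when the population first
    reaches ``2 ** subclone_time`` cells; if that never happens before
    biopsy, or the subclone lineage dies out, the tumour is returned with
    cellular fraction 0 (flagged by the labels, not an error).
    """
    params.validate()
    founder_size = int(round(2.0 ** params.subclone_time))
    rng = np.random.default_rng(params.seed)
    for _ in range(100):
        out = _grow_deterministic(
            int(rng.integers(_SEED_MOD)), params.n_final,
            float(params.mutation_rate), float(params.subclone_fitness),
            founder_size, float(params.birth_rate), float(params.death_rate),
            int(10 * params.n_final *
                params.birth_rate / (params.birth_rate - params.death_rate)))
        if out[0] == 0:
            break
    else:
        raise RuntimeError("population went extinct in 100 attempts")
    _, ngen, parent, ncells, nmut, sub_gen = out
    sub = _subtree_counts(ngen, parent, ncells)
    n = params.n_final

    frac = float(sub[sub_gen]) / n if sub_gen >= 0 else 0.0
    gvafs = [np.array([0.5])] if params.n_clonal > 0 else []
    gcounts = [np.array([params.n_clonal])] if params.n_clonal > 0 else []
    alive = nmut[:ngen] > 0
    gvafs.append(sub[alive] / (2.0 * n))
    gcounts.append(nmut[:ngen][alive])
    lineages = []
    if sub_gen >= 0 and frac > 0:
        lineages.append(DriverLineage(genotype=int(sub_gen),
                                      s=params.subclone_fitness - 1.0,
                                      cellular_fraction=frac,
                                      fitness=params.subclone_fitness))
    truth = TumourTruth(
        n_final=n, n_clonal=params.n_clonal,
        group_vafs=np.concatenate(gvafs),
        group_counts=np.concatenate(gcounts).astype(np.int64),
        driver_lineages=lineages)
    from .sim_selection import label_subclones
    truth.labels = label_subclones(truth)
    labels = TransferLabels(
        mutation_rate=params.mutation_rate,
        subclone_fitness=params.subclone_fitness,
        subclone_time=params.subclone_time,
        subclone_cellular_fraction=frac)
    return truth, labels


@njit(cache=True)
def _grow_deterministic(seed, n_final, mu, fitness, founder_size,
                        birth, death, gen_cap):
    """Birth-death growth with one subclone initiated at a fixed size."""
    np.random.seed(seed)
    parent = np.full(gen_cap, -1, np.int64)
    ncells = np.zeros(gen_cap, np.int64)
    nmut = np.zeros(gen_cap, np.int64)
    gbirth = np.empty(gen_cap, np.float64)

    cells = np.empty(n_final, np.int64)
    cells[0] = 0
    ncells[0] = 1
    gbirth[0] = birth
    ngen = 1
    n = 1
    bmax = birth
    sub_birth = death + (birth - death) * fitness
    sub_gen = np.int64(-1)
    initiated = False
    total = bmax + death
    while n < n_final:
        if not initiated and n >= founder_size:
            j = int(np.random.random() * n)
            if j == n:
                j = n - 1
            g = cells[j]
            gi = ngen
            ngen += 1
            parent[gi] = g
            nmut[gi] = 0
            gbirth[gi] = sub_birth
            ncells[gi] = 1
            ncells[g] -= 1
            cells[j] = gi
            sub_gen = gi
            if sub_birth > bmax:
                bmax = sub_birth
                total = bmax + death
            initiated = True
        j = int(np.random.random() * n)
        if j == n:
            j = n - 1
        g = cells[j]
        r = np.random.random() * total
        bg = gbirth[g]
        if r < bg:
            ncells[g] -= 1
            for dtr in range(2):
                k = np.random.poisson(mu) if mu > 0.0 else 0
                if k > 0:
                    if ngen >= gen_cap:
                        return 2, ngen, parent, ncells, nmut, sub_gen
                    gi = ngen
                    ngen += 1
                    parent[gi] = g
                    nmut[gi] = k
                    gbirth[gi] = bg
                    ncells[gi] = 1
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
                return 1, ngen, parent, ncells, nmut, sub_gen
    return 0, ngen, parent, ncells, nmut, sub_gen


# ---------------------------------------------------------------------------
# viable (fitness, t_s) sampling
# ---------------------------------------------------------------------------

def make_pilot_table(n: int = 150, seed: int = 0,
                     fitness_range=(1.2, 8.0),
                     t_s_range=(1.0, 12.0)) -> np.ndarray:
    """Pilot simulations mapping (fitness, t_s) to realised subclone VAF.

    Pilot conditions: mutation rate 20, 100x depth, beta-binomial noise --
    read noise does not enter the table since the true lineage fraction is
    recorded directly.  Returns an (n, 3) array [fitness, t_s, subclone VAF].
    """
    rng = np.random.default_rng(seed)
    rows = np.empty((n, 3))
    for i in range(n):
        w = float(rng.uniform(*fitness_range))
        ts = float(rng.uniform(*t_s_range))
        _, lab = simulate_deterministic(DeterministicSimParams(
            mutation_rate=20.0, subclone_fitness=w, subclone_time=ts,
            seed=int(rng.integers(_SEED_MOD))))
        rows[i] = (w, ts, lab.subclone_cellular_fraction / 2.0)
    return rows


@dataclass
class ViableParamSampler:
    """Draws fitness uniformly, then a viable emergence time from a noisy
    Gaussian-process regression of t_s on fitness."""

    gp: object
    x_mean: float
    x_std: float
    y_mean: float
    y_std: float
    fitness_range: tuple[float, float]
    t_s_range: tuple[float, float]
    noisy: bool = True   # False collapses draws onto the GP mean

    def sample(self, rng: np.random.Generator,
               size: int = 1) -> np.ndarray:
        w = rng.uniform(*self.fitness_range, size=size)
        xs = ((w - self.x_mean) / self.x_std)[:, None]
        mean, std = self.gp.predict(xs, return_std=True)
        if not self.noisy:
            std = np.zeros_like(std)
        ts = (mean + rng.normal(0.0, 1.0, size) * std) * self.y_std + self.y_mean
        ts = np.clip(ts, *self.t_s_range)
        return np.stack([w, ts], axis=1)


def viable_param_sampler(pilot_table: np.ndarray,
                         window=DETECTABLE) -> ViableParamSampler:
    """Fit the noisy GP (RBF length scale 100 + dot product + white noise,
    alpha 1e-6) to the pilot rows that produced a detectable subclone.

    Inputs are standardised before fitting, so the stated kernel scales act
    on z-scores.  The white-noise component is what spreads sampled
    emergence times over the whole viable band rather than its centre.
    """
    pilot_table = np.asarray(pilot_table, dtype=float)
    _check(pilot_table.ndim == 2 and pilot_table.shape[1] == 3,
           "pilot_table must be (n, 3): fitness, t_s, subclone VAF")
    _check(pilot_table.shape[0] >= 50, "pilot_table needs at least 50 rows")
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import (RBF, DotProduct,
                                                  WhiteKernel)
    ok = (pilot_table[:, 2] >= window[0]) & (pilot_table[:, 2] <= window[1])
    _check(int(ok.sum()) >= 10, "too few viable pilot rows")
    x, y = pilot_table[ok, 0], pilot_table[ok, 1]
    xm, xs = float(x.mean()), float(x.std() + 1e-12)
    ym, ys = float(y.mean()), float(y.std() + 1e-12)
    kernel = RBF(length_scale=100.0) + DotProduct() + WhiteKernel()
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                  normalize_y=False, random_state=0)
    gp.fit(((x - xm) / xs)[:, None], (y - ym) / ys)
    return ViableParamSampler(gp=gp, x_mean=xm, x_std=xs, y_mean=ym,
                              y_std=ys,
                              fitness_range=(float(x.min()), float(x.max())),
                              t_s_range=(float(y.min()), float(y.max())))


# ---------------------------------------------------------------------------
# transfer dataset
# ---------------------------------------------------------------------------

#: fixed output scales bringing all four regression targets to order one;
#: fitness regresses in log space (its evaluation metric is a percentage
#: error, which an L1 loss matches on the log scale; for emergence time the
#: linear scale proved better balanced across the viable band)
HEAD_SCALES = (100.0, 2.0, 13.0, 1.0)
HEAD_TRANSFORMS = ("linear", "log", "linear", "linear")


@dataclass
class TransferSet:
    X: np.ndarray
    mutation_rate: np.ndarray
    fitness: np.ndarray
    t_s: np.ndarray
    cellular_fraction: np.ndarray
    detectable: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "TransferSet":
        return TransferSet(self.X[idx], self.mutation_rate[idx],
                           self.fitness[idx], self.t_s[idx],
                           self.cellular_fraction[idx], self.detectable[idx],
                           dict(self.meta))

    def task_arrays(self, spec: ModelSpec):
        scales = spec.head_scales or (1.0,) * 4
        transforms = spec.head_transforms or ("linear",) * 4
        raw = {"mutation_rate": self.mutation_rate, "fitness": self.fitness,
               "emergence_time": self.t_s,
               "cellular_fraction": self.cellular_fraction}
        targets = {}
        for (name, v), sc, tr in zip(raw.items(), scales, transforms):
            if tr == "log":
                v = np.log(np.maximum(v, 1e-6))
            targets[name] = (v / sc)[:, None]
        return self.X, targets


def make_transfer_set(n_sims: int, sampler: ViableParamSampler,
                      seed: int = 0, mu_range=TRANSFER_MU,
                      depth_range=TRANSFER_DEPTHS, rho_range=TRANSFER_RHO,
                      min_true_vaf: float = 0.004,
                      k_list=DEFAULT_K) -> TransferSet:
    """Simulate ``n_sims`` deterministic-subclone tumours and featurize them.

    Mutation rates are drawn log-uniformly over ``mu_range``; (fitness, t_s)
    come from the viable-parameter sampler, so most tumours carry a
    detectable subclone while the noisy GP still covers the band edges.
    """
    rng = np.random.default_rng(seed)
    dim = sum(k_list)
    X = np.empty((n_sims, dim))
    mu = np.empty(n_sims)
    fit = np.empty(n_sims)
    ts = np.empty(n_sims)
    frac = np.empty(n_sims)
    for i in range(n_sims):
        w, t_s = sampler.sample(rng, 1)[0]
        m = float(np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]))))
        truth, lab = simulate_deterministic(DeterministicSimParams(
            mutation_rate=m, subclone_fitness=float(w),
            subclone_time=float(t_s), seed=int(rng.integers(_SEED_MOD))))
        seq = SequencingParams(mean_depth=float(rng.uniform(*depth_range)),
                               rho=float(rng.uniform(*rho_range)),
                               depth_pool=truth.n_final)
        obs = virtual_biopsy(truth, seq, seed=int(rng.integers(_SEED_MOD)),
                             min_true_vaf=min_true_vaf)
        X[i] = featurize(obs, k_list).values
        mu[i], fit[i], ts[i] = m, w, t_s
        frac[i] = lab.subclone_cellular_fraction
    detectable = (frac / 2.0 >= DETECTABLE[0]) & (frac / 2.0 <= DETECTABLE[1])
    return TransferSet(X, mu, fit, ts, frac, detectable,
                       meta={"k_list": list(k_list), "seed": seed,
                             "min_true_vaf": min_true_vaf})


# ---------------------------------------------------------------------------
# renovation, fine-tuning, calibration
# ---------------------------------------------------------------------------

def renovate(model_ms: MultiTaskCNN, model_1s: MultiTaskCNN,
             seed: int = 0, branch_layers: int | None = None) -> MultiTaskCNN:
    """Combine the convolutional trunks of M_ms and M_1s and attach four
    fresh task branches.  Trunk weights are copied verbatim; a featurization
    mismatch between the two checkpoints is an error."""
    for attr in ("k_list", "normalized_input", "log1p_input"):
        _check(getattr(model_ms.spec, attr) == getattr(model_1s.spec, attr),
               f"featurization mismatch between source models ({attr})")
    # trunks may come from differently sized source models (channel counts
    # differ); layer count, kernel and pooling layout must line up so the
    # copied weights describe the same computation
    _check(model_ms.spec.n_conv_layers == model_1s.spec.n_conv_layers
           and model_ms.spec.kernel == model_1s.spec.kernel
           and model_ms.spec.branch_type == model_1s.spec.branch_type
           and model_ms.spec.pooling == model_1s.spec.pooling,
           "source trunk layouts differ")
    base = model_ms.spec

    def _ch(m):
        return (m.spec.trunk_channels if m.spec.trunk_channels is not None
                else (m.spec.channels,) * len(m.spec.trunk_segments))

    spec = replace(base, task="transfer",
                   trunk_inputs=tuple(base.trunk_segments)
                   + tuple(model_1s.spec.trunk_segments),
                   trunk_channels=_ch(model_ms) + _ch(model_1s),
                   branch_hidden=max(base.branch_hidden,
                                     model_1s.spec.branch_hidden),
                   branch_layers=(branch_layers if branch_layers is not None
                                  else base.branch_layers),
                   head_scales=HEAD_SCALES,
                   head_transforms=HEAD_TRANSFORMS)
    model = build_network(spec, seed=seed)
    source = model_ms.trunk_params() + model_1s.trunk_params()
    for dst, src in zip(model.trunk_params(), source):
        dst[0][...] = src[0]
    return model


def finetune(model: MultiTaskCNN, data: TransferSet,
             cfg: TrainConfig | None = None) -> dict:
    """Fine-tune a renovated model on deterministic-subclone simulations
    (L1 loss on all four heads; trunks trainable at a 10x reduced rate by
    default, frozen via ``cfg.freeze_trunks``)."""
    cfg = cfg or TrainConfig(trunk_lr_mult=0.1)
    return train(model, data, cfg)


@dataclass
class MutationRateCalibration:
    """Degree-2 polynomial ridge map from predicted to true mutation rate."""

    coef: np.ndarray        # (c0, c1, c2) for c0 + c1 x + c2 x^2
    n_fit: int

    def __call__(self, predicted: np.ndarray) -> np.ndarray:
        x = np.asarray(predicted, dtype=float)
        return self.coef[0] + self.coef[1] * x + self.coef[2] * x * x


def calibrate_mu(model: MultiTaskCNN, calibration: TransferSet,
                 T: int = 50, seed: int = 0,
                 ridge_alpha: float = 1.0) -> MutationRateCalibration:
    """Fit the post-hoc mutation-rate correction on calibration simulations."""
    from sklearn.linear_model import Ridge
    from sklearn.preprocessing import PolynomialFeatures
    draws = mc_draws(model, calibration.X, T=T, seed=seed, branch_only=True)
    pred = draws["mutation_rate"].mean(axis=0)[:, 0]
    _check(float(np.std(pred)) > 1e-9, "degenerate (zero-variance) predictions")
    P = PolynomialFeatures(degree=2, include_bias=False).fit_transform(
        pred[:, None])
    r = Ridge(alpha=ridge_alpha).fit(P, calibration.mutation_rate)
    coef = np.array([r.intercept_, r.coef_[0], r.coef_[1]])
    return MutationRateCalibration(coef=coef, n_fit=calibration.n)


def transfer_desk_bundle(model_ms: MultiTaskCNN, model_1s: MultiTaskCNN,
                         seed: int = 0, n_train: int = 25_000,
                         n_holdout: int = 5_000, n_calibration: int = 1_000,
                         max_epochs: int = 20, n_members: int = 1) -> dict:
    """Run the scaled-down transfer study end to end.

    Fits the viable-parameter GP to a pilot grid, simulates the fine-tuning,
    held-out and calibration sets, renovates the source models and
    fine-tunes ``n_members`` independently initialised replicas whose best
    validation checkpoints are merged into one prediction-time ensemble
    (with one member this is plain snapshot ensembling).  Fits the
    mutation-rate calibration on the resulting model.  Returns everything
    needed for evaluation.
    """
    rng = np.random.default_rng(seed)

    def s():
        return int(rng.integers(_SEED_MOD))

    sampler = viable_param_sampler(make_pilot_table(300, seed=s()))
    train_set = make_transfer_set(n_train, sampler, seed=s())
    holdout = make_transfer_set(n_holdout, sampler, seed=s())
    calib = make_transfer_set(n_calibration, sampler, seed=s())
    members = []
    histories = []
    for _ in range(n_members):
        m = renovate(model_ms, model_1s, seed=s())
        histories.append(finetune(m, train_set,
                                  TrainConfig(max_epochs=max_epochs,
                                              patience=5, trunk_lr_mult=0.1,
                                              snapshot_k=3, seed=s())))
        members.append(m)
    model = members[0]
    if n_members > 1:
        model.snapshots = [w for m in members
                           for w in (m.snapshots or [m.get_weights()])]
    calibration = calibrate_mu(model, calib, T=50, seed=s())
    return {"model": model, "holdout": holdout, "calibration": calibration,
            "sampler": sampler, "train_set": train_set,
            "history": histories[0]}


def predict_transfer(model: MultiTaskCNN, X: np.ndarray,
                     calibration: MutationRateCalibration | None = None,
                     T: int = 500, seed: int = 0) -> dict:
    """Point transfer-task predictions over T Monte Carlo dropout passes.

    Dropout is active on the new task branches only (the pre-trained trunks
    run deterministically), following the transfer-model convention.  Heads
    trained in log space are averaged in log space (geometric mean): the
    network's raw output is the log-value, so this is the plain average of
    network outputs and avoids the exp-noise inflation an arithmetic mean
    of back-transformed draws would carry.
    """
    draws = mc_draws(model, X, T=T, seed=seed, branch_only=True)
    transforms = model.spec.head_transforms or ("linear",) * len(draws)
    out = {}
    for (name, d), tr in zip(draws.items(), transforms):
        if tr == "log":
            out[name] = np.exp(np.log(d).mean(axis=0))[:, 0]
        else:
            out[name] = d.mean(axis=0)[:, 0]
    if calibration is not None:
        out["mutation_rate"] = calibration(out["mutation_rate"])
    return out
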