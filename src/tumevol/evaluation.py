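"""Batch evaluation harnesses for the desk-scale validation studies.

These mirror the per-sample pipeline (correct -> adjust -> featurize ->
predict -> call) in vectorised form so that thousands of synthetic tumours
can be scored quickly: held-out selection/neutral classification (AUROC and
conditional subclone-frequency MAE), the purity-error robustness grid
(false-positive rate for selection under mis-estimated purity), and the
transfer-task percentage errors.
"""

from __future__ import annotations

import numpy as np

from .biopsy import SequencingParams, virtual_biopsy
from .features import featurize
from .netmodel import MultiTaskCNN, TrainingSet, mc_draws
from .postprocess import clonal_peak_adjust, purity_correct
from .sim_neutral import NeutralParams, generate_neutral, sample_pareto_shape
from .transfer import TransferSet, predict_transfer

__all__ = ["call_batch", "evaluate_classification",
           "evaluate_purity_robustness", "evaluate_transfer_mpe"]

_SEED_MOD = 2**31 - 1


def call_batch(sel_draws: np.ndarray, nsub_draws: np.ndarray) -> np.ndarray:
    """Vectorised parsimonious calling rule (89% ETI lower bound > 0.5).

    ``sel_draws``: (T, n) P(Selection) draws; ``nsub_draws``: (T, n, 3).
    Returns the called number of subclones per sample (0 forced whenever
    selection is not called).
    """
    sel_lo = np.quantile(sel_draws, 0.055, axis=0)
    lo1 = np.quantile(nsub_draws[:, :, 1], 0.055, axis=0)
    lo2 = np.quantile(nsub_draws[:, :, 2], 0.055, axis=0)
    n = np.zeros(sel_lo.size, dtype=int)
    sel = sel_lo > 0.5
    n[sel & (lo1 > 0.5)] = 1
    n[sel & (lo2 > 0.5) & ~(lo1 > 0.5)] = 2
    fallback = sel & ~(lo1 > 0.5) & ~(lo2 > 0.5)
    n[fallback] = np.where(nsub_draws[:, fallback, 1].mean(axis=0)
                           >= nsub_draws[:, fallback, 2].mean(axis=0), 1, 2)
    return n


def evaluate_classification(models: dict, test: TrainingSet, T: int = 50,
                            seed: int = 0) -> dict:
    """Held-out AUROC for selection vs neutrality and subclone-frequency
    MAE restricted to samples whose subclone count was called correctly."""
    from sklearn.metrics import roc_auc_score
    d = mc_draws(models["ms"], test.X, T=T, seed=seed)
    sel = d["selection"][:, :, 0]
    auroc = float(roc_auc_score(test.y_sel, sel.mean(axis=0)))
    n_called = call_batch(sel, d["nsub"])
    errors = []
    ok1 = (n_called == 1) & (test.y_nsub == 1)
    if ok1.any():
        pred = mc_draws(models["1s"], test.X[ok1], T=T,
                        seed=seed + 1)["freq"].mean(axis=0)[:, 0]
        errors.extend(np.abs(pred - test.f1[ok1]))
    ok2 = (n_called == 2) & (test.y_nsub == 2)
    if ok2.any():
        pred = mc_draws(models["2s"], test.X[ok2], T=T,
                        seed=seed + 2)["freqs"].mean(axis=0)
        errors.extend(np.abs(pred[:, 0] - test.f1[ok2]))
        errors.extend(np.abs(pred[:, 1] - test.f2[ok2]))
    return {"auroc": auroc,
            "freq_mae": float(np.mean(errors)) if errors else float("nan"),
            "n_freq_calls": len(errors),
            "n_called": np.bincount(n_called, minlength=3).tolist(),
            "n_true": np.bincount(test.y_nsub, minlength=3).tolist()}


def evaluate_purity_robustness(model: MultiTaskCNN, n_tumours: int = 2000,
                               seed: int = 0, rho: float = 0.03,
                               purity_range=(0.2, 1.0),
                               depth_range=(20.0, 200.0),
                               purity_error: float = 0.25,
                               min_effective_depth: float = 40.0,
                               T: int = 50) -> dict:
    """False-positive rate for selection on neutral tumours with erroneous
    purity estimates.

    Each tumour is biopsied at its true purity, corrected with a purity
    estimate perturbed by up to ``+-purity_error`` (relative), clonal-peak
    adjusted, featurized and classified.  The FPR is reported over the
    samples whose true mean effective coverage (purity x depth) reaches
    ``min_effective_depth``.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((n_tumours, 192))
    qualifying = np.empty(n_tumours, dtype=bool)
    for i in range(n_tumours):
        purity = float(rng.uniform(*purity_range))
        depth = float(rng.uniform(*depth_range))
        mu = float(np.exp(rng.uniform(np.log(5.0), np.log(100.0))))
        truth = generate_neutral(NeutralParams(
            pareto_shape=sample_pareto_shape(rng), pareto_scale=5e-4,
            n_tail=int(2 * mu * 999), n_clonal=int(rng.integers(200, 2001)),
            trim_f=float(rng.uniform(0.1, 0.3)),
            clonal_center=float(rng.uniform(0.45, 0.5)),
            seed=int(rng.integers(_SEED_MOD))))
        seq = SequencingParams(mean_depth=depth, rho=rho, purity=purity,
                               depth_pool=1000)
        obs = virtual_biopsy(truth, seq, seed=int(rng.integers(_SEED_MOD)),
                             min_true_vaf=0.004 * purity)
        wrong = purity * (1.0 + rng.uniform(-purity_error, purity_error))
        corrected = purity_correct(obs, min(max(wrong, 0.05), 1.0))
        adjusted = clonal_peak_adjust(corrected).sample
        X[i] = featurize(adjusted).values
        qualifying[i] = purity * depth >= min_effective_depth
    d = mc_draws(model, X, T=T, seed=int(rng.integers(_SEED_MOD)))
    lo = np.quantile(d["selection"][:, :, 0], 0.055, axis=0)
    fp = int(((lo > 0.5) & qualifying).sum())
    nq = int(qualifying.sum())
    return {"fpr": fp / nq, "n_qualifying": nq, "n_total": n_tumours,
            "n_false_positive": fp}


def evaluate_transfer_mpe(model: MultiTaskCNN, holdout: TransferSet,
                          calibration=None, T: int = 50,
                          seed: int = 0) -> dict:
    """Signed mean/median percentage error per transfer task on the
    held-out tumours carrying a detectable subclone."""
    pred = predict_transfer(model, holdout.X, calibration=calibration,
                            T=T, seed=seed)
    det = holdout.detectable
    truth = {"mutation_rate": holdout.mutation_rate,
             "fitness": holdout.fitness,
             "emergence_time": holdout.t_s,
             "cellular_fraction": holdout.cellular_fraction}
    out = {"n_detectable": int(det.sum())}
    for name, true in truth.items():
        pe = (pred[name][det] - true[det]) / true[det] * 100.0
        out[name] = {"mean_pe": float(np.mean(pe)),
                     "median_pe": float(np.median(pe)),
                     "mape": float(np.mean(np.abs(pe)))}
    return out
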