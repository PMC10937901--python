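"""Scoring discovered edge sets against simulated truth.

Metrics over unordered off-diagonal pairs: false discovery proportion
FDP = FP / max(R, 1), total power TP / m1, and excess power
(TP - TP_prior) / (m1 - TP_prior) — the power on true edges outside the
prior set, where TP_prior counts the discovered true edges that were in
the prior.  ROC and Precision-Recall sweeps rank edges by |statistic|
with the strictly-greater threshold rule (tied edges enter together).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    PriorSpec,
    SimulationConfig,
    generate_model,
    generate_prior_set,
    sample_expression,
)

__all__ = [
    "EvaluationRecord",
    "score_discoveries",
    "sweep_curves",
    "auc",
    "empirical_fdr_curve",
]


def _norm_pairs(edges) -> frozenset:
    return frozenset((min(a, b), max(a, b)) for a, b in edges)


@dataclass
class EvaluationRecord:
    """Confusion counts and derived metrics for one discovered edge set."""

    tp: int
    fp: int
    fn: int
    tn: int
    tp_prior: int
    m1: int
    fdp: float
    power: float
    excess_power: float | None  # None when m1 == tp_prior (undefined)

    @property
    def discoveries(self) -> int:
        return self.tp + self.fp


def score_discoveries(discovered, truth, prior, p: int) -> EvaluationRecord:
    """Exact set arithmetic over the p(p-1)/2 unordered pairs."""
    discovered = _norm_pairs(discovered)
    truth = _norm_pairs(truth)
    prior = _norm_pairs(prior if prior is not None else ())
    total_pairs = p * (p - 1) // 2
    tp = len(discovered & truth)
    fp = len(discovered - truth)
    fn = len(truth - discovered)
    tn = total_pairs - tp - fp - fn
    tp_prior = len(discovered & truth & prior)
    m1 = len(truth)
    r = tp + fp
    fdp = fp / r if r > 0 else 0.0
    power = tp / m1 if m1 > 0 else float("nan")
    excess = (tp - tp_prior) / (m1 - tp_prior) if m1 > tp_prior else None
    return EvaluationRecord(
        tp=tp, fp=fp, fn=fn, tn=tn, tp_prior=tp_prior, m1=m1,
        fdp=fdp, power=power, excess_power=excess,
    )


def sweep_curves(statistics: np.ndarray, truth) -> pd.DataFrame:
    """ROC / Precision-Recall sweep over all distinct |statistic| values.

    Returns a frame with columns (threshold, tpr, fpr, precision, recall),
    ordered by decreasing threshold; an initial row at threshold = +inf
    (no discoveries, precision 1 by convention) anchors the curves at the
    origin.  Edges with equal |statistic| enter together (the threshold
    rule is strictly-greater).
    """
    stats = np.asarray(statistics, dtype=float)
    p = stats.shape[0]
    iu = np.triu_indices(p, k=1)
    absT = np.abs(stats[iu])
    truth = _norm_pairs(truth)
    is_true = np.array([(a, b) in truth for a, b in zip(*iu)])
    m1 = int(is_true.sum())
    m0 = absT.size - m1

    order = np.argsort(-absT, kind="mergesort")
    absT_sorted = absT[order]
    true_sorted = is_true[order]

    rows = [(math.inf, 0.0, 0.0, 1.0, 0.0)]
    cum_tp = np.cumsum(true_sorted)
    cum_fp = np.cumsum(~true_sorted)
    # group ties: a threshold just below each distinct value admits the
    # whole tied group
    distinct = np.nonzero(
        np.diff(absT_sorted, append=-np.inf) != 0.0
    )[0]
    for idx in distinct:
        tp = int(cum_tp[idx])
        fp = int(cum_fp[idx])
        r = tp + fp
        rows.append(
            (
                float(absT_sorted[idx]),
                tp / m1 if m1 else 0.0,
                fp / m0 if m0 else 0.0,
                tp / r if r else 1.0,
                tp / m1 if m1 else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["threshold", "tpr", "fpr", "precision", "recall"])


def auc(curve: pd.DataFrame, x: str = "fpr", y: str = "tpr") -> float:
    """Trapezoid area under a sweep curve (sorted by the x column)."""
    cx = np.concatenate([[0.0], np.asarray(curve[x], dtype=float), [1.0]])
    cy = np.concatenate([[0.0], np.asarray(curve[y], dtype=float), [1.0]])
    order = np.argsort(cx, kind="mergesort")
    return float(np.trapezoid(cy[order], cx[order]))


def empirical_fdr_curve(
    method_runner,
    config: SimulationConfig,
    prior_spec: PriorSpec | None,
    alphas,
) -> pd.DataFrame:
    """Replicate study: mean FDP / power (with Monte-Carlo SEs) per level.

    ``method_runner(Y, prior, alpha)`` must return a set of unordered
    index pairs.  The precision matrix is generated once from the config
    seed and held fixed; each replicate draws a fresh dataset from it.
    The prior (if any) is built once from the truth.
    """
    if config.n_reps < 2:
        raise ValueError("need at least 2 replicates for Monte-Carlo SEs")
    model_rng = np.random.default_rng([config.seed, 2**20])
    model = generate_model(config, model_rng)
    if prior_spec is not None and prior_spec.pis > 0:
        prior = generate_prior_set(
            model.support, prior_spec, config.p,
            rng=np.random.default_rng([prior_spec.seed, 2**21]),
        )
    else:
        prior = None

    alphas = list(alphas)
    fdps = {a: [] for a in alphas}
    powers = {a: [] for a in alphas}
    for rep in range(config.n_reps):
        rng = np.random.default_rng([config.seed, rep])
        X = sample_expression(
            model, config.n, data_type=config.data_type,
            count_mean=config.count_mean, rng=rng,
            floor_counts=config.floor_counts,
        )
        for a in alphas:
            discovered = method_runner(X.values, prior, a)
            rec = score_discoveries(
                discovered, model.support,
                prior.edges if prior is not None else (), config.p,
            )
            fdps[a].append(rec.fdp)
            powers[a].append(rec.power)

    rows = []
    for a in alphas:
        f = np.asarray(fdps[a])
        w = np.asarray(powers[a])
        rows.append(
            {
                "alpha": a,
                "mean_fdp": f.mean(),
                "fdp_se": f.std(ddof=1) / math.sqrt(len(f)),
                "mean_power": w.mean(),
                "power_se": w.std(ddof=1) / math.sqrt(len(w)),
                "n_reps": len(f),
            }
        )
    return pd.DataFrame(rows)
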