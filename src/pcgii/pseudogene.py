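"""Pseudogene supplementation: self-calibrating priors for datasets
without prior knowledge.

A synthetic "pseudogene" with expression ``Z_i ~ N(0, 1)`` is appended to
the data and folded into the observed genes,

    Ytilde[i, j] = Y[i, j] + a[j] * Z[i],

so the supplemented vector ``(Ytilde_i, Z_i)`` has covariance
``[[Sigma + a a', a], [a', 1]]``.  Its precision matrix has the original
``Omega`` as its upper p x p block, so the partial-correlation network
among the original genes is unchanged, while the pseudogene's partial
correlations are proportional to ``(Omega a)_j`` — known by construction.
The pseudogene's connections therefore serve as a verifiable prior: how
well they are recovered at a given nominal FDR level is an empirical
check of calibration and power on data that otherwise lacks ground truth.

Note that ``(Omega a)_j`` can be nonzero for network *neighbors* of
supplemented genes even where ``a_j = 0``; the support of ``a`` coincides
with the pseudogene's true edge set only when the supplemented genes have
no other connections.  The recovery experiment below treats the support
of ``a`` as truth, so for a clean false-positive count the supplemented
genes should be conditionally independent of the rest (see
:func:`recovery_model`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .evaluate import EvaluationRecord
from .ggm import PrecisionModel
from .inference import infer_network
from .prior import PriorEdgeSet
from .simulate import finalize_precision, sample_expression

__all__ = [
    "AugmentedDataset",
    "supplement_data",
    "recovery_model",
    "pseudogene_recovery_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class AugmentedDataset:
    """Supplemented data with the pseudogene in the last column."""

    data: np.ndarray            # n x (p + 1); column p is the pseudogene Z
    coefficients: np.ndarray    # length-p vector a
    truth_edges: frozenset      # pairs (j, p) for every j with a[j] != 0
    z: np.ndarray               # the raw pseudogene draw

    @property
    def p(self) -> int:
        """Number of original genes (the pseudogene column index)."""
        return self.data.shape[1] - 1

    @property
    def prior(self) -> PriorEdgeSet:
        """The pseudogene's known connections, usable as a prior."""
        return PriorEdgeSet(self.truth_edges, p=self.p + 1)


def supplement_data(
    Y: np.ndarray, a: np.ndarray, rng: np.random.Generator
) -> AugmentedDataset:
    """Append a standard-normal pseudogene and fold it into the genes."""
    Y = np.asarray(Y, dtype=float)
    a = np.asarray(a, dtype=float)
    n, p = Y.shape
    if a.shape != (p,):
        raise ValueError(f"a must have length {p}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("a must be finite")
    if np.all(a == 0):
        logger.warning("all pseudogene coefficients are zero: the prior is empty")
    z = rng.standard_normal(n)
    data = np.empty((n, p + 1))
    data[:, :p] = Y + np.outer(z, a)
    data[:, p] = z
    truth = frozenset((int(j), p) for j in np.nonzero(a)[0])
    return AugmentedDataset(data=data, coefficients=a, truth_edges=truth, z=z)


def recovery_model(
    p: int,
    n_isolated: int,
    rng: np.random.Generator,
    structure_eta: float = 0.10,
) -> tuple[PrecisionModel, np.ndarray]:
    """A base model whose first ``n_isolated`` genes are isolated.

    The remaining genes carry an Erdos-Renyi network (edge probability
    ``structure_eta``, standard magnitudes).  Supplementing the isolated
    genes keeps the pseudogene's true edge set identical to the support of
    ``a`` (no leakage to network neighbors).  Returns the model and the
    indices of the isolated genes.
    """
    if n_isolated > p:
        raise ValueError("n_isolated cannot exceed p")
    rest = range(n_isolated, p)
    iu = [(a, b) for a in rest for b in rest if a < b]
    draw = rng.random(len(iu)) < structure_eta
    support = {e for e, keep in zip(iu, draw) if keep}
    model = finalize_precision(support, p, rng)
    return model, np.arange(n_isolated)


def pseudogene_recovery_experiment(
    model: PrecisionModel,
    n: int,
    n_nonzero: int,
    a_magnitude: float,
    alpha: float,
    rng: np.random.Generator,
    support: np.ndarray | None = None,
    lam=None,
) -> EvaluationRecord:
    """One replicate of the pseudogene calibration check.

    Simulates data from the model, supplements it with a pseudogene whose
    coefficients are ``+-a_magnitude`` on ``n_nonzero`` genes (randomly
    selected unless ``support`` gives the indices), runs inference with
    the pseudogene's connections as the prior, and scores only the edges
    incident to the pseudogene against the support of ``a``.
    """
    p = model.p
    if n_nonzero > p:
        raise ValueError("n_nonzero cannot exceed p")
    if support is None:
        support = rng.choice(p, size=n_nonzero, replace=False)
    else:
        support = np.asarray(support, dtype=int)
        if support.size != n_nonzero:
            raise ValueError("support size must equal n_nonzero")
    a = np.zeros(p)
    signs = np.where(rng.random(n_nonzero) < 0.5, 1.0, -1.0)
    a[support] = signs * a_magnitude

    X = sample_expression(model, n, rng=rng)
    aug = supplement_data(X.values, a, rng)
    result = infer_network(aug.data, prior=aug.prior, alpha=alpha, lam=lam)

    pseudo = p  # pseudogene column index
    discovered_pseudo = {e for e in result.discoveries if pseudo in e}
    truth = set(aug.truth_edges)
    tp = len(discovered_pseudo & truth)
    fp = len(discovered_pseudo - truth)
    fn = len(truth - discovered_pseudo)
    tn = p - tp - fp - fn  # universe: the p candidate pseudogene edges
    m1 = len(truth)
    r = tp + fp
    return EvaluationRecord(
        tp=tp, fp=fp, fn=fn, tn=tn, tp_prior=tp, m1=m1,
        fdp=fp / r if r else 0.0,
        power=tp / m1 if m1 else math.nan,
        excess_power=None,
    )
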