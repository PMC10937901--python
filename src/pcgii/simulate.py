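"""Simulation engine: network structures, expression sampling, priors.

Three network structures are generated:

* ``block`` — a block-diagonal covariance with compound-symmetric k x k
  blocks (diagonal value ~ U(1, 1.25), off-diagonal ~ U(0.3, 0.5)); the
  true edges are all within-block pairs.
* ``random`` — Erdos-Renyi support with edge probability ``eta``.
* ``scalefree`` — Barabasi-Albert preferential attachment adding ``e``
  edges per new node (seed graph: star on e+1 nodes, so a run with
  parameters (p, e) has exactly e*(p - e) edges; e = 1 gives a tree).

For the random and scale-free structures the nonzero precision entries
are drawn uniformly from (-0.5, -0.2) u (0.2, 0.5) (fair sign coin) and
the diagonal is set to the absolute row sum plus 0.1, which guarantees
positive definiteness by strict diagonal dominance.

Expression data are i.i.d. multivariate normal rows; count data are
normal rows with a nonzero mean, rounded to the nearest integer (floored
at zero by default).

Priors with controlled size (PIS: fraction of true edges included) and
accuracy (PA: fraction of prior edges that are true) are sampled from the
true support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np
import yaml

from .ggm import PrecisionModel, partial_correlation_from_precision, validate_spd
from .io import ExpressionMatrix
from .prior import PriorEdgeSet

__all__ = [
    "SimulationConfig",
    "PriorSpec",
    "generate_block_sigma",
    "generate_random_precision",
    "generate_scalefree_precision",
    "finalize_precision",
    "generate_model",
    "sample_expression",
    "generate_prior_set",
    "replicate_rngs",
]

STRUCTURES = ("block", "random", "scalefree")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SimulationConfig:
    """One simulation setting (structure, size, data type, replication)."""

    structure: str = "scalefree"
    p: int = 100
    n: int = 80
    k: int = 4          # block size (block structure)
    eta: float = 0.02   # edge probability (random structure)
    e: int = 1          # edges per step (scale-free structure)
    data_type: str = "normal"
    count_mean: float = 10.0
    floor_counts: bool = True
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if self.data_type not in ("normal", "count"):
            raise ValueError("data_type must be 'normal' or 'count'")
        if self.structure == "block" and self.p % self.k != 0:
            raise ValueError(f"block size k={self.k} must divide p={self.p}")
        if self.structure == "random" and not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must be in [0, 1)")
        if self.structure == "scalefree" and self.e < 1:
            raise ValueError("e must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class PriorSpec:
    """Prior construction knobs: PIS (size) and PA (accuracy)."""

    pis: float = 0.3
    pa: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pis <= 1.0:
            raise ValueError("pis must be in [0, 1]")
        if not 0.0 < self.pa <= 1.0:
            raise ValueError("pa must be in (0, 1]")


def generate_block_sigma(p: int, k: int, rng: np.random.Generator) -> PrecisionModel:
    """Block-diagonal compound-symmetric covariance; edges = within-block pairs."""
    if p % k != 0:
        raise ValueError(f"block size k={k} must divide p={p}")
    H = p // k
    sigma = np.zeros((p, p))
    omega = np.zeros((p, p))
    support = set()
    for h in range(H):
        b1 = rng.uniform(1.0, 1.25)
        b2 = rng.uniform(0.3, 0.5)
        block = np.full((k, k), b2)
        np.fill_diagonal(block, b1)
        sl = slice(h * k, (h + 1) * k)
        sigma[sl, sl] = block
        omega[sl, sl] = np.linalg.inv(block)
        for a in range(h * k, (h + 1) * k):
            for b in range(a + 1, (h + 1) * k):
                support.add((a, b))
    omega = (omega + omega.T) / 2.0
    validate_spd(omega)
    return PrecisionModel(
        omega=omega,
        sigma=sigma,
        support=frozenset(support),
        rho=partial_correlation_from_precision(omega),
    )


def _er_support(p: int, eta: float, rng: np.random.Generator) -> set:
    iu = np.triu_indices(p, k=1)
    draw = rng.random(iu[0].size) < eta
    return set(zip(iu[0][draw].tolist(), iu[1][draw].tolist()))


def generate_random_precision(
    p: int, eta: float, rng: np.random.Generator
) -> PrecisionModel:
    """Erdos-Renyi support: each unordered pair is an edge with probability eta."""
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta must be in [0, 1)")
    return finalize_precision(_er_support(p, eta, rng), p, rng)


def generate_scalefree_precision(
    p: int, e: int, rng: np.random.Generator
) -> PrecisionModel:
    """Barabasi-Albert support: e preferential-attachment edges per new node."""
    if e < 1:
        raise ValueError("e must be >= 1")
    graph = nx.barabasi_albert_graph(p, e, seed=int(rng.integers(2**31)))
    support = {(min(a, b), max(a, b)) for a, b in graph.edges()}
    return finalize_precision(support, p, rng)


def finalize_precision(
    support, p: int, rng: np.random.Generator
) -> PrecisionModel:
    """Fill a support set with magnitudes and make the precision SPD.

    Off-diagonal entries ~ U(0.2, 0.5) with a fair sign coin; diagonal =
    absolute row sums + 0.1 (strict diagonal dominance with margin 0.1).
    """
    omega = np.zeros((p, p))
    for a, b in sorted(support):
        if a == b:
            raise ValueError(f"self-pair ({a}, {b}) in support")
        mag = rng.uniform(0.2, 0.5)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        omega[a, b] = omega[b, a] = sign * mag
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + 0.1)
    validate_spd(omega)
    sigma = np.linalg.inv(omega)
    sigma = (sigma + sigma.T) / 2.0
    return PrecisionModel(
        omega=omega,
        sigma=sigma,
        support=frozenset((min(a, b), max(a, b)) for a, b in support),
        rho=partial_correlation_from_precision(omega),
    )


def generate_model(config: SimulationConfig, rng: np.random.Generator) -> PrecisionModel:
    """Dispatch on ``config.structure``; the model is fixed once per setting."""
    if config.structure == "block":
        model = generate_block_sigma(config.p, config.k, rng)
    elif config.structure == "random":
        model = generate_random_precision(config.p, config.eta, rng)
    else:
        model = generate_scalefree_precision(config.p, config.e, rng)
    if config.data_type == "count":
        model.mu = np.full(config.p, float(config.count_mean))
    return model


def sample_expression(
    model: PrecisionModel,
    n: int,
    data_type: str = "normal",
    count_mean: float = 10.0,
    rng: np.random.Generator | None = None,
    floor_counts: bool = True,
) -> ExpressionMatrix:
    """Draw n i.i.d. expression profiles from the model.

    ``normal``: rows ~ N(0, Sigma).  ``count``: rows ~ N(count_mean, Sigma)
    rounded to the nearest integer and (by default) floored at zero.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    p = model.p
    L = np.linalg.cholesky(model.sigma)
    X = rng.standard_normal((n, p)) @ L.T
    if data_type == "count":
        mu = model.mu if model.mu is not None else np.full(p, float(count_mean))
        X = np.rint(X + mu)
        if floor_counts:
            X = np.maximum(X, 0.0)
    elif data_type != "normal":
        raise ValueError("data_type must be 'normal' or 'count'")
    width = len(str(p))
    return ExpressionMatrix(
        values=X,
        gene_names=[f"g{j + 1:0{width}d}" for j in range(p)],
        sample_ids=[f"s{i + 1}" for i in range(n)],
    )


def generate_prior_set(
    truth, spec: PriorSpec, p: int, rng: np.random.Generator | None = None
) -> PriorEdgeSet:
    """Sample a prior of controlled size (PIS) and accuracy (PA).

    ``round(pis * m1)`` true edges are drawn without replacement; when
    ``pa < 1``, false edges are added from the non-edges so that
    true/total = pa.  Rounding is to the nearest integer, ties up.
    """
    truth = sorted((min(a, b), max(a, b)) for a, b in truth)
    m1 = len(truth)
    if spec.pis > 0 and m1 == 0:
        raise ValueError("cannot build a prior from an empty truth set")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_true = _round_half_up(spec.pis * m1)
    chosen = [truth[i] for i in rng.choice(m1, size=n_true, replace=False)] if n_true else []
    n_false = _round_half_up(n_true * (1.0 - spec.pa) / spec.pa)
    if n_false > 0:
        truth_set = set(truth)
        non_edges = [
            (a, b)
            for a in range(p)
            for b in range(a + 1, p)
            if (a, b) not in truth_set
        ]
        if n_false > len(non_edges):
            raise ValueError(
                f"requested {n_false} false prior edges but only "
                f"{len(non_edges)} non-edges exist"
            )
        chosen += [non_edges[i] for i in rng.choice(len(non_edges), size=n_false, replace=False)]
    return PriorEdgeSet(chosen, p=p)


def replicate_rngs(seed: int, n_reps: int) -> Iterator[np.random.Generator]:
    """Independent, individually reproducible per-replicate streams."""
    for rep in range(n_reps):
        yield np.random.default_rng([seed, rep])
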