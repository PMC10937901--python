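"""Readers and writers for expression matrices, prior edge lists and
result tables, plus group-centering preprocessing.

All tabular formats are delimited text.  Expression files have a header
row and a leading identifier column; the orientation flag selects
genes-as-columns (default) or genes-as-rows.  Prior edge lists are
two-column files of gene-name pairs (undirected).  Result tables carry a
commented metadata header and one row per unordered gene pair, with
values written at 17 significant digits for round-trip fidelity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prior import PriorEdgeSet

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_prior_edges",
    "read_group_labels",
    "center_by_group",
    "write_network",
    "read_network",
]

logger = logging.getLogger(__name__)


def _sniff_sep(path, sep: str | None) -> str:
    """Sniff the delimiter from the first line unless one was given."""
    if sep is not None:
        return sep
    with open(path) as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t; ").delimiter
    except csv.Error:
        return ","


@dataclass
class ExpressionMatrix:
    """An n x p expression matrix with gene names and sample ids."""

    values: np.ndarray
    gene_names: list[str]
    sample_ids: list[str]
    group_labels: list[str] | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.gene_names) != p:
            raise ValueError(f"{len(self.gene_names)} gene names for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.gene_names)) != p:
            dupes = sorted(
                {g for g in self.gene_names if self.gene_names.count(g) > 1}
            )
            raise ValueError(f"duplicate gene names: {dupes}")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise ValueError("group_labels length must match sample count")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at sample '{self.sample_ids[i]}', "
                f"gene '{self.gene_names[j]}'"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path, sep: str = ",") -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_names)
        df.index.name = "sample"
        df.to_csv(path, sep=sep, float_format="%.17g")


def read_expression(
    path, genes_as: str = "columns", sep: str | None = None
) -> ExpressionMatrix:
    """Read a delimited expression file (header + leading id column).

    ``genes_as`` is "columns" (samples are rows) or "rows" (the file is
    transposed on load).  The delimiter is sniffed unless ``sep`` is given.
    Missing values, non-numeric cells, duplicate gene names and ragged
    rows each raise a distinct error.
    """
    if genes_as not in ("columns", "rows"):
        raise ValueError("genes_as must be 'columns' or 'rows'")
    sep = _sniff_sep(path, sep)
    try:
        # C engine with round_trip parsing: full floating-point fidelity
        df = pd.read_csv(
            path, sep=sep, index_col=0, float_precision="round_trip"
        )
        header = pd.read_csv(path, sep=sep, header=None, nrows=1)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed delimited file {path}: {exc}") from exc
    if genes_as == "columns":
        # pandas mangles duplicate header names; check the raw header
        raw = [str(x) for x in header.iloc[0, 1:]]
        if len(set(raw)) != len(raw):
            dupes = sorted({g for g in raw if raw.count(g) > 1})
            raise ValueError(f"duplicate gene names: {dupes}")
    else:
        df = df.T
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"missing value at row '{row}', column '{col}'")
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in column '{col}': {exc}") from exc
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_names=[str(g) for g in df.columns],
        sample_ids=[str(s) for s in df.index],
    )


def read_prior_edges(path, gene_names: list[str], sep: str | None = None) -> PriorEdgeSet:
    """Read a two-column gene-name pair file into a :class:`PriorEdgeSet`.

    Duplicates and reversed duplicates collapse; unknown gene names raise
    with the offenders listed; an empty file yields an empty prior.
    """
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path, sep), header=None, comment="#")
    except pd.errors.EmptyDataError:
        return PriorEdgeSet.empty()
    if df.shape[1] < 2:
        raise ValueError(f"prior edge file {path} must have two columns")
    pairs = [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    return PriorEdgeSet.from_names(pairs, gene_names)


def read_group_labels(path, sample_ids: list[str], sep: str | None = None) -> list[str]:
    """Read sample -> group labels from a two-column file."""
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), header=None, comment="#")
    mapping = {str(a): str(b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"no group label for samples: {missing}")
    return [mapping[s] for s in sample_ids]


def center_by_group(X: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's within-group mean (controls treatment effects).

    With a single group this is global centering.  The operation is
    idempotent.  Groups with one sample get a warning (their values
    become exactly zero).
    """
    if X.group_labels is None:
        raise ValueError("group_labels are required for group centering")
    values = X.values.copy()
    labels = np.asarray(X.group_labels)
    for g in np.unique(labels):
        idx = labels == g
        if idx.sum() == 1:
            logger.warning("group '%s' has a single sample; its values become 0", g)
        values[idx] -= values[idx].mean(axis=0)
    return ExpressionMatrix(
        values=values,
        gene_names=list(X.gene_names),
        sample_ids=list(X.sample_ids),
        group_labels=list(X.group_labels),
    )


def write_network(
    result,
    estimate,
    gene_names: list[str],
    path,
    prior: PriorEdgeSet | None = None,
    full_matrix: bool = False,
    seed=None,
    extra_metadata: dict | None = None,
) -> None:
    """Write an inference result as a tab-delimited edge table.

    One row per unordered gene pair in the discovery set (or all pairs
    with ``full_matrix``), ordered lexicographically by gene names, with
    a commented metadata header recording n, p, lambda, alpha, tau and the
    fallback flag.
    """
    from . import __version__

    p = len(gene_names)
    prior = prior if prior is not None else PriorEdgeSet.empty()
    rho = estimate.rho_hat
    T = result.statistics
    discovered = result.discoveries

    if full_matrix:
        pairs = [(a, b) for a in range(p) for b in range(a + 1, p)]
    else:
        pairs = sorted(discovered)

    lam = getattr(estimate, "lambda_used", None)
    rows = []
    for a, b in pairs:
        g1, g2 = gene_names[a], gene_names[b]
        if g2 < g1:
            g1, g2 = g2, g1
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "rho_hat": rho[a, b],
                "statistic": T[a, b],
                "in_prior": (a, b) in prior,
                "discovered": (a, b) in discovered,
                "abs_rho_gt_1": bool(abs(rho[a, b]) > 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene1", "gene2", "rho_hat", "statistic",
            "in_prior", "discovered", "abs_rho_gt_1",
        ],
    ).sort_values(["gene1", "gene2"], kind="mergesort")

    meta = {
        "n": result.n,
        "p": p,
        "alpha": result.alpha,
        "tau_hat": repr(result.tau_hat),
        "fallback_used": result.fallback_used,
        "n_discoveries": len(discovered),
        "version": __version__,
    }
    if lam is not None:
        meta["lambda"] = repr(float(np.asarray(lam).ravel()[0]))
    if seed is not None:
        meta["seed"] = seed
    if extra_metadata:
        meta.update(extra_metadata)

    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_network(path) -> pd.DataFrame:
    """Read back a network table written by :func:`write_network`."""
    return pd.read_csv(path, sep="\t", comment="#")
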