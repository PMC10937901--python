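"""Prior edge sets: known gene-gene connections that exempt coefficients
from the lasso penalty in the node-wise regressions."""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

__all__ = ["PriorEdgeSet"]


def _normalize_pair(a: int, b: int) -> tuple[int, int]:
    a, b = int(a), int(b)
    if a == b:
        raise ValueError(f"self-pair ({a}, {b}) is not a valid edge")
    return (a, b) if a < b else (b, a)


class PriorEdgeSet:
    """An undirected set of known connections over genes indexed ``0..p-1``.

    Edges are stored as unordered index pairs ``(j1, j2)`` with ``j1 < j2``;
    duplicates and reversed duplicates collapse.  The per-node view
    ``neighbors(j)`` gives the set of genes whose coefficients are exempt
    from the penalty in the node-wise regression of gene ``j``.
    """

    def __init__(self, edges: Iterable[tuple[int, int]] = (), p: int | None = None):
        pairs = {_normalize_pair(a, b) for a, b in edges}
        if p is not None:
            bad = [e for e in pairs if e[0] < 0 or e[1] >= p]
            if bad:
                raise ValueError(f"edge indices out of range [0, {p}): {sorted(bad)[:5]}")
        self._edges = frozenset(pairs)
        self._p = p

    @classmethod
    def empty(cls) -> "PriorEdgeSet":
        return cls(())

    @classmethod
    def from_names(
        cls, name_pairs: Iterable[tuple[str, str]], gene_names: list[str]
    ) -> "PriorEdgeSet":
        """Map name pairs onto indices; unknown names raise with offenders listed."""
        index = {g: i for i, g in enumerate(gene_names)}
        unknown = sorted(
            {n for pair in name_pairs for n in pair if n not in index}
        )
        if unknown:
            raise ValueError(f"unknown gene names in prior edges: {unknown}")
        return cls(
            ((index[a], index[b]) for a, b in name_pairs), p=len(gene_names)
        )

    @property
    def edges(self) -> frozenset:
        return self._edges

    def neighbors(self, j: int) -> set[int]:
        """Prior-connected partners of gene ``j`` (the exempt set I_j)."""
        return {b if a == j else a for a, b in self._edges if j in (a, b)}

    def mask(self, p: int) -> np.ndarray:
        """Boolean (p, p) symmetric matrix, True where the coefficient is exempt."""
        m = np.zeros((p, p), dtype=bool)
        for a, b in self._edges:
            if b >= p:
                raise ValueError(f"edge ({a}, {b}) out of range for p={p}")
            m[a, b] = m[b, a] = True
        return m

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(sorted(self._edges))

    def __contains__(self, pair) -> bool:
        try:
            return _normalize_pair(*pair) in self._edges
        except ValueError:
            return False

    def __eq__(self, other) -> bool:
        if isinstance(other, PriorEdgeSet):
            return self._edges == other._edges
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._edges)

    def __repr__(self) -> str:
        return f"PriorEdgeSet({len(self._edges)} edges)"
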