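"""Semantic distance matrices, mapping scores, and threshold modes.

Semantic closeness between two type names is scored by a pair of square
symmetric matrices (one for vertex types, one for edge types) with entries in
[-1, 1]: 1 for semantically identical types, 0 for unrelated types, -1 for
opposite types; graded intermediate values let users encode hierarchy-derived
similarity.  A type pair absent from a matrix scores 0 ("unrelated"), so a
target graph with extra types needs no matrix edits.

The semantic score SS of a complete mapping is the arithmetic mean of the
pairwise scores over all |V(Q)| vertex elements and |E(Q)| edge elements.
A user-chosen semantic threshold ST in [0, 1] is applied either per element
(every element must score >= ST) or cumulatively (the mean must be >= ST).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SDCMatrices",
    "SearchConfig",
    "load_sdc",
    "identity_sdc",
    "score_pair",
    "score_mapping",
    "passes_threshold",
]

#: absolute slack used when comparing a score against the threshold, so that
#: exact boundary cases (e.g. mean 4/5 against ST 0.8) are not lost to
#: floating-point rounding.
_EPS = 1e-9


def _validate_matrix(m: pd.DataFrame, label: str) -> pd.DataFrame:
    if list(m.index) != list(m.columns):
        raise ValueError(f"{label} matrix rows and columns must carry identical type names")
    vals = m.to_numpy(dtype=float)
    if ((vals < -1 - _EPS) | (vals > 1 + _EPS)).any():
        raise ValueError(f"{label} matrix entries must lie in [-1, 1]")
    n = len(m)
    for i in range(n):
        if abs(vals[i, i] - 1.0) > _EPS:
            raise ValueError(f"{label} matrix diagonal must equal 1")
        for j in range(i + 1, n):
            if abs(vals[i, j] - vals[j, i]) > _EPS:
                raise ValueError(f"{label} matrix must be symmetric")
    return m.astype(float)


@dataclass
class SDCMatrices:
    """The semantic distance calculator: vertex-type and edge-type matrices."""

    vertex_matrix: pd.DataFrame
    edge_matrix: pd.DataFrame

    def __post_init__(self):
        self.vertex_matrix = _validate_matrix(self.vertex_matrix, "vertex")
        self.edge_matrix = _validate_matrix(self.edge_matrix, "edge")
        # dict lookup is ~10x faster than DataFrame.at in the inner search loop
        self._v = {(a, b): float(x)
                   for a, row in self.vertex_matrix.iterrows()
                   for b, x in row.items()}
        self._e = {(a, b): float(x)
                   for a, row in self.edge_matrix.iterrows()
                   for b, x in row.items()}

    def score_vertex(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._v.get((a, b), 0.0)

    def score_edge(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._e.get((a, b), 0.0)


@dataclass
class SearchConfig:
    """User-facing knobs of a mining run.

    st            semantic threshold in [0, 1]
    mode          'per_element' (every element >= st) or 'cumulative' (mean >= st)
    anchor_type   vertex type the initial candidate set is drawn from
    prune_enabled remove semantically distant vertices from G before searching
    split_enabled decompose queries with more than 3 vertices before searching
    strict_degree optional literal closed-world variant requiring mapped target
                  vertices to have exactly the query vertex's total degree
    dedup_orbits  collapse automorphic re-embeddings onto the same vertex set
    """

    st: float = 0.8
    mode: str = "per_element"
    anchor_type: str = "Compound"
    prune_enabled: bool | None = None
    split_enabled: bool = True
    seed: int = 0
    max_mappings: int | None = None
    strict_degree: bool = False
    dedup_orbits: bool = False

    def __post_init__(self):
        if not 0.0 <= self.st <= 1.0:
            raise ValueError(f"st must lie in [0, 1], got {self.st}")
        if self.mode not in ("per_element", "cumulative"):
            raise ValueError(f"mode must be per_element or cumulative, got {self.mode!r}")
        if self.prune_enabled is None:
            # pruning is safe in per-element mode; in cumulative mode it can
            # discard below-threshold elements a high-scoring mapping would
            # have absorbed, so it defaults off there
            self.prune_enabled = self.mode == "per_element"


def load_sdc(vertex_path: str | Path, edge_path: str | Path) -> SDCMatrices:
    """Read the two matrices from TSV (first row/column are type names)."""
    vm = pd.read_csv(vertex_path, sep="\t", index_col=0)
    em = pd.read_csv(edge_path, sep="\t", index_col=0)
    vm.index = vm.index.astype(str)
    vm.columns = vm.columns.astype(str)
    em.index = em.index.astype(str)
    em.columns = em.columns.astype(str)
    return SDCMatrices(vm, em)


def save_sdc(matrices: SDCMatrices, vertex_path: str | Path, edge_path: str | Path) -> None:
    matrices.vertex_matrix.to_csv(vertex_path, sep="\t")
    matrices.edge_matrix.to_csv(edge_path, sep="\t")


def identity_sdc(vertex_types: Iterable[str], edge_types: Iterable[str]) -> SDCMatrices:
    """Matrices scoring 1 for identical types and 0 otherwise."""
    vtypes = sorted(set(vertex_types))
    etypes = sorted(set(edge_types))
    if not vtypes or not etypes:
        raise ValueError("type vocabularies must be non-empty")
    import numpy as np
    vm = pd.DataFrame(np.eye(len(vtypes)), index=vtypes, columns=vtypes)
    em = pd.DataFrame(np.eye(len(etypes)), index=etypes, columns=etypes)
    return SDCMatrices(vm, em)


def score_pair(matrices: SDCMatrices, kind: str, a: str, b: str) -> float:
    """Semantic score of a type pair; identical types score 1, missing pairs 0."""
    if kind == "vertex":
        return matrices.score_vertex(a, b)
    if kind == "edge":
        return matrices.score_edge(a, b)
    raise ValueError(f"kind must be vertex or edge, got {kind!r}")


def element_scores(mapping, Q, G, matrices: SDCMatrices) -> list[float]:
    """Per-element semantic scores of a complete mapping, vertices then edges."""
    scores = []
    for role, vid in mapping.vertex_assignment.items():
        scores.append(matrices.score_vertex(Q.role_type(role), G.vertex_type(vid)))
    for qe_id, ge_id in mapping.edge_assignment.items():
        scores.append(matrices.score_edge(Q.edge_type(qe_id), G.edge(ge_id).type))
    return scores


def score_mapping(M, Q, G, matrices: SDCMatrices) -> float:
    """Mean semantic score SS over the |V(Q)| + |E(Q)| elements of a mapping."""
    if len(M.vertex_assignment) != Q.num_vertices() or len(M.edge_assignment) != Q.num_edges():
        raise ValueError("score_mapping requires a complete mapping of Q")
    scores = element_scores(M, Q, G, matrices)
    return sum(scores) / len(scores)


def passes_threshold(scores: Sequence[float], st: float, mode: str) -> bool:
    """Apply the semantic threshold to a mapping's element scores."""
    if mode == "per_element":
        return all(s >= st - _EPS for s in scores)
    if mode == "cumulative":
        return sum(scores) / len(scores) >= st - _EPS
    raise ValueError(f"mode must be per_element or cumulative, got {mode!r}")
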