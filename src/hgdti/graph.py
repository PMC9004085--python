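"""Heterogeneous drug-target graph: data model and DTINet-dialect matrix I/O.

The graph has four node types (drug, protein, disease, side_effect) and eight
undirected relations: two interaction networks (drug-drug, protein-protein),
two similarity networks (chemical-structure, sequence), the drug-protein
interaction network that carries the prediction labels, and three association
networks (drug-disease, protein-disease, drug-side_effect).

Interaction and association edges have weight exactly 1; similarity edges have
weights in (0, 1].  Zero entries mean "unrelated" and are represented by the
absence of an edge.  Similarity self-entries (the matrix diagonal) are kept as
metadata for exact round-trip serialization but are never materialized as
self-edges: neighbor aggregation in the model runs over u != v.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NODE_TYPES",
    "RELATIONS",
    "DEFAULT_LAYOUT",
    "HeteroGraph",
    "DTIPair",
    "GraphValidationError",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "load_heterograph",
    "save_heterograph",
    "ablate",
]

NODE_TYPES = ("drug", "protein", "disease", "side_effect")

#: relation name -> (source node type, target node type, kind)
RELATIONS = {
    "drug-interaction-drug": ("drug", "drug", "interaction"),
    "drug-similarity-drug": ("drug", "drug", "similarity"),
    "protein-interaction-protein": ("protein", "protein", "interaction"),
    "protein-similarity-protein": ("protein", "protein", "similarity"),
    "drug-interaction-protein": ("drug", "protein", "interaction"),
    "drug-association-disease": ("drug", "disease", "association"),
    "protein-association-disease": ("protein", "disease", "association"),
    "drug-association-side_effect": ("drug", "side_effect", "association"),
}

#: DTINet file naming (the dataset family's dialect); overridable via config.
DEFAULT_LAYOUT = {
    "drug-interaction-protein": "mat_drug_protein.txt",
    "drug-interaction-drug": "mat_drug_drug.txt",
    "protein-interaction-protein": "mat_protein_protein.txt",
    "drug-similarity-drug": "Similarity_Matrix_Drugs.txt",
    "protein-similarity-protein": "Similarity_Matrix_Proteins.txt",
    "drug-association-disease": "mat_drug_disease.txt",
    "protein-association-disease": "mat_protein_disease.txt",
    "drug-association-side_effect": "mat_drug_se.txt",
}


class MatrixFormatError(ValueError):
    """Raised for ragged rows, non-numeric tokens or shape mismatches."""


class GraphValidationError(ValueError):
    """Raised when a matrix violates a graph invariant (asymmetry, range...)."""


@dataclass(frozen=True)
class DTIPair:
    """A drug-protein pair with its interaction label (1 = known DTI)."""

    drug: int
    protein: int
    label: int


@dataclass
class HeteroGraph:
    """Typed node sets plus eight typed weighted edge lists.

    ``nodes`` maps node type -> ordered list of integer ids (0-based row
    indices of the source matrices).  ``edges`` maps relation name -> list of
    ``(a, b, weight)`` with unordered pairs canonicalized (``a < b`` for
    same-type relations).  ``sim_diagonals`` keeps similarity self-entries so
    that serialization is an exact inverse of loading.
    """

    nodes: dict[str, list[int]] = field(default_factory=dict)
    edges: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    sim_diagonals: dict[str, np.ndarray] = field(default_factory=dict)

    def n_nodes(self, node_type: str) -> int:
        return len(self.nodes.get(node_type, []))

    @property
    def n_drugs(self) -> int:
        return self.n_nodes("drug")

    @property
    def n_proteins(self) -> int:
        return self.n_nodes("protein")

    def relation_matrix(self, relation: str) -> np.ndarray:
        """Dense weight matrix of one relation (rows = source type ids).

        Same-type relations come back symmetric with a zero diagonal; the
        similarity diagonal lives in :attr:`sim_diagonals`, not here.
        """
        src, dst, _ = RELATIONS[relation]
        mat = np.zeros((self.n_nodes(src), self.n_nodes(dst)))
        for a, b, w in self.edges.get(relation, []):
            mat[a, b] = w
            if src == dst:
                mat[b, a] = w
        return mat

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Known DTIs as (drug, protein) index pairs, sorted."""
        return sorted((a, b) for a, b, _ in self.edges["drug-interaction-protein"])

    def n_edges(self, relation: str | None = None) -> int:
        if relation is not None:
            return len(self.edges.get(relation, []))
        return sum(len(v) for v in self.edges.values())

    def validate(self) -> None:
        """Check all type invariants; raise GraphValidationError on failure."""
        for rel, edge_list in self.edges.items():
            if rel not in RELATIONS:
                raise GraphValidationError(f"unknown relation {rel!r}")
            src, dst, kind = RELATIONS[rel]
            n_src, n_dst = self.n_nodes(src), self.n_nodes(dst)
            seen = set()
            for a, b, w in edge_list:
                if not (0 <= a < n_src and 0 <= b < n_dst):
                    raise GraphValidationError(
                        f"{rel}: endpoint ({a}, {b}) outside node range"
                    )
                if src == dst and a >= b:
                    raise GraphValidationError(
                        f"{rel}: same-type pair ({a}, {b}) not canonical (a < b)"
                    )
                if (a, b) in seen:
                    raise GraphValidationError(f"{rel}: duplicate edge ({a}, {b})")
                seen.add((a, b))
                if kind == "similarity":
                    if not (0.0 < w <= 1.0):
                        raise GraphValidationError(
                            f"{rel}: similarity weight {w} outside (0, 1]"
                        )
                elif w != 1.0:
                    raise GraphValidationError(
                        f"{rel}: {kind} weight {w} != 1"
                    )


def read_matrix(path: str | os.PathLike, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a whitespace-separated dense numeric matrix.

    Raises
    ------
    MatrixFormatError
        On ragged rows, non-numeric tokens, or a shape mismatch against
        ``expected_shape``.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}: non-numeric token on line {lineno}: {exc}"
                ) from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise MatrixFormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(rows[-1])} columns, expected {len(rows[0])})"
                )
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    mat = np.asarray(rows, dtype=float)
    if expected_shape is not None and mat.shape != tuple(expected_shape):
        raise MatrixFormatError(
            f"{path}: shape {mat.shape} != expected {tuple(expected_shape)}"
        )
    return mat


def write_matrix(path: str | os.PathLike, mat: np.ndarray, fmt: str = "%.12g") -> None:
    """Write a dense matrix in the whitespace-separated dialect."""
    np.savetxt(path, np.atleast_2d(mat), fmt=fmt, delimiter=" ")


def _validate_binary(mat: np.ndarray, name: str) -> None:
    if not np.isin(mat, (0.0, 1.0)).all():
        bad = mat[~np.isin(mat, (0.0, 1.0))].flat[0]
        raise GraphValidationError(f"{name}: non-binary entry {bad} in 0/1 matrix")


def _validate_similarity(mat: np.ndarray, name: str, atol: float = 1e-6) -> None:
    if mat.shape[0] != mat.shape[1]:
        raise GraphValidationError(f"{name}: similarity matrix not square {mat.shape}")
    if not np.allclose(mat, mat.T, atol=atol):
        raise GraphValidationError(f"{name}: similarity matrix not symmetric")
    if mat.min() < 0 or mat.max() > 1:
        raise GraphValidationError(
            f"{name}: similarity entries outside [0, 1] "
            f"(min {mat.min()}, max {mat.max()})"
        )


def _edges_from_matrix(mat: np.ndarray, same_type: bool) -> list[tuple[int, int, float]]:
    if same_type:
        # upper triangle, excluding the diagonal: one canonical edge per pair
        ii, jj = np.nonzero(np.triu(mat, k=1))
    else:
        ii, jj = np.nonzero(mat)
    return [(int(i), int(j), float(mat[i, j])) for i, j in zip(ii, jj)]


def load_heterograph(directory: str | os.PathLike, layout: dict[str, str] | None = None) -> HeteroGraph:
    """Load the eight DTINet-dialect matrices from ``directory``.

    Node counts are taken from the matrix dimensions and cross-checked across
    files; similarity matrices must be symmetric (1e-6) with entries in [0, 1]
    and interaction/association matrices strictly 0/1.
    """
    layout = dict(DEFAULT_LAYOUT, **(layout or {}))
    mats: dict[str, np.ndarray] = {}
    for rel in RELATIONS:
        mats[rel] = read_matrix(os.path.join(directory, layout[rel]))

    counts: dict[str, int] = {}

    def _claim(node_type: str, n: int, source: str) -> None:
        if node_type in counts and counts[node_type] != n:
            raise GraphValidationError(
                f"{source}: {node_type} count {n} contradicts earlier {counts[node_type]}"
            )
        counts.setdefault(node_type, n)

    for rel, mat in mats.items():
        src, dst, kind = RELATIONS[rel]
        name = layout[rel]
        if kind == "similarity":
            _validate_similarity(mat, name)
        else:
            _validate_binary(mat, name)
            if src == dst and not np.allclose(mat, mat.T):
                raise GraphValidationError(f"{name}: interaction matrix not symmetric")
        _claim(src, mat.shape[0], name)
        _claim(dst, mat.shape[1], name)

    graph = HeteroGraph(
        nodes={t: list(range(counts.get(t, 0))) for t in NODE_TYPES},
        edges={
            rel: _edges_from_matrix(mat, RELATIONS[rel][0] == RELATIONS[rel][1])
            for rel, mat in mats.items()
        },
        sim_diagonals={
            rel: np.diag(mats[rel]).copy()
            for rel in RELATIONS
            if RELATIONS[rel][2] == "similarity"
        },
    )
    graph.validate()
    return graph


def save_heterograph(graph: HeteroGraph, directory: str | os.PathLike,
                     layout: dict[str, str] | None = None) -> None:
    """Serialize back to the matrix dialect; exact inverse of loading."""
    layout = dict(DEFAULT_LAYOUT, **(layout or {}))
    os.makedirs(directory, exist_ok=True)
    for rel, (src, dst, kind) in RELATIONS.items():
        mat = graph.relation_matrix(rel)
        if kind == "similarity" and rel in graph.sim_diagonals:
            np.fill_diagonal(mat, graph.sim_diagonals[rel])
        fmt = "%d" if kind != "similarity" else "%.12g"
        write_matrix(os.path.join(directory, layout[rel]), mat, fmt=fmt)


def ablate(graph: HeteroGraph, drop: set[str] | frozenset[str]) -> HeteroGraph:
    """Return a copy with the named relations and/or node types removed.

    Dropping a node type removes the type and every relation incident to it.
    The drug-interaction-protein relation (and the drug/protein types) carry
    the labels and cannot be dropped.
    """
    drop = set(drop)
    unknown = drop - set(RELATIONS) - set(NODE_TYPES)
    if unknown:
        raise ValueError(f"unknown relation/node types: {sorted(unknown)}")
    if "drug-interaction-protein" in drop or drop & {"drug", "protein"}:
        raise ValueError("the drug-interaction-protein backbone cannot be dropped")

    dropped_types = drop & set(NODE_TYPES)
    dropped_rels = drop & set(RELATIONS)
    dropped_rels |= {
        rel for rel, (src, dst, _) in RELATIONS.items()
        if src in dropped_types or dst in dropped_types
    }
    return HeteroGraph(
        nodes={t: list(ids) for t, ids in graph.nodes.items() if t not in dropped_types},
        edges={rel: list(e) for rel, e in graph.edges.items() if rel not in dropped_rels},
        sim_diagonals={
            rel: d.copy() for rel, d in graph.sim_diagonals.items()
            if rel not in dropped_rels
        },
    )
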