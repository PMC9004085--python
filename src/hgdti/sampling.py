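"""Reliable negative sampling for drug-target pairs.

An unknown pair (d_i, t_j) is scored

    s_ij = exp(-(s_DT_ij + s_TD_ji)),

where s_DT_ij sums the sequence similarity between t_j and every target known
to interact with d_i, and s_TD_ji sums the chemical similarity between d_i and
every drug known to hit t_j.  A pair that is dissimilar from everything around
the known interactome scores close to 1 and is a reliable negative; a pair
embedded among known interactions scores close to 0.  Negatives are taken
from pairs scoring above a threshold (default 0.1), either uniformly at
random or as the top scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import DTIPair, HeteroGraph

__all__ = ["ReliableScoreTable", "reliable_scores", "select_negatives", "build_dataset"]


@dataclass
class ReliableScoreTable:
    """Reliable scores over all unknown drug-target pairs.

    ``scores`` is dense |D| x |T|; ``known_mask`` marks the known-DTI cells,
    which are excluded from every query.
    """

    scores: np.ndarray
    known_mask: np.ndarray

    @property
    def n_unknown(self) -> int:
        return int((~self.known_mask).sum())

    def score(self, drug: int, protein: int) -> float:
        if self.known_mask[drug, protein]:
            raise KeyError(f"({drug}, {protein}) is a known DTI, not in the table")
        return float(self.scores[drug, protein])

    def ranked(self) -> list[tuple[int, int, float]]:
        """Unknown pairs in descending score order, ties by (drug, protein)."""
        ii, jj = np.nonzero(~self.known_mask)
        order = np.lexsort((jj, ii, -self.scores[ii, jj]))
        return [(int(ii[k]), int(jj[k]), float(self.scores[ii[k], jj[k]]))
                for k in order]

    def histogram(self, bins: int = 10) -> str:
        """Text histogram of the unknown-pair score distribution."""
        vals = self.scores[~self.known_mask]
        counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
        width = max(counts.max(), 1)
        lines = [
            f"[{lo:.2f}, {hi:.2f}{']' if i == bins - 1 else ')'} "
            f"{c:6d} {'#' * int(round(40 * c / width))}"
            for i, (lo, hi, c) in enumerate(zip(edges[:-1], edges[1:], counts))
        ]
        return "\n".join(lines)


def reliable_scores(A: np.ndarray, B: np.ndarray,
                    known: set[tuple[int, int]] | list[tuple[int, int]]) -> ReliableScoreTable:
    """Score every unknown pair given drug-drug (A) and protein-protein (B)
    similarity matrices and the set of known DTI index pairs."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("similarity matrices must be square")
    if A.min() < 0 or B.min() < 0:
        raise ValueError("similarity matrices must be non-negative")

    P = np.zeros((A.shape[0], B.shape[0]))
    for d, t in known:
        P[d, t] = 1.0
    # s_DT[i, j] = sum_{t_k in T_{d_i}} B[t_j, t_k];  s_TD[i, j] = sum_{d_k in D_{t_j}} A[d_i, d_k]
    s_dt = P @ B.T
    s_td = A @ P
    scores = np.exp(-(s_dt + s_td))
    return ReliableScoreTable(scores=scores, known_mask=P.astype(bool))


def select_negatives(table: ReliableScoreTable, threshold: float = 0.1,
                     n_neg: int = 0, seed: int | np.random.Generator = 0,
                     mode: str = "uniform") -> list[DTIPair]:
    """Draw ``n_neg`` label-0 pairs from unknown pairs scoring above ``threshold``.

    ``mode='uniform'`` samples uniformly without replacement from the
    candidate set; ``mode='top'`` takes the highest-scoring candidates
    (descending, ties broken by (drug, protein) index).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if mode not in ("uniform", "top"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    candidates = [(d, t) for d, t, s in table.ranked() if s > threshold]
    if n_neg > len(candidates):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(candidates)} candidates "
            f"score above {threshold} (shortfall {n_neg - len(candidates)})"
        )
    if mode == "top":
        chosen = candidates[:n_neg]
    else:
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(candidates), size=n_neg, replace=False)
        chosen = [candidates[k] for k in picks]
    return [DTIPair(d, t, 0) for d, t in chosen]


def build_dataset(graph: HeteroGraph, ratio: int = 10, threshold: float = 0.1,
                  seed: int | np.random.Generator = 0, mode: str = "uniform",
                  positives: list[tuple[int, int]] | None = None):
    """Assemble the labelled pair set: all known DTIs plus ``ratio`` times as
    many reliable negatives.

    ``positives`` restricts the label-1 pairs (e.g. after redundancy
    filtering); scoring still uses the full known interactome.  With
    ``threshold=0`` and ``mode='uniform'`` this degenerates to plain random
    sampling over all unknown pairs.

    Returns
    -------
    X : (n, 2) int array of (drug, protein) index pairs
    y : (n,) int array of labels
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    known = graph.positive_pairs()
    pos = known if positives is None else sorted(positives)
    A = graph.relation_matrix("drug-similarity-drug")
    if "drug-similarity-drug" in graph.sim_diagonals:
        np.fill_diagonal(A, graph.sim_diagonals["drug-similarity-drug"])
    B = graph.relation_matrix("protein-similarity-protein")
    if "protein-similarity-protein" in graph.sim_diagonals:
        np.fill_diagonal(B, graph.sim_diagonals["protein-similarity-protein"])
    table = reliable_scores(A, B, known)
    negs = select_negatives(table, threshold=threshold, n_neg=ratio * len(pos),
                            seed=seed, mode=mode)
    pairs = [DTIPair(d, t, 1) for d, t in pos] + negs
    X = np.array([(p.drug, p.protein) for p in pairs], dtype=int)
    y = np.array([p.label for p in pairs], dtype=int)
    return X, y
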