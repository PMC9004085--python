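"""Experimental protocol: stratified cross-validation with seeded repeats,
AUROC/AUPR, redundancy-removal filters, the unique/non-unique split, and the
scenario driver used for ablation / sampling-mode / aggregation-depth studies.

All results are reported per trial and per fold and aggregated as
mean +/- standard deviation over the configured number of trials; fresh
negatives are drawn for every trial seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import NodeContent
from .graph import HeteroGraph, ablate
from .model import HGDTIClassifier
from .sampling import build_dataset

__all__ = [
    "FoldSplit",
    "EvalReport",
    "stratified_kfold",
    "auroc",
    "aupr",
    "filter_similar_dtis",
    "filter_jaccard",
    "unique_split",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined with a single class present")


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank / Mann-Whitney form, ties count 1/2)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve by step integration
    (sum over thresholds of precision x recall increment)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, float)))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """k disjoint index subsets with per-fold class ratios matching the
    global one (within one pair)."""

    folds: list[np.ndarray]
    seed: int

    def train_test(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return train, test


def stratified_kfold(y, k: int = 10, seed: int = 0) -> FoldSplit:
    """Hierarchical (label-stratified) k-fold assignment of pair indices."""
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} members of each class, have {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    return FoldSplit(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# redundancy-removal filters and the unique split
# ---------------------------------------------------------------------------

def filter_similar_dtis(positives, drug_sim: np.ndarray, prot_sim: np.ndarray,
                        t_drug: float = 0.6, t_prot: float = 0.4):
    """Greedily drop positives whose drug is too similar (> t_drug) or whose
    protein is too homologous (> t_prot) to an already-retained positive.

    The scan runs in fixed (drug, protein) id order, so the first of any
    redundant group is kept; returns (survivors, removal_log) where the log
    maps each removed pair to the retained pair that triggered the removal.
    """
    if not (0 <= t_drug <= 1 and 0 <= t_prot <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    kept: list[tuple[int, int]] = []
    removed: dict[tuple[int, int], tuple[int, int]] = {}
    for d, t in sorted(positives):
        trigger = next(
            (prev for prev in kept
             if drug_sim[d, prev[0]] > t_drug or prot_sim[t, prev[1]] > t_prot),
            None)
        if trigger is None:
            kept.append((d, t))
        else:
            removed[(d, t)] = trigger
    return kept, removed


def _jaccard_rows(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.isin(M, (0.0, 1.0)).all():
        raise ValueError("association matrix must be binary for Jaccard similarity")
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return J


def filter_jaccard(positives, drug_assoc: np.ndarray | None = None,
                   prot_assoc: np.ndarray | None = None, threshold: float = 0.6):
    """Greedily drop positives whose drug (and, when ``prot_assoc`` is given,
    whose protein) shares its association profile with a retained positive at
    Jaccard similarity above ``threshold``.

    ``drug_assoc`` rows are per-drug binary profiles (drug interactions,
    side-effects or diseases); ``prot_assoc`` adds the protein-disease check
    used by the shared-disease scenario.
    """
    J_drug = _jaccard_rows(drug_assoc) if drug_assoc is not None else None
    J_prot = _jaccard_rows(prot_assoc) if prot_assoc is not None else None
    kept: list[tuple[int, int]] = []
    removed: dict[tuple[int, int], tuple[int, int]] = {}
    for d, t in sorted(positives):
        trigger = None
        for prev in kept:
            if J_drug is not None and J_drug[d, prev[0]] > threshold:
                trigger = prev
                break
            if J_prot is not None and J_prot[t, prev[1]] > threshold:
                trigger = prev
                break
        if trigger is None:
            kept.append((d, t))
        else:
            removed[(d, t)] = trigger
    return kept, removed


def unique_split(positives):
    """Partition known DTIs into non-unique and unique interactions.

    A pair is *unique* when its drug interacts with exactly one target and
    its target with exactly one drug in the positive set.
    """
    positives = list(positives)
    d_deg: dict[int, int] = {}
    t_deg: dict[int, int] = {}
    for d, t in positives:
        d_deg[d] = d_deg.get(d, 0) + 1
        t_deg[t] = t_deg.get(t, 0) + 1
    unique = [(d, t) for d, t in positives if d_deg[d] == 1 and t_deg[t] == 1]
    non_unique = [p for p in positives if p not in set(unique)]
    return non_unique, unique


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-trial, per-fold metrics plus their aggregation."""

    scenario: str
    records: pd.DataFrame  # columns: trial, fold, auroc, aupr
    trial_seeds: list[int] = field(default_factory=list)

    @property
    def auroc_mean(self) -> float:
        return float(self.records["auroc"].mean())

    @property
    def auroc_sd(self) -> float:
        return float(self.records.groupby("trial")["auroc"].mean().std(ddof=0))

    @property
    def aupr_mean(self) -> float:
        return float(self.records["aupr"].mean())

    @property
    def aupr_sd(self) -> float:
        return float(self.records.groupby("trial")["aupr"].mean().std(ddof=0))

    def summary(self) -> str:
        return (f"{self.scenario}: AUROC {self.auroc_mean:.3f} +/- {self.auroc_sd:.3f}, "
                f"AUPR {self.aupr_mean:.3f} +/- {self.aupr_sd:.3f} "
                f"({len(self.trial_seeds)} trials)")


def derive_trial_seeds(base_seed: int, n_trials: int) -> list[int]:
    """Second-level trial seeds derived from the first-level seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_trials)]


def _positives_for_scenario(graph: HeteroGraph, scenario: str):
    pos = graph.positive_pairs()
    if scenario in ("cv", "ablation", "depth", "random-negatives", "unique"):
        return pos
    drug_sim = graph.relation_matrix("drug-similarity-drug")
    np.fill_diagonal(drug_sim, graph.sim_diagonals.get(
        "drug-similarity-drug", np.ones(graph.n_drugs)))
    prot_sim = graph.relation_matrix("protein-similarity-protein")
    np.fill_diagonal(prot_sim, graph.sim_diagonals.get(
        "protein-similarity-protein", np.ones(graph.n_proteins)))
    if scenario == "filtered-similarity":
        kept, _ = filter_similar_dtis(pos, drug_sim, prot_sim)
        return kept
    if scenario == "filtered-interactions":
        kept, _ = filter_jaccard(pos, graph.relation_matrix("drug-interaction-drug"))
        return kept
    if scenario == "filtered-side-effects":
        kept, _ = filter_jaccard(pos, graph.relation_matrix("drug-association-side_effect"))
        return kept
    if scenario == "filtered-diseases":
        kept, _ = filter_jaccard(pos, graph.relation_matrix("drug-association-disease"),
                                 graph.relation_matrix("protein-association-disease"))
        return kept
    raise ValueError(f"unknown scenario {scenario!r}")


def run_experiment(graph: HeteroGraph, scenario: str = "cv", *,
                   content: NodeContent | None = None,
                   n_trials: int = 10, k: int = 10, ratio: int = 10,
                   threshold: float = 0.1, base_seed: int = 10,
                   drop: set[str] | None = None, depth: int = 1,
                   sampling_mode: str = "uniform",
                   model_params: dict | None = None) -> EvalReport:
    """Run one evaluation scenario and aggregate AUROC/AUPR over trials.

    Scenarios: ``cv`` (plain stratified k-fold), the four redundancy-removal
    variants (``filtered-similarity``, ``filtered-interactions``,
    ``filtered-side-effects``, ``filtered-diseases``), ``unique`` (train on
    non-unique positives, test on unique ones), ``ablation`` (k-fold on the
    graph with ``drop`` removed), ``depth`` (k-fold with ``depth`` stacked
    aggregation layers) and ``random-negatives`` (threshold-free uniform
    negative sampling).

    Negatives are re-drawn for every trial seed; each trial's seed also
    drives the fold assignment and the model initialization.
    """
    work_graph = ablate(graph, drop) if scenario == "ablation" and drop else graph
    eff_threshold = 0.0 if scenario == "random-negatives" else threshold
    positives = _positives_for_scenario(graph, scenario)
    trial_seeds = derive_trial_seeds(base_seed, n_trials)
    model_params = dict(model_params or {})
    if scenario == "depth":
        model_params["depth"] = depth

    rows = []
    for trial, seed in enumerate(trial_seeds):
        if scenario == "unique":
            rows.extend(_run_unique_trial(
                work_graph, content, positives, ratio, eff_threshold,
                sampling_mode, seed, trial, model_params))
            continue
        X, y = build_dataset(work_graph, ratio=ratio, threshold=eff_threshold,
                             seed=seed, mode=sampling_mode, positives=positives)
        split = stratified_kfold(y, k=k, seed=seed % (2 ** 31))
        for fold in range(k):
            tr, te = split.train_test(fold)
            clf = HGDTIClassifier(graph=work_graph, content=content,
                                  random_state=seed, **model_params)
            clf.fit(X[tr], y[tr])
            scores = clf.predict_proba(X[te])[:, 1]
            rows.append({"trial": trial, "fold": fold,
                         "auroc": auroc(scores, y[te]),
                         "aupr": aupr(scores, y[te])})
    records = pd.DataFrame(rows)
    return EvalReport(scenario=scenario, records=records, trial_seeds=trial_seeds)


def _run_unique_trial(graph, content, positives, ratio, threshold, mode,
                      seed, trial, model_params):
    """Train on non-unique positives, test on unique ones (single split).

    Negatives are drawn once at the configured ratio and split between the
    two sides so the train and test pair sets stay disjoint.
    """
    non_unique, unique = unique_split(positives)
    if not unique or not non_unique:
        raise ValueError("unique scenario needs both unique and non-unique positives")
    X, y = build_dataset(graph, ratio=ratio, threshold=threshold,
                         seed=seed, mode=mode, positives=positives)
    neg = np.flatnonzero(y == 0)
    neg = np.random.default_rng(seed + 1).permutation(neg)
    pair_index = {tuple(p): i for i, p in enumerate(map(tuple, X))}
    tr_pos = [pair_index[p] for p in non_unique]
    te_pos = [pair_index[p] for p in unique]
    n_tr_neg = ratio * len(non_unique)
    tr_idx = np.concatenate([tr_pos, neg[:n_tr_neg]]).astype(int)
    te_idx = np.concatenate([te_pos, neg[n_tr_neg:]]).astype(int)
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_te, y_te = X[te_idx], y[te_idx]
    clf = HGDTIClassifier(graph=graph, content=content, random_state=seed,
                          **model_params)
    clf.fit(X_tr, y_tr)
    scores = clf.predict_proba(X_te)[:, 1]
    return [{"trial": trial, "fold": 0,
             "auroc": auroc(scores, y_te), "aupr": aupr(scores, y_te)}]
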