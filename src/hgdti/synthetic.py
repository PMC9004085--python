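"""Synthetic DTINet-layout heterogeneous graphs with planted low-rank structure.

Drugs and proteins get k-dimensional latent vectors; drug-protein
interactions are Bernoulli draws with probability sigmoid(z_d . z_t + bias),
the bias calibrated so the realized density matches the configured one.
Similarity networks are cosine similarities of the latents mapped to [0, 1]
with clipped Gaussian noise; same-type interaction networks threshold the
latent affinity; diseases and side-effects attach preferentially to latent
clusters.  Because the interaction signal and both similarity networks share
the same latents, reliable-negative scoring and the graph model have a real
signal to recover — which is what makes end-to-end learning testable offline.

``generate_sequences`` additionally emits valid small-molecule SMILES and
random amino-acid sequences so the content-feature path can run end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .graph import DEFAULT_LAYOUT, write_matrix

__all__ = ["SynthConfig", "generate", "generate_sequences"]

_AA = "ARNDCQEGHILKMFPSTWYV"

# small, definitely-parseable scaffolds; one per latent cluster
_SMILES_SCAFFOLDS = (
    "CCO", "CC(=O)O", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "CC(N)C(=O)O",
    "c1ccc2ccccc2c1", "C1CCNCC1",
)
# chain-terminal suffixes, ordered by increasing decoration; each parses when
# appended to any scaffold above
_SMILES_SUFFIXES = (
    "", "C", "CC", "CCC", "CCCC", "CO", "CCO", "CN",
    "CCN", "CCl", "CBr", "COC", "CC(C)C", "CCOC", "CC(=O)C", "CCNC",
)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark."""

    n_drug: int = 50
    n_protein: int = 80
    n_disease: int = 20
    n_se: int = 15
    k: int = 4
    density: float = 0.05
    noise: float = 0.1
    seed: int = 10

    def validate(self) -> None:
        if min(self.n_drug, self.n_protein, self.n_disease, self.n_se) <= 0:
            raise ValueError("all node counts must be positive")
        if not 0.0 < self.density < 1.0:
            raise ValueError(f"density {self.density} must lie strictly in (0, 1)")
        if self.k < 1:
            raise ValueError("latent dimension k must be >= 1")


def _cosine_similarity(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    U = Z / norms
    return U @ U.T


def _similarity_matrix(Z: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    # positive-part cosine, squared: most pairs weakly similar, a high tail
    # for genuinely co-oriented latents (mirrors real chemical/sequence
    # similarity matrices, which concentrate near zero)
    S = np.clip(_cosine_similarity(Z), 0.0, None) ** 2
    S = S + rng.normal(0.0, noise, S.shape)
    S = (S + S.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def _threshold_interactions(Z: np.ndarray, quantile: float,
                            rng: np.random.Generator) -> np.ndarray:
    aff = _cosine_similarity(Z) + rng.normal(0.0, 0.05, (len(Z), len(Z)))
    aff = (aff + aff.T) / 2.0
    iu = np.triu_indices(len(Z), k=1)
    cut = np.quantile(aff[iu], quantile)
    mat = (aff > cut).astype(float)
    np.fill_diagonal(mat, 0.0)
    return np.maximum(mat, mat.T)


def _calibrate_bias(logits: np.ndarray, density: float) -> float:
    """Bias b such that mean(sigmoid(logits + b)) == density (bisection)."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if (1.0 / (1.0 + np.exp(-(logits + mid)))).mean() > density:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0


def _cluster_associations(Z: np.ndarray, centers: np.ndarray, per_entity: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Binary associations: each entity (column) links to the nodes whose
    latent affinity to its center is highest, plus Bernoulli noise."""
    aff = (Z / np.linalg.norm(Z, axis=1, keepdims=True)) @ centers.T
    n, m = aff.shape
    mat = np.zeros((n, m))
    top = max(1, int(round(per_entity * n)))
    for j in range(m):
        idx = np.argsort(-aff[:, j])[:top]
        mat[idx, j] = 1.0
    mat = np.maximum(mat, rng.random((n, m)) < 0.02)
    return mat.astype(float)


@dataclass
class GroundTruth:
    latents_drug: np.ndarray
    latents_protein: np.ndarray
    positives: list[tuple[int, int]] = field(default_factory=list)


def generate(config: SynthConfig, out: str | os.PathLike) -> GroundTruth:
    """Write the 8 DTINet-dialect matrices plus ``ground_truth.tsv``.

    Deterministic given ``config.seed`` (byte-identical files).
    """
    config.validate()
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    Zd = rng.normal(size=(config.n_drug, config.k))
    Zt = rng.normal(size=(config.n_protein, config.k))

    logits = Zd @ Zt.T * (3.0 / np.sqrt(config.k))
    bias = _calibrate_bias(logits, config.density)
    probs = 1.0 / (1.0 + np.exp(-(logits + bias)))
    dti = (rng.random(probs.shape) < probs).astype(float)

    mats = {
        "drug-interaction-protein": dti,
        "drug-similarity-drug": _similarity_matrix(Zd, config.noise, rng),
        "protein-similarity-protein": _similarity_matrix(Zt, config.noise, rng),
        "drug-interaction-drug": _threshold_interactions(Zd, 0.9, rng),
        "protein-interaction-protein": _threshold_interactions(Zt, 0.9, rng),
        "drug-association-disease": _cluster_associations(
            Zd, rng.normal(size=(config.n_disease, config.k)), 0.15, rng),
        "protein-association-disease": _cluster_associations(
            Zt, rng.normal(size=(config.n_disease, config.k)), 0.15, rng),
        "drug-association-side_effect": _cluster_associations(
            Zd, rng.normal(size=(config.n_se, config.k)), 0.2, rng),
    }
    for rel, mat in mats.items():
        fmt = "%d" if "similarity" not in rel else "%.6f"
        write_matrix(os.path.join(out, DEFAULT_LAYOUT[rel]), mat, fmt=fmt)

    positives = [(int(i), int(j)) for i, j in zip(*np.nonzero(dti))]
    with open(os.path.join(out, "ground_truth.tsv"), "w") as fh:
        fh.write("# planted latent vectors and positive pairs\n")
        for i, z in enumerate(Zd):
            fh.write("drug\t%d\t%s\n" % (i, "\t".join(f"{v:.8f}" for v in z)))
        for j, z in enumerate(Zt):
            fh.write("protein\t%d\t%s\n" % (j, "\t".join(f"{v:.8f}" for v in z)))
        for i, j in positives:
            fh.write(f"positive\t{i}\t{j}\n")
    return GroundTruth(latents_drug=Zd, latents_protein=Zt, positives=positives)


def _unit_rows(Z: np.ndarray) -> np.ndarray:
    return Z / np.linalg.norm(Z, axis=1, keepdims=True)


def generate_sequences(config: SynthConfig, out: str | os.PathLike) -> tuple[str, str]:
    """Emit ``smiles.tsv`` (id TAB smiles) and ``proteins.fasta`` fixtures.

    In the real benchmark the similarity networks are *computed from* the
    node content (chemical similarity from fingerprints, sequence similarity
    from alignment), so content and similarity share provenance.  The
    fixtures preserve that coupling: molecules and sequences are organized
    around the same latent vectors that :func:`generate` plants.  Drugs in
    the same latent cluster share a scaffold (decorated more heavily the
    further the drug sits from the cluster center); proteins are mutated
    copies of a per-cluster prototype sequence, with the mutation rate
    growing with latent distance.  Fingerprint and PseAAC features computed
    from these files therefore correlate with the planted similarity
    structure, as they do on real data.
    """
    config.validate()
    os.makedirs(out, exist_ok=True)
    # identical first draws as generate(): the same latents are recovered
    rng = np.random.default_rng(config.seed)
    Zd = rng.normal(size=(config.n_drug, config.k))
    Zt = rng.normal(size=(config.n_protein, config.k))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    smiles_path = os.path.join(out, "smiles.tsv")
    fasta_path = os.path.join(out, "proteins.fasta")

    n_clust = len(_SMILES_SCAFFOLDS)
    centers = _unit_rows(rng.normal(size=(n_clust, config.k)))
    aff = _unit_rows(Zd) @ centers.T
    with open(smiles_path, "w") as fh:
        for i in range(config.n_drug):
            c = int(np.argmax(aff[i]))
            j = min(int(round((1.0 - aff[i, c]) * (len(_SMILES_SUFFIXES) - 1))),
                    len(_SMILES_SUFFIXES) - 1)
            fh.write(f"drug_{i}\t{_SMILES_SCAFFOLDS[c] + _SMILES_SUFFIXES[j]}\n")

    n_proto = 6
    centers = _unit_rows(rng.normal(size=(n_proto, config.k)))
    protos = ["".join(_AA[k] for k in rng.integers(0, 20, int(rng.integers(120, 301))))
              for _ in range(n_proto)]
    aff = _unit_rows(Zt) @ centers.T
    with open(fasta_path, "w") as fh:
        for j in range(config.n_protein):
            c = int(np.argmax(aff[j]))
            rate = 0.05 + 0.45 * (1.0 - aff[j, c])
            seq = "".join(_AA[rng.integers(0, 20)] if rng.random() < rate else ch
                          for ch in protos[c])
            fh.write(f">protein_{j}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start:start + 60] + "\n")
    return smiles_path, fasta_path
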