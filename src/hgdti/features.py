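"""Initial node content vectors C(v).

Drugs: a 1024-bit Morgan fingerprint (radius 2) rendered as a 256-digit
hexadecimal string; each hex digit's value (0-15) is one component of the raw
256-vector, which is reduced to length 128 by averaging its two halves.

Proteins: type-1 pseudo amino acid composition (PseAAC) over hydrophobicity,
hydrophilicity and side-chain mass — 20 composition terms plus lam = 44
sequence-order correlation factors, 64 components total, expanded to 128 by
duplicate concatenation.

Diseases and side-effects carry no intrinsic content; they get seeded random
vectors, min-max standardized per vector, that the model treats as trainable
parameters.  The same fallback applies to drugs/proteins when no SMILES/FASTA
is supplied (matrix-only runs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeError",
    "NodeContent",
    "drug_fingerprint",
    "reduce_fingerprint",
    "protein_pseaac",
    "expand_protein",
    "init_learnable_content",
    "build_node_content",
    "read_smiles_file",
    "read_fasta_file",
]

RAW_FINGERPRINT_LEN = 256
RAW_PSEAAC_LEN = 64
DEFAULT_LAM = 44
DEFAULT_W = 0.05

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Chou's three physicochemical scales over the 20 standard residues
# (order A R N D C Q E G H I L K M F P S T W Y V).
_HYDROPHOBICITY = np.array([
    0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40, 1.38,
    1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08,
])
_HYDROPHILICITY = np.array([
    -0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
    -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5,
])
_SIDE_CHAIN_MASS = np.array([
    15.0, 101.0, 58.0, 59.0, 47.0, 72.0, 73.0, 1.0, 82.0, 57.0,
    57.0, 73.0, 75.0, 91.0, 42.0, 45.0, 59.0, 130.0, 107.0, 43.0,
])


class MoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def _standardize_scale(values: np.ndarray) -> np.ndarray:
    # Chou's normalization: subtract the 20-residue mean, divide by the
    # population standard deviation over the 20 residues.
    centered = values - values.mean()
    return centered / np.sqrt((centered ** 2).mean())


_SCALES = np.stack([
    _standardize_scale(_HYDROPHOBICITY),
    _standardize_scale(_HYDROPHILICITY),
    _standardize_scale(_SIDE_CHAIN_MASS),
])  # (3, 20)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def drug_fingerprint(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Raw drug content: Morgan fingerprint as 256 hexadecimal digit values.

    The ``n_bits``-long bit vector is grouped into 4-bit nibbles, each read as
    one hexadecimal digit, giving ``n_bits / 4`` integers in 0..15.

    Raises
    ------
    MoleculeError
        If the SMILES does not parse.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.array(gen.GetFingerprint(mol), dtype=int)
    nibbles = bits.reshape(-1, 4)
    weights = np.array([8, 4, 2, 1])
    return (nibbles * weights).sum(axis=1).astype(float)


def reduce_fingerprint(raw: np.ndarray) -> np.ndarray:
    """Drug content C_d: elementwise mean of the two 128-long halves."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (RAW_FINGERPRINT_LEN,):
        raise ValueError(
            f"raw fingerprint must have length {RAW_FINGERPRINT_LEN}, got {raw.shape}"
        )
    half = RAW_FINGERPRINT_LEN // 2
    return (raw[:half] + raw[half:]) / 2.0


def protein_pseaac(sequence: str, lam: int = DEFAULT_LAM, w: float = DEFAULT_W,
                   strict: bool = False) -> np.ndarray:
    """Type-1 PseAAC vector of a protein sequence (length ``20 + lam``).

    The first 20 components are the weighted amino-acid composition fractions,
    the remaining ``lam`` are sequence-order correlation factors built from
    the three standardized physicochemical scales.  With x the output and the
    standard denominator, sum(x) = 1.

    Parameters
    ----------
    sequence : amino-acid string over the 20 standard one-letter codes
        (case-insensitive).  Non-standard letters are stripped with a warning,
        or rejected when ``strict``.
    lam : number of correlation tiers; the effective sequence length must
        exceed it.
    w : weight factor balancing composition against sequence order.
    """
    seq = sequence.upper()
    cleaned = [c for c in seq if c in _AA_INDEX]
    if len(cleaned) != len(seq):
        bad = sorted({c for c in seq if c not in _AA_INDEX})
        if strict:
            raise ValueError(f"non-standard residues {bad} in sequence")
        warnings.warn(f"stripping non-standard residues {bad}", stacklevel=2)
    idx = np.array([_AA_INDEX[c] for c in cleaned], dtype=int)
    L = len(idx)
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lam={lam}")

    freqs = np.bincount(idx, minlength=20) / L
    props = _SCALES[:, idx]  # (3, L)
    thetas = np.empty(lam)
    for d in range(1, lam + 1):
        diff = props[:, : L - d] - props[:, d:]
        # mean over positions of the mean squared property difference
        thetas[d - 1] = (diff ** 2).mean(axis=0).sum() / (L - d)

    denom = freqs.sum() + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


def expand_protein(raw: np.ndarray) -> np.ndarray:
    """Protein content C_t: duplicate concatenation of the 64-long raw vector."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (RAW_PSEAAC_LEN,):
        raise ValueError(f"raw PseAAC must have length {RAW_PSEAAC_LEN}, got {raw.shape}")
    return np.concatenate([raw, raw])


def init_learnable_content(node_type: str, count: int, dim: int,
                           seed: int | np.random.Generator) -> np.ndarray:
    """Seeded uniform vectors, 0-1 (min-max) standardized per vector.

    These rows are flagged trainable by the model and updated with the rest
    of the parameters during optimization.
    """
    if count < 0 or dim <= 0:
        raise ValueError("count must be >= 0 and dim > 0")
    rng = np.random.default_rng(seed)
    vecs = rng.uniform(0.0, 1.0, size=(count, dim))
    lo = vecs.min(axis=1, keepdims=True)
    span = vecs.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0
    return (vecs - lo) / span


def read_smiles_file(path: str) -> dict[str, str]:
    """Read ``id<TAB>smiles`` records, one per line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smiles = line.split("\t")
            out[name] = smiles
    return out


def read_fasta_file(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def _minmax_rows(M: np.ndarray) -> np.ndarray:
    """0-1 (min-max) standardization per row vector."""
    lo = M.min(axis=1, keepdims=True)
    span = M.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0
    return (M - lo) / span


def _content_dim_reduce(raw: np.ndarray, dim: int) -> np.ndarray:
    """Fold a raw length-256 drug vector to ``dim`` by repeated half-averaging."""
    vec = np.asarray(raw, dtype=float)
    while vec.size > dim:
        half = vec.size // 2
        vec = (vec[:half] + vec[half:]) / 2.0
    return vec


def _content_dim_expand(raw: np.ndarray, dim: int) -> np.ndarray:
    """Tile a raw length-64 protein vector up to ``dim`` by concatenation."""
    vec = np.asarray(raw, dtype=float)
    reps = int(np.ceil(dim / vec.size))
    return np.tile(vec, reps)[:dim]


@dataclass
class NodeContent:
    """Per-type content matrices plus which types the model may train.

    ``content[t]`` has shape (n_nodes of type t, dim).  ``raw`` holds the
    pre-reduction drug fingerprints (n x 256) and protein PseAAC vectors
    (n x 64) when computed from structures/sequences.
    """

    content: dict[str, np.ndarray]
    trainable: frozenset[str]
    dim: int
    raw: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for t, mat in self.content.items():
            if mat.ndim != 2 or mat.shape[1] != self.dim:
                raise ValueError(f"content[{t}] has shape {mat.shape}, want (*, {self.dim})")


def build_node_content(graph, dim: int = 128, seed: int = 0,
                       smiles: dict[str, str] | None = None,
                       fasta: dict[str, str] | None = None,
                       lam: int = DEFAULT_LAM, w: float = DEFAULT_W) -> NodeContent:
    """Assemble C(v) for every node in ``graph``.

    ``smiles``/``fasta`` map node ids to molecule strings and sequences,
    matched to matrix rows by record order.  Types without supplied
    structures fall back to seeded learnable vectors; the fallback is logged.

    Every content row is 0-1 (min-max) standardized, putting fingerprint
    content (hex digits 0-15), PseAAC content (fractions summing to 1) and
    the learnable vectors on one common scale; the unstandardized raw
    fingerprint/PseAAC vectors are kept in ``raw``.
    """
    ss = np.random.SeedSequence(seed)
    type_seeds = {t: s for t, s in zip(
        ("drug", "protein", "disease", "side_effect"), ss.spawn(4))}

    content: dict[str, np.ndarray] = {}
    raw: dict[str, np.ndarray] = {}
    trainable: set[str] = set()

    for t in graph.nodes:
        n = graph.n_nodes(t)
        if t == "drug" and smiles is not None:
            keys = list(smiles)
            if len(keys) != n:
                raise ValueError(f"{len(keys)} SMILES records for {n} drugs")
            rng = np.random.default_rng(type_seeds[t])
            raws = np.zeros((n, RAW_FINGERPRINT_LEN))
            rows = np.zeros((n, dim))
            for i, key in enumerate(keys):
                try:
                    raws[i] = drug_fingerprint(smiles[key])
                    rows[i] = _content_dim_reduce(raws[i], dim)
                except MoleculeError:
                    logger.warning("drug %s: unparseable SMILES, random fallback", key)
                    rows[i] = init_learnable_content(t, 1, dim, rng.integers(2 ** 31))[0]
            content[t], raw[t] = _minmax_rows(rows), raws
        elif t == "protein" and fasta is not None:
            keys = list(fasta)
            if len(keys) != n:
                raise ValueError(f"{len(keys)} FASTA records for {n} proteins")
            raws = np.stack([protein_pseaac(fasta[k], lam=lam, w=w) for k in keys])
            content[t] = _minmax_rows(np.stack([_content_dim_expand(r, dim) for r in raws]))
            raw[t] = raws
        else:
            if t in ("drug", "protein"):
                logger.info("no structures for %s nodes: seeded learnable content", t)
            content[t] = init_learnable_content(t, n, dim, type_seeds[t])
            trainable.add(t)

    nc = NodeContent(content=content, trainable=frozenset(trainable), dim=dim, raw=raw)
    nc.validate()
    return nc
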