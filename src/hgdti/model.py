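"""Scikit-learn style estimator for heterogeneous-graph DTI prediction.

`HGDTIClassifier` is a binary classifier over drug-protein index pairs: X is
an ``(n_pairs, 2)`` integer array of ``(drug_index, protein_index)`` rows, y
the 0/1 interaction labels.  The heterogeneous graph and the node content are
constructor parameters, so the estimator composes directly with sklearn
cross-validation utilities operating on the pair array.

The building blocks (content encoding, weighted homogeneous aggregation,
attention fusion, the pair classifier head, the cross-entropy loss) are
re-exported here as plain functions for direct use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._network import (
    HGDTINetwork,
    aggregate_homogeneous,
    bce_loss,
    fuse_attention,
    predict_pair,
    train_network,
)
from .features import NodeContent, build_node_content
from .graph import HeteroGraph

__all__ = [
    "HGDTIClassifier",
    "aggregate_homogeneous",
    "fuse_attention",
    "predict_pair",
    "bce_loss",
]


class HGDTIClassifier(ClassifierMixin, BaseEstimator):
    """Heterogeneous graph neural network classifier for drug-target pairs.

    Per-type bidirectional LSTM content encoders feed relation-wise weighted
    neighbor aggregation; an attention softmax fuses the self content with
    the per-relation aggregates into the final drug/protein embeddings, and a
    two-layer head maps each concatenated pair embedding to an interaction
    probability.  All parameters (including the learnable content vectors of
    diseases and side-effects) are trained end-to-end with Adam on the mean
    binary cross-entropy.

    Parameters
    ----------
    graph : HeteroGraph
        The heterogeneous network (required before ``fit``).
    content : NodeContent or None
        Initial node content; None builds seeded learnable content for every
        node type (matrix-only mode).
    dim : int, default 128
        Embedding dimension; must be even.
    lr : float, default 1e-3
        Adam learning rate.
    tol : float, default 1e-4
        Stop when the epoch loss changes by less than this.
    max_epochs : int, default 100
    depth : int, default 1
        Number of stacked aggregation layers (1 reproduces the single-layer
        design; larger values re-aggregate previous-layer outputs).
    leaky_slope : float, default 0.2
        Negative slope of the attention LeakyReLU.
    batch_size : int or None, default 32
        Mini-batch size over pairs (the whole graph's embeddings are refreshed
        for every update); None trains full-batch.
    self_term : {'content', 'encoded'}, default 'content'
        Whether the attention self candidate is the raw content C(v) or its
        LSTM encoding f1(v).
    mask_test_edges : bool, default True
        Restrict the drug-protein aggregation edges to the positive pairs
        present in the training data, so held-out interactions cannot leak
        through message passing.
    dtype : str or numpy dtype, default 'float32'
        Floating-point precision of the network; float32 halves the memory
        traffic of training (use float64 for gradient diagnostics).
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray [0, 1]
    network_ : fitted HGDTINetwork (parameters in ``network_.params``)
    loss_trace_ : list of per-epoch losses
    n_epochs_ : epochs actually run
    """

    def __init__(self, graph: HeteroGraph | None = None,
                 content: NodeContent | None = None, dim: int = 128,
                 lr: float = 1e-3, tol: float = 1e-4, max_epochs: int = 100,
                 depth: int = 1, leaky_slope: float = 0.2,
                 batch_size: int | None = 32, self_term: str = "content",
                 mask_test_edges: bool = True, dtype: str = "float32",
                 random_state: int = 0):
        self.graph = graph
        self.content = content
        self.dim = dim
        self.lr = lr
        self.tol = tol
        self.max_epochs = max_epochs
        self.depth = depth
        self.leaky_slope = leaky_slope
        self.batch_size = batch_size
        self.self_term = self_term
        self.mask_test_edges = mask_test_edges
        self.dtype = dtype
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _validate_pairs(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_pairs, 2) array of (drug, protein) indices")
        if not np.issubdtype(X.dtype, np.integer):
            if not np.all(X == X.astype(int)):
                raise ValueError("pair indices must be integers")
            X = X.astype(int)
        if X.size and (X[:, 0].min() < 0 or X[:, 0].max() >= self.graph.n_drugs
                       or X[:, 1].min() < 0 or X[:, 1].max() >= self.graph.n_proteins):
            raise ValueError("pair indices outside the graph's node ranges")
        return X

    def _dti_weights(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        W = self.graph.relation_matrix("drug-interaction-protein")
        if not self.mask_test_edges:
            return W
        allowed = np.zeros_like(W, dtype=bool)
        pos = X[y == 1]
        allowed[pos[:, 0], pos[:, 1]] = True
        return np.where(allowed, W, 0.0)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        if self.graph is None:
            raise ValueError("a HeteroGraph must be supplied before fitting")
        if self.dim % 2:
            raise ValueError("dim must be even")
        X = self._validate_pairs(X)
        y = np.asarray(y).astype(int).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if set(classes.tolist()) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(classes) < 2:
            raise ValueError("training requires both interaction classes")
        self.classes_ = np.array([0, 1])

        ss = np.random.SeedSequence(self.random_state)
        s_content, s_params, s_batches = ss.spawn(3)
        content = self.content
        if content is None:
            content = build_node_content(
                self.graph, dim=self.dim,
                seed=int(s_content.generate_state(1)[0] % (2 ** 31)))
        if content.dim != self.dim:
            raise ValueError(f"content dim {content.dim} != estimator dim {self.dim}")

        fixed = {t: m for t, m in content.content.items() if t not in content.trainable}
        trainable = {t: m for t, m in content.content.items() if t in content.trainable}
        self.network_ = HGDTINetwork(
            self.graph, fixed, trainable, dim=self.dim,
            leaky_slope=self.leaky_slope, depth=self.depth,
            self_term=self.self_term, seed=s_params,
            dti_weights=self._dti_weights(X, y), dtype=np.dtype(self.dtype))
        self.loss_trace_ = train_network(
            self.network_, X, y, lr=self.lr, tol=self.tol,
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            seed=s_batches)
        self.n_epochs_ = len(self.loss_trace_)
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._validate_pairs(X)
        p = self.network_.predict_pairs(X)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def embed_all(self) -> dict[str, np.ndarray]:
        """Final embeddings F(v) for every drug and protein node."""
        check_is_fitted(self, "network_")
        embeddings, _ = self.network_.forward_embeddings()
        return embeddings
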