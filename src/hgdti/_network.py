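"""Numerical core of the DTI network: forward pass, analytic gradients, Adam.

The model, per training step:

1. content encoding — each node type has its own bidirectional LSTM that
   reads the content vector C(v) as a one-element sequence and emits
   f1(v) = h_fwd (+) h_bwd (each direction dim/2 wide).  With a single
   element the initial cell state is zero, so the forget gate multiplies
   zero and drops out of the computation; the cell reduces to c = i * g,
   h = o * tanh(c) with input, candidate and output gates.
2. homogeneous aggregation — per relation r incident to a drug/protein node,
   G^r(v) is the edge-weight-normalized mean of the neighbors' encodings.
3. attention fusion — the self content C(v) and the per-relation aggregates
   compete through a softmax over LeakyReLU(u . [candidate (+) C(v)]) scores;
   F(v) is the resulting convex combination.
4. pair classification — sigmoid(FC2(ReLU(FC1(F_d (+) F_t)))) with FC1 of
   width dim/2, trained with mean binary cross-entropy.

Everything is float64 numpy; gradients are hand-derived and verified against
central finite differences in the test suite.  For speed, all parameters are
views into one flat buffer (so an Adam step is a handful of vectorized ops)
and the six gate blocks of each node type's two LSTM directions are fused
into a single (6*H, dim) matrix, making a type's encoding one matmul.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

from .graph import RELATIONS, HeteroGraph

EPS_PROB = 1e-7

#: relations aggregated for drug nodes and for protein nodes, in fixed order.
DRUG_RELATIONS = (
    "drug-similarity-drug",
    "drug-interaction-drug",
    "drug-interaction-protein",
    "drug-association-disease",
    "drug-association-side_effect",
)
PROTEIN_RELATIONS = (
    "protein-similarity-protein",
    "protein-interaction-protein",
    "drug-interaction-protein",
    "protein-association-disease",
)


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def bce_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped to [eps, 1-eps]."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if ((p <= 0) | (p >= 1)).any():
        import warnings

        warnings.warn("probabilities at 0/1 clamped for the cross-entropy", stacklevel=2)
    p = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# single building blocks (also exposed through hgdti.model for direct use)
# ---------------------------------------------------------------------------

def lstm_encode(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Bidirectional LSTM over length-1 sequences; returns (f1, cache).

    ``W`` is the fused (6*H, dim) gate matrix — rows are the [input;
    candidate; output] gates of the forward direction followed by the same
    three blocks of the backward direction — and ``b`` the fused bias.  The
    output concatenates the two H-long hidden states per row of ``X``.
    """
    H = W.shape[0] // 6
    A = X @ W.T + b
    i = sigmoid(np.concatenate([A[:, 0:H], A[:, 3 * H:4 * H]], axis=1))
    g = np.tanh(np.concatenate([A[:, H:2 * H], A[:, 4 * H:5 * H]], axis=1))
    o = sigmoid(np.concatenate([A[:, 2 * H:3 * H], A[:, 5 * H:]], axis=1))
    tc = np.tanh(i * g)
    f1 = o * tc
    return f1, (X, i, g, o, tc)


def lstm_encode_backward(df1, cache, W):
    """Gradients of :func:`lstm_encode`; returns (dX, dW, db)."""
    X, i, g, o, tc = cache
    H = W.shape[0] // 6
    do = df1 * tc
    dc = df1 * o * (1.0 - tc ** 2)
    dai = dc * g * i * (1.0 - i)
    dag = dc * i * (1.0 - g ** 2)
    dao = do * o * (1.0 - o)
    dA = np.concatenate(
        [dai[:, :H], dag[:, :H], dao[:, :H],
         dai[:, H:], dag[:, H:], dao[:, H:]], axis=1)
    return dA @ W, dA.T @ X, dA.sum(axis=0)


def aggregate_homogeneous(neighbor_encodings: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean of neighbor encodings within one relation (single node).

    ``neighbor_encodings``: (m, dim); ``weights``: (m,) non-negative edge
    weights.  Raises on an all-zero weight vector over a nonempty neighbor
    set (the normalization term would be degenerate).
    """
    f1 = np.atleast_2d(np.asarray(neighbor_encodings, dtype=float))
    w = np.asarray(weights, dtype=float).ravel()
    if f1.shape[0] != w.size:
        raise ValueError("one weight per neighbor required")
    if (w < 0).any():
        raise ValueError("edge weights must be non-negative")
    total = w.sum()
    if f1.shape[0] and total == 0:
        raise ValueError("degenerate aggregation: nonempty neighbor set with zero total weight")
    return (w[:, None] * f1).sum(0) / total


def fuse_attention(C: np.ndarray, aggregates: np.ndarray | None, u: np.ndarray,
                   slope: float = 0.2):
    """Attention fusion for a single node.

    ``aggregates``: (k, dim) per-relation aggregated embeddings (k may be 0).
    Scores are LeakyReLU(u . [candidate (+) C]); the softmax weights combine
    the self content with the aggregates.  Returns (F, alphas).
    """
    C = np.asarray(C, dtype=float).ravel()
    dim = C.size
    u = np.asarray(u, dtype=float).ravel()
    if u.size != 2 * dim:
        raise ValueError(f"attention parameter must have length {2 * dim}")
    G = np.empty((0, dim)) if aggregates is None else np.atleast_2d(aggregates)
    cands = np.vstack([C[None, :], G])
    pre = cands @ u[:dim] + C @ u[dim:]
    scores = leaky_relu(pre, slope)
    if not np.isfinite(scores).all():
        raise FloatingPointError(f"non-finite attention scores: {scores}")
    z = scores - scores.max()
    alphas = np.exp(z) / np.exp(z).sum()
    return alphas @ cands, alphas


def predict_pair(F_d: np.ndarray, F_t: np.ndarray, fc1_W, fc1_b, fc2_W, fc2_b) -> float:
    """Interaction probability of one drug-protein embedding pair."""
    z = np.concatenate([np.ravel(F_d), np.ravel(F_t)])
    if z.size != fc1_W.shape[1]:
        raise ValueError(
            f"concatenated embedding length {z.size} != FC1 input {fc1_W.shape[1]}"
        )
    h = np.maximum(fc1_W @ z + fc1_b, 0.0)
    return float(sigmoid(np.atleast_1d(fc2_W @ h + fc2_b))[0])


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class HGDTINetwork:
    """Parameter container + vectorized forward/backward over a whole graph.

    Parameters
    ----------
    graph : HeteroGraph
    fixed_content : dict of node type -> (n, dim) arrays for types whose
        content is data (fingerprints, PseAAC).
    trainable_init : dict of node type -> (n, dim) initial values for types
        whose content is a learnable parameter.
    dim : embedding dimension (even).
    dti_weights : optional override of the drug-protein interaction weight
        matrix used for aggregation (e.g. with held-out edges masked out).

    ``params`` maps parameter names to arrays that are views into one flat
    float64 buffer (``param_flat``); mutating either is mutating both.
    """

    def __init__(self, graph: HeteroGraph, fixed_content: dict[str, np.ndarray],
                 trainable_init: dict[str, np.ndarray], dim: int = 128,
                 leaky_slope: float = 0.2, depth: int = 1,
                 self_term: str = "content", seed: int | np.random.SeedSequence = 0,
                 dti_weights: np.ndarray | None = None, dtype=np.float64):
        if dim % 2:
            raise ValueError("dim must be even (bidirectional split)")
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if self_term not in ("content", "encoded"):
            raise ValueError("self_term must be 'content' or 'encoded'")
        self.graph = graph
        self.dim = dim
        self.slope = leaky_slope
        self.depth = depth
        self.self_term = self_term
        self.dtype = np.dtype(dtype)
        self.types = [t for t in graph.nodes if graph.n_nodes(t) > 0]
        self.fixed_content = {t: np.asarray(v, self.dtype) for t, v in fixed_content.items()}
        self.trainable_types = tuple(trainable_init)

        # per-side relation structure: (relation, neighbor type, row-normalized
        # weight matrix, its transpose, neighbor-presence mask); rows with no
        # neighbors stay zero so their aggregate is dropped by the mask.
        self.relation_plan: dict[str, list] = {}
        for side, rels in (("drug", DRUG_RELATIONS), ("protein", PROTEIN_RELATIONS)):
            plan = []
            for rel in rels:
                if rel not in graph.edges or not graph.edges[rel]:
                    continue
                src, dst, _ = RELATIONS[rel]
                if src not in self.types or dst not in self.types:
                    continue
                if rel == "drug-interaction-protein":
                    W = (graph.relation_matrix(rel) if dti_weights is None
                         else np.asarray(dti_weights, float))
                    nbr = "protein" if side == "drug" else "drug"
                    Wm = W if side == "drug" else W.T
                else:
                    Wm = graph.relation_matrix(rel)
                    nbr = dst if src == side else src
                    if src != side:
                        Wm = Wm.T
                if Wm.sum() > 0:
                    M = Wm.sum(axis=1)
                    has = M > 0
                    Wn = (Wm / np.where(has, M, 1.0)[:, None]).astype(self.dtype)
                    plan.append((rel, nbr, Wn, np.ascontiguousarray(Wn.T), has))
            self.relation_plan[side] = plan

        self._build_params(trainable_init, seed)

    # -- parameters ---------------------------------------------------------

    def _param_shapes(self, trainable_init) -> dict[str, tuple]:
        dim, H = self.dim, self.dim // 2
        shapes: dict[str, tuple] = {}
        for t in self.types:
            shapes[f"lstm_{t}_W"] = (6 * H, dim)
            shapes[f"lstm_{t}_b"] = (6 * H,)
        shapes["attn_u"] = (2 * dim,)
        shapes["fc1_W"] = (H, 2 * dim)
        shapes["fc1_b"] = (H,)
        shapes["fc2_W"] = (H,)
        shapes["fc2_b"] = (1,)
        for t in trainable_init:
            shapes[f"content_{t}"] = trainable_init[t].shape
        return shapes

    @staticmethod
    def _as_views(flat: np.ndarray, shapes: dict[str, tuple]) -> dict[str, np.ndarray]:
        views, pos = {}, 0
        for k, shp in shapes.items():
            size = int(np.prod(shp))
            views[k] = flat[pos:pos + size].reshape(shp)
            pos += size
        return views

    def _build_params(self, trainable_init: dict[str, np.ndarray], seed) -> None:
        rng = np.random.default_rng(seed)
        dim, H = self.dim, self.dim // 2
        self._shapes = self._param_shapes(trainable_init)
        total = sum(int(np.prod(s)) for s in self._shapes.values())
        self.param_flat = np.empty(total, dtype=self.dtype)
        self.params = self._as_views(self.param_flat, self._shapes)
        self._grad_flat = np.zeros(total, dtype=self.dtype)
        self._grads = self._as_views(self._grad_flat, self._shapes)

        bound = 1.0 / np.sqrt(dim)
        # input/output gate biases start at +1 ("open" gates) so content
        # signal and gradients flow through the squashing cell from epoch 1
        gate_open = np.zeros(6 * H)
        gate_open[0:H] = gate_open[2 * H:3 * H] = 1.0
        gate_open[3 * H:4 * H] = gate_open[5 * H:] = 1.0
        for t in self.types:
            self.params[f"lstm_{t}_W"][:] = rng.uniform(-bound, bound, (6 * H, dim))
            self.params[f"lstm_{t}_b"][:] = rng.uniform(-bound, bound, 6 * H) + gate_open
        self.params["attn_u"][:] = rng.uniform(-bound, bound, 2 * dim)
        b1 = 1.0 / np.sqrt(2 * dim)
        self.params["fc1_W"][:] = rng.uniform(-b1, b1, (H, 2 * dim))
        self.params["fc1_b"][:] = rng.uniform(-b1, b1, H)
        b2 = 1.0 / np.sqrt(H)
        self.params["fc2_W"][:] = rng.uniform(-b2, b2, H)
        self.params["fc2_b"][:] = rng.uniform(-b2, b2, 1)
        for t, init in trainable_init.items():
            self.params[f"content_{t}"][:] = np.asarray(init, float)

    def content_matrix(self, t: str, params=None) -> np.ndarray:
        params = self.params if params is None else params
        key = f"content_{t}"
        return params[key] if key in params else self.fixed_content[t]

    # -- forward ------------------------------------------------------------

    def encode_content(self, t: str, C: np.ndarray, params=None) -> np.ndarray:
        """f1 for content rows C (n, dim) of node type ``t``."""
        params = self.params if params is None else params
        C = np.atleast_2d(np.asarray(C, float))
        if C.shape[1] != self.dim:
            raise ValueError(f"content must have width {self.dim}")
        f1, _ = lstm_encode(C, params[f"lstm_{t}_W"], params[f"lstm_{t}_b"])
        return f1

    def _attention_layer(self, side: str, C: np.ndarray, H_prev: dict[str, np.ndarray],
                         params) -> tuple[np.ndarray, dict]:
        """One aggregation + fusion layer for all nodes of one side."""
        u = params["attn_u"]
        u1, u2 = u[: self.dim], u[self.dim:]
        plan = self.relation_plan[side]
        n = C.shape[0]
        k = len(plan)
        cands = np.zeros((n, k + 1, self.dim), dtype=self.dtype)
        present = np.zeros((n, k + 1), dtype=bool)
        present[:, 0] = True
        cands[:, 0] = C if self.self_term == "content" else H_prev[side]
        for r, (rel, nbr, Wn, WnT, has) in enumerate(plan, start=1):
            cands[:, r] = Wn @ H_prev[nbr]
            present[:, r] = has
        pre = cands @ u1 + (C @ u2)[:, None]
        scores = leaky_relu(pre, self.slope)
        if not np.isfinite(scores).all():
            raise FloatingPointError("non-finite attention scores")
        z = np.where(present, scores, -np.inf)
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        alphas = ez / ez.sum(axis=1, keepdims=True)
        F = np.einsum("nk,nkd->nd", alphas, cands)
        cache = {"cands": cands, "present": present, "pre": pre,
                 "alphas": alphas, "C": C}
        return F, cache

    def forward_embeddings(self, params=None) -> tuple[dict[str, np.ndarray], dict]:
        """Encode all nodes and run ``depth`` aggregation layers.

        Returns the final embeddings {'drug': (n_d, dim), 'protein': ...} and
        the cache needed for the backward pass.
        """
        params = self.params if params is None else params
        contents = {t: self.content_matrix(t, params) for t in self.types}
        f1, enc_caches = {}, {}
        for t in self.types:
            f1[t], enc_caches[t] = lstm_encode(
                contents[t], params[f"lstm_{t}_W"], params[f"lstm_{t}_b"])

        H = dict(f1)
        layer_caches = []
        for _ in range(self.depth):
            cache_l, H_new = {}, dict(H)
            for side in ("drug", "protein"):
                F_side, cache = self._attention_layer(side, contents[side], H, params)
                cache_l[side] = cache
                H_new[side] = F_side
            layer_caches.append({"caches": cache_l, "H_prev": H})
            H = H_new

        cache = {"contents": contents, "f1": f1, "enc_caches": enc_caches,
                 "layers": layer_caches}
        return {"drug": H["drug"], "protein": H["protein"]}, cache

    def predict_pairs(self, X: np.ndarray, params=None,
                      embeddings: dict[str, np.ndarray] | None = None):
        params = self.params if params is None else params
        if embeddings is None:
            embeddings, _ = self.forward_embeddings(params)
        Fd = embeddings["drug"][X[:, 0]]
        Ft = embeddings["protein"][X[:, 1]]
        Z = np.hstack([Fd, Ft])
        A1 = Z @ params["fc1_W"].T + params["fc1_b"]
        H1 = np.maximum(A1, 0.0)
        logits = H1 @ params["fc2_W"] + params["fc2_b"][0]
        return sigmoid(logits)

    # -- backward -----------------------------------------------------------

    def _attention_layer_backward(self, side: str, dF: np.ndarray, cache, params,
                                  grads, dH_prev: dict[str, np.ndarray], dC_acc):
        u = params["attn_u"]
        u1 = u[: self.dim]
        cands, present, pre, alphas, C = (
            cache["cands"], cache["present"], cache["pre"], cache["alphas"], cache["C"])
        plan = self.relation_plan[side]

        dalpha = np.einsum("nd,nkd->nk", dF, cands)
        dcands = alphas[..., None] * dF[:, None, :]
        # softmax backward (absent columns have alpha = 0, hence zero grad)
        ds = alphas * (dalpha - (alphas * dalpha).sum(axis=1, keepdims=True))
        dpre = ds * np.where(pre > 0, 1.0, self.slope)
        dpre = np.where(present, dpre, 0.0)

        grads["attn_u"][: self.dim] += np.einsum("nk,nkd->d", dpre, cands)
        grads["attn_u"][self.dim:] += dpre.sum(axis=1) @ C
        dcands += dpre[..., None] * u1

        # self candidate
        if self.self_term == "content":
            dC_acc[side] += dcands[:, 0]
        else:
            dH_prev[side] = dH_prev.get(side, 0) + dcands[:, 0]
        # the score concatenation uses C regardless of the self-term choice
        dC_acc[side] += dpre.sum(axis=1)[:, None] * u[self.dim:]

        for r, (rel, nbr, Wn, WnT, has) in enumerate(plan, start=1):
            # rows without neighbors have zero attention weight and zero dpre,
            # so dcands[:, r] is already zero there
            dH_prev[nbr] = dH_prev.get(nbr, 0) + WnT @ dcands[:, r]

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, params=None):
        """Mean BCE over the pairs in X plus gradients for every parameter.

        Returns ``(loss, grads, probabilities)`` with ``grads`` an
        independent dict (safe to keep across calls).
        """
        loss, p = self._loss_grads_into(X, y, params)
        return loss, {k: v.copy() for k, v in self._grads.items()}, p

    def _loss_grads_into(self, X: np.ndarray, y: np.ndarray, params=None):
        """Fast path: gradients land in the persistent ``_grad_flat`` buffer."""
        params = self.params if params is None else params
        grads = self._grads
        self._grad_flat[:] = 0.0

        embeddings, cache = self.forward_embeddings(params)
        Fd = embeddings["drug"][X[:, 0]]
        Ft = embeddings["protein"][X[:, 1]]
        Z = np.hstack([Fd, Ft])
        A1 = Z @ params["fc1_W"].T + params["fc1_b"]
        H1 = np.maximum(A1, 0.0)
        logits = H1 @ params["fc2_W"] + params["fc2_b"][0]
        p = sigmoid(logits)
        pc = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
        yf = y.astype(float)
        loss = float(-np.mean(yf * np.log(pc) + (1.0 - yf) * np.log(1.0 - pc)))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        n = X.shape[0]
        dlogit = (p - yf) / n
        grads["fc2_W"] += H1.T @ dlogit
        grads["fc2_b"] += dlogit.sum()
        dH1 = np.outer(dlogit, params["fc2_W"])
        dA1 = dH1 * (A1 > 0)
        grads["fc1_W"] += dA1.T @ Z
        grads["fc1_b"] += dA1.sum(axis=0)
        dZ = dA1 @ params["fc1_W"]

        dF = {"drug": np.zeros_like(embeddings["drug"]),
              "protein": np.zeros_like(embeddings["protein"])}
        np.add.at(dF["drug"], X[:, 0], dZ[:, : self.dim])
        np.add.at(dF["protein"], X[:, 1], dZ[:, self.dim:])

        dC_acc = {t: np.zeros_like(cache["contents"][t]) for t in self.types}
        df1 = {t: np.zeros_like(cache["f1"][t]) for t in self.types}

        dH_cur = {"drug": dF["drug"], "protein": dF["protein"]}
        for layer in reversed(cache["layers"]):
            dH_prev: dict[str, np.ndarray] = {}
            for side in ("drug", "protein"):
                self._attention_layer_backward(
                    side, dH_cur[side], layer["caches"][side], params,
                    grads, dH_prev, dC_acc)
            is_first = layer is cache["layers"][0]
            dH_cur = {}
            for t, g in dH_prev.items():
                if t in ("drug", "protein") and not is_first:
                    dH_cur[t] = dH_cur.get(t, 0) + g
                else:
                    df1[t] += g

        for t in self.types:
            dX, dW, db = lstm_encode_backward(
                df1[t], cache["enc_caches"][t], params[f"lstm_{t}_W"])
            grads[f"lstm_{t}_W"] += dW
            grads[f"lstm_{t}_b"] += db
            dC_acc[t] += dX
            if f"content_{t}" in params:
                grads[f"content_{t}"] += dC_acc[t]

        return loss, p


class AdamOptimizer:
    """Plain Adam (beta1 0.9, beta2 0.999, eps 1e-8) over flat arrays.

    Updates run in place through preallocated scratch buffers; a step
    allocates nothing.
    """

    def __init__(self, n_params: int, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 dtype=np.float64):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params, dtype=dtype)
        self.v = np.zeros(n_params, dtype=dtype)
        self._s1 = np.empty(n_params, dtype=dtype)
        self._s2 = np.empty(n_params, dtype=dtype)
        self.t = 0

    def step(self, param_flat: np.ndarray, grad_flat: np.ndarray) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        m, v, s1, s2 = self.m, self.v, self._s1, self._s2
        m *= self.b1
        np.multiply(grad_flat, 1.0 - self.b1, out=s1)
        m += s1
        v *= self.b2
        np.square(grad_flat, out=s1)
        s1 *= 1.0 - self.b2
        v += s1
        np.divide(v, bc2, out=s2)
        np.sqrt(s2, out=s2)
        s2 += self.eps
        np.divide(m, bc1, out=s1)
        s1 /= s2
        s1 *= self.lr
        param_flat -= s1


def train_network(net: HGDTINetwork, X: np.ndarray, y: np.ndarray,
                  lr: float = 1e-3, tol: float = 1e-4, max_epochs: int = 100,
                  batch_size: int | None = 32, seed: int | np.random.SeedSequence = 0,
                  patience: int = 3) -> list[float]:
    """Adam training until the epoch-loss change stays below ``tol``.

    Seeded mini-batches over pairs with the whole graph's embeddings (and
    their gradients) recomputed for every batch; ``batch_size=None`` trains
    full-batch.  With stochastic mini-batch losses a single small
    epoch-to-epoch change is not convergence, so training stops only after
    ``patience`` consecutive sub-``tol`` changes (or at ``max_epochs``).
    Returns the loss trace (one mean loss per epoch).
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes in the dataset")
    opt = AdamOptimizer(net.param_flat.size, lr=lr, dtype=net.param_flat.dtype)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    quiet = 0
    for _ in range(max_epochs):
        if batch_size is None:
            loss, _ = net._loss_grads_into(X, y)
            opt.step(net.param_flat, net._grad_flat)
            epoch_loss = loss
        else:
            order = rng.permutation(len(y))
            total = 0.0
            for start in range(0, len(y), batch_size):
                idx = order[start:start + batch_size]
                loss, _ = net._loss_grads_into(X[idx], y[idx])
                opt.step(net.param_flat, net._grad_flat)
                total += loss * len(idx)
            epoch_loss = total / len(y)  # sample-weighted over uneven batches
        trace.append(epoch_loss)
        if len(trace) > 1:
            quiet = quiet + 1 if abs(trace[-1] - trace[-2]) < tol else 0
            if quiet >= patience:
                break
    return trace
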