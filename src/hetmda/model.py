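"""GCN + attention-reinforcement + bilinear-decoder link-prediction model.

Architecture (all matrices dense; node order: miRNAs then diseases):

1. One graph-convolution layer over the heterogeneous graph produces the
   initial embedding ``F = ReLU(A_hat @ A_F @ W0)`` where ``A_hat`` is the
   symmetrically normalized heterogeneous adjacency and ``A_F`` the
   RWR-derived feature matrix.
2. A reinforcement layer re-aggregates embeddings with attention
   coefficients over graph neighborhoods: ``e_ij = ReLU((W h_i)^T (W h_j))``
   for ``j`` in ``N_i``, ``a_ij = softmax_j(e_ij)``, ``H_i = sum_j a_ij h_j``.
   A quadratic penalty ``L_H = sum_i sum_{j in N_i} a_ij ||H_i - H_j||^2``
   pulls the embeddings of attended neighbors together.
3. A bilinear decoder scores every miRNA-disease pair:
   ``Y = sigmoid(H_r @ W' @ H_d^T)``.

Training minimizes ``L = L_cross + lambda * L_H`` by full-batch gradient
descent, where ``L_cross`` is the summed binary cross-entropy over the
verified positives and the (sampled or full) unknown pairs.  Gradients are
derived analytically and verified against finite differences in the test
suite.  With a fixed seed the whole run is bit-reproducible.

Two ablation switches mirror the model's design questions: the
reinforcement layer can be replaced by a plain second GCN hidden layer
(``reinforce_mode="gcn"``), and the RWR features by raw similarity rows
(``use_rwr=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .graph import (
    AssociationData,
    HeteroAdjacency,
    NormalizedAdjacency,
    SimilarityMatrix,
    build_hetero_adjacency,
    symmetric_normalize,
)
from .rwr import CombinedFeatures, RestartConfig, build_feature_matrix, rwr_feature_matrix

__all__ = [
    "ModelConfig",
    "GCNWeights",
    "Embedding",
    "AttentionState",
    "DecoderState",
    "LossReport",
    "ModelState",
    "gcn_layer",
    "neighborhoods_from_adjacency",
    "attention_coefficients",
    "reinforce",
    "reinforcement_loss",
    "decode",
    "cross_entropy_loss",
    "train",
    "predict",
]

EPS = 1e-12


@dataclass
class ModelConfig:
    """Hyperparameters of the link-prediction model.

    Attributes
    ----------
    h
        Embedding dimension (hidden-layer width).
    lambda_reinforce
        Weight of the reinforcement penalty in the total loss.
    learning_rate
        Fixed step size of plain gradient descent.
    epochs
        Number of full-batch descent steps.
    neg_ratio
        ``None`` trains on every unknown pair; an integer ``r`` samples
        ``r`` unknowns per positive (seeded) once before training.
    seed
        Seed for parameter initialization and negative sampling.
    neighbor_rule
        ``"nonzero"`` takes all off-diagonal nonzero entries of A_H as the
        neighborhood; ``"top_k"`` keeps only the ``k`` strongest.
    top_k
        Neighborhood size when ``neighbor_rule="top_k"``.
    attention_score
        ``"dot"``: e_ij = ReLU((W h_i)^T (W h_j));
        ``"concat"``: e_ij = ReLU(a^T [W h_i || W h_j]).
    reinforce_mode
        ``"attention"`` for the reinforcement layer, ``"gcn"`` for a plain
        second GCN hidden layer (ablation).
    use_rwr
        Use RWR features as A_F; ``False`` uses raw similarity rows.
    feature_placement
        Block placement of RM/RD inside A_F.
    """

    h: int = 32
    lambda_reinforce: float = 0.1
    learning_rate: float = 0.01
    epochs: int = 500
    neg_ratio: int | None = None
    seed: int = 0
    neighbor_rule: str = "nonzero"
    top_k: int = 10
    attention_score: str = "dot"
    reinforce_mode: str = "attention"
    use_rwr: bool = True
    feature_placement: str = "diagonal"

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("embedding dimension h must be >= 1")
        if self.lambda_reinforce < 0:
            raise ValueError("lambda_reinforce must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.neighbor_rule not in ("nonzero", "top_k"):
            raise ValueError(f"unknown neighbor_rule {self.neighbor_rule!r}")
        if self.attention_score not in ("dot", "concat"):
            raise ValueError(f"unknown attention_score {self.attention_score!r}")
        if self.reinforce_mode not in ("attention", "gcn"):
            raise ValueError(f"unknown reinforce_mode {self.reinforce_mode!r}")


@dataclass
class GCNWeights:
    """Input-to-hidden weight matrix W0 of shape (m+n, h)."""

    w0: np.ndarray


@dataclass
class Embedding:
    """(m+n) x h node embedding (F after the GCN, H after reinforcement)."""

    values: np.ndarray


@dataclass
class AttentionState:
    """Neighborhoods, raw scores and softmax coefficients of the attention layer.

    ``mask`` is the boolean neighbor indicator (i, j); ``scores`` the raw
    e_ij and ``coefficients`` the row-softmax a_ij, both zero outside the
    mask.  ``agg`` is the aggregation matrix actually applied to the
    embedding: equal to ``coefficients`` except that a node with an empty
    neighborhood keeps its own embedding (identity fallback row).
    """

    w_att: np.ndarray
    mask: np.ndarray
    scores: np.ndarray | None = None
    coefficients: np.ndarray | None = None
    agg: np.ndarray | None = None
    att_vec: np.ndarray | None = None  # concat-score variant only
    score_form: str = "dot"

    def neighborhood(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.mask[i])


@dataclass
class DecoderState:
    """Bilinear decoder: trainable h x h matrix W' and the m x n score matrix."""

    w_prime: np.ndarray
    scores: np.ndarray | None = None


@dataclass
class LossReport:
    """Per-epoch loss components of a training run."""

    cross_entropy: list[float] = field(default_factory=list)
    reinforcement: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)


@dataclass
class ModelState:
    """Everything a trained model needs to score pairs."""

    config: ModelConfig
    w0: np.ndarray
    w_att: np.ndarray | None
    att_vec: np.ndarray | None
    w_hidden: np.ndarray | None
    w_prime: np.ndarray
    scores: np.ndarray
    embedding: np.ndarray
    mirna_names: list[str]
    disease_names: list[str]
    loss_report: LossReport


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------


def gcn_layer(
    features: CombinedFeatures | np.ndarray,
    norm_adj: NormalizedAdjacency | np.ndarray,
    weights: GCNWeights | np.ndarray,
) -> Embedding:
    """One graph-convolution layer: ``F = ReLU(A_hat @ A_F @ W0)``."""
    x = features.values if isinstance(features, CombinedFeatures) else np.asarray(features, float)
    a = norm_adj.values if isinstance(norm_adj, NormalizedAdjacency) else np.asarray(norm_adj, float)
    w = weights.w0 if isinstance(weights, GCNWeights) else np.asarray(weights, float)
    if a.shape[1] != x.shape[0] or x.shape[1] != w.shape[0]:
        raise ValueError(
            f"non-conformable shapes: adjacency {a.shape}, features {x.shape}, weights {w.shape}"
        )
    return Embedding(values=np.maximum(a @ x @ w, 0.0))


def neighborhoods_from_adjacency(
    adj: HeteroAdjacency | np.ndarray, rule: str = "nonzero", top_k: int = 10
) -> np.ndarray:
    """Boolean neighbor mask from the heterogeneous adjacency.

    Neighbors are the nonzero off-diagonal entries (similarity edges plus
    association edges).  ``rule="top_k"`` keeps, per row, only the ``k``
    largest weights.
    """
    a = adj.values if isinstance(adj, HeteroAdjacency) else np.asarray(adj, float)
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    mask = off != 0
    if rule == "top_k":
        keep = np.zeros_like(mask)
        for i in range(off.shape[0]):
            nz = np.flatnonzero(mask[i])
            if nz.size:
                order = nz[np.argsort(off[i, nz])[::-1][:top_k]]
                keep[i, order] = True
        mask = keep
    return mask


def attention_coefficients(emb: Embedding | np.ndarray, att: AttentionState) -> AttentionState:
    """Compute raw attention scores e_ij and softmax coefficients a_ij.

    The coefficients of every node with at least one neighbor sum to 1.
    Nodes with an empty neighborhood get an identity row in ``agg`` so that
    aggregation passes their embedding through unchanged.
    """
    f = emb.values if isinstance(emb, Embedding) else np.asarray(emb, float)
    g = f @ att.w_att.T  # row i = W h_i
    if att.score_form == "dot":
        raw = g @ g.T
    elif att.score_form == "concat":
        if att.att_vec is None:
            raise ValueError("concat score form requires att_vec")
        hdim = att.w_att.shape[0]
        p = g @ att.att_vec[:hdim]
        q = g @ att.att_vec[hdim:]
        raw = p[:, None] + q[None, :]
    else:
        raise ValueError(f"unknown score form {att.score_form!r}")
    e = np.where(att.mask, np.maximum(raw, 0.0), 0.0)
    # row-softmax over the neighborhood, numerically shifted
    neg_inf = np.full_like(e, -np.inf)
    logits = np.where(att.mask, e, neg_inf)
    has_nb = att.mask.any(axis=1)
    coeff = np.zeros_like(e)
    if has_nb.any():
        shifted = logits[has_nb] - logits[has_nb].max(axis=1, keepdims=True)
        ex = np.exp(shifted)
        ex[~att.mask[has_nb]] = 0.0
        coeff[has_nb] = ex / ex.sum(axis=1, keepdims=True)
    agg = coeff.copy()
    for i in np.flatnonzero(~has_nb):
        agg[i, i] = 1.0  # pass-through fallback
    return replace(att, scores=e, coefficients=coeff, agg=agg)


def reinforce(emb: Embedding | np.ndarray, att: AttentionState) -> Embedding:
    """Attention-weighted neighbor aggregation ``H_i = sum_j a_ij h_j``."""
    f = emb.values if isinstance(emb, Embedding) else np.asarray(emb, float)
    if att.agg is None:
        raise ValueError("attention coefficients not computed")
    return Embedding(values=att.agg @ f)


def reinforcement_loss(reinforced: Embedding | np.ndarray, att: AttentionState) -> float:
    """Quadratic attention-weighted disagreement penalty.

    ``sum_i sum_{j in N_i} a_ij ||H_i - H_j||^2`` — zero iff attended
    neighbors share identical embeddings; scales as t^2 under H -> tH.
    """
    h = reinforced.values if isinstance(reinforced, Embedding) else np.asarray(reinforced, float)
    if att.coefficients is None:
        raise ValueError("attention coefficients not computed")
    d2 = _pairwise_sq_dists(h)
    return float((att.coefficients * d2).sum())


def _pairwise_sq_dists(h: np.ndarray) -> np.ndarray:
    sq = (h * h).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (h @ h.T)
    return np.maximum(d2, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(reinforced: Embedding | np.ndarray, dec: DecoderState, m: int) -> np.ndarray:
    """Bilinear sigmoid decoder ``Y = sigmoid(H_r @ W' @ H_d^T)`` (m x n)."""
    h = reinforced.values if isinstance(reinforced, Embedding) else np.asarray(reinforced, float)
    hr, hd = h[:m], h[m:]
    if dec.w_prime.shape != (h.shape[1], h.shape[1]):
        raise ValueError(
            f"decoder matrix {dec.w_prime.shape} does not match embedding width {h.shape[1]}"
        )
    y = _sigmoid(hr @ dec.w_prime @ hd.T)
    dec.scores = y
    return y


def cross_entropy_loss(
    scores: np.ndarray,
    truth: np.ndarray,
    sample_mask: np.ndarray | None = None,
) -> float:
    """Summed binary cross-entropy over the sampled pairs.

    ``- sum [y log y' + (1 - y) log(1 - y')]`` with scores clipped to
    ``[1e-12, 1 - 1e-12]`` to stay finite.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, float)
    if sample_mask is None:
        sample_mask = np.ones_like(scores, dtype=bool)
    if not sample_mask.any():
        raise ValueError("empty sample set for cross-entropy loss")
    y = truth[sample_mask]
    p = np.clip(scores[sample_mask], EPS, 1.0 - EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class _Pipeline:
    """Fixed (non-trainable) quantities of a training problem."""

    p: np.ndarray  # A_hat @ A_F, the GCN input product
    a_hat: np.ndarray
    mask: np.ndarray  # neighbor mask
    truth: np.ndarray  # m x n binary
    sample_mask: np.ndarray  # m x n bool
    m: int
    n: int


def _build_pipeline(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    assoc: AssociationData,
    cfg: ModelConfig,
    rwr_cfg: RestartConfig | None,
) -> _Pipeline:
    adj = build_hetero_adjacency(sm, sd, assoc)
    a_hat = symmetric_normalize(adj).values
    if cfg.use_rwr:
        rm = rwr_feature_matrix(sm, rwr_cfg or RestartConfig())
        rd = rwr_feature_matrix(sd, rwr_cfg or RestartConfig())
    else:
        rm, rd = sm.values, sd.values  # ablation: raw similarity rows as features
    a_f = build_feature_matrix(rm, rd, placement=cfg.feature_placement).values
    mask = neighborhoods_from_adjacency(adj, rule=cfg.neighbor_rule, top_k=cfg.top_k)
    truth = assoc.matrix.astype(float)
    m, n = assoc.shape
    sample_mask = np.ones((m, n), dtype=bool)
    if cfg.neg_ratio is not None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        sample_mask = truth.astype(bool).copy()
        unknown = np.argwhere(truth == 0)
        n_neg = min(len(unknown), cfg.neg_ratio * int(truth.sum()))
        pick = rng.choice(len(unknown), size=n_neg, replace=False)
        for i, j in unknown[pick]:
            sample_mask[i, j] = True
    return _Pipeline(
        p=a_hat @ a_f, a_hat=a_hat, mask=mask, truth=truth, sample_mask=sample_mask, m=m, n=n
    )


def _init_params(pipe: _Pipeline, cfg: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    nn = pipe.m + pipe.n
    params = {"w0": _xavier(rng, nn, cfg.h), "w_prime": _xavier(rng, cfg.h, cfg.h)}
    if cfg.reinforce_mode == "attention":
        params["w_att"] = _xavier(rng, cfg.h, cfg.h)
        if cfg.attention_score == "concat":
            params["att_vec"] = _xavier(rng, 2 * cfg.h, 1)[:, 0]
    else:
        params["w_hidden"] = _xavier(rng, cfg.h, cfg.h)
    return params


def _forward_backward(
    params: dict[str, np.ndarray], pipe: _Pipeline, cfg: ModelConfig, want_grads: bool = True
) -> tuple[float, float, dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """One full forward pass; analytic gradients of L = L_ce + lambda*L_H.

    Returns (cross_entropy, reinforcement_loss, grads, scores Y, embedding H).
    """
    m, lam = pipe.m, cfg.lambda_reinforce
    s0 = pipe.p @ params["w0"]
    f = np.maximum(s0, 0.0)

    att = None
    if cfg.reinforce_mode == "attention":
        att = AttentionState(
            w_att=params["w_att"],
            mask=pipe.mask,
            att_vec=params.get("att_vec"),
            score_form=cfg.attention_score,
        )
        att = attention_coefficients(Embedding(f), att)
        h = att.agg @ f
        d2 = _pairwise_sq_dists(h)
        l_reinf = float((att.coefficients * d2).sum())
    else:
        s1 = pipe.a_hat @ f @ params["w_hidden"]
        h = np.maximum(s1, 0.0)
        l_reinf = 0.0

    hr, hd = h[:m], h[m:]
    logits = hr @ params["w_prime"] @ hd.T
    y = _sigmoid(logits)
    l_ce = cross_entropy_loss(y, pipe.truth, pipe.sample_mask)

    if not want_grads:
        return l_ce, l_reinf, {}, y, h

    grads: dict[str, np.ndarray] = {}
    dlogits = np.where(pipe.sample_mask, y - pipe.truth, 0.0)
    grads["w_prime"] = hr.T @ dlogits @ hd
    dh = np.zeros_like(h)
    dh[:m] = dlogits @ hd @ params["w_prime"].T
    dh[m:] = dlogits.T @ hr @ params["w_prime"]

    if cfg.reinforce_mode == "attention":
        coeff = att.coefficients
        # d L_H / dH with coefficients held fixed
        rs = coeff.sum(axis=1)
        cs = coeff.sum(axis=0)
        dh += lam * 2.0 * (rs[:, None] * h - coeff @ h + cs[:, None] * h - coeff.T @ h)
        # gradient through the aggregation H = agg @ F and direct d L_H / da
        da = (dh @ f.T) * pipe.mask + lam * d2 * pipe.mask
        # softmax backward (rows with neighbors only; fallback rows have zero coeff)
        t = (coeff * da).sum(axis=1, keepdims=True)
        de = coeff * (da - t)
        g = f @ params["w_att"].T
        if cfg.attention_score == "dot":
            raw = g @ g.T
            ds = np.where((raw > 0) & pipe.mask, de, 0.0)
            dg = (ds + ds.T) @ g
        else:
            hdim = cfg.h
            u, v = params["att_vec"][:hdim], params["att_vec"][hdim:]
            raw = (g @ u)[:, None] + (g @ v)[None, :]
            ds = np.where((raw > 0) & pipe.mask, de, 0.0)
            dp = ds.sum(axis=1)
            dq = ds.sum(axis=0)
            dg = dp[:, None] * u[None, :] + dq[:, None] * v[None, :]
            grads["att_vec"] = np.concatenate([g.T @ dp, g.T @ dq])
        grads["w_att"] = dg.T @ f
        df = att.agg.T @ dh + dg @ params["w_att"]
    else:
        ds1 = np.where(s1 > 0, dh, 0.0)
        grads["w_hidden"] = (pipe.a_hat @ f).T @ ds1
        df = pipe.a_hat.T @ ds1 @ params["w_hidden"].T

    ds0 = np.where(s0 > 0, df, 0.0)
    grads["w0"] = pipe.p.T @ ds0
    return l_ce, l_reinf, grads, y, h


def train(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    assoc: AssociationData,
    cfg: ModelConfig | None = None,
    rwr_cfg: RestartConfig | None = None,
) -> ModelState:
    """Train the full pipeline end-to-end by plain gradient descent.

    Deterministic for a fixed ``cfg.seed``: two runs with identical inputs
    and config produce bit-identical loss histories and parameters.

    Raises
    ------
    FloatingPointError
        if the loss becomes non-finite, reporting the epoch.
    """
    cfg = cfg or ModelConfig()
    pipe = _build_pipeline(sm, sd, assoc, cfg, rwr_cfg)
    params = _init_params(pipe, cfg)
    report = LossReport()
    lr = cfg.learning_rate
    for epoch in range(cfg.epochs):
        l_ce, l_reinf, grads, y, h = _forward_backward(params, pipe, cfg)
        total = l_ce + cfg.lambda_reinforce * l_reinf
        if not np.isfinite(total):
            raise FloatingPointError(f"training diverged at epoch {epoch}: loss={total}")
        report.cross_entropy.append(l_ce)
        report.reinforcement.append(l_reinf)
        report.total.append(total)
        for name, grad in grads.items():
            params[name] = params[name] - lr * grad
    # final forward with updated parameters
    l_ce, l_reinf, _, y, h = _forward_backward(params, pipe, cfg, want_grads=False)
    return ModelState(
        config=cfg,
        w0=params["w0"],
        w_att=params.get("w_att"),
        att_vec=params.get("att_vec"),
        w_hidden=params.get("w_hidden"),
        w_prime=params["w_prime"],
        scores=y,
        embedding=h,
        mirna_names=list(assoc.mirna_names),
        disease_names=list(assoc.disease_names),
        loss_report=report,
    )


def predict(
    model: ModelState, pairs: Iterable[tuple[str, str]] | None = None
) -> list[tuple[str, str, float]]:
    """Scores for the requested (miRNA name, disease name) pairs.

    ``pairs=None`` returns all m*n pairs in row-major order.
    """
    mi = {name: i for i, name in enumerate(model.mirna_names)}
    di = {name: j for j, name in enumerate(model.disease_names)}
    if pairs is None:
        pairs = [(r, d) for r in model.mirna_names for d in model.disease_names]
    out = []
    for r, d in pairs:
        if r not in mi:
            raise KeyError(f"unknown miRNA name {r!r}")
        if d not in di:
            raise KeyError(f"unknown disease name {d!r}")
        out.append((r, d, float(model.scores[mi[r], di[d]])))
    return out
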