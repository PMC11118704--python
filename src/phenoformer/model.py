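"""Bidirectional transformer encoder with a tied output head, in numpy.

The encoder follows the pre-norm block composition

    x_bar = LayerNorm(x);  m = MultiHead(x_bar) + x
    m_bar = LayerNorm(m);  out = FeedForward(m_bar) + m

with multi-head scaled dot-product attention, a GELU feed-forward expansion,
a final layer norm after the last block, and output scores S = X_L W_e^T
tied to the token-embedding table.  Slot-wise legal-set masking confines the
softmax of each position to the tokens that may legally occur there (bin
tokens at gene slots, a field's categories at its phenotype slot).

Both the forward pass and the exact analytic backward pass are implemented
here; gradients are verified against finite differences in the test suite.
PAD slots are embedded but excluded from attention keys and from the loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import CorruptedCells, SoftLabelSpec, Vocabulary
from .errors import ParameterError, ValidationError

NEG = -1e30  # additive logit/attention mask for illegal entries


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden`` must be divisible by ``n_heads``; the per-head width is
    ``hidden // n_heads``.  ``attn_scale`` selects the attention-score
    normalization: "sqrt" (1/sqrt(d), the conventional choice) or "dim"
    (1/d).  The desk-scale reference configuration is 4 layers, hidden 128,
    4 heads, 10 bins.
    """

    n_layers: int = 4
    hidden: int = 128
    n_heads: int = 4
    B: int = 10
    T: int = 64
    F: int = 4
    vocab_size: int = 0
    ffn_mult: int = 4
    dropout: float = 0.1
    attn_scale: str = "sqrt"

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads:
            raise ParameterError("hidden width must be divisible by n_heads")
        if min(self.n_layers, self.hidden, self.n_heads, self.B, self.T, self.F) < 0:
            raise ParameterError("config dimensions must be non-negative")
        if self.attn_scale not in ("sqrt", "dim"):
            raise ParameterError("attn_scale must be 'sqrt' or 'dim'")

    @property
    def d_head(self) -> int:
        return self.hidden // self.n_heads

    @property
    def seq_len(self) -> int:
        return self.F + self.T

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))

    @classmethod
    def for_cells(cls, cells, **overrides) -> "ModelConfig":
        """Config whose F/T/B/vocab_size match a tokenized-cell batch."""
        return cls(
            B=cells.vocab.B,
            T=cells.T,
            F=cells.F,
            vocab_size=cells.vocab.size,
            **overrides,
        )


ParameterSet = dict[str, np.ndarray]


def init_params(
    cfg: ModelConfig, rng: np.random.Generator, dtype=np.float64
) -> ParameterSet:
    """Gaussian(0, 0.02) weights, unit layer-norm gains, zero biases."""
    h, ff = cfg.hidden, cfg.ffn_mult * cfg.hidden
    p: ParameterSet = {
        "We": rng.normal(0, 0.02, (cfg.vocab_size, h)),
        "Wp": rng.normal(0, 0.02, (cfg.seq_len, h)),
        "lnf.g": np.ones(h),
        "lnf.b": np.zeros(h),
    }
    for i in range(cfg.n_layers):
        L = f"L{i}."
        p[L + "ln1.g"] = np.ones(h)
        p[L + "ln1.b"] = np.zeros(h)
        for w in ("Wq", "Wk", "Wv", "Wo"):
            p[L + w] = rng.normal(0, 0.02, (h, h))
            p[L + w.replace("W", "b")] = np.zeros(h)
        p[L + "ln2.g"] = np.ones(h)
        p[L + "ln2.b"] = np.zeros(h)
        p[L + "W1"] = rng.normal(0, 0.02, (h, ff))
        p[L + "b1"] = np.zeros(ff)
        p[L + "W2"] = rng.normal(0, 0.02, (ff, h))
        p[L + "b2"] = np.zeros(h)
    return {k: v.astype(dtype) for k, v in p.items()}


# -- primitive layers --------------------------------------------------------

_LN_EPS = 1e-5


def _ln_fwd(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(tuple(range(dy.ndim - 1)))
    db = dy.sum(tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


_GELU_C = float(np.sqrt(2.0 / np.pi))  # python float: keeps float32 arrays float32


def _gelu(x: np.ndarray) -> np.ndarray:
    """tanh-approximation GELU (the common transformer variant)."""
    t = np.tanh(_GELU_C * (x + 0.044715 * x * x * x))
    return 0.5 * x * (1.0 + t)


def _gelu_grad_from_t(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """d/dx of the tanh-approximation GELU, reusing t = tanh(.) from forward."""
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (
        1.0 + 3 * 0.044715 * x * x
    )


def _flat_mm(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """sum_{n,s} A[n,s,:]^T B[n,s,:] as one BLAS call."""
    return np.ascontiguousarray(A).reshape(-1, A.shape[-1]).T @ np.ascontiguousarray(
        B
    ).reshape(-1, B.shape[-1])


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(-1, keepdims=True)


def attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    attn_mask: np.ndarray | None = None,
    scale: str = "sqrt",
) -> np.ndarray:
    """Single-head scaled dot-product attention on S x d matrices.

    ``attn_mask`` is a boolean vector over key positions (True = usable).
    Each output row is a convex combination of the unmasked V rows; a query
    with no usable keys yields a zero row.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    d = Q.shape[-1]
    s = scores = Q @ K.T / (np.sqrt(d) if scale == "sqrt" else d)
    if attn_mask is not None:
        attn_mask = np.asarray(attn_mask, dtype=bool)
        if not attn_mask.any():
            return np.zeros_like(V[: Q.shape[0]])
        s = np.where(attn_mask[None, :], scores, NEG)
    return _softmax(s) @ V


# -- full forward/backward ---------------------------------------------------


def build_legal_bias(vocab: Vocabulary, slot_classes: list[str]) -> np.ndarray:
    """(seq_len, vocab_size) additive bias: 0 on each slot's legal tokens, a
    large negative constant elsewhere (including PAD and MASK)."""
    S, V = len(slot_classes), vocab.size
    bias = np.full((S, V), NEG)
    legal = vocab.legal_sets
    for s, cls in enumerate(slot_classes):
        bias[s, legal[cls]] = 0.0
    return bias


def embed_input(tokens: np.ndarray, params: ParameterSet) -> np.ndarray:
    """X0[b, t] = W_e[token] + W_p[t]."""
    tokens = np.asarray(tokens)
    if tokens.max() >= params["We"].shape[0]:
        raise ParameterError("token id outside the embedding table")
    return params["We"][tokens] + params["Wp"][None, : tokens.shape[1], :]


def forward(
    params: ParameterSet,
    cfg: ModelConfig,
    tokens: np.ndarray,
    pad_mask: np.ndarray,
    legal_bias: np.ndarray | None = None,
    train: bool = False,
    drop_rng: np.random.Generator | None = None,
):
    """Run the encoder; returns (logits, hidden_states, cache).

    ``hidden_states`` are the final-norm outputs (n, S, h) — the
    contextualized embeddings.  ``cache`` carries every intermediate needed
    by :func:`backward`.
    """
    n, S = tokens.shape
    k, d, h = cfg.n_heads, cfg.d_head, cfg.hidden
    scale = float(1.0 / np.sqrt(d)) if cfg.attn_scale == "sqrt" else 1.0 / d
    keep = 1.0 - cfg.dropout if train and cfg.dropout > 0 else 1.0
    if train and cfg.dropout > 0 and drop_rng is None:
        raise ParameterError("training with dropout requires a seeded rng")

    x = embed_input(tokens, params)
    dt = x.dtype
    key_bias = np.where(pad_mask, NEG, 0.0).astype(dt)[:, None, None, :]  # (n,1,1,S)
    layers = []
    for i in range(cfg.n_layers):
        L = f"L{i}."
        xb, c1 = _ln_fwd(x, params[L + "ln1.g"], params[L + "ln1.b"])
        Q = (xb @ params[L + "Wq"] + params[L + "bq"]).reshape(n, S, k, d).transpose(0, 2, 1, 3)
        K = (xb @ params[L + "Wk"] + params[L + "bk"]).reshape(n, S, k, d).transpose(0, 2, 1, 3)
        Vv = (xb @ params[L + "Wv"] + params[L + "bv"]).reshape(n, S, k, d).transpose(0, 2, 1, 3)
        P = _softmax(Q @ K.swapaxes(-1, -2) * scale + key_bias)
        ctx = (P @ Vv).transpose(0, 2, 1, 3).reshape(n, S, h)
        proj = ctx @ params[L + "Wo"] + params[L + "bo"]
        dm_a = ((drop_rng.random(proj.shape) < keep) / keep).astype(dt) if keep < 1.0 else None
        if dm_a is not None:
            proj = proj * dm_a
        m = proj + x
        mb, c2 = _ln_fwd(m, params[L + "ln2.g"], params[L + "ln2.b"])
        f1 = mb @ params[L + "W1"] + params[L + "b1"]
        ef1 = np.tanh(_GELU_C * (f1 + 0.044715 * f1 * f1 * f1))
        a = 0.5 * f1 * (1.0 + ef1)
        f2 = a @ params[L + "W2"] + params[L + "b2"]
        dm_f = ((drop_rng.random(f2.shape) < keep) / keep).astype(dt) if keep < 1.0 else None
        if dm_f is not None:
            f2 = f2 * dm_f
        x_next = f2 + m
        layers.append((x, xb, c1, Q, K, Vv, P, ctx, dm_a, m, mb, c2, f1, ef1, a, dm_f))
        x = x_next
        if not np.isfinite(x).all():
            raise ValidationError(f"non-finite activations in block {i}")

    y, cf = _ln_fwd(x, params["lnf.g"], params["lnf.b"])
    logits = y @ params["We"].T
    if legal_bias is not None:
        logits = logits.astype(np.float64) + legal_bias[None]
    cache = (tokens, key_bias, scale, layers, x, y, cf)
    return logits, y, cache


def backward(
    dlogits: np.ndarray, params: ParameterSet, cfg: ModelConfig, cache
) -> ParameterSet:
    """Exact gradients of the scalar loss whose logit-gradient is ``dlogits``."""
    tokens, key_bias, scale, layers, x_top, y, cf = cache
    n, S = tokens.shape
    k, d, h = cfg.n_heads, cfg.d_head, cfg.hidden
    g: ParameterSet = {name: np.zeros_like(w) for name, w in params.items()}

    # tied head
    dy = dlogits @ params["We"]
    g["We"] += _flat_mm(dlogits, y)
    dx, g["lnf.g"], g["lnf.b"] = _ln_bwd(dy, cf)

    for i in reversed(range(cfg.n_layers)):
        L = f"L{i}."
        (x, xb, c1, Q, K, Vv, P, ctx, dm_a, m, mb, c2, f1, ef1, a, dm_f) = layers[i]
        # out = f2*dm + m
        df2 = dx * dm_f if dm_f is not None else dx
        dm = dx.copy()
        da = df2 @ params[L + "W2"].T
        g[L + "W2"] += _flat_mm(a, df2)
        g[L + "b2"] += df2.sum((0, 1))
        df1 = da * _gelu_grad_from_t(f1, ef1)
        dmb = df1 @ params[L + "W1"].T
        g[L + "W1"] += _flat_mm(mb, df1)
        g[L + "b1"] += df1.sum((0, 1))
        dm2, g[L + "ln2.g"], g[L + "ln2.b"] = _ln_bwd(dmb, c2)
        dm += dm2
        # m = proj*dm_a + x
        dproj = dm * dm_a if dm_a is not None else dm
        dx_res = dm
        dctx = dproj @ params[L + "Wo"].T
        g[L + "Wo"] += _flat_mm(ctx, dproj)
        g[L + "bo"] += dproj.sum((0, 1))
        dctx_h = dctx.reshape(n, S, k, d).transpose(0, 2, 1, 3)
        dP = dctx_h @ Vv.swapaxes(-1, -2)
        dV = P.swapaxes(-1, -2) @ dctx_h
        dscores = P * (dP - (dP * P).sum(-1, keepdims=True))
        dQ = dscores @ K * scale
        dK = dscores.swapaxes(-1, -2) @ Q * scale
        dxb = np.zeros_like(xb)
        for dmat, W, bname in ((dQ, "Wq", "bq"), (dK, "Wk", "bk"), (dV, "Wv", "bv")):
            dflat = dmat.transpose(0, 2, 1, 3).reshape(n, S, h)
            dxb += dflat @ params[L + W].T
            g[L + W] += _flat_mm(xb, dflat)
            g[L + bname] += dflat.sum((0, 1))
        dx1, g[L + "ln1.g"], g[L + "ln1.b"] = _ln_bwd(dxb, c1)
        dx = dx_res + dx1

    # embedding: X0 = We[tokens] + Wp
    np.add.at(g["We"], tokens, dx)
    g["Wp"][:S] += dx.sum(0)
    return g


# -- loss --------------------------------------------------------------------


def build_soft_targets(
    corrupted: CorruptedCells,
    vocab: Vocabulary,
    slot_classes: list[str],
    spec: SoftLabelSpec,
) -> np.ndarray:
    """Dense (n, S, V) soft-label tensor, nonzero only at masked positions."""
    n, S = corrupted.tokens.shape
    q = np.zeros((n, S, vocab.size))
    legal = vocab.legal_sets
    for s, cls in enumerate(slot_classes):
        rows = np.where(corrupted.masked[:, s])[0]
        if rows.size == 0:
            continue
        ids = legal[cls]
        if len(ids) == 1:
            q[rows, s, ids[0]] = 1.0
            continue
        q[np.ix_(rows, [s], ids)] = spec.r_smooth / (len(ids) - 1)
        q[rows, s, corrupted.labels[rows, s]] = 1.0 - spec.r_smooth
    return q


def masked_ce_loss(
    logits: np.ndarray,
    corrupted: CorruptedCells,
    vocab: Vocabulary,
    slot_classes: list[str],
    spec: SoftLabelSpec,
    return_dlogits: bool = False,
):
    """Mean soft-label cross-entropy over masked positions.

    Logits must already carry the legal-set bias.  Unmasked and PAD
    positions contribute nothing.  An all-unmasked batch yields 0.0.
    """
    n_masked = int(corrupted.masked.sum())
    if n_masked == 0:
        import warnings

        warnings.warn("no masked tokens in batch; loss defined as 0")
        zero = np.zeros_like(logits) if return_dlogits else None
        return (0.0, zero) if return_dlogits else 0.0
    q = build_soft_targets(corrupted, vocab, slot_classes, spec)
    shift = logits - logits.max(-1, keepdims=True)
    logp = shift - np.log(np.exp(shift).sum(-1, keepdims=True))
    loss = float(-(q * logp).sum() / n_masked)
    if not return_dlogits:
        return loss
    p = np.exp(logp)
    dlogits = (p - q) * corrupted.masked[:, :, None] / n_masked
    return loss, dlogits


def forward_logits(
    params: ParameterSet,
    cfg: ModelConfig,
    corrupted: CorruptedCells,
    vocab: Vocabulary,
    slot_classes: list[str],
) -> np.ndarray:
    """Inference-mode logits with legal-set masking (no dropout)."""
    bias = build_legal_bias(vocab, slot_classes)
    logits, _, _ = forward(params, cfg, corrupted.tokens, corrupted.pad_mask, bias)
    return logits


def loss_and_grads(
    params: ParameterSet,
    cfg: ModelConfig,
    corrupted: CorruptedCells,
    vocab: Vocabulary,
    slot_classes: list[str],
    spec: SoftLabelSpec,
    train: bool = True,
    drop_rng: np.random.Generator | None = None,
):
    """One fused forward/backward pass; returns (loss, grads)."""
    bias = build_legal_bias(vocab, slot_classes)
    logits, _, cache = forward(
        params, cfg, corrupted.tokens, corrupted.pad_mask, bias,
        train=train, drop_rng=drop_rng,
    )
    loss, dlogits = masked_ce_loss(
        logits, corrupted, vocab, slot_classes, spec, return_dlogits=True
    )
    grads = backward(dlogits.astype(params["We"].dtype), params, cfg, cache)
    return loss, grads


# -- checkpointing -----------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | Path,
    params: ParameterSet,
    cfg: ModelConfig,
    vocab: Vocabulary,
    gene_slots: list[str],
) -> None:
    """Single-file archive of named weight arrays plus JSON metadata."""
    meta = json.dumps(
        {
            "version": CHECKPOINT_VERSION,
            "config": json.loads(cfg.to_json()),
            "vocab": json.loads(vocab.to_json()),
            "gene_slots": gene_slots,
        }
    )
    np.savez_compressed(path, __meta__=np.array(meta), **params)


def load_checkpoint(path: str | Path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    vocab = Vocabulary(B=meta["vocab"]["B"], schema=meta["vocab"]["schema"])
    return params, cfg, vocab, meta["gene_slots"]
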