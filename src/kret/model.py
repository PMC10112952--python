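"""Mask-self-attention transformer encoder with a relation-classification head.

The encoder is a standard BERT-style stack — token + position + segment
embeddings, L layers of multi-head self-attention and feed-forward blocks
with residuals and layer normalization — with two changes:

* position embeddings are indexed by *soft* (tree) positions, which may
  repeat across trunk and branch tokens;
* attention receives an additive mask built from the visible matrix
  (0 where visible, a large negative constant where invisible), so a token
  attends only to positions on its own trunk-or-branch path.

Classification reads the hidden state at the CLS position through a tanh
pooler and a linear head; training minimizes class-weighted cross-entropy.

The implementation is pure NumPy (float32 by default, float64 for
oracle-grade comparisons) with hand-written backprop, sized
for desk-scale experiments; parameters live in a flat name -> array dict so
checkpoints are a transparent tensor manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seeing import CLS_TOKEN, PAD_TOKEN, FlattenedInput

logger = logging.getLogger(__name__)

NEG_INF = -1e9  # additive-mask realization of "invisible"
UNK_TOKEN = "[UNK]"


class Vocabulary:
    """Token -> id mapping with PAD/CLS/UNK specials at fixed ids."""

    def __init__(self, tokens: Iterable[str] = ()) -> None:
        self._ids: dict[str, int] = {PAD_TOKEN: 0, CLS_TOKEN: 1, UNK_TOKEN: 2}
        for tok in tokens:
            self.add(tok)

    def add(self, token: str) -> int:
        return self._ids.setdefault(token, len(self._ids))

    def __len__(self) -> int:
        return len(self._ids)

    def __getitem__(self, token: str) -> int:
        return self._ids.get(token, self._ids[UNK_TOKEN])

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self[t] for t in tokens], dtype=np.int64)

    def tokens(self) -> list[str]:
        """All known tokens in id order (specials included)."""
        return list(self._ids)


@dataclass
class ModelConfig:
    vocab_size: int
    n_labels: int
    hidden: int = 64
    layers: int = 2
    heads: int = 2
    max_len: int = 64
    ffn_mult: int = 4
    class_weights: np.ndarray | None = None
    dropout: float = 0.0
    seed: int = 0
    init_scale: float = 0.02
    dtype: str = "float32"  # float64 available for oracle-grade comparisons

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError("hidden width must be divisible by the head count")
        if self.class_weights is None:
            self.class_weights = np.ones(self.n_labels)
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if len(self.class_weights) != self.n_labels:
            raise ValueError("need one class weight per label")
        if np.any(self.class_weights <= 0):
            raise ValueError("class weights must be positive")


# ---------------------------------------------------------------------------
# primitives

def attention_mask(visible: np.ndarray) -> np.ndarray:
    """Additive mask from a boolean visible matrix: 0 visible, -1e9 not.

    A row with no visible positions would make softmax degenerate; such rows
    fall back to self-only attention (diagonal forced visible) with a log.
    """
    vis = np.asarray(visible, dtype=bool).copy()
    if vis.ndim < 2 or vis.shape[-1] != vis.shape[-2]:
        raise ValueError("visible matrix must be square")
    rows_empty = ~vis.any(axis=-1)
    if rows_empty.any():
        logger.warning(
            "%d all-invisible rows; falling back to self-only attention",
            int(rows_empty.sum()),
        )
        eye = np.eye(vis.shape[-1], dtype=bool)
        vis = vis | (rows_empty[..., None] & eye)
    return np.where(vis, 0.0, NEG_INF)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def mask_self_attention(
    queries: np.ndarray,
    keys: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Scaled dot-product attention with an additive visibility mask.

    ``mask`` holds 0 at visible pairs and a large negative number at
    invisible ones; after softmax, invisible positions carry ~0 weight, so
    each output row is a convex combination of value rows at visible
    positions only.
    """
    d = queries.shape[-1]
    scores = queries @ np.swapaxes(keys, -1, -2) * float(1.0 / np.sqrt(d)) + mask
    return softmax(scores) @ values


_GELU_C = float(np.sqrt(2.0 / np.pi))


def _gelu_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.tanh(_GELU_C * (x + 0.044715 * (x * x * x)))
    return 0.5 * x * (1.0 + t), t


def gelu(x: np.ndarray) -> np.ndarray:
    return _gelu_forward(x)[0]


def _gelu_grad(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    # t = tanh term cached from the forward pass
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (
        1.0 + 3 * 0.044715 * (x * x)
    )


def _outer_grad(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Gradient of ``a @ W`` w.r.t. W summed over batch/time: a^T d via BLAS."""
    k = a.shape[-1]
    return a.reshape(-1, k).T @ d.reshape(-1, d.shape[-1])


def _ln_forward(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


# ---------------------------------------------------------------------------
# the encoder

class MaskTransformer:
    """BERT-style encoder over masked attention, with manual gradients."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else init_params(config)
        self._cache: dict | None = None

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        ids: np.ndarray,
        soft: np.ndarray,
        seg: np.ndarray,
        visible: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Return per-label scores, shape (batch, n_labels)."""
        p, cfg = self.params, self.config
        if ids.max() >= cfg.vocab_size:
            raise ValueError("token id outside vocabulary")
        if soft.max() >= p["emb/pos"].shape[0]:
            raise ValueError("soft position outside the position table")
        B, T = ids.shape
        cache: dict = {"ids": ids, "soft": soft, "seg": seg, "layers": []}

        x = p["emb/token"][ids] + p["emb/pos"][soft] + p["emb/seg"][seg]
        x, cache["emb_ln"] = _ln_forward(x, p["emb/ln_g"], p["emb/ln_b"])
        x, cache["emb_drop"] = self._dropout(x, train, rng)

        add_mask = attention_mask(visible).astype(x.dtype)[:, None, :, :]  # (B,1,T,T)
        cache["add_mask"] = add_mask
        for layer in range(cfg.layers):
            x = self._layer_forward(layer, x, add_mask, cache, train, rng)

        cache["h_final"] = x
        h0 = x[:, 0, :]
        pooled_pre = h0 @ p["pooler/w"] + p["pooler/b"]
        pooled = np.tanh(pooled_pre)
        logits = pooled @ p["cls/w"] + p["cls/b"]
        cache.update(h0=h0, pooled=pooled)
        self._cache = cache
        return logits

    def _dropout(self, x, train, rng):
        rate = self.config.dropout
        if not train or rate <= 0.0:
            return x, None
        if rng is None:
            raise ValueError("training with dropout requires an rng")
        keep = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.dtype)
        return x * keep, keep

    def _layer_forward(self, layer, x, add_mask, cache, train, rng):
        p, cfg = self.params, self.config
        nh, dh = cfg.heads, cfg.hidden // cfg.heads
        B, T, H = x.shape
        lp = f"layer{layer}/"

        q = x @ p[lp + "attn/wq"] + p[lp + "attn/bq"]
        k = x @ p[lp + "attn/wk"] + p[lp + "attn/bk"]
        v = x @ p[lp + "attn/wv"] + p[lp + "attn/bv"]

        def heads(t):
            return t.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        qh, kh, vh = heads(q), heads(k), heads(v)
        scores = qh @ kh.transpose(0, 1, 3, 2) * float(1.0 / np.sqrt(dh)) + add_mask
        attn = softmax(scores)
        ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, H)
        attn_out = ctx @ p[lp + "attn/wo"] + p[lp + "attn/bo"]
        attn_out, drop1 = self._dropout(attn_out, train, rng)
        x1, ln1 = _ln_forward(x + attn_out, p[lp + "ln1_g"], p[lp + "ln1_b"])

        ff_pre = x1 @ p[lp + "ffn/w1"] + p[lp + "ffn/b1"]
        ff_act, ff_tanh = _gelu_forward(ff_pre)
        ff = ff_act @ p[lp + "ffn/w2"] + p[lp + "ffn/b2"]
        ff, drop2 = self._dropout(ff, train, rng)
        x2, ln2 = _ln_forward(x1 + ff, p[lp + "ln2_g"], p[lp + "ln2_b"])

        cache["layers"].append(
            dict(x=x, qh=qh, kh=kh, vh=vh, attn=attn, ctx=ctx, ln1=ln1,
                 x1=x1, ff_pre=ff_pre, ff_act=ff_act, ff_tanh=ff_tanh,
                 ln2=ln2, drop1=drop1, drop2=drop2)
        )
        return x2

    # -- backward -----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss w.r.t. every parameter.

        Must follow a ``forward`` call on the same batch.
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        p, cfg, cache = self.params, self.config, self._cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        pooled, h0 = cache["pooled"], cache["h0"]
        grads["cls/w"] = pooled.T @ dlogits
        grads["cls/b"] = dlogits.sum(0)
        dpooled = dlogits @ p["cls/w"].T
        dpooled_pre = dpooled * (1.0 - pooled**2)
        grads["pooler/w"] = h0.T @ dpooled_pre
        grads["pooler/b"] = dpooled_pre.sum(0)
        dh0 = dpooled_pre @ p["pooler/w"].T

        dx = np.zeros_like(cache["h_final"])
        dx[:, 0, :] = dh0

        for layer in range(cfg.layers - 1, -1, -1):
            dx = self._layer_backward(layer, dx, cache["layers"][layer], grads)

        if cache["emb_drop"] is not None:
            dx = dx * cache["emb_drop"]
        dx, dg, db = _ln_backward(dx, cache["emb_ln"])
        grads["emb/ln_g"], grads["emb/ln_b"] = dg, db
        np.add.at(grads["emb/token"], cache["ids"], dx)
        np.add.at(grads["emb/pos"], cache["soft"], dx)
        np.add.at(grads["emb/seg"], cache["seg"], dx)
        return grads

    def _layer_backward(self, layer, dx2, lc, grads):
        p, cfg = self.params, self.config
        nh, dh = cfg.heads, cfg.hidden // cfg.heads
        lp = f"layer{layer}/"
        x, x1 = lc["x"], lc["x1"]
        B, T, H = x.shape

        dsum2, dg, db = _ln_backward(dx2, lc["ln2"])
        grads[lp + "ln2_g"], grads[lp + "ln2_b"] = dg, db
        dff = dsum2.copy()
        if lc["drop2"] is not None:
            dff = dff * lc["drop2"]
        grads[lp + "ffn/w2"] = _outer_grad(lc["ff_act"], dff)
        grads[lp + "ffn/b2"] = dff.sum((0, 1))
        dff_act = dff @ p[lp + "ffn/w2"].T
        dff_pre = dff_act * _gelu_grad(lc["ff_pre"], lc["ff_tanh"])
        grads[lp + "ffn/w1"] = _outer_grad(x1, dff_pre)
        grads[lp + "ffn/b1"] = dff_pre.sum((0, 1))
        dx1 = dsum2 + dff_pre @ p[lp + "ffn/w1"].T

        dsum1, dg, db = _ln_backward(dx1, lc["ln1"])
        grads[lp + "ln1_g"], grads[lp + "ln1_b"] = dg, db
        dattn_out = dsum1.copy()
        if lc["drop1"] is not None:
            dattn_out = dattn_out * lc["drop1"]
        grads[lp + "attn/wo"] = _outer_grad(lc["ctx"], dattn_out)
        grads[lp + "attn/bo"] = dattn_out.sum((0, 1))
        dctx = (dattn_out @ p[lp + "attn/wo"].T).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        attn, vh = lc["attn"], lc["vh"]
        dattn = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
        dscores *= float(1.0 / np.sqrt(dh))
        dqh = dscores @ lc["kh"]
        dkh = dscores.transpose(0, 1, 3, 2) @ lc["qh"]

        def merge(t):
            return t.transpose(0, 2, 1, 3).reshape(B, T, H)

        dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
        grads[lp + "attn/wq"] = _outer_grad(x, dq)
        grads[lp + "attn/bq"] = dq.sum((0, 1))
        grads[lp + "attn/wk"] = _outer_grad(x, dk)
        grads[lp + "attn/bk"] = dk.sum((0, 1))
        grads[lp + "attn/wv"] = _outer_grad(x, dv)
        grads[lp + "attn/bv"] = dv.sum((0, 1))
        dx = (
            dsum1
            + dq @ p[lp + "attn/wq"].T
            + dk @ p[lp + "attn/wk"].T
            + dv @ p[lp + "attn/wv"].T
        )
        return dx


def init_params(config: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    H, F = config.hidden, config.ffn_mult * config.hidden
    s = config.init_scale
    dt = np.dtype(config.dtype)

    def w(*shape):
        return rng.normal(0.0, s, size=shape).astype(dt)

    p: dict[str, np.ndarray] = {
        "emb/token": w(config.vocab_size, H),
        # soft positions can run past max_len by one branch; small headroom
        "emb/pos": w(config.max_len + 8, H),
        "emb/seg": w(2, H),
        "emb/ln_g": np.ones(H, dt),
        "emb/ln_b": np.zeros(H, dt),
        "pooler/w": w(H, H),
        "pooler/b": np.zeros(H, dt),
        "cls/w": w(H, config.n_labels),
        "cls/b": np.zeros(config.n_labels, dt),
    }
    for i in range(config.layers):
        lp = f"layer{i}/"
        p.update({
            lp + "attn/wq": w(H, H), lp + "attn/bq": np.zeros(H, dt),
            lp + "attn/wk": w(H, H), lp + "attn/bk": np.zeros(H, dt),
            lp + "attn/wv": w(H, H), lp + "attn/bv": np.zeros(H, dt),
            lp + "attn/wo": w(H, H), lp + "attn/bo": np.zeros(H, dt),
            lp + "ln1_g": np.ones(H, dt), lp + "ln1_b": np.zeros(H, dt),
            lp + "ffn/w1": w(H, F), lp + "ffn/b1": np.zeros(F, dt),
            lp + "ffn/w2": w(F, H), lp + "ffn/b2": np.zeros(H, dt),
            lp + "ln2_g": np.ones(H, dt), lp + "ln2_b": np.zeros(H, dt),
        })
    return p


# ---------------------------------------------------------------------------
# batching, loss, checkpoints

@dataclass
class EncodedBatch:
    ids: np.ndarray        # (B, T) int64
    soft: np.ndarray       # (B, T) int64
    seg: np.ndarray        # (B, T) int64, all zeros for segment A
    visible: np.ndarray    # (B, T, T) bool
    labels: np.ndarray     # (B,) int64


def batch_inputs(
    flattened: Sequence[FlattenedInput],
    vocab: Vocabulary,
    label_ids: dict[str, int],
) -> EncodedBatch:
    """Stack equal-length flattened inputs into arrays (run truncate_pad first)."""
    lengths = {len(f) for f in flattened}
    if len(lengths) != 1:
        raise ValueError("flattened inputs must share one padded length")
    ids = np.stack([vocab.encode(f.tokens) for f in flattened])
    soft = np.stack([np.asarray(f.soft_pos, dtype=np.int64) for f in flattened])
    seg = np.zeros_like(ids)
    visible = np.stack([f.visible for f in flattened])
    labels = np.array([label_ids[f.label] for f in flattened], dtype=np.int64)
    return EncodedBatch(ids, soft, seg, visible, labels)


def forward_classify(model: MaskTransformer, batch: EncodedBatch, **kw) -> np.ndarray:
    """Per-label scores for a batch; deterministic given seed and weights."""
    return model.forward(batch.ids, batch.soft, batch.seg, batch.visible, **kw)


def weighted_loss(
    scores: np.ndarray, gold: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy, mean over the batch, plus d(loss)/d(scores).

    The loss is (1/B) sum_i w[y_i] * NLL_i, so uniform unit weights reduce to
    plain cross-entropy and doubling a class's weight doubles its summands.
    """
    gold = np.asarray(gold)
    if gold.min() < 0 or gold.max() >= scores.shape[1]:
        raise ValueError("gold label out of range")
    B = scores.shape[0]
    probs = softmax(scores)
    w = np.asarray(class_weights, dtype=float)[gold]
    nll = -np.log(probs[np.arange(B), gold] + 1e-300)
    loss = float((w * nll).mean())
    dscores = probs.copy()
    dscores[np.arange(B), gold] -= 1.0
    dscores *= (w / B)[:, None]
    return loss, dscores


def save_checkpoint(model: MaskTransformer, path: str | Path) -> None:
    """Write parameters as an .npz tensor manifest (names preserve layout)."""
    np.savez(Path(path), **model.params)


def load_checkpoint(
    path: str | Path, config: ModelConfig
) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Best-effort load: overlapping tensors copied, the rest seed-initialized.

    Returns (params, report) where report lists loaded / missing /
    ignored tensor names.  A name that matches but whose shape disagrees is a
    hard error naming the tensor.
    """
    params = init_params(config)
    with np.load(Path(path)) as ckpt:
        loaded, ignored = [], []
        for name in ckpt.files:
            if name not in params:
                ignored.append(name)
                continue
            if ckpt[name].shape != params[name].shape:
                raise ValueError(
                    f"shape mismatch for tensor {name!r}: "
                    f"checkpoint {ckpt[name].shape}, model {params[name].shape}"
                )
            params[name] = ckpt[name].copy()
            loaded.append(name)
    missing = [n for n in params if n not in loaded]
    report = {"loaded": sorted(loaded), "missing": sorted(missing), "ignored": sorted(ignored)}
    if missing:
        logger.info("checkpoint missing %d tensors; seed-initialized", len(missing))
    return params, report
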