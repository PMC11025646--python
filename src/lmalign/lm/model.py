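"""A small GPT-2-style causal transformer in NumPy (float64).

Pre-norm residual blocks: x -> x + Attn(LN1(x)) -> (+) MLP(LN2(.)), followed
by a final layer norm and an untied linear head over the vocabulary. The
forward pass, per-layer activation extraction, and the full analytic backward
pass (for Adam training) are implemented here; at the desk scales used
throughout (2-4 layers, 32-128 units) NumPy is entirely adequate.

Causality holds exactly, not just to rounding: attention scores at future
positions are masked to -inf before the softmax, so the attention weight on
any future value vector is exactly 0 and position t is bit-wise invariant to
tokens after t at every layer.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

from .config import InitScheme, TransformerConfig

__all__ = ["TransformerLM", "init_params"]

_LN_EPS = 1e-5
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------- primitives


def _layer_norm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv_std
    return g * xhat + b, (xhat, inv_std, g)


def _layer_norm_bwd(dy, cache):
    xhat, inv_std, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv_std * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _gelu_fwd(x):
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return x * phi, (x, phi)


def _gelu_bwd(dy, cache):
    x, phi = cache
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return dy * (phi + x * pdf)


def _attention_fwd(x, p, prefix, n_heads):
    B, T, D = x.shape
    dh = D // n_heads
    qkv = x @ p[f"{prefix}.wqkv"] + p[f"{prefix}.bqkv"]
    q, k, v = np.split(qkv, 3, axis=-1)

    def heads(a):  # [B, T, D] -> [B, H, T, dh]
        return a.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)

    q, k, v = heads(q), heads(k), heads(v)
    scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh)
    mask = np.tril(np.ones((T, T), dtype=bool))
    scores = np.where(mask, scores, -np.inf)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    A = e / e.sum(axis=-1, keepdims=True)  # rows over keys <= query position
    o = A @ v  # [B, H, T, dh]
    o_merged = o.transpose(0, 2, 1, 3).reshape(B, T, D)
    out = o_merged @ p[f"{prefix}.wo"] + p[f"{prefix}.bo"]
    cache = (x, q, k, v, A, o_merged, p[f"{prefix}.wqkv"], p[f"{prefix}.wo"], n_heads)
    return out, cache


def _attention_bwd(dout, cache, grads, prefix):
    x, q, k, v, A, o_merged, wqkv, wo, n_heads = cache
    B, T, D = x.shape
    dh = D // n_heads
    grads[f"{prefix}.wo"] += o_merged.reshape(-1, D).T @ dout.reshape(-1, D)
    grads[f"{prefix}.bo"] += dout.sum(axis=(0, 1))
    do = (dout @ wo.T).reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
    dA = do @ v.transpose(0, 1, 3, 2)
    dv = A.transpose(0, 1, 3, 2) @ do
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    scale = 1.0 / math.sqrt(dh)
    dq = dS @ k * scale
    dk = dS.transpose(0, 1, 3, 2) @ q * scale

    def merge(a):  # [B, H, T, dh] -> [B, T, D]
        return a.transpose(0, 2, 1, 3).reshape(B, T, D)

    dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
    grads[f"{prefix}.wqkv"] += x.reshape(-1, D).T @ dqkv.reshape(-1, 3 * D)
    grads[f"{prefix}.bqkv"] += dqkv.sum(axis=(0, 1))
    return dqkv @ wqkv.T


# ------------------------------------------------------------ initialization


def init_params(config: TransformerConfig, scheme: InitScheme, seed: int) -> dict:
    """Sample a parameter dict. Deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    C = config
    p: dict[str, np.ndarray] = {}

    if scheme.name == "gaussian":
        def w(*shape):
            return rng.normal(scheme.mean, scheme.sd, size=shape)
        vec = w
    else:
        def w(*shape):
            return rng.normal(0.0, 0.02, size=shape)
        def vec(*shape):
            return np.zeros(shape)

    p["wte"] = w(C.vocab_size, C.d_model)
    p["wpe"] = w(C.context_size, C.d_model)
    for i in range(C.n_layers):
        h = f"h{i}"
        for ln in ("ln1", "ln2"):
            p[f"{h}.{ln}.g"] = (
                w(C.d_model) if scheme.name == "gaussian" else np.ones(C.d_model)
            )
            p[f"{h}.{ln}.b"] = vec(C.d_model)
        p[f"{h}.attn.wqkv"] = w(C.d_model, 3 * C.d_model)
        p[f"{h}.attn.bqkv"] = vec(3 * C.d_model)
        p[f"{h}.attn.wo"] = w(C.d_model, C.d_model)
        p[f"{h}.attn.bo"] = vec(C.d_model)
        p[f"{h}.mlp.w1"] = w(C.d_model, C.d_ff)
        p[f"{h}.mlp.b1"] = vec(C.d_ff)
        p[f"{h}.mlp.w2"] = w(C.d_ff, C.d_model)
        p[f"{h}.mlp.b2"] = vec(C.d_model)
    p["lnf.g"] = w(C.d_model) if scheme.name == "gaussian" else np.ones(C.d_model)
    p["lnf.b"] = vec(C.d_model)
    p["head.w"] = w(C.d_model, C.vocab_size)
    p["head.b"] = vec(C.vocab_size)
    return p


# -------------------------------------------------------------------- model


class TransformerLM:
    """Causal transformer language model over integer token ids."""

    def __init__(self, config: TransformerConfig, params: dict):
        self.config = config
        self.params = params

    @classmethod
    def init(
        cls,
        config: TransformerConfig,
        scheme: InitScheme | None = None,
        seed: int = 0,
    ) -> "TransformerLM":
        return cls(config, init_params(config, scheme or InitScheme(), seed))

    # -- forward -----------------------------------------------------------

    def _check_ids(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.ndim == 1:
            ids = ids[None, :]
        if ids.shape[1] < 1 or ids.shape[1] > self.config.context_size:
            raise ValueError(
                f"sequence length must be in [1, {self.config.context_size}]"
            )
        if ids.min() < 0 or ids.max() >= self.config.vocab_size:
            raise ValueError("token id outside vocabulary")
        return ids

    def _forward(self, ids: np.ndarray, keep_caches: bool = False):
        p = self.params
        C = self.config
        B, T = ids.shape
        x = p["wte"][ids] + p["wpe"][:T]  # layer-0 activation: token + position
        layer_outputs = [x]
        caches = []
        for i in range(C.n_layers):
            h = f"h{i}"
            n1, c_ln1 = _layer_norm_fwd(x, p[f"{h}.ln1.g"], p[f"{h}.ln1.b"])
            a, c_attn = _attention_fwd(n1, p, f"{h}.attn", C.n_heads)
            x1 = x + a
            n2, c_ln2 = _layer_norm_fwd(x1, p[f"{h}.ln2.g"], p[f"{h}.ln2.b"])
            ff1 = n2 @ p[f"{h}.mlp.w1"] + p[f"{h}.mlp.b1"]
            g, c_gelu = _gelu_fwd(ff1)
            m = g @ p[f"{h}.mlp.w2"] + p[f"{h}.mlp.b2"]
            x = x1 + m
            layer_outputs.append(x)
            if keep_caches:
                caches.append((c_ln1, c_attn, x1, c_ln2, n2, c_gelu, g))
        hf, c_lnf = _layer_norm_fwd(x, p["lnf.g"], p["lnf.b"])
        logits = hf @ p["head.w"] + p["head.b"]
        return logits, layer_outputs, (caches, c_lnf, hf, ids)

    def logits(self, tokens) -> np.ndarray:
        """Next-token logits, shape [T, vocab] for a 1-D token sequence."""
        ids = self._check_ids(tokens)
        out, _, _ = self._forward(ids)
        return out[0] if np.asarray(tokens).ndim == 1 else out

    def log_probs(self, tokens) -> np.ndarray:
        """Per-position next-token natural-log probabilities [T, vocab];
        each row exponentiates to a distribution summing to 1."""
        lg = self.logits(tokens)
        lg = lg - lg.max(axis=-1, keepdims=True)
        return lg - np.log(np.exp(lg).sum(axis=-1, keepdims=True))

    def log2_next_token_probs(self, tokens) -> np.ndarray:
        """Scorer protocol for perplexity evaluation: base-2 log probs."""
        return self.log_probs(tokens) / math.log(2.0)

    def layer_activations(self, tokens) -> list[np.ndarray]:
        """Per-layer activations for a 1-D token sequence.

        Returns ``n_layers + 1`` matrices of shape [T, d_model]; index 0 is
        the embedding output (token + position), index i the output of
        residual block i.
        """
        ids = self._check_ids(np.asarray(tokens))
        if np.asarray(tokens).ndim != 1:
            raise ValueError("layer_activations expects a single sequence")
        _, layers, _ = self._forward(ids)
        acts = [a[0] for a in layers]
        for a in acts:
            if not np.all(np.isfinite(a)):
                raise FloatingPointError("non-finite activation")
        return acts

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(self, ids: np.ndarray):
        """Mean next-token cross-entropy (nats) over a [B, T+1] batch and the
        gradient dict (same keys as params)."""
        ids = np.asarray(ids, dtype=np.int64)
        inputs, targets = ids[:, :-1], ids[:, 1:]
        inputs = self._check_ids(inputs)
        p = self.params
        C = self.config
        logits, _, (caches, c_lnf, hf, _) = self._forward(inputs, keep_caches=True)
        B, T, V = logits.shape
        shifted = logits - logits.max(axis=-1, keepdims=True)
        expl = np.exp(shifted)
        Z = expl.sum(axis=-1, keepdims=True)
        logp = shifted - np.log(Z)
        n = B * T
        bi = np.arange(B)[:, None]
        ti = np.arange(T)[None, :]
        loss = float(-logp[bi, ti, targets].mean())

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = expl / Z
        dlogits[bi, ti, targets] -= 1.0
        dlogits /= n

        grads["head.w"] += hf.reshape(-1, C.d_model).T @ dlogits.reshape(-1, V)
        grads["head.b"] += dlogits.sum(axis=(0, 1))
        dhf = dlogits @ p["head.w"].T
        dx, dg, db = _layer_norm_bwd(dhf, c_lnf)
        grads["lnf.g"] += dg
        grads["lnf.b"] += db

        for i in reversed(range(C.n_layers)):
            h = f"h{i}"
            c_ln1, c_attn, x1, c_ln2, n2, c_gelu, g = caches[i]
            # mlp branch
            dm = dx
            grads[f"{h}.mlp.w2"] += g.reshape(-1, C.d_ff).T @ dm.reshape(-1, C.d_model)
            grads[f"{h}.mlp.b2"] += dm.sum(axis=(0, 1))
            dgelu = _gelu_bwd(dm @ p[f"{h}.mlp.w2"].T, c_gelu)
            grads[f"{h}.mlp.w1"] += n2.reshape(-1, C.d_model).T @ dgelu.reshape(-1, C.d_ff)
            grads[f"{h}.mlp.b1"] += dgelu.sum(axis=(0, 1))
            dn2 = dgelu @ p[f"{h}.mlp.w1"].T
            dx1, dg2, db2 = _layer_norm_bwd(dn2, c_ln2)
            grads[f"{h}.ln2.g"] += dg2
            grads[f"{h}.ln2.b"] += db2
            dx1 = dx1 + dx  # residual
            # attention branch
            dn1 = _attention_bwd(dx1, c_attn, grads, f"{h}.attn")
            dx0, dg1, db1 = _layer_norm_bwd(dn1, c_ln1)
            grads[f"{h}.ln1.g"] += dg1
            grads[f"{h}.ln1.b"] += db1
            dx = dx0 + dx1  # residual
        # embeddings
        np.add.at(grads["wte"], inputs, dx)
        grads["wpe"][:T] += dx.sum(axis=0)
        return loss, grads
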