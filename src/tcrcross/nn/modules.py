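"""Transformer building blocks: linear/embedding layers, multi-head attention,
post-LayerNorm encoder and decoder layers, and per-modality sequence encoders.

Attention layers keep their probability tensors (`last_probs`) inside the
autodiff graph so explanation methods can read both the probabilities and, after
a backward pass, the gradient of a loss with respect to them.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, concat, embedding, gelu, layer_norm, softmax

NEG_INF = np.float32(-1e30)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Module:
    """Minimal parameter container with train/eval mode and state dicts."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Module):
                        yield f"{name}.{k}", v

    def _params(self):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Parameter):
                        yield f"{name}.{i}", v
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Parameter):
                        yield f"{name}.{k}", v

    def parameters(self) -> list[Tensor]:
        out = [p for _, p in self._params()]
        for _, child in self._children():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params()]
        for cname, child in self._children():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def train(self, flag: bool = True):
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (n, d)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, self.eps)


class Dropout(Module):
    """Inverted dropout; active only in training mode. Uses a module-held rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        keep = (u >= self.rate).astype(x.data.dtype)
        keep *= 1.0 / (1.0 - self.rate)
        return x * Tensor(keep)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; PAD keys get zero probability mass.

    After a call, ``last_probs`` holds the (B, heads, Lq, Lk) probability
    tensor, still attached to the graph.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.d = d
        self.n_heads = n_heads
        self.dh = d // n_heads
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.o_proj = Linear(d, d, rng)
        self.last_probs: Tensor | None = None

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, memory: Tensor, key_mask: np.ndarray) -> Tensor:
        B, Lq, _ = query.shape
        Lk = memory.shape[1]
        scale = 1.0 / float(np.sqrt(self.dh))
        bias = np.where(np.asarray(key_mask, bool), 0.0, NEG_INF).astype(np.float32)
        if self.n_heads == 1:
            # single-head fast path: stay 3-D, expose probs as (B, 1, Lq, Lk)
            q = self.q_proj(query)
            k = self.k_proj(memory)
            v = self.v_proj(memory)
            scores = (q @ k.swapaxes(-1, -2)) * scale + Tensor(bias[:, None, :])
            probs = softmax(scores, axis=-1).reshape(B, 1, Lq, Lk)
            self.last_probs = probs  # on the loss path, so its grad is readable
            return self.o_proj(probs.reshape(B, Lq, Lk) @ v)
        q = self._split(self.q_proj(query), B, Lq)
        k = self._split(self.k_proj(memory), B, Lk)
        v = self._split(self.v_proj(memory), B, Lk)
        scores = (q @ k.swapaxes(-1, -2)) * scale
        scores = scores + Tensor(bias[:, None, None, :])
        probs = softmax(scores, axis=-1)
        self.last_probs = probs
        ctx = (probs @ v).transpose(0, 2, 1, 3).reshape(B, Lq, self.d)
        return self.o_proj(ctx)


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, d_ff, rng)
        self.fc2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class EncoderLayer(Module):
    """Post-LN transformer encoder layer (self-attention + FFN)."""

    def __init__(self, d: int, n_heads: int, d_ff: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.ffn = FeedForward(d, d_ff, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x, x, mask)))
        return self.ln2(x + self.drop2(self.ffn(x)))


class DecoderLayer(Module):
    """Self-attention on the query stream, cross-attention into memory, FFN."""

    def __init__(self, d: int, n_heads: int, d_ff: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(d, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d, n_heads, rng)
        self.ffn = FeedForward(d, d_ff, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ln3 = LayerNorm(d)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.drop3 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, q_mask: np.ndarray, memory: Tensor, mem_mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop1(self.self_attn(x, x, q_mask)))
        x = self.ln2(x + self.drop2(self.cross_attn(x, memory, mem_mask)))
        return self.ln3(x + self.drop3(self.ffn(x)))


class SequenceEncoder(Module):
    """Token + learned absolute positional embeddings, then encoder layers.

    Bidirectional self-attention; PAD positions are masked out as keys.
    """

    def __init__(self, vocab_size: int, max_len: int, d: int, n_layers: int,
                 n_heads: int, d_ff: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.tok = Embedding(vocab_size, d, rng)
        self.pos = Embedding(max_len, d, rng)
        self.ln = LayerNorm(d)
        self.drop = Dropout(dropout, rng)
        self.layers = [EncoderLayer(d, n_heads, d_ff, dropout, rng) for _ in range(n_layers)]
        self.max_len = max_len

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        B, L = ids.shape
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.max_len}")
        x = self.tok(ids) + self.pos(np.arange(L))
        x = self.drop(self.ln(x))
        for layer in self.layers:
            x = layer(x, mask)
        return x

    def self_attention_probs(self) -> list[Tensor]:
        return [layer.attn.last_probs for layer in self.layers]


class Decoder(Module):
    """A stack of decoder layers over a query feature stream and one memory."""

    def __init__(self, d: int, n_layers: int, n_heads: int, d_ff: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.layers = [DecoderLayer(d, n_heads, d_ff, dropout, rng) for _ in range(n_layers)]

    def __call__(self, x: Tensor, q_mask: np.ndarray, memory: Tensor, mem_mask: np.ndarray) -> Tensor:
        for layer in self.layers:
            x = layer(x, q_mask, memory, mem_mask)
        return x

    def cross_attention_probs(self) -> list[Tensor]:
        return [layer.cross_attn.last_probs for layer in self.layers]


def masked_mean_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean of features over non-PAD positions, per sample."""
    m = np.asarray(mask, dtype=x.data.dtype)
    denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
    return (x * Tensor(m[:, :, None])).sum(axis=1) * Tensor(1.0 / denom)


def concat_memory(features: list[Tensor], masks: list[np.ndarray]) -> tuple[Tensor, np.ndarray, list[tuple[int, int]]]:
    """Concatenate memories along the sequence axis; return segment spans."""
    spans, start = [], 0
    for f in features:
        spans.append((start, start + f.shape[1]))
        start += f.shape[1]
    return concat(features, axis=1), np.concatenate(masks, axis=1), spans
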