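"""Network architectures: bidirectional GRU with attention, fusion, text encoder.

The BIRNN maps a padded token-index sequence through an embedding of width
``floor(D ** 1/4)`` (D the vocabulary size), a forward GRU and a second GRU
run over the time-reversed input, concatenates both hidden sequences,
pools them with a learned single-score attention over valid positions,
optionally concatenates a static modality vector, and applies one affine
map to a scalar score. Padded steps are gated so they neither update the
recurrent state nor receive attention mass.

The text scorer is a two-layer single-head transformer encoder (width 32)
over note chunks with masked mean pooling; the fusion model concatenates
component pre-classifier vectors and learns one affine head jointly.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, embedding, masked_softmax, parameter


def embedding_dim(vocab_size: int) -> int:
    """Width of the symbol embedding: floor of the fourth root of D."""
    return max(1, int(math.floor(vocab_size ** 0.25 + 1e-9)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    """Parameter container with flat named access for optimizers/checkpoints."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def add_param(self, name: str, data) -> Tensor:
        t = parameter(data)
        self.params[name] = t
        return t

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def gru_sequence(xs: Tensor, W: Tensor, U: Tensor, b: Tensor,
                 mask: np.ndarray, reverse: bool = False) -> Tensor:
    """Full GRU pass as one fused op with hand-written backprop-through-time.

    xs: (B, L, e); W: (e, 3H) fused gate/input projections in z|r|n order;
    U: (H, 3H); b: (3H,). Gate equations per step (h the previous state):

        z = sigma(xW_z + hU_z + b_z),  r = sigma(xW_r + hU_r + b_r),
        n = tanh(xW_n + b_n + r * (hU_n)),  h' = (1-z) n + z h.

    Padded steps (mask 0) carry the state through unchanged, so pad content
    cannot leak into valid positions — important for the reversed pass,
    which consumes the padding first. Returns the (B, L, H) state sequence.
    """
    B, L, _ = xs.data.shape
    H = U.data.shape[0]
    xproj = xs.data @ W.data + b.data          # (B, L, 3H)
    m = mask.astype(np.float64)[:, :, None]    # (B, L, 1)
    order = range(L - 1, -1, -1) if reverse else range(L)
    hs = np.zeros((B, L, H))
    cache = {}
    h = np.zeros((B, H))
    for t in order:
        p = xproj[:, t, :]
        hp = h @ U.data                        # (B, 3H)
        z = _sigmoid(p[:, :H] + hp[:, :H])
        r = _sigmoid(p[:, H:2 * H] + hp[:, H:2 * H])
        hun = hp[:, 2 * H:]
        n = np.tanh(p[:, 2 * H:] + r * hun)
        h_new = (1.0 - z) * n + z * h
        mt = m[:, t, :]
        h_out = mt * h_new + (1.0 - mt) * h
        cache[t] = (h, z, r, n, hun)
        hs[:, t, :] = h_out
        h = h_out
    out = Tensor(hs, parents=(xs, W, U, b))

    def backward(g):
        dxproj = np.zeros_like(xproj)
        dU = np.zeros_like(U.data)
        dh = np.zeros((B, H))
        Uz, Ur, Un = U.data[:, :H], U.data[:, H:2 * H], U.data[:, 2 * H:]
        for t in list(order)[::-1]:    # reverse of the forward processing order
            h_prev, z, r, n, hun = cache[t]
            dh = dh + g[:, t, :]
            mt = m[:, t, :]
            dh_new = dh * mt
            dh_prev = dh * (1.0 - mt)
            dz = dh_new * (h_prev - n)
            dn = dh_new * (1.0 - z)
            dh_prev = dh_prev + dh_new * z
            dan = dn * (1.0 - n * n)
            dr = dan * hun
            dhun = dan * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dxproj[:, t, :H] = daz
            dxproj[:, t, H:2 * H] = dar
            dxproj[:, t, 2 * H:] = dan
            dh_prev = dh_prev + daz @ Uz.T + dar @ Ur.T + dhun @ Un.T
            dU[:, :H] += h_prev.T @ daz
            dU[:, H:2 * H] += h_prev.T @ dar
            dU[:, 2 * H:] += h_prev.T @ dhun
            dh = dh_prev
        if xs.grad is not None:
            xs.grad += dxproj @ W.data.T
        if W.grad is not None:
            W.grad += np.tensordot(xs.data, dxproj, axes=([0, 1], [0, 1]))
        if U.grad is not None:
            U.grad += dU
        if b.grad is not None:
            b.grad += dxproj.sum(axis=(0, 1))

    out._backward = backward
    return out


class GRULayer:
    """Batched GRU over time with per-step validity gating (fused kernel)."""

    def __init__(self, owner: Module, prefix: str, input_dim: int, hidden: int,
                 rng: np.random.Generator):
        self.hidden = hidden
        self.W = owner.add_param(f"{prefix}.W", _glorot(rng, input_dim, 3 * hidden))
        self.U = owner.add_param(f"{prefix}.U", _glorot(rng, hidden, 3 * hidden))
        self.b = owner.add_param(f"{prefix}.b", np.zeros(3 * hidden))

    def run(self, xs: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
        """xs: (B, L, input_dim); mask: (B, L). Returns (B, L, hidden)."""
        return gru_sequence(xs, self.W, self.U, self.b, mask, reverse=reverse)


class AttentionPool:
    """Learned per-timestep scalar score, soft-normalized over valid steps."""

    def __init__(self, owner: Module, prefix: str, width: int, rng: np.random.Generator):
        self.w = owner.add_param(f"{prefix}.w", _glorot(rng, width, 1))
        self.b = owner.add_param(f"{prefix}.b", np.zeros(1))

    def __call__(self, H: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """H: (B, L, W) -> (pooled (B, W), weights (B, L))."""
        scores = (H @ self.w + self.b).reshape(H.shape[0], H.shape[1])
        alpha = masked_softmax(scores, mask, axis=-1)
        pooled = (alpha.reshape(*alpha.shape, 1) * H).sum(axis=1)
        return pooled, alpha


class BirnnNetwork(Module):
    """Embedding -> two GRUs (forward / time-reversed) -> attention -> affine.

    ``dense_dim`` switches the input from a token-index sequence (embedding
    lookup) to a per-timestep feature matrix (the interpolated multivariate
    layout), which bypasses the embedding.
    """

    def __init__(self, vocab_size: int, max_len: int, hidden: int = 64,
                 extra_dims: int = 0, dense_dim: int | None = None, seed: int = 0):
        super().__init__()
        self.vocab_size = vocab_size
        self.max_len = max_len
        self.hidden = hidden
        self.extra_dims = extra_dims
        self.dense_dim = dense_dim
        rng = np.random.default_rng(seed)
        if dense_dim is None:
            self.emb_dim = embedding_dim(vocab_size)
            self.emb = self.add_param(
                "emb", rng.normal(0, 0.1, size=(vocab_size, self.emb_dim)))
        else:
            self.emb_dim = dense_dim
            self.emb = None
        self.gru_fwd = GRULayer(self, "gru_fwd", self.emb_dim, hidden, rng)
        self.gru_bwd = GRULayer(self, "gru_bwd", self.emb_dim, hidden, rng)
        self.attn = AttentionPool(self, "attn", 2 * hidden, rng)
        self.head_w = self.add_param("head.w", _glorot(rng, 2 * hidden + extra_dims, 1))
        self.head_b = self.add_param("head.b", np.zeros(1))

    @property
    def pre_classifier_width(self) -> int:
        return 2 * self.hidden

    def pre_attention(self, batch: dict) -> tuple[Tensor, np.ndarray]:
        """Concatenated forward/backward hidden sequence, (B, L, 2h)."""
        mask = batch["mask"]
        if self.emb is not None:
            xs = embedding(self.emb, batch["indices"])
        else:
            xs = Tensor(batch["dense"])
        fwd = self.gru_fwd.run(xs, mask, reverse=False)
        bwd = self.gru_bwd.run(xs, mask, reverse=True)
        return concat([fwd, bwd], axis=-1), mask

    def pre_classifier(self, batch: dict) -> Tensor:
        H, mask = self.pre_attention(batch)
        pooled, _ = self.attn(H, mask)
        return pooled

    def forward(self, batch: dict) -> Tensor:
        """Scalar score per sample, (B,)."""
        pooled = self.pre_classifier(batch)
        if self.extra_dims:
            extra = batch["extra"]
            if extra.shape[-1] != self.extra_dims:
                raise ValueError(
                    f"extra vector width {extra.shape[-1]} != {self.extra_dims}")
            pooled = concat([pooled, Tensor(extra)], axis=-1)
        return (pooled @ self.head_w + self.head_b).reshape(pooled.shape[0])


class LayerNorm:
    def __init__(self, owner: Module, prefix: str, width: int):
        self.g = owner.add_param(f"{prefix}.g", np.ones(width))
        self.b = owner.add_param(f"{prefix}.b", np.zeros(width))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + 1e-5).sqrt() * self.g + self.b


class TransformerTextNetwork(Module):
    """Tiny transformer encoder for note chunks: 2 layers, width 32, 1 head.

    Token + learned positional embeddings, residual self-attention and
    feed-forward blocks with layer norm, masked mean pooling, affine head.
    Randomly initialized: it exercises the fine-tuning and aggregation path
    at desk scale; pretrained clinical weights are an optional drop-in via
    ``load_state_dict`` on a matching shape.
    """

    def __init__(self, vocab_size: int, max_len: int, width: int = 32,
                 n_layers: int = 2, ffn_mult: int = 2, seed: int = 0):
        super().__init__()
        self.vocab_size = vocab_size
        self.max_len = max_len
        self.width = width
        self.n_layers = n_layers
        rng = np.random.default_rng(seed)
        self.emb = self.add_param("emb", rng.normal(0, 0.1, size=(vocab_size, width)))
        self.pos = self.add_param("pos", rng.normal(0, 0.1, size=(max_len, width)))
        self.blocks = []
        for i in range(n_layers):
            blk = {
                "q": self.add_param(f"blk{i}.q", _glorot(rng, width, width)),
                "k": self.add_param(f"blk{i}.k", _glorot(rng, width, width)),
                "v": self.add_param(f"blk{i}.v", _glorot(rng, width, width)),
                "o": self.add_param(f"blk{i}.o", _glorot(rng, width, width)),
                "ln1": LayerNorm(self, f"blk{i}.ln1", width),
                "f1": self.add_param(f"blk{i}.f1", _glorot(rng, width, ffn_mult * width)),
                "f1b": self.add_param(f"blk{i}.f1b", np.zeros(ffn_mult * width)),
                "f2": self.add_param(f"blk{i}.f2", _glorot(rng, ffn_mult * width, width)),
                "f2b": self.add_param(f"blk{i}.f2b", np.zeros(width)),
                "ln2": LayerNorm(self, f"blk{i}.ln2", width),
            }
            self.blocks.append(blk)
        self.head_w = self.add_param("head.w", _glorot(rng, width, 1))
        self.head_b = self.add_param("head.b", np.zeros(1))

    @property
    def pre_classifier_width(self) -> int:
        return self.width

    def pre_classifier(self, batch: dict) -> Tensor:
        idx, mask = batch["indices"], batch["mask"]
        B, T = idx.shape
        x = embedding(self.emb, idx) + self.pos[:T, :]
        scale = 1.0 / math.sqrt(self.width)
        attn_mask = mask[:, None, :]          # (B, 1, T): keys at pad masked out
        for blk in self.blocks:
            q, k, v = x @ blk["q"], x @ blk["k"], x @ blk["v"]
            scores = (q @ k.swap_last()) * scale          # (B, T, T)
            alpha = masked_softmax(scores, attn_mask, axis=-1)
            attended = (alpha @ v) @ blk["o"]
            x = blk["ln1"](x + attended)
            h = (x @ blk["f1"] + blk["f1b"]).tanh() @ blk["f2"] + blk["f2b"]
            x = blk["ln2"](x + h)
        m = mask.astype(np.float64)
        denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
        pooled = (x * Tensor(m[:, :, None])).sum(axis=1) / Tensor(denom)
        return pooled

    def forward(self, batch: dict) -> Tensor:
        pooled = self.pre_classifier(batch)
        return (pooled @ self.head_w + self.head_b).reshape(pooled.shape[0])


class FusionNetwork(Module):
    """Joint multimodal model: component pre-classifier vectors concatenated,
    one affine map to a score, all parameters trained together.

    ``components`` maps name -> network exposing ``pre_classifier`` and
    ``pre_classifier_width``; ``static_dims`` appends raw static vectors
    (e.g. the demographics one-hot) without a subnetwork.
    """

    def __init__(self, components: dict[str, Module], static_dims: int = 0, seed: int = 0):
        super().__init__()
        if len(components) + (static_dims > 0) < 2:
            raise ValueError("fusion needs at least two components")
        self.components = components
        self.static_dims = static_dims
        for name, comp in components.items():
            for pname, p in comp.params.items():
                self.params[f"{name}.{pname}"] = p
        width = sum(c.pre_classifier_width for c in components.values()) + static_dims
        rng = np.random.default_rng(seed)
        self.head_w = self.add_param("fusion.head.w", _glorot(rng, width, 1))
        self.head_b = self.add_param("fusion.head.b", np.zeros(1))
        self.fusion_width = width

    def forward(self, batch: dict) -> Tensor:
        parts = [comp.pre_classifier(batch[name]) for name, comp in self.components.items()]
        if self.static_dims:
            parts.append(Tensor(batch["static"]))
        fused = concat(parts, axis=-1)
        return (fused @ self.head_w + self.head_b).reshape(fused.shape[0])
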