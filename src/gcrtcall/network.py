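"""The basecaller network.

Architecture: a three-layer convolutional frontend (channels 4/6/512,
kernels 5/5/19, strides 1/1/10 — a 10x downsampler), followed by 8
Conformer-style blocks and a linear CTC head over {blank, A, C, G, U}.
Each block interleaves two half-step (macaron) feed-forward sub-blocks, a
relative-position multi-head self-attention and a gated depthwise-separable
convolution module, all pre-normalized with residual connections.

During training two 2-layer causal Transformer decoder stacks are attached
on top of the encoder: a forward decoder with a lower-triangular
self-attention mask and a reverse decoder with an anti-lower-triangular
mask.  Both are dropped at inference.

Two ablation switches are wired through :class:`~gcrtcall.config.ModelConfig`:
``use_relative_shift=False`` keeps the position-score pathway but skips the
relative-shift rearrangement ("w/o RS"), and ``block_type='transformer'``
replaces each Conformer block by a plain pre-norm Transformer encoder layer
with absolute sinusoidal positions ("Transcall").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concat, log_softmax, no_grad, pad, softmax
from .config import DECODER_VOCAB_SIZE, ModelConfig, VOCAB

__all__ = ["FrameLogProbs", "DecoderOutput", "relative_shift", "glu",
           "RelativeMultiHeadAttention", "MultiHeadAttention",
           "GatedConvBlock", "FeedForward", "ConformerBlock",
           "TransformerBlock", "ConvFrontend", "Encoder", "Decoder",
           "BasecallerModel", "count_parameters", "save_checkpoint",
           "load_checkpoint"]

NEG_INF = -1e9


@dataclass
class FrameLogProbs:
    """Per-frame log-probabilities over (blank, A, C, G, U)."""

    frames: np.ndarray          # (B, T, 5) or (T, 5)
    valid_lengths: np.ndarray   # (B,) frames that correspond to real signal

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.valid_lengths = np.atleast_1d(np.asarray(self.valid_lengths))


@dataclass
class DecoderOutput:
    """Teacher-forced log-probabilities from both training decoders."""

    forward_frames: np.ndarray  # (B, U, 7)
    reverse_frames: np.ndarray  # (B, U, 7)


# ---------------------------------------------------------------------------
# relative shift
# ---------------------------------------------------------------------------

def relative_shift(scores):
    """Rearrange per-offset position scores into (query, key) layout.

    Input has shape ``(..., T, P)`` with ``T <= P <= 2T-1``; column ``c``
    holds the score of a query against relative offset ``T - 1 - c``
    (offsets decrease left to right: ``P = 2T-1`` covers every offset of a
    bidirectional encoder, ``P = T`` the past-only offsets of the square
    causal case).  The output ``(..., T, T)`` entry ``(i, j)`` is the score
    of query ``i`` at offset ``i - j``; offsets absent from the input (only
    possible when ``P < 2T-1``) are zero.

    Implemented by the pad-reshape-slice trick; gradients flow through the
    constituent primitives.
    """
    x = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores))
    was_tensor = isinstance(scores, Tensor)
    *lead, T, P = x.shape
    if not T <= P <= 2 * T - 1:
        raise ValueError(f"expected T <= P <= 2T-1, got T={T}, P={P}")
    pad_width = [(0, 0)] * len(lead) + [(0, 0), (1, 0)]
    y = pad(x, tuple(pad_width))                    # (..., T, P+1)
    y = y.reshape(*lead, T * (P + 1))
    y = y.reshape(*lead, P + 1, T)
    idx = (Ellipsis, slice(1, None), slice(None))
    y = y[idx]                                      # (..., P, T)
    y = y.reshape(*lead, T, P)
    y = y[(Ellipsis, slice(None), slice(0, T))]     # (..., T, T)
    if P < 2 * T - 1:
        i = np.arange(T)[:, None]
        j = np.arange(T)[None, :]
        src = (T - 1) + j - i
        mask = ((src >= 0) & (src < P)).astype(np.float32)
        y = y * Tensor(mask)
    return y if was_tensor else y.data


def relative_shift_gather(scores: np.ndarray) -> np.ndarray:
    """Explicit-gather reference: indexes position scores by (i - j) directly."""
    scores = np.asarray(scores)
    *lead, T, P = scores.shape
    out = np.zeros((*lead, T, T), dtype=scores.dtype)
    for i in range(T):
        for j in range(T):
            c = (T - 1) + j - i
            if 0 <= c < P:
                out[..., i, j] = scores[..., i, c]
    return out


# ---------------------------------------------------------------------------
# GLU
# ---------------------------------------------------------------------------

def glu(x):
    """Gated linear unit over the last axis: ``a * sigmoid(b)``.

    ``a`` is the first half of the channels, ``b`` the second half.
    """
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    dim = t.shape[-1]
    if dim % 2:
        raise ValueError("GLU requires an even channel dimension")
    half = dim // 2
    a = t[(Ellipsis, slice(0, half))]
    b = t[(Ellipsis, slice(half, None))]
    out = a * b.sigmoid()
    return out if isinstance(x, Tensor) else out.data


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class RelativeMultiHeadAttention(nn.Module):
    """Multi-head self-attention with Transformer-XL relative positions.

    Scores are ``[(Q + b_k) K^T + relative_shift((Q + b_p) K_p^T)] / sqrt(d_k)``
    where ``K_p`` is a linear projection of the sinusoidal encoding of the
    relative offsets ``T-1 .. -(T-1)`` and ``b_k``/``b_p`` are global
    per-head content/position biases.
    """

    def __init__(self, d_model: int, n_heads: int, dropout: float = 0.0,
                 use_relative_shift: bool = True, *, rng=None):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_k = d_model // n_heads
        self.use_relative_shift = use_relative_shift
        self.w_q = nn.Linear(d_model, d_model, rng=rng)
        self.w_k = nn.Linear(d_model, d_model, rng=rng)
        self.w_v = nn.Linear(d_model, d_model, rng=rng)
        self.w_p = nn.Linear(d_model, d_model, bias=False, rng=rng)
        self.w_o = nn.Linear(d_model, d_model, rng=rng)
        self.b_k = nn.Parameter(np.zeros((n_heads, 1, self.d_k)))
        self.b_p = nn.Parameter(np.zeros((n_heads, 1, self.d_k)))
        self.dropout = nn.Dropout(dropout, rng=rng)

    def _split(self, t: Tensor, B: int, T: int) -> Tensor:
        return t.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None,
                return_weights: bool = False):
        B, T, _ = x.shape
        d = self.d_model
        # one fused projection for Q, K, V (same math, one BLAS call)
        w = concat([self.w_q.weight, self.w_k.weight, self.w_v.weight], axis=1)
        b = concat([self.w_q.bias, self.w_k.bias, self.w_v.bias], axis=0)
        qkv = (x @ w + b).reshape(B, T, 3, self.n_heads, self.d_k) \
            .transpose(2, 0, 3, 1, 4)           # (3, B, H, T, d_k)
        q, k, v = qkv[0], qkv[1], qkv[2]
        kt = k.transpose(0, 1, 3, 2)
        content = (q + self.b_k) @ kt           # (B, H, T, T)

        offsets = np.arange(T - 1, -T, -1)      # T-1 .. -(T-1)
        pos = nn.sinusoidal_encoding(offsets, self.d_model)
        kp = self.w_p(Tensor(pos))              # (2T-1, d_model)
        kp = kp.reshape(2 * T - 1, self.n_heads, self.d_k).transpose(1, 2, 0)
        pos_scores = (q + self.b_p) @ kp        # (B, H, T, 2T-1)
        if self.use_relative_shift:
            pos_term = relative_shift(pos_scores)
        else:  # ablation: raw (unshifted) scores, first T columns
            pos_term = pos_scores[(Ellipsis, slice(None), slice(0, T))]

        scores = (content + pos_term) * (1.0 / np.sqrt(self.d_k))
        if key_mask is not None:  # (B, T) True = valid
            add = np.where(key_mask[:, None, None, :], 0.0, NEG_INF)
            scores = scores + Tensor(add.astype(np.float32))
        weights = softmax(scores, axis=-1)
        ctx = self.dropout(weights) @ v         # (B, H, T, d_k)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
        out = self.w_o(ctx)
        if return_weights:
            return out, weights.data
        return out


class MultiHeadAttention(nn.Module):
    """Plain scaled dot-product multi-head attention (self or cross)."""

    def __init__(self, d_model: int, n_heads: int, dropout: float = 0.0, *, rng=None):
        super().__init__()
        self.d_model, self.n_heads = d_model, n_heads
        self.d_k = d_model // n_heads
        self.w_q = nn.Linear(d_model, d_model, rng=rng)
        self.w_k = nn.Linear(d_model, d_model, rng=rng)
        self.w_v = nn.Linear(d_model, d_model, rng=rng)
        self.w_o = nn.Linear(d_model, d_model, rng=rng)
        self.dropout = nn.Dropout(dropout, rng=rng)

    def forward(self, query: Tensor, memory: Tensor,
                mask: np.ndarray | None = None) -> Tensor:
        B, Tq, _ = query.shape
        Tk = memory.shape[1]
        split = lambda t, T: t.reshape(B, T, self.n_heads, self.d_k) \
            .transpose(0, 2, 1, 3)
        if query is memory:  # self-attention: fuse all three projections
            w = concat([self.w_q.weight, self.w_k.weight, self.w_v.weight],
                       axis=1)
            b = concat([self.w_q.bias, self.w_k.bias, self.w_v.bias], axis=0)
            qkv = (query @ w + b).reshape(B, Tq, 3, self.n_heads, self.d_k) \
                .transpose(2, 0, 3, 1, 4)
            q, k, v = qkv[0], qkv[1], qkv[2]
        else:                # cross-attention: fuse the two memory projections
            q = split(self.w_q(query), Tq)
            w = concat([self.w_k.weight, self.w_v.weight], axis=1)
            b = concat([self.w_k.bias, self.w_v.bias], axis=0)
            kv = (memory @ w + b).reshape(B, Tk, 2, self.n_heads, self.d_k) \
                .transpose(2, 0, 3, 1, 4)
            k, v = kv[0], kv[1]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        if mask is not None:  # boolean, True = attend; (Tq,Tk) or (B,Tq,Tk)
            add = np.where(mask, 0.0, NEG_INF).astype(np.float32)
            if add.ndim == 2:
                add = add[None, None]
            else:
                add = add[:, None]
            scores = scores + Tensor(add)
        weights = softmax(scores, axis=-1)
        ctx = (self.dropout(weights) @ v).transpose(0, 2, 1, 3) \
            .reshape(B, Tq, self.d_model)
        return self.w_o(ctx)


# ---------------------------------------------------------------------------
# block sub-modules
# ---------------------------------------------------------------------------

class FeedForward(nn.Module):
    def __init__(self, d_model: int, expansion: int, dropout: float, *, rng=None):
        super().__init__()
        self.norm = nn.LayerNorm(d_model)
        self.lin1 = nn.Linear(d_model, d_model * expansion, rng=rng)
        self.lin2 = nn.Linear(d_model * expansion, d_model, rng=rng)
        self.dropout = nn.Dropout(dropout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.lin1(self.norm(x)).swish()
        return self.dropout(self.lin2(self.dropout(h)))


class GatedConvBlock(nn.Module):
    """Gated depthwise-separable convolution module.

    Pointwise conv to 2*d channels, GLU gate back to d, depthwise conv,
    batch normalization, swish — sequence length preserved.
    """

    def __init__(self, d_model: int, kernel: int, dropout: float, *, rng=None):
        super().__init__()
        self.norm = nn.LayerNorm(d_model)
        self.pointwise = nn.Linear(d_model, 2 * d_model, rng=rng)
        self.depthwise = nn.DepthwiseConv1d(d_model, kernel, rng=rng)
        self.batchnorm = nn.BatchNorm1d(d_model)
        self.dropout = nn.Dropout(dropout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = glu(self.pointwise(self.norm(x)))
        h = self.batchnorm(self.depthwise(h)).swish()
        return self.dropout(h)


class ConformerBlock(nn.Module):
    """Half-step FF -> relative MHSA -> gated conv -> half-step FF -> LN."""

    def __init__(self, cfg: ModelConfig, *, rng=None):
        super().__init__()
        d = cfg.d_model
        self.ff1 = FeedForward(d, cfg.ff_expansion, cfg.dropout, rng=rng)
        self.attn_norm = nn.LayerNorm(d)
        self.attn = RelativeMultiHeadAttention(
            d, cfg.n_heads, cfg.dropout,
            use_relative_shift=cfg.use_relative_shift, rng=rng)
        self.conv = GatedConvBlock(d, cfg.conv_kernel, cfg.dropout, rng=rng)
        self.ff2 = FeedForward(d, cfg.ff_expansion, cfg.dropout, rng=rng)
        self.final_norm = nn.LayerNorm(d)

    def forward(self, x: Tensor, key_mask=None) -> Tensor:
        x = x + self.ff1(x) * 0.5
        x = x + self.attn(self.attn_norm(x), key_mask=key_mask)
        x = x + self.conv(x)
        x = x + self.ff2(x) * 0.5
        return self.final_norm(x)


class TransformerBlock(nn.Module):
    """Plain pre-norm Transformer encoder layer (the Transcall ablation)."""

    def __init__(self, cfg: ModelConfig, *, rng=None):
        super().__init__()
        d = cfg.d_model
        self.attn_norm = nn.LayerNorm(d)
        self.attn = MultiHeadAttention(d, cfg.n_heads, cfg.dropout, rng=rng)
        self.ff_norm = nn.LayerNorm(d)
        self.lin1 = nn.Linear(d, d * cfg.ff_expansion, rng=rng)
        self.lin2 = nn.Linear(d * cfg.ff_expansion, d, rng=rng)
        self.dropout = nn.Dropout(cfg.dropout, rng=rng)

    def forward(self, x: Tensor, key_mask=None) -> Tensor:
        h = self.attn_norm(x)
        mask = None if key_mask is None else \
            np.broadcast_to(key_mask[:, None, :],
                            (x.shape[0], x.shape[1], x.shape[1]))
        x = x + self.attn(h, h, mask=mask)
        h = self.lin1(self.ff_norm(x)).swish()
        return x + self.dropout(self.lin2(h))


# ---------------------------------------------------------------------------
# encoder / decoder
# ---------------------------------------------------------------------------

class ConvFrontend(nn.Module):
    """Three 1-D convolutions for downsampling and feature extraction."""

    def __init__(self, cfg: ModelConfig, *, rng=None):
        super().__init__()
        chans = (1,) + cfg.frontend_channels
        self.convs = [
            nn.Conv1d(chans[i], chans[i + 1], cfg.frontend_kernels[i],
                      cfg.frontend_strides[i], rng=rng)
            for i in range(3)
        ]
        if cfg.frontend_channels[-1] != cfg.d_model:
            self.project = nn.Linear(cfg.frontend_channels[-1], cfg.d_model,
                                     rng=rng)
        else:
            self.project = None

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).swish()
        if self.project is not None:
            x = self.project(x)
        return x


class Encoder(nn.Module):
    """Frontend, block stack, and CTC head producing frame log-probs."""

    def __init__(self, cfg: ModelConfig, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.frontend = ConvFrontend(cfg, rng=rng)
        block_cls = ConformerBlock if cfg.block_type == "conformer" \
            else TransformerBlock
        self.blocks = [block_cls(cfg, rng=rng) for _ in range(cfg.n_blocks)]
        self.head = nn.Linear(cfg.d_model, len(VOCAB), rng=rng)

    def forward(self, chunks: Tensor, valid_lengths: np.ndarray | None = None,
                return_hidden: bool = False):
        """``chunks``: (B, L, 1) normalized signal.  Returns (B, T, 5) tensor
        of log-probs and the per-example count of valid frames (and, when
        requested, the (B, T, d_model) hidden states for decoder memory)."""
        B, L, _ = chunks.shape
        h = self.frontend(chunks)
        T = h.shape[1]
        stride = self.cfg.total_stride
        if valid_lengths is None:
            valid_lengths = np.full(B, L, dtype=np.int64)
        frame_lengths = (np.asarray(valid_lengths) - 1) // stride + 1
        key_mask = np.arange(T)[None, :] < frame_lengths[:, None]
        if self.cfg.block_type == "transformer":
            h = h + Tensor(nn.sinusoidal_encoding(np.arange(T),
                                                  self.cfg.d_model))
        for block in self.blocks:
            h = block(h, key_mask=key_mask if not np.all(key_mask) else None)
        logp = log_softmax(self.head(h), axis=-1)
        if return_hidden:
            return logp, h, frame_lengths
        return logp, frame_lengths


class DecoderLayer(nn.Module):
    def __init__(self, cfg: ModelConfig, *, rng=None):
        super().__init__()
        d = cfg.d_model
        self.self_norm = nn.LayerNorm(d)
        self.self_attn = MultiHeadAttention(d, cfg.n_heads, cfg.dropout, rng=rng)
        self.cross_norm = nn.LayerNorm(d)
        self.cross_attn = MultiHeadAttention(d, cfg.n_heads, cfg.dropout, rng=rng)
        self.ff_norm = nn.LayerNorm(d)
        self.lin1 = nn.Linear(d, d * cfg.ff_expansion, rng=rng)
        self.lin2 = nn.Linear(d * cfg.ff_expansion, d, rng=rng)
        self.dropout = nn.Dropout(cfg.dropout, rng=rng)

    def forward(self, x, memory, self_mask, memory_mask):
        h = self.self_norm(x)
        x = x + self.self_attn(h, h, mask=self_mask)
        x = x + self.cross_attn(self.cross_norm(x), memory, mask=memory_mask)
        h = self.lin1(self.ff_norm(x)).swish()
        return x + self.dropout(self.lin2(h))


class Decoder(nn.Module):
    """Causal Transformer decoder over the 7-token target vocabulary.

    ``direction='forward'`` uses a lower-triangular self-attention mask
    (position i attends j <= i); ``direction='reverse'`` an
    anti-lower-triangular one (j >= i), i.e. causal over the reversed target.
    """

    def __init__(self, cfg: ModelConfig, direction: str, *, rng=None):
        super().__init__()
        if direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {direction!r}")
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg, self.direction = cfg, direction
        self.embed = nn.Embedding(DECODER_VOCAB_SIZE, cfg.d_model, rng=rng)
        self.layers = [DecoderLayer(cfg, rng=rng)
                       for _ in range(cfg.n_decoder_layers)]
        self.final_norm = nn.LayerNorm(cfg.d_model)
        self.head = nn.Linear(cfg.d_model, DECODER_VOCAB_SIZE, rng=rng)

    def forward(self, memory: Tensor, tokens: np.ndarray,
                memory_key_mask: np.ndarray | None = None,
                token_mask: np.ndarray | None = None) -> Tensor:
        """Teacher-forced pass.  ``tokens``: (B, U) int ids; returns
        (B, U, 7) log-probs.  Output position i depends only on tokens
        j <= i (forward) or j >= i (reverse).  ``token_mask`` (B, U) marks
        real (non-padding) positions; padding is never attended."""
        tokens = np.atleast_2d(np.asarray(tokens))
        if tokens.shape[1] == 0:
            raise ValueError("decoder requires a nonempty target sequence")
        B, U = tokens.shape
        i = np.arange(U)[:, None]
        j = np.arange(U)[None, :]
        self_mask = (j <= i) if self.direction == "forward" else (j >= i)
        if token_mask is not None:
            self_mask = self_mask[None] & token_mask[:, None, :]
            self_mask = self_mask | np.eye(U, dtype=bool)[None]
        memory_mask = None
        if memory_key_mask is not None:
            memory_mask = np.broadcast_to(
                memory_key_mask[:, None, :], (B, U, memory.shape[1]))
        x = self.embed(tokens) + Tensor(
            nn.sinusoidal_encoding(np.arange(U), self.cfg.d_model))
        for layer in self.layers:
            x = layer(x, memory, self_mask, memory_mask)
        return log_softmax(self.head(self.final_norm(x)), axis=-1)


class BasecallerModel(nn.Module):
    """Encoder plus the two training-only decoders."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng=rng)
        self.forward_decoder = Decoder(cfg, "forward", rng=rng)
        self.reverse_decoder = Decoder(cfg, "reverse", rng=rng)
        # how raw signal must be scaled before encoding (set by training)
        self.signal_scaling = {"mode": "read"}

    def forward(self, chunks, valid_lengths=None):
        return self.encoder(as_tensor(chunks), valid_lengths)

    def encode(self, chunks, valid_lengths=None) -> FrameLogProbs:
        """Inference pass returning detached frame log-probabilities."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logp, frame_lengths = self.encoder(as_tensor(chunks),
                                                   valid_lengths)
        finally:
            if was_training:
                self.train()
        return FrameLogProbs(frames=logp.data, valid_lengths=frame_lengths)


def count_parameters(cfg: ModelConfig, include_decoders: bool = False) -> int:
    """Exact count of trainable scalars for a given configuration."""
    model = BasecallerModel(cfg)
    if include_decoders:
        return model.n_parameters()
    return model.encoder.n_parameters()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: BasecallerModel, *,
                    include_decoders: bool = False, extra: dict | None = None):
    """Single-file .npz archive holding config JSON + weights.

    By default only the inference network (encoder) is saved; the training
    decoders are dropped, as they are unused at basecalling time.
    """
    source = model if include_decoders else model.encoder
    state = {f"w/{k}": v for k, v in source.state_dict().items()}
    merged = {"signal_scaling": getattr(model, "signal_scaling",
                                        {"mode": "read"})}
    merged.update(extra or {})
    meta = {"config": model.cfg.to_dict(),
            "include_decoders": include_decoders, "extra": merged}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> BasecallerModel:
    path = Path(path)
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[2:]: archive[k] for k in archive.files if k.startswith("w/")}
    cfg = ModelConfig.from_dict(meta["config"])
    model = BasecallerModel(cfg)
    if meta["include_decoders"]:
        model.load_state_dict(state)
    else:
        model.encoder.load_state_dict(state)
    scaling = meta.get("extra", {}).get("signal_scaling")
    if scaling:
        model.signal_scaling = scaling
    model.eval()
    return model
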