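"""Joint training loss: CTC on encoder frames + KL-divergence on decoders.

``L_joint(x, y) = λ·L_CTC(x_E, y) + (1 − λ)·L_KLDiv(x_D, y)`` with λ = 0.5
by default.  ``x_E`` is the encoder's per-frame log-probability matrix,
``x_D`` the teacher-forced output of the forward and reverse decoders; the
KLDiv term is the unweighted mean of the two decoder losses, each the mean
per-position KL between the label-smoothed one-hot target and the predicted
distribution.

The CTC loss is the negative log of the total probability of all frame
paths that collapse (merge repeats, drop blanks) to the target, computed by
the standard forward recursion in log space; its gradient with respect to
the input log-probabilities comes from the forward-backward posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .config import BASES, EOS, SOS
from .network import DecoderOutput, FrameLogProbs

__all__ = ["LossReport", "ctc_loss", "ctc_forward_backward", "ctc_loss_batch",
           "kldiv_loss", "joint_loss", "encode_target", "teacher_pairs",
           "smoothed_one_hot"]

_BASE_IDS = {b: i + 1 for i, b in enumerate(BASES)}  # 0 is the CTC blank
NEG_INF = -np.inf


def encode_target(target: str) -> np.ndarray:
    """Base string -> CTC label ids (A,C,G,U -> 1..4; T accepted as U)."""
    target = target.upper().replace("T", "U")
    try:
        return np.array([_BASE_IDS[b] for b in target], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in target") from None


def teacher_pairs(target_ids: np.ndarray, direction: str):
    """Decoder (input, label) token sequences for one target.

    forward: input [SOS, y], label [y, EOS] with a lower-triangular mask;
    reverse: input [y, EOS], label [SOS, y] with an anti-lower-triangular
    mask, so each label position is predicted from strictly later tokens.
    """
    y = np.asarray(target_ids, dtype=np.int64)
    if direction == "forward":
        return np.concatenate([[SOS], y]), np.concatenate([y, [EOS]])
    if direction == "reverse":
        return np.concatenate([y, [EOS]]), np.concatenate([[SOS], y])
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# CTC
# ---------------------------------------------------------------------------

def _extend_labels(target: np.ndarray) -> np.ndarray:
    ext = np.zeros(2 * len(target) + 1, dtype=np.int64)
    ext[1::2] = target
    return ext


def ctc_forward_backward(logp: np.ndarray, target: np.ndarray):
    """CTC loss and its gradient w.r.t. the (T, V) log-probabilities.

    Returns ``(loss, grad)``; ``loss`` is ``inf`` (grad zero) when the
    target cannot be emitted in T frames.
    """
    logp = np.asarray(logp, dtype=np.float64)
    target = np.asarray(target, dtype=np.int64)
    T, V = logp.shape
    ext = _extend_labels(target)
    S = len(ext)
    # feasibility: repeats need a separating blank
    min_frames = len(target) + np.count_nonzero(target[1:] == target[:-1])
    if len(target) > 0 and T < min_frames:
        return np.inf, np.zeros_like(logp)

    can_skip = np.zeros(S, dtype=bool)
    can_skip[2:] = (ext[2:] != 0) & (ext[2:] != ext[:-2])

    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = logp[0, 0]
    if S > 1:
        alpha[0, 1] = logp[0, ext[1]]
    for t in range(1, T):
        prev = alpha[t - 1]
        step = np.full(S, NEG_INF)
        step[1:] = prev[:-1]
        skip = np.full(S, NEG_INF)
        skip[2:] = prev[:-2]
        skip = np.where(can_skip, skip, NEG_INF)
        alpha[t] = np.logaddexp(np.logaddexp(prev, step), skip) + logp[t, ext]

    log_total = alpha[T - 1, S - 1] if S == 1 else \
        np.logaddexp(alpha[T - 1, S - 1], alpha[T - 1, S - 2])
    if not np.isfinite(log_total):
        return np.inf, np.zeros_like(logp)

    beta = np.full((T, S), NEG_INF)
    beta[T - 1, S - 1] = 0.0
    if S > 1:
        beta[T - 1, S - 2] = 0.0
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + logp[t + 1, ext]
        step = np.full(S, NEG_INF)
        step[:-1] = nxt[1:]
        skip = np.full(S, NEG_INF)
        skip[:-2] = np.where(can_skip[2:], nxt[2:], NEG_INF)
        beta[t] = np.logaddexp(np.logaddexp(nxt, step), skip)

    # grad[t, k] = -sum_{s: ext[s]=k} exp(alpha + beta - log_total)
    gamma = alpha + beta - log_total
    grad = np.zeros_like(logp)
    w = np.exp(np.clip(gamma, -745.0, 50.0))
    for s in range(S):
        grad[:, ext[s]] -= w[:, s]
    return float(-log_total), grad


def ctc_loss(frames: FrameLogProbs, target: str) -> float:
    """CTC loss of one read's frames against a base-string target."""
    logp = np.asarray(frames.frames, dtype=np.float64)
    if logp.ndim == 3:
        if logp.shape[0] != 1:
            raise ValueError("pass a single example (or use ctc_loss_batch)")
        logp = logp[0]
    T = int(frames.valid_lengths[0])
    loss, _ = ctc_forward_backward(logp[:T], encode_target(target))
    return loss


def ctc_loss_batch(logp: Tensor, targets: Sequence[np.ndarray],
                   frame_lengths: np.ndarray, *,
                   target_length_norm: bool = False):
    """Mean CTC loss over the feasible examples of a batch.

    Infeasible examples (target longer than the frames can emit) are
    excluded from the mean and counted.  Returns ``(loss_tensor, n_skipped)``.
    """
    data = np.asarray(logp.data, dtype=np.float64)
    B = data.shape[0]
    losses, grads, feasible = [], [], []
    for b in range(B):
        T = int(frame_lengths[b])
        loss, grad = ctc_forward_backward(data[b, :T], targets[b])
        if not np.isfinite(loss):
            continue
        scale = 1.0 / max(len(targets[b]), 1) if target_length_norm else 1.0
        losses.append(loss * scale)
        g = np.zeros(data.shape[1:], dtype=np.float64)
        g[:T] = grad * scale
        grads.append(g)
        feasible.append(b)
    n_skipped = B - len(feasible)
    if not feasible:
        return Tensor(np.float64(np.nan)), n_skipped
    mean_loss = float(np.mean(losses))
    grad_stack = np.stack(grads) / len(feasible)

    out = Tensor(np.float64(mean_loss))

    def backward(g):
        if logp.requires_grad:
            full = np.zeros_like(logp.data)
            full[np.array(feasible)] = (float(g) * grad_stack).astype(logp.data.dtype)
            logp._accum(full)

    return Tensor._make(out.data, (logp,), backward), n_skipped


# ---------------------------------------------------------------------------
# KL divergence on decoder outputs
# ---------------------------------------------------------------------------

def smoothed_one_hot(tokens: np.ndarray, n_classes: int,
                     epsilon: float) -> np.ndarray:
    """Label-smoothed one-hot targets: 1-ε+ε/V on the label, ε/V elsewhere."""
    tokens = np.asarray(tokens, dtype=np.int64)
    q = np.full(tokens.shape + (n_classes,), epsilon / n_classes)
    np.put_along_axis(q, tokens[..., None], 1.0 - epsilon + epsilon / n_classes,
                      axis=-1)
    return q


def kldiv_loss(decoded: Tensor, target_tokens: np.ndarray, *,
               epsilon: float = 0.1,
               position_mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean per-position KL(q ‖ p) between smoothed targets and predictions.

    ``decoded``: (B, U, V) log-probabilities; ``target_tokens``: (B, U) ids.
    ``position_mask`` (B, U) excludes padding positions from the mean.
    """
    target_tokens = np.atleast_2d(np.asarray(target_tokens))
    if decoded.shape[:2] != target_tokens.shape:
        raise ValueError("decoded and target token shapes disagree")
    V = decoded.shape[-1]
    q = smoothed_one_hot(target_tokens, V, epsilon)
    with np.errstate(divide="ignore"):
        qlogq = np.where(q > 0, q * np.log(np.maximum(q, 1e-300)), 0.0)
    if position_mask is None:
        position_mask = np.ones(target_tokens.shape, dtype=bool)
    n = max(int(position_mask.sum()), 1)
    m = position_mask.astype(np.float64)[..., None]
    const = float((qlogq * m).sum() / n)
    cross = (decoded * Tensor(q * m)).sum() * (-1.0 / n)
    return cross + const


# ---------------------------------------------------------------------------
# joint loss
# ---------------------------------------------------------------------------

@dataclass
class LossReport:
    """Scalar components of one batch's joint loss."""

    ctc: float
    kl_forward: float
    kl_reverse: float
    joint: float
    batch_size: int
    n_skipped: int = 0
    joint_node: object = field(default=None, repr=False, compare=False)


def joint_loss(x_E: Tensor, x_D: DecoderOutput | tuple, targets,
               frame_lengths: np.ndarray, lam: float = 0.5, *,
               epsilon: float = 0.1, decoder_masks=None,
               target_length_norm: bool = False) -> LossReport:
    """``λ·CTC + (1−λ)·mean(KL_forward, KL_reverse)`` for one batch.

    ``x_E``: (B, T, 5) encoder log-probs; ``x_D``: the two decoder tensors
    (teacher-forced, (B, U, 7) log-probs each) with matching label token
    arrays in ``targets`` — a dict with keys ``ctc`` (list of id arrays),
    ``fwd_labels`` and ``rev_labels`` ((B, U) arrays).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    ctc_t, n_skipped = ctc_loss_batch(x_E, targets["ctc"], frame_lengths,
                                      target_length_norm=target_length_norm)
    fwd = x_D.forward_frames if isinstance(x_D, DecoderOutput) else x_D[0]
    rev = x_D.reverse_frames if isinstance(x_D, DecoderOutput) else x_D[1]
    masks = decoder_masks or {}
    kl_f = kldiv_loss(fwd, targets["fwd_labels"], epsilon=epsilon,
                      position_mask=masks.get("fwd"))
    kl_r = kldiv_loss(rev, targets["rev_labels"], epsilon=epsilon,
                      position_mask=masks.get("rev"))
    joint = ctc_t * lam + (kl_f + kl_r) * (0.5 * (1.0 - lam))
    B = x_E.shape[0] if x_E.ndim == 3 else 1
    return LossReport(ctc=float(ctc_t.data), kl_forward=float(kl_f.data),
                      kl_reverse=float(kl_r.data), joint=float(joint.data),
                      batch_size=B, n_skipped=n_skipped, joint_node=joint)
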