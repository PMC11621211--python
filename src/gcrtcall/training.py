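"""Training loop, optimizers and ablation configuration.

The optimization recipe mirrors the published one — Ranger (RAdam +
Lookahead) at learning rate 0.002 with weight decay 0.01, batch size 140,
and a ReduceLROnPlateau schedule on the validation loss (patience 1, factor
0.5, threshold 0.1) — with a desk-scale preset that trains a tiny model on
one CPU core in minutes.  Decoders participate in the joint loss during
training and are excluded from the saved inference checkpoint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor
from .config import EOS, ModelConfig, TrainConfig
from .network import BasecallerModel, save_checkpoint
from .objective import encode_target, joint_loss, teacher_pairs
from .signal_io import chunk_read, read_mapped_hdf5

__all__ = ["Ranger", "AdamW", "ReduceLROnPlateau", "make_ablation", "train",
           "TrainResult"]


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Ranger:
    """RAdam with Lookahead (k=6, alpha=0.5) and decoupled weight decay.

    RAdam rectifies the adaptive step while the second-moment estimate has
    too little variance information, removing the need for explicit warmup;
    Lookahead keeps slow copies of the weights and interpolates toward the
    fast ones every k steps.
    """

    def __init__(self, params, lr=0.002, betas=(0.95, 0.999), eps=1e-5,
                 weight_decay=0.01, lookahead_k=6, lookahead_alpha=0.5):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.k, self.alpha = lookahead_k, lookahead_alpha
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.slow = [p.data.copy() for p in self.params]
        b2 = betas[1]
        self.rho_inf = 2.0 / (1.0 - b2) - 1.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        rho = self.rho_inf - 2.0 * self.t * b2 ** self.t / bc2
        if rho > 4.0:
            r = np.sqrt(((rho - 4) * (rho - 2) * self.rho_inf)
                        / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho))
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / bc1
            if r is not None:
                update = r * m_hat / (np.sqrt(v / bc2) + self.eps)
            else:
                update = m_hat
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update
        if self.t % self.k == 0:
            for p, s in zip(self.params, self.slow):
                s += self.alpha * (p.data - s)
                p.data[...] = s

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def make_optimizer(name: str, params, lr: float, weight_decay: float):
    if name == "ranger":
        return Ranger(params, lr=lr, weight_decay=weight_decay)
    if name == "adamw":
        return AdamW(params, lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")


class ReduceLROnPlateau:
    """Halve (by ``factor``) when the monitored loss stops improving.

    With relative threshold mode a validation loss counts as an improvement
    when it drops below ``best * (1 - threshold)``; after more than
    ``patience`` consecutive non-improving evaluations the learning rate is
    multiplied by ``factor``.
    """

    def __init__(self, optimizer, patience=1, factor=0.5, threshold=0.1,
                 threshold_mode="rel"):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.patience, self.factor = patience, factor
        self.threshold, self.threshold_mode = threshold, threshold_mode
        self.best = np.inf
        self.num_bad = 0

    def _improved(self, value: float) -> bool:
        if self.threshold_mode == "rel":
            return value < self.best * (1.0 - self.threshold)
        return value < self.best - self.threshold

    def step(self, value: float) -> bool:
        """Returns True when the learning rate was reduced."""
        if self._improved(value):
            self.best = value
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad > self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def make_ablation(config: ModelConfig, which: str) -> ModelConfig:
    """Return a config for one of the published ablations.

    ``no_relative_shift`` disables the relative-shift rearrangement of the
    position scores ("w/o RS"); ``transcall`` swaps Conformer blocks for
    plain Transformer layers; ``none`` returns the config unchanged.
    """
    d = config.to_dict()
    if which == "none":
        pass
    elif which == "no_relative_shift":
        d["use_relative_shift"] = False
    elif which == "transcall":
        d["block_type"] = "transformer"
    else:
        raise ValueError(f"unknown ablation {which!r}")
    return ModelConfig.from_dict(d)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _val_split(read_id: str, fraction: float) -> bool:
    h = int(hashlib.md5(read_id.encode()).hexdigest()[:8], 16)
    return (h % 10_000) < fraction * 10_000


def load_examples(dataset_path, train_cfg: TrainConfig, total_stride: int = 10):
    """Read, scale and chunk a mapped-signal file into train/val sets.

    Returns ``(train, val, scaling)`` where ``scaling`` records the signal
    normalization the basecaller must replicate at inference: per-read
    median/MAD ("read"), pooled dataset constants ("dataset"), or none.
    """
    train_reads, val_reads = [], []
    for read in read_mapped_hdf5(dataset_path):
        dest = val_reads if _val_split(read.read_id, train_cfg.val_fraction) \
            else train_reads
        dest.append(read)
    if not train_reads:
        raise ValueError("no training reads after splitting")
    mode = train_cfg.normalization
    scaling = {"mode": mode}
    if mode == "dataset":
        from .signal_io import dataset_scaling, scale_signal
        center, scale = dataset_scaling(train_reads)
        scaling.update(center=center, scale=scale)
        for read in train_reads + val_reads:
            read.samples = scale_signal(read.samples, center, scale)
    stride = train_cfg.chunk_stride or train_cfg.chunk_len
    train, val = [], []
    for reads, dest in ((train_reads, train), (val_reads, val)):
        for read in reads:
            dest.extend(chunk_read(read, train_cfg.chunk_len, stride,
                                   normalize=(mode == "read"),
                                   total_stride=total_stride))
            suffix = _suffix_window(read, train_cfg.chunk_len,
                                    normalize=(mode == "read"))
            if stride < train_cfg.chunk_len and suffix is not None:
                dest.append(suffix)
    return train, val, scaling


def _suffix_window(read, chunk_len: int, *, normalize: bool):
    """A complete window ending exactly at the read's last sample.

    The sliding-window grid labels no base whose dwell is cut by the window
    edge, so the model never sees a labelled final base mid-read; without
    this extra window it learns to suppress emissions near the window end
    and clips the true end of each read at inference.
    """
    from .signal_io import TrainingExample, normalize_signal
    L = len(read.samples)
    if read.boundaries is None or L <= chunk_len:
        return None
    samples = normalize_signal(read.samples) if normalize else read.samples
    off = L - chunk_len
    keep = read.boundaries >= off
    target = "".join(b for b, k in zip(read.sequence, keep) if k)
    return TrainingExample(chunk=samples[off:], target=target,
                           source_read=read.read_id, offset=off,
                           valid_length=chunk_len)


def _make_batches(examples, batch_size, rng):
    """Bucket by length (to limit padding), then shuffle batch order."""
    order = sorted(range(len(examples)),
                   key=lambda i: examples[i].valid_length)
    batches = [order[i:i + batch_size]
               for i in range(0, len(order), batch_size)]
    rng.shuffle(batches)
    return batches


def _prepare_batch(examples, idxs, total_stride: int, *,
                   noise_sd: float = 0.0, rng=None):
    exs = [examples[i] for i in idxs]
    max_valid = max(e.valid_length for e in exs)
    L = -(-max_valid // total_stride) * total_stride  # round up to frame grid
    B = len(exs)
    x = np.zeros((B, L, 1), dtype=np.float32)
    lengths = np.zeros(B, dtype=np.int64)
    ctc_targets, fwd_in, fwd_lab, rev_in, rev_lab = [], [], [], [], []
    for b, e in enumerate(exs):
        chunk = e.chunk[:e.valid_length]
        if noise_sd > 0 and rng is not None:
            chunk = chunk + rng.normal(0.0, noise_sd,
                                       size=chunk.shape).astype(np.float32)
        x[b, :e.valid_length, 0] = chunk
        lengths[b] = e.valid_length
        y = encode_target(e.target)
        ctc_targets.append(y)
        fi, fl = teacher_pairs(y, "forward")
        ri, rl = teacher_pairs(y, "reverse")
        fwd_in.append(fi); fwd_lab.append(fl)
        rev_in.append(ri); rev_lab.append(rl)
    U = max(len(t) for t in fwd_in)
    pad_tok = EOS

    def pad_stack(seqs):
        out = np.full((B, U), pad_tok, dtype=np.int64)
        mask = np.zeros((B, U), dtype=bool)
        for b, s in enumerate(seqs):
            out[b, :len(s)] = s
            mask[b, :len(s)] = True
        return out, mask

    fwd_in, fwd_mask = pad_stack(fwd_in)
    fwd_lab, _ = pad_stack(fwd_lab)
    rev_in, rev_mask = pad_stack(rev_in)
    rev_lab, _ = pad_stack(rev_lab)
    return {"x": x, "lengths": lengths, "ctc": ctc_targets,
            "fwd_in": fwd_in, "fwd_labels": fwd_lab, "fwd_mask": fwd_mask,
            "rev_in": rev_in, "rev_labels": rev_lab, "rev_mask": rev_mask}


def _batch_loss(model: BasecallerModel, batch, model_cfg: ModelConfig,
                train_cfg: TrainConfig):
    logp, hidden, frame_lengths = model.encoder(
        Tensor(batch["x"]), batch["lengths"], return_hidden=True)
    T = hidden.shape[1]
    mem_mask = np.arange(T)[None, :] < frame_lengths[:, None]
    fwd = model.forward_decoder(hidden, batch["fwd_in"],
                                memory_key_mask=mem_mask,
                                token_mask=batch["fwd_mask"])
    rev = model.reverse_decoder(hidden, batch["rev_in"],
                                memory_key_mask=mem_mask,
                                token_mask=batch["rev_mask"])
    targets = {"ctc": batch["ctc"], "fwd_labels": batch["fwd_labels"],
               "rev_labels": batch["rev_labels"]}
    masks = {"fwd": batch["fwd_mask"], "rev": batch["rev_mask"]}
    return joint_loss(logp, (fwd, rev), targets, frame_lengths,
                      lam=model_cfg.lambda_weight,
                      epsilon=model_cfg.label_smoothing,
                      decoder_masks=masks,
                      target_length_norm=train_cfg.ctc_target_length_norm)


def _clip_gradients(params, max_norm: float):
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


@dataclass
class TrainResult:
    model: BasecallerModel
    history: list = field(default_factory=list)   # per-step loss records
    val_history: list = field(default_factory=list)
    n_skipped: int = 0
    checkpoint_path: Optional[Path] = None


def train(model_config: ModelConfig, train_config: TrainConfig, dataset_path,
          out_dir=None, ablation: str = "none",
          log_every: int = 1) -> TrainResult:
    """Optimize the joint loss on a mapped-signal dataset.

    Deterministic given the seeds in the configs (up to BLAS reduction
    order).  Writes ``checkpoint.npz`` (inference weights only) and a JSONL
    step log when ``out_dir`` is given.
    """
    model_config = make_ablation(model_config, ablation)
    model = BasecallerModel(model_config).train()
    params = model.parameters()
    opt = make_optimizer(train_config.optimizer_name, params,
                         train_config.learning_rate,
                         train_config.weight_decay)
    sched = ReduceLROnPlateau(opt,
                              patience=train_config.scheduler.patience,
                              factor=train_config.scheduler.factor,
                              threshold=train_config.scheduler.threshold,
                              threshold_mode=train_config.scheduler.threshold_mode)
    rng = np.random.default_rng(train_config.seed)
    train_ex, val_ex, scaling = load_examples(dataset_path, train_config,
                                              model_config.total_stride)
    model.signal_scaling = scaling

    out_dir = Path(out_dir) if out_dir is not None else None
    log_fh = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_fh = open(out_dir / "train_log.jsonl", "w")

    result = TrainResult(model=model)
    step = 0
    swa_sum, swa_n = None, 0
    try:
        for epoch in range(train_config.epochs):
            model.train()
            if epoch > 0:
                opt.lr *= train_config.epoch_lr_scale
            in_swa = train_config.swa and epoch == train_config.epochs - 1
            for idxs in _make_batches(train_ex, train_config.batch_size, rng):
                batch = _prepare_batch(train_ex, idxs,
                                       model_config.total_stride,
                                       noise_sd=train_config.input_noise_sd,
                                       rng=rng)
                model.zero_grad()
                report = _batch_loss(model, batch, model_config, train_config)
                result.n_skipped += report.n_skipped
                if not np.isfinite(report.joint):
                    raise FloatingPointError(
                        f"non-finite loss at step {step}: {report}")
                report.joint_node.backward()
                _clip_gradients(params, train_config.grad_clip)
                opt.step()
                step += 1
                if in_swa and step % 10 == 0:
                    if swa_sum is None:
                        swa_sum = [p.data.copy() for p in params]
                    else:
                        for s, p in zip(swa_sum, params):
                            s += p.data
                    swa_n += 1
                rec = {"step": step, "epoch": epoch, "lr": opt.lr,
                       "ctc": report.ctc, "kl_fwd": report.kl_forward,
                       "kl_rev": report.kl_reverse, "joint": report.joint}
                result.history.append(rec)
                if log_fh and step % log_every == 0:
                    log_fh.write(json.dumps(rec) + "\n")
            val_loss = evaluate_loss(model, val_ex or train_ex,
                                     model_config, train_config)
            result.val_history.append({"epoch": epoch, "val_loss": val_loss,
                                       "lr": opt.lr})
            sched.step(val_loss)
            if log_fh:
                log_fh.write(json.dumps(
                    {"epoch": epoch, "val_loss": val_loss, "lr": opt.lr}) + "\n")
                log_fh.flush()
    finally:
        if log_fh:
            log_fh.close()
    if swa_n > 1:
        for s, p in zip(swa_sum, params):
            p.data[...] = s / swa_n
        _refresh_batchnorm(model, train_ex, model_config, train_config, rng)
    model.eval()
    if out_dir is not None:
        ckpt = out_dir / "checkpoint.npz"
        save_checkpoint(ckpt, model, include_decoders=False,
                        extra={"steps": step, "signal_scaling": scaling})
        result.checkpoint_path = ckpt
    return result


def _refresh_batchnorm(model, examples, model_config, train_config, rng,
                       n_batches: int = 60):
    """Recompute batch-norm running statistics for averaged weights."""
    from . import nn
    from .autodiff import Tensor, no_grad
    bns = [m for m in model.encoder.modules()
           if isinstance(m, nn.BatchNorm1d)]
    for bn in bns:
        bn._buffers["running_mean"][:] = 0.0
        bn._buffers["running_var"][:] = 1.0
        bn.momentum = 0.2
    model.train()
    with no_grad():
        for idxs in _make_batches(examples, train_config.batch_size,
                                  rng)[:n_batches]:
            batch = _prepare_batch(examples, idxs, model_config.total_stride)
            model.encoder(Tensor(batch["x"]), batch["lengths"])
    for bn in bns:
        bn.momentum = 0.1


def evaluate_loss(model: BasecallerModel, examples, model_config: ModelConfig,
                  train_config: TrainConfig) -> float:
    """Mean joint loss over a held-out example list (eval mode)."""
    from .autodiff import no_grad
    was_training = model.training
    model.eval()
    rng = np.random.default_rng(0)
    losses = []
    with no_grad():
        for idxs in _make_batches(examples, train_config.batch_size, rng):
            batch = _prepare_batch(examples, idxs, model_config.total_stride)
            report = _batch_loss(model, batch, model_config, train_config)
            losses.append(report.joint)
    if was_training:
        model.train()
    return float(np.mean(losses))
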