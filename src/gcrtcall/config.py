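"""Model and training configuration.

``ModelConfig`` holds every architectural hyperparameter of the basecaller,
including the two ablation switches: ``use_relative_shift=False`` removes the
relative-shift operation from the position scores ("w/o RS"), and
``block_type="transformer"`` swaps the Conformer blocks for plain Transformer
encoder layers with absolute sinusoidal positions ("Transcall").

Defaults reproduce the published architecture: a 3-layer convolutional
frontend (channels 4/6/512, kernels 5/5/19, strides 1/1/10, i.e. 10x
downsampling), 8 Conformer blocks, a 5-symbol CTC head, and two training-only
causal decoder stacks (forward and reverse).  The encoder width, head count,
feed-forward expansion and block kernel are chosen so the inference network
totals ~50M trainable parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

VOCAB = ("-", "A", "C", "G", "U")  # index 0 is the CTC blank
BASES = "ACGU"
# decoder token ids: bases share encoder ids; SOS/EOS appended
SOS, EOS = 5, 6
DECODER_VOCAB_SIZE = 7


@dataclass
class ModelConfig:
    frontend_channels: tuple = (4, 6, 512)
    frontend_kernels: tuple = (5, 5, 19)
    frontend_strides: tuple = (1, 1, 10)
    n_blocks: int = 8
    d_model: int = 512
    n_heads: int = 8
    ff_expansion: int = 4
    conv_kernel: int = 31
    dropout: float = 0.1
    use_relative_shift: bool = True
    block_type: str = "conformer"  # or "transformer" (Transcall ablation)
    n_decoder_layers: int = 2
    lambda_weight: float = 0.5
    label_smoothing: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.frontend_channels = tuple(self.frontend_channels)
        self.frontend_kernels = tuple(self.frontend_kernels)
        self.frontend_strides = tuple(self.frontend_strides)
        if not (len(self.frontend_channels) == len(self.frontend_kernels)
                == len(self.frontend_strides) == 3):
            raise ValueError("frontend specs must each have length 3")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.block_type not in ("conformer", "transformer"):
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def total_stride(self) -> int:
        s = 1
        for x in self.frontend_strides:
            s *= x
        return s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("frontend_channels", "frontend_kernels", "frontend_strides"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: trains in minutes on one CPU core."""
        base = dict(frontend_channels=(16, 32, 64), n_blocks=2, d_model=64,
                    n_heads=4, ff_expansion=4, conv_kernel=15, dropout=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class SchedulerConfig:
    patience: int = 1
    factor: float = 0.5
    threshold: float = 0.1
    threshold_mode: str = "rel"  # or "abs"

    def __post_init__(self):
        if not 0.0 < self.factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class TrainConfig:
    batch_size: int = 140
    learning_rate: float = 0.002
    weight_decay: float = 0.01
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    epochs: int = 12
    seed: int = 0
    optimizer_name: str = "ranger"  # or "adamw"
    grad_clip: float = 5.0
    val_fraction: float = 0.05
    chunk_len: int = 4096
    chunk_stride: int | None = None  # None: non-overlapping windows
    normalization: str = "read"      # "read" | "dataset" | "none"
    epoch_lr_scale: float = 1.0      # extra per-epoch LR decay factor
    input_noise_sd: float = 0.0      # Gaussian dither on training chunks
    swa: bool = False                # average weights over the final epoch
    ctc_target_length_norm: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.normalization not in ("read", "dataset", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0.0 < self.epoch_lr_scale <= 1.0:
            raise ValueError("epoch_lr_scale must lie in (0, 1]")
        if isinstance(self.scheduler, dict):
            self.scheduler = SchedulerConfig(**self.scheduler)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU-friendly preset used by the scaled-down protocols.

        Short overlapping windows multiply the gradient steps per epoch, a
        per-epoch LR decay sharpens the final fit, and pooled (dataset)
        signal scaling avoids the unstable per-read statistics of very
        short synthetic reads.
        """
        base = dict(batch_size=8, learning_rate=0.01, epochs=3,
                    chunk_len=512, chunk_stride=24, normalization="dataset",
                    epoch_lr_scale=0.4, swa=True)
        base.update(overrides)
        return cls(**base)
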