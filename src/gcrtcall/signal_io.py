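"""Mapped-signal I/O, normalization and chunking.

Reads the Taiyaki-style mapped-signal HDF5 layout (``Reads/<id>`` groups
with raw signal, integer-encoded reference and base-to-sample mapping),
normalizes raw signals by the per-read median / scaled-MAD, and cuts reads
into fixed-length chunks with CTC-feasible base targets.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import h5py
import numpy as np

from .config import BASES

__all__ = ["RawRead", "TrainingExample", "read_mapped_hdf5",
           "normalize_signal", "chunk_read"]

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes the MAD a consistent SD estimator for a Gaussian
_EPS = 1e-8


@dataclass
class RawRead:
    read_id: str
    samples: np.ndarray
    sequence: Optional[str] = None
    boundaries: Optional[np.ndarray] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.size == 0:
            raise ValueError(f"read {self.read_id}: empty signal")
        if self.boundaries is not None:
            self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
            if self.sequence is None or len(self.boundaries) != len(self.sequence):
                raise ValueError(f"read {self.read_id}: boundaries require a "
                                 "sequence of matching length")
            if len(self.boundaries) and (
                    np.any(np.diff(self.boundaries) <= 0)
                    or self.boundaries[0] < 0
                    or self.boundaries[-1] >= len(self.samples)):
                raise ValueError(f"read {self.read_id}: invalid boundaries")


@dataclass
class TrainingExample:
    """One fixed-length normalized chunk with its base-string target."""

    chunk: np.ndarray
    target: str
    source_read: str
    offset: int
    valid_length: int

    def __post_init__(self):
        self.chunk = np.asarray(self.chunk, dtype=np.float32)
        if self.valid_length > len(self.chunk):
            raise ValueError("valid_length exceeds chunk length")


def read_mapped_hdf5(path) -> Iterator[RawRead]:
    """Stream reads from a Taiyaki-style mapped-signal file.

    Malformed read groups are skipped with a logged warning carrying the
    read_id; a file with no ``Reads`` group (or none readable) raises.
    """
    with h5py.File(path, "r") as fh:
        if "Reads" not in fh or len(fh["Reads"]) == 0:
            raise ValueError(f"{path}: no reads found (missing/empty 'Reads' group)")
        n_yielded = 0
        for read_id in fh["Reads"]:
            g = fh["Reads"][read_id]
            try:
                samples = np.asarray(g["Dacs"], dtype=np.float32)
                ref = np.asarray(g["Reference"], dtype=np.int64)
                if np.any(ref < 0) or np.any(ref >= len(BASES)):
                    raise ValueError("reference codes out of range")
                sequence = "".join(BASES[i] for i in ref)
                r2s = np.asarray(g["Ref_to_signal"], dtype=np.int64)
                boundaries = r2s[:-1] if len(r2s) == len(sequence) + 1 else r2s
                read = RawRead(read_id=read_id, samples=samples,
                               sequence=sequence, boundaries=boundaries)
            except (KeyError, ValueError) as exc:
                logger.warning("skipping read %s: %s", read_id, exc)
                continue
            n_yielded += 1
            yield read
        if n_yielded == 0:
            raise ValueError(f"{path}: every read group was malformed")


def normalize_signal(samples: np.ndarray) -> np.ndarray:
    """Per-read median / scaled-MAD normalization (robust to current spikes).

    Returns ``(x - median(x)) / max(1.4826 * median(|x - median(x)|), eps)``.
    """
    samples = np.asarray(samples, dtype=np.float32)
    if samples.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(samples)
    mad = MAD_SCALE * np.median(np.abs(samples - med))
    return ((samples - med) / max(mad, _EPS)).astype(np.float32)


def dataset_scaling(reads) -> tuple[float, float]:
    """Pooled median / scaled-MAD over a collection of reads.

    For very short reads the per-read statistics of :func:`normalize_signal`
    have large sampling error (the median of a few dozen dwell levels moves
    by a sizeable fraction of the level spacing read to read); pooling the
    same robust statistics over the whole dataset gives stable constants.
    """
    pooled = np.concatenate([np.asarray(r.samples, dtype=np.float32)
                             for r in reads])
    if pooled.size == 0:
        raise ValueError("no samples to estimate scaling from")
    med = float(np.median(pooled))
    mad = MAD_SCALE * float(np.median(np.abs(pooled - med)))
    return med, max(mad, _EPS)


def scale_signal(samples: np.ndarray, center: float, scale: float) -> np.ndarray:
    return ((np.asarray(samples, dtype=np.float32) - center)
            / max(scale, _EPS)).astype(np.float32)


def n_output_frames(length: int, total_stride: int = 10) -> int:
    """Encoder frames produced for ``length`` input samples (same padding)."""
    if length < 1:
        return 0
    return (length - 1) // total_stride + 1


def chunk_read(read: RawRead, chunk_len: int, stride: int, *,
               normalize: bool = True, total_stride: int = 10,
               drop_infeasible: bool = True) -> list[TrainingExample]:
    """Cut a read into fixed-length windows at offsets 0, stride, 2*stride...

    The final partial window is zero-padded with its valid length recorded.
    When the read carries a base-to-sample mapping, each chunk's target is
    the bases whose dwell START falls inside ``[offset, offset+chunk_len)``;
    bases straddling the right edge are excluded.  Chunks whose target
    cannot fit in the encoder's output frames (CTC-infeasible) are dropped
    when ``drop_infeasible`` is set.
    """
    if chunk_len < 1:
        raise ValueError("chunk_len must be >= 1")
    if not 1 <= stride <= chunk_len:
        raise ValueError("stride must satisfy 1 <= stride <= chunk_len")
    samples = normalize_signal(read.samples) if normalize else \
        np.asarray(read.samples, dtype=np.float32)
    L = len(samples)
    examples = []
    offset = 0
    while offset < L:
        window = samples[offset:offset + chunk_len]
        valid = len(window)
        if valid < chunk_len:
            window = np.pad(window, (0, chunk_len - valid))
        target = ""
        if read.boundaries is not None:
            ends = np.append(read.boundaries[1:], len(read.samples))
            lo = np.searchsorted(read.boundaries, offset, side="left")
            hi = np.searchsorted(read.boundaries, offset + valid, side="left")
            # bases straddling the right edge (dwell truncated) are excluded
            while hi > lo and ends[hi - 1] > offset + valid:
                hi -= 1
            target = read.sequence[lo:hi]
        if drop_infeasible and len(target) > n_output_frames(valid, total_stride):
            offset += stride
            continue
        examples.append(TrainingExample(chunk=window, target=target,
                                        source_read=read.read_id,
                                        offset=offset, valid_length=valid))
        if offset + chunk_len >= L:
            break
        offset += stride
    return examples
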