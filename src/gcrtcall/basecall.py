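"""CTC decoding and end-to-end basecalling.

Raw signal is normalized, cut into overlapping chunks, run through the
encoder, decoded per chunk (greedy collapse or prefix beam search over the
collapsed-label posterior), and stitched by trimming the overlapping frame
flanks so no base is emitted twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import VOCAB
from .network import BasecallerModel, FrameLogProbs
from .signal_io import RawRead, normalize_signal, read_mapped_hdf5, scale_signal

__all__ = ["DecodeConfig", "BasecallResult", "greedy_decode", "beam_decode",
           "stitch_chunks", "basecall_read", "basecall_file", "write_calls"]


@dataclass
class DecodeConfig:
    mode: str = "greedy"        # or "beam"
    beam_width: int = 8
    blank_bias: float = 0.0     # subtracted from blank log-probs pre-decode;
                                # counteracts CTC under-emission of short dwells
    chunk_len: int = 4096
    overlap: int = 200          # samples shared between adjacent chunks
    emit_quality: bool = True
    dna_alphabet: bool = False  # write T instead of U
    reverse_output: bool = False  # direct RNA passes the pore 3'->5'

    def __post_init__(self):
        if self.mode not in ("greedy", "beam"):
            raise ValueError(f"unknown decode mode {self.mode!r}")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        # frame-aligned stitching needs sample-domain geometry on the
        # 10-sample frame grid
        self.overlap -= self.overlap % 10
        if self.overlap >= self.chunk_len:
            raise ValueError("overlap must be smaller than chunk_len")


@dataclass
class BasecallResult:
    read_id: str
    sequence: str
    mean_frame_confidence: float
    n_chunks: int

    def __post_init__(self):
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")


def _valid_frames(frames: FrameLogProbs) -> np.ndarray:
    f = np.asarray(frames.frames)
    if f.ndim == 3:
        if f.shape[0] != 1:
            raise ValueError("expected a single example")
        f = f[0]
    return f[: int(frames.valid_lengths[0])]


def greedy_decode(frames: FrameLogProbs) -> str:
    """Argmax per frame, collapse consecutive repeats, drop blanks."""
    logp = _valid_frames(frames)
    ids = np.argmax(logp, axis=-1)
    out = []
    prev = 0
    for i in ids:
        if i != 0 and i != prev:
            out.append(VOCAB[i])
        prev = i
    return "".join(out)


def beam_decode(frames: FrameLogProbs, width: int) -> str:
    """CTC prefix beam search over the collapsed-label posterior.

    Hypotheses collapsing to the same prefix are merged; the beam keeps the
    ``width`` highest-probability prefixes per frame, ties broken
    lexicographically.  For small frame counts a wide enough beam returns
    the exact maximum-posterior label sequence.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    logp = _valid_frames(frames).astype(np.float64)
    T, V = logp.shape
    # prefix -> (log P ending in blank, log P ending in non-blank)
    beams = {(): (0.0, -np.inf)}
    for t in range(T):
        nxt: dict = {}

        def add(prefix, pb, pnb):
            old = nxt.get(prefix, (-np.inf, -np.inf))
            nxt[prefix] = (np.logaddexp(old[0], pb) if pb != -np.inf else old[0],
                           np.logaddexp(old[1], pnb) if pnb != -np.inf else old[1])

        for prefix, (pb, pnb) in beams.items():
            total = np.logaddexp(pb, pnb)
            # blank keeps the prefix
            add(prefix, total + logp[t, 0], -np.inf)
            last = prefix[-1] if prefix else None
            for s in range(1, V):
                p_s = logp[t, s]
                if s == last:
                    # repeat without blank extends the same prefix;
                    # after a blank it starts a new symbol
                    add(prefix, -np.inf, pnb + p_s)
                    add(prefix + (s,), -np.inf, pb + p_s)
                else:
                    add(prefix + (s,), -np.inf, total + p_s)
        ranked = sorted(nxt.items(),
                        key=lambda kv: (-np.logaddexp(*kv[1]), kv[0]))
        beams = dict(ranked[:width])
    best = min(beams.items(), key=lambda kv: (-np.logaddexp(*kv[1]), kv[0]))[0]
    return "".join(VOCAB[s] for s in best)


def decode_frames(frames: FrameLogProbs, cfg: DecodeConfig) -> str:
    if cfg.blank_bias:
        logp = np.array(frames.frames, copy=True)
        logp[..., 0] -= cfg.blank_bias
        frames = FrameLogProbs(frames=logp, valid_lengths=frames.valid_lengths)
    if cfg.mode == "beam":
        return beam_decode(frames, cfg.beam_width)
    return greedy_decode(frames)


def stitch_chunks(chunk_frames: Sequence[FrameLogProbs], overlap: int,
                  cfg: DecodeConfig | None = None, *,
                  total_stride: int = 10) -> str:
    """Decode overlapping chunk frames into one sequence.

    Adjacent chunks share ``overlap`` samples = ``overlap/total_stride``
    frames.  Each junction is cut once inside the shared window — at the
    position nearest its midpoint where both chunks' argmax symbol is the
    CTC blank, falling back to the midpoint when no such frame exists — so
    every frame is decoded exactly once and no base emission can straddle
    the cut.  The per-chunk decodes are then concatenated.
    """
    cfg = cfg or DecodeConfig(overlap=overlap)
    if overlap % total_stride:
        raise ValueError("overlap must be a multiple of the frontend stride")
    if not chunk_frames:
        raise ValueError("no chunks to stitch")
    ov_f = overlap // total_stride
    n_frames = [int(f.valid_lengths[0]) for f in chunk_frames]
    if len(chunk_frames) > 1 and min(n_frames[:-1]) <= ov_f:
        raise ValueError("chunk geometry inconsistent with overlap")

    logps = [_valid_frames(f) for f in chunk_frames]
    # cut position (within the shared window) for each junction
    cuts = []
    for i in range(len(logps) - 1):
        left, right = logps[i], logps[i + 1]
        best = ov_f // 2
        if ov_f > 0:
            left_ids = np.argmax(left[len(left) - ov_f:], axis=-1)
            right_ids = np.argmax(right[:ov_f], axis=-1)
            both_blank = np.flatnonzero((left_ids == 0) & (right_ids == 0))
            if len(both_blank):
                best = int(both_blank[np.argmin(np.abs(both_blank
                                                       - ov_f / 2))])
        cuts.append(best)

    pieces = []
    for i, logp in enumerate(logps):
        a = cuts[i - 1] if i > 0 else 0
        b = len(logp) - (ov_f - cuts[i]) if i < len(logps) - 1 else len(logp)
        piece = FrameLogProbs(frames=logp[a:b], valid_lengths=[b - a])
        pieces.append(decode_frames(piece, cfg))
    return "".join(pieces)


def _apply_scaling(model: BasecallerModel, samples: np.ndarray) -> np.ndarray:
    scaling = getattr(model, "signal_scaling", {"mode": "read"})
    mode = scaling.get("mode", "read")
    if mode == "read":
        return normalize_signal(samples)
    if mode == "dataset":
        return scale_signal(samples, scaling["center"], scaling["scale"])
    return np.asarray(samples, dtype=np.float32)


def basecall_read(model: BasecallerModel, read: RawRead,
                  cfg: DecodeConfig) -> BasecallResult:
    """Scale (as the model was trained), chunk, encode, decode, stitch."""
    samples = _apply_scaling(model, read.samples)
    stride = cfg.chunk_len - cfg.overlap
    offsets = list(range(0, max(len(samples) - cfg.overlap, 1), stride))
    chunk_frames: List[FrameLogProbs] = []
    confidences = []
    for off in offsets:
        window = samples[off:off + cfg.chunk_len]
        frames = model.encode(window[None, :, None],
                              valid_lengths=np.array([len(window)]))
        chunk_frames.append(frames)
        logp = _valid_frames(frames)
        confidences.append(np.exp(logp.max(axis=-1)).mean())
    sequence = stitch_chunks(chunk_frames, cfg.overlap if len(offsets) > 1 else 0,
                             cfg)
    if cfg.reverse_output:
        sequence = sequence[::-1]
    if cfg.dna_alphabet:
        sequence = sequence.replace("U", "T")
    return BasecallResult(read_id=read.read_id, sequence=sequence,
                          mean_frame_confidence=float(np.mean(confidences)),
                          n_chunks=len(offsets))


def basecall_file(model: BasecallerModel, path, cfg: DecodeConfig) \
        -> Iterable[BasecallResult]:
    for read in read_mapped_hdf5(path):
        yield basecall_read(model, read, cfg)


def _phred(confidence: float) -> int:
    err = max(1.0 - confidence, 1e-4)
    return min(40, int(round(-10.0 * math.log10(err))))


def write_calls(results: Sequence[BasecallResult], path,
                fmt: str = "fasta") -> None:
    """Write calls as multi-record FASTA or FASTQ (constant per-base quality
    derived from the mean frame confidence, Phred-capped at 40)."""
    results = list(results)
    if not results:
        raise ValueError("no basecall results to write")
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    records = []
    for r in results:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            q = _phred(r.mean_frame_confidence)
            rec.letter_annotations["phred_quality"] = [q] * len(r.sequence)
        records.append(rec)
    count = SeqIO.write(records, str(path), fmt)
    if count != len(records):
        raise OSError(f"failed to write all records to {path}")
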