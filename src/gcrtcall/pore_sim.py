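"""Synthetic direct-RNA squiggle simulator.

Real direct-RNA training data pairs each read's raw current trace with a
corrected reference sequence and a base-to-sample mapping.  This module
produces desk-scale stand-ins with the same statistical structure: k-mer
dependent current levels (neighbouring bases shift the level, as in a real
pore), per-base dwell times consistent with RNA translocating at or below
~100 bases/s, additive Gaussian within-dwell noise, and exact ground-truth
labels over {A, C, G, U}.

The level table is not a physical pore model: levels are drawn once from a
seeded generator on an evenly spaced grid with a guaranteed minimum pairwise
gap, which makes the noise-free reconstruction oracle (and hence the
learnability tests downstream) well-posed.

Dwell model: the per-base dwell (in samples) is ``1 + NegBinomial(r, p)``
with mean ``sampling_rate / translocation_speed``; the dispersion parameter
interpolates between a deterministic dwell (0) and the geometric
distribution (1, the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .config import BASES

__all__ = ["PoreModel", "SimConfig", "SimulatedRead", "make_pore_model",
           "simulate_read", "simulate_dataset", "write_truth_fasta"]

_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


@dataclass
class PoreModel:
    """Maps every k-mer over {A,C,G,U} to a mean current level and noise SD."""

    k: int
    level_mean: dict
    level_sd: dict

    def __post_init__(self):
        n_expected = 4 ** self.k
        if len(self.level_mean) != n_expected or len(self.level_sd) != n_expected:
            raise ValueError(f"pore model must cover all {n_expected} {self.k}-mers")
        means = np.array(list(self.level_mean.values()), dtype=float)
        sds = np.array(list(self.level_sd.values()), dtype=float)
        if not np.all(np.isfinite(means)):
            raise ValueError("level means must be finite")
        if not np.all(sds > 0):
            raise ValueError("all level SDs must be positive")

    def context_kmer(self, sequence: str, i: int) -> str:
        """Centered k-mer context of base ``i``, edge-padded by repetition."""
        half = (self.k - 1) // 2
        idx = np.clip(np.arange(i - half, i - half + self.k), 0, len(sequence) - 1)
        return "".join(sequence[j] for j in idx)


@dataclass
class SimConfig:
    """Squiggle generation parameters.

    Defaults (3012 samples/s, 70 bases/s) are typical direct-RNA values;
    the mean dwell is ``sampling_rate / translocation_speed`` samples.
    """

    sampling_rate: float = 3012.0
    translocation_speed: float = 70.0
    dwell_dispersion: float = 1.0
    noise_sd_scale: float = 1.0
    seed: int = 0
    reverse_signal: bool = False  # direct RNA is read 3'->5'; off for synthetic

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.translocation_speed <= 100:
            raise ValueError("translocation_speed must lie in (0, 100] bases/s")
        if self.dwell_dispersion < 0:
            raise ValueError("dwell_dispersion must be >= 0")
        if self.noise_sd_scale < 0:
            raise ValueError("noise_sd_scale must be >= 0")

    @property
    def mean_dwell(self) -> float:
        return self.sampling_rate / self.translocation_speed


@dataclass
class SimulatedRead:
    read_id: str
    samples: np.ndarray
    sequence: str
    boundaries: np.ndarray  # first signal sample index of each base

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        if len(self.boundaries) != len(self.sequence):
            raise ValueError("one boundary per base required")
        if len(self.boundaries) and (
                np.any(np.diff(self.boundaries) <= 0)
                or self.boundaries[-1] >= len(self.samples)
                or self.boundaries[0] < 0):
            raise ValueError("boundaries must be strictly increasing and in range")


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in BASES]
    return kmers


def make_pore_model(k: int, seed: int, *, level_range: float = 5.0,
                    context_span: float = 0.7,
                    min_gap: float | None = None) -> PoreModel:
    """Build a seeded k-mer level table with well-separated means.

    The table is center-base dominant, mirroring the physics of a real pore
    where the nucleotide in the constriction sets the bulk of the current
    and flanking bases modulate it: each of the four central bases owns one
    of four evenly spaced bands across ``[-level_range/2, level_range/2]``,
    and the ``4^(k-1)`` flanking contexts spread over the middle
    ``context_span`` fraction of the band as a jittered, permuted grid.
    The minimum pairwise gap between any two k-mer levels stays above
    ``min_gap`` (default: 40% of the within-band grid spacing), so a
    noise-free squiggle is exactly decodable.  Within-dwell noise SDs are
    drawn uniformly in [0.08, 0.12].
    """
    if not 1 <= int(k) == k:
        raise ValueError("k must be a positive integer")
    if k > 6:
        raise ValueError("k > 6 is not supported (4^k levels become degenerate)")
    rng = np.random.default_rng(seed)
    kmers = _all_kmers(k)
    center = (k - 1) // 2
    band_width = level_range / 4.0
    band_centers = (np.arange(4) - 1.5) * band_width
    n_ctx = 4 ** (k - 1)
    if n_ctx > 1:
        spacing = context_span * band_width / (n_ctx - 1)
        if min_gap is None:
            min_gap = 0.4 * spacing
        jitter_amp = max((spacing - min_gap) / 2.0, 0.0)
        grid = np.linspace(-context_span * band_width / 2,
                           context_span * band_width / 2, n_ctx)
    else:
        grid = np.zeros(1)
        jitter_amp = 0.0
    levels = {}
    for b, base in enumerate(BASES):
        offsets = rng.permutation(grid + rng.uniform(-jitter_amp, jitter_amp,
                                                     size=n_ctx))
        ctx_kmers = [km for km in kmers if km[center] == base]
        for km, off in zip(ctx_kmers, offsets):
            levels[km] = float(band_centers[b] + off)
    level_mean = {km: levels[km] for km in kmers}
    sds = rng.uniform(0.08, 0.12, size=len(kmers))
    return PoreModel(k=k, level_mean=level_mean,
                     level_sd=dict(zip(kmers, sds.tolist())))


def _draw_dwells(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mu = cfg.mean_dwell
    if mu < 1:
        raise ValueError("mean dwell below one sample per base")
    delta = cfg.dwell_dispersion
    if delta == 0:
        # deterministic Bresenham-style dwell: exact long-run mean, integer dwells
        acc = np.floor(np.arange(1, n + 1) * mu) - np.floor(np.arange(n) * mu)
        return acc.astype(np.int64)
    r = 1.0 / delta
    p = r / (r + mu - 1.0)
    return 1 + rng.negative_binomial(r, p, size=n).astype(np.int64)


def _validate_sequence(sequence: str, k: int) -> None:
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    bad = set(sequence) - set(BASES)
    if bad:
        raise ValueError(f"sequence contains invalid symbols {sorted(bad)}; "
                         f"alphabet is {{A,C,G,U}}")


def simulate_read(sequence: str, model: PoreModel, cfg: SimConfig,
                  seed: int, read_id: str = "read") -> SimulatedRead:
    """Simulate one squiggle for ``sequence``; deterministic given ``seed``."""
    sequence = sequence.upper().replace("T", "U")
    _validate_sequence(sequence, model.k)
    rng = np.random.default_rng(seed)
    n = len(sequence)
    dwells = _draw_dwells(n, cfg, rng)
    boundaries = np.concatenate([[0], np.cumsum(dwells)[:-1]])
    total = int(dwells.sum())
    samples = np.empty(total, dtype=np.float32)
    for i in range(n):
        km = model.context_kmer(sequence, i)
        lo, hi = boundaries[i], boundaries[i] + dwells[i]
        level = model.level_mean[km]
        if cfg.noise_sd_scale > 0:
            sd = cfg.noise_sd_scale * model.level_sd[km]
            samples[lo:hi] = level + rng.normal(0.0, sd, size=hi - lo)
        else:
            samples[lo:hi] = level
    if cfg.reverse_signal:
        samples = samples[::-1].copy()
        boundaries = total - (boundaries + dwells)
        boundaries = boundaries[::-1].copy()
        sequence = sequence[::-1]
    return SimulatedRead(read_id=read_id, samples=samples,
                         sequence=sequence, boundaries=boundaries)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def simulate_dataset(n_reads: int, length_range: tuple[int, int],
                     model: PoreModel, cfg: SimConfig, out_path,
                     fasta_path=None) -> list[SimulatedRead]:
    """Simulate ``n_reads`` reads and write a Taiyaki-style mapped-signal HDF5.

    Sequence lengths are uniform over ``length_range`` (inclusive) and
    sequences are uniform over {A,C,G,U}; everything derives from
    ``cfg.seed``.  Optionally also writes the ground-truth sequences as a
    FASTA for the evaluator.  Returns the simulated reads.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    lo, hi = length_range
    if lo < model.k:
        raise ValueError("minimum length must be >= k")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with max >= min")
    rng = np.random.default_rng(cfg.seed)
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        seq = random_sequence(length, rng)
        read_seed = int(rng.integers(0, 2 ** 31 - 1))
        reads.append(simulate_read(seq, model, cfg, read_seed,
                                   read_id=f"read_{i:05d}"))
    write_mapped_hdf5(reads, out_path)
    if fasta_path is not None:
        write_truth_fasta(reads, fasta_path)
    return reads


def write_mapped_hdf5(reads: Sequence[SimulatedRead], out_path) -> None:
    """Write reads in the Taiyaki mapped-signal layout.

    ``Reads/<id>`` groups hold ``Dacs`` (raw signal), ``Reference``
    (integer-encoded bases, 0..3 = A,C,G,U) and ``Ref_to_signal``
    (per-base start sample indices plus an end sentinel, length n+1).
    """
    out_path = Path(out_path)
    try:
        fh = h5py.File(out_path, "w")
    except OSError as exc:
        raise OSError(f"cannot write dataset to {out_path}: {exc}") from exc
    with fh:
        fh.attrs["alphabet"] = BASES
        grp = fh.create_group("Reads")
        for read in reads:
            g = grp.create_group(read.read_id)
            g.create_dataset("Dacs", data=read.samples.astype(np.float32))
            ref = np.array([_BASE_TO_INT[b] for b in read.sequence], dtype=np.int8)
            g.create_dataset("Reference", data=ref)
            r2s = np.concatenate([read.boundaries,
                                  [len(read.samples)]]).astype(np.int64)
            g.create_dataset("Ref_to_signal", data=r2s)


def write_truth_fasta(reads: Iterable[SimulatedRead], fasta_path) -> None:
    with open(fasta_path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")


def reconstruct_noise_free(samples: np.ndarray, model: PoreModel,
                           dwell: int) -> str:
    """Decode a dispersion-free, noise-free squiggle by nearest level mean.

    Oracle for decodability: with a constant integer ``dwell`` (samples per
    base) and zero noise, mapping one sample per dwell back to the nearest
    k-mer level recovers the centered-context base sequence exactly, because
    the level table enforces a minimum pairwise gap.
    """
    kmers = list(model.level_mean)
    levels = np.array([model.level_mean[km] for km in kmers])
    n = len(samples) // dwell
    out = []
    for i in range(n):
        v = samples[i * dwell]
        out.append(kmers[int(np.argmin(np.abs(levels - v)))])
    return "".join(km[(model.k - 1) // 2] for km in out)
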