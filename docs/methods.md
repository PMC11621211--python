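# Methods

This note documents the models, numerical choices, and open design
decisions behind the package, and what the synthetic-data experiments do
and do not demonstrate.

## Network

The encoder maps a normalized raw-current chunk of length L to
`floor((L−1)/10)+1` frames of log-probabilities over {blank, A, C, G, U}.

**Frontend.** Three 1-D convolutions with channels (4, 6, 512), kernels
(5, 5, 19), strides (1, 1, 10), each followed by a swish activation, with
"same" padding throughout so the downsampling arithmetic is exactly 10×.
When the block width differs from the last frontend channel count (as in
the desk-scale preset) a linear projection follows.

**Conformer blocks.** Pre-norm residual sub-blocks in the order: half-step
feed-forward (×0.5 residual weight), relative-position multi-head
self-attention, gated depthwise-separable convolution, half-step
feed-forward, final layer norm. The convolution module is pointwise conv
(d→2d) → GLU → depthwise conv (kernel 31, one filter per channel) → batch
normalization → swish, with no trailing pointwise convolution. Batch
normalization uses batch statistics in training and running statistics
(momentum 0.1) at inference.

**Relative attention.** Per head,
`softmax([(Q+b_k)Kᵀ + shift((Q+b_p)K_pᵀ)]/√d_k)·V`, heads concatenated and
projected. `K_p` is a bias-free linear projection of the sinusoidal
encoding of relative offsets `T−1 … −(T−1)`; `b_k`, `b_p` are global
per-head content/position bias vectors initialized at zero. The
`relative_shift` operation accepts any per-offset width `T ≤ P ≤ 2T−1`
(columns encode offsets `T−1−c`), applies the pad-reshape-slice
rearrangement, and zeroes entries whose offset is absent from the input —
this makes it agree exactly with direct `(i−j)` indexing in both the
bidirectional (`P = 2T−1`) and square causal (`P = T`) layouts. With the
relative shift disabled (the "w/o RS" ablation) the raw first T columns of
the position-score matrix are used, so only the position-score pathway
changes.

**Transformer ablation.** `block_type="transformer"` replaces each block
with a plain pre-norm Transformer encoder layer (absolute sinusoidal
positions added after the frontend, standard scaled-dot-product attention,
single full-step feed-forward, no convolution module).

**Decoders (training only).** Two separate 2-layer Transformer decoder
stacks over a 7-token vocabulary (blank + 4 bases + SOS/EOS; the blank id
is retained so encoder and decoder share base ids, though the blank is
never a target). Token protocol: forward — input `[SOS, y]`, labels
`[y, EOS]`, lower-triangular self-attention mask; reverse — input
`[y, EOS]`, labels `[SOS, y]`, anti-lower-triangular mask, so each label is
predicted from strictly later tokens. The decoders share no parameters
with each other. They are excluded from inference checkpoints.

With defaults d_model 512, 8 heads, feed-forward expansion 4, dropout 0.1,
block kernel 31, the inference network counts 48 550 043 trainable scalars
(≈50 M; the exact value is recomputed by `scripts/acceptance.py`). These
widths are conventional Conformer values chosen so the total lands at that
figure; they are not otherwise constrained.

## Losses

CTC is computed by the standard forward recursion in log space over the
blank-extended label sequence; its gradient with respect to the input
log-probabilities comes from forward-backward posteriors. Targets longer
than the available frames are infeasible: they are excluded from the batch
mean and counted. Batch reduction is a plain mean (per-target-length
normalization available behind a flag, off by default).

The decoder loss is the mean per-position KL divergence between
label-smoothed one-hot targets (ε = 0.1) and the predicted distribution,
masked over padding. The two decoders are averaged without weighting. The
joint loss is `λ·CTC + (1−λ)·mean(KL_fwd, KL_rev)` with λ = 0.5.

## Optimization

Ranger = RAdam (variance rectification, β = (0.95, 0.999), eps 1e-5) with
Lookahead (k = 6, α = 0.5) and decoupled weight decay; a plain AdamW is
available by name. Gradients are clipped at global norm 5. The
ReduceLROnPlateau schedule monitors validation loss with relative threshold
0.1 (an "abs" mode flag exists since the published description does not
say which), patience 1, factor 0.5: the learning rate halves after two
consecutive non-improving validations. Validation is a 5% split of reads by
MD5 hash of the read_id.

Paper-scale defaults (batch 140, lr 0.002, 12 epochs) are kept as the
`paper` preset. The `desk` preset trains the tiny model (d_model 64,
2 blocks, 4 heads, frontend channels 16/32/64, block kernel 15, no dropout)
with batch 8, lr 0.01 decayed ×0.4 per epoch, 3 epochs. Two desk-specific
training choices matter and are worth recording:

- **Overlapping training windows** (chunk 512 samples, stride 24, plus one
  complete suffix window per read). Short windows shrink the CTC alignment
  space and multiply gradient steps per epoch. The window grid never labels
  a base whose dwell is cut by the right edge, so without the suffix window
  the model learns to suppress emissions near window ends and clips the
  final bases of reads at inference.
- **Dataset-level signal scaling.** The default normalization is per-read
  median/MAD (robust to current spikes, standard for real reads of
  thousands of samples). On 30–60-base synthetic reads the per-read median
  moves by a sizeable fraction of the k-mer level spacing from read to
  read, which measurably caps what a small model can learn in a short run;
  the desk preset therefore pools the same robust statistics over the
  training set and stores the two constants in the checkpoint, so
  basecalling applies exactly the scaling the model was trained with.
- **Weight averaging.** The desk preset averages weights over the final
  epoch (every 10th step) and then refreshes batch-norm running statistics;
  this reduces seed-to-seed spread of the final accuracy.

## Simulator

The simulator emulates the statistical structure of mapped direct-RNA
training data: per-base dwell times at `sampling_rate/translocation_speed`
samples (defaults 3012 Hz, 70 bases/s, consistent with RNA translocating at
or below ~100 bases/s), k-mer-dependent current levels, additive Gaussian
within-dwell noise, and exact base-to-sample mappings written in a
Taiyaki-style HDF5 layout (`Reads/<id>/{Dacs, Reference, Ref_to_signal}`,
with the conventional n+1-long `Ref_to_signal`).

Dwells are `1 + NegBinomial(r = 1/δ, p)` with the stated mean; δ = 1 (the
default) is exactly the geometric distribution, δ → 0 degenerates to a
deterministic integer dwell with the exact long-run mean. The level table
is center-base dominant: each central base owns one of four evenly spaced
bands across the level range, and the 4^(k−1) flanking contexts spread over
the middle 70% of the band as a jittered permuted grid with a guaranteed
minimum pairwise gap. This mirrors the physics of a real pore — the
constriction base dominates the current, neighbours modulate it — and makes
noise-free squiggles exactly decodable, which the reconstruction oracle
test exploits. A uniformly spaced i.i.d. table was tried first and rejected:
with 64 levels the gaps are so small that short-read normalization error
alone exceeds them, making the desk-scale learnability experiment ill-posed.

What the simulator does *not* model: pA-scale calibration and DAC units,
baseline drift, adapter/poly(A) segments, event-detection artifacts,
chemistry-specific signal shapes, and modified bases. Signal is emitted in
sequence order by default; a `reverse_signal` flag emits the 3′→5′
convention of real direct-RNA reads. Consequently, passing desk-scale tests
demonstrates that the architecture, losses, decoding and evaluation are
implemented coherently and can learn a k-mer signal code end to end — not
that the model reaches any particular accuracy on real squiggles.

## Decoding and stitching

Greedy decoding takes per-frame argmaxes, collapses repeats, drops blanks.
Beam decoding is a prefix beam search over the collapsed-label posterior
with lexicographic tie-breaking; width 1 is not guaranteed to equal greedy
(it maximizes a different objective). A `blank_bias` knob subtracts a
constant from blank log-probabilities before decoding (default 0).

Reads longer than one chunk are decoded in overlapping chunks (default
4096 samples, overlap 200, rounded down to the 10-sample frame grid). Each
junction is cut once inside the shared frame window, at the position
nearest the midpoint where both chunks' argmax is blank (midpoint fallback),
and the trimmed pieces are decoded and concatenated. Cutting at a mutually
blank frame prevents a base emission from straddling the cut; a fixed
midpoint cut was tried first and loses or doubles a base when the two
chunks place a boundary emission on opposite sides. Known residual
limitation: when a homopolymer run longer than ~3 spans a junction, the
emission positions inside the run are arbitrary and a repeat can still be
dropped or doubled — alignment-based overlap merging would fix this and is
noted as an alternative.

## Evaluation

The in-repo aligner is a semi-global dynamic program (match +1, mismatch
−1, gap −2, free end-gaps on the reference, i.e. unaligned reference flanks
are neither penalized nor counted) with deterministic traceback preference
match > mismatch > deletion > insertion and, for the free suffix, the
largest-coordinate optimum. Insertions are query-relative (extra bases in
the call). Rates are counts over alignment length ×100 and sum to 100% per
read; per-dataset summaries are medians, overall and per length bin.
T and U are synonyms at every comparison boundary. At genome scale one
would substitute minimap2 primary alignments; the DP aligner is the
desk-scale stand-in and is oracle-tested against an independent memoized
recursion.

## Degenerate inputs and numerical notes

- `normalize_signal` guards the MAD with ε = 1e-8 (constant signals map to
  zeros); it is idempotent to float32 rounding.
- CTC: empty targets reduce to the all-blank path; log-space recursions use
  −inf initialization and `logaddexp`; posteriors are clipped before
  exponentiation.
- Attention masks are additive −1e9 in float32; fully padded rows cannot
  occur because frame lengths are at least 1.
- The autodiff engine accumulates gradients with a buffer-ownership
  discipline (a backward pass may adopt the dead gradient buffer of its
  output; shared buffers are copied once) — this is an internal memory
  optimization with no numerical effect, covered by finite-difference
  tests.
- Checkpoints are single `.npz` archives holding a JSON config, the
  encoder weights (decoders optional), batch-norm buffers, and the signal
  scaling constants.

## Problem sizes used in tests

Unit tests run on micro fixtures (frames ≤ 16, sequences ≤ 8, exhaustive
oracles). The learnability experiments train the tiny preset on 200
simulated reads of 30–60 bases for 3 epochs (~4.5k steps, a few minutes on
one CPU) and score 50 held-out reads; the ablation comparison uses three
matched-seed 1-epoch pairs at a coarser window stride. These sizes were
chosen so the whole suite runs comfortably on a single CPU core.
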