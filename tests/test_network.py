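"""Architecture unit tests: shapes, attention math, masks, parameter counts."""

import numpy as np
import pytest

from gcrtcall.autodiff import Tensor, no_grad, softmax
from gcrtcall.config import ModelConfig
from gcrtcall.network import (BasecallerModel, ConformerBlock, ConvFrontend,
                              Decoder, Encoder, GatedConvBlock,
                              RelativeMultiHeadAttention, TransformerBlock,
                              count_parameters, glu, load_checkpoint,
                              relative_shift, relative_shift_gather,
                              save_checkpoint)

rng = np.random.default_rng(7)


def tiny_cfg(**over):
    return ModelConfig.tiny(seed=0, **over)


# -- conv frontend ----------------------------------------------------------

@pytest.mark.parametrize("L,expected", [(4000, 400), (1, 1), (10, 1),
                                        (11, 2), (4096, 410)])
def test_frontend_downsampling_arithmetic(L, expected):
    cfg = tiny_cfg()
    frontend = ConvFrontend(cfg, rng=np.random.default_rng(0))
    with no_grad():
        out = frontend(Tensor(rng.normal(size=(1, L, 1)).astype(np.float32)))
    assert out.shape == (1, expected, cfg.d_model)


# -- relative shift ---------------------------------------------------------

def test_relative_shift_single_position_is_identity():
    x = rng.normal(size=(1, 1))
    assert np.array_equal(relative_shift(x), x)


@pytest.mark.parametrize("T", [2, 3, 4, 8, 16])
def test_relative_shift_matches_gather_oracle(T):
    for P in {T, 2 * T - 1}:
        x = rng.normal(size=(2, 2, T, P))
        assert np.array_equal(relative_shift(x), relative_shift_gather(x))


def test_relative_shift_rejects_invalid_width():
    with pytest.raises(ValueError):
        relative_shift(rng.normal(size=(4, 9)))  # P > 2T-1


def test_disabling_relative_shift_changes_only_position_pathway():
    """With the position projection and bias zeroed, toggling the shift
    flag must not change the output at all."""
    x = Tensor(rng.normal(size=(1, 6, 64)).astype(np.float32))
    outs = []
    for flag in (True, False):
        attn = RelativeMultiHeadAttention(64, 4, use_relative_shift=flag,
                                          rng=np.random.default_rng(3))
        attn.w_p.weight.data[:] = 0.0
        attn.b_p.data[:] = 0.0
        attn.eval()
        with no_grad():
            outs.append(attn(x).data)
    assert np.allclose(outs[0], outs[1], atol=1e-6)


# -- attention --------------------------------------------------------------

def plain_attention_oracle(x, attn):
    """Standard scaled dot-product attention with the same projections."""
    q = x @ attn.w_q.weight.data + attn.w_q.bias.data
    k = x @ attn.w_k.weight.data + attn.w_k.bias.data
    v = x @ attn.w_v.weight.data + attn.w_v.bias.data
    B, T, d = x.shape
    H, dk = attn.n_heads, attn.d_k
    split = lambda a: a.reshape(B, T, H, dk).transpose(0, 2, 1, 3)
    q, k, v = split(q), split(k), split(v)
    s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dk)
    w = np.exp(s - s.max(-1, keepdims=True))
    w /= w.sum(-1, keepdims=True)
    ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
    return ctx @ attn.w_o.weight.data + attn.w_o.bias.data


def test_relative_attention_reduces_to_plain_attention():
    attn = RelativeMultiHeadAttention(32, 4, rng=np.random.default_rng(1))
    attn.w_p.weight.data[:] = 0.0
    attn.b_k.data[:] = 0.0
    attn.b_p.data[:] = 0.0
    attn.eval()
    x = rng.normal(size=(2, 9, 32)).astype(np.float32)
    with no_grad():
        out = attn(Tensor(x)).data
    assert np.allclose(out, plain_attention_oracle(x, attn), atol=1e-5)


def test_attention_rows_are_normalized():
    attn = RelativeMultiHeadAttention(32, 4, rng=np.random.default_rng(2))
    attn.eval()
    x = Tensor(rng.normal(size=(2, 11, 32)).astype(np.float32))
    with no_grad():
        _, weights = attn(x, return_weights=True)
    assert np.abs(weights.sum(-1) - 1.0).max() < 1e-5


def test_single_position_attention_is_projected_value():
    attn = RelativeMultiHeadAttention(32, 4, rng=np.random.default_rng(4))
    attn.eval()
    x = rng.normal(size=(1, 1, 32)).astype(np.float32)
    with no_grad():
        out = attn(Tensor(x)).data
    v = x @ attn.w_v.weight.data + attn.w_v.bias.data
    expected = v @ attn.w_o.weight.data + attn.w_o.bias.data
    assert np.allclose(out, expected, atol=1e-5)


# -- GLU and gated conv -----------------------------------------------------

def test_glu_worked_examples():
    assert np.allclose(glu(np.array([1.0, 2.0, 0.0, 0.0])), [0.5, 1.0])
    a = np.array([3.0, -1.0])
    assert np.allclose(glu(np.concatenate([a, [20.0, 20.0]])), a, atol=1e-8)
    x = np.array([-1.0, 3.0, np.log(3), np.log(1 / 3)])
    assert np.allclose(glu(x), [-0.75, 0.75], atol=1e-12)


def test_glu_rejects_odd_dimension():
    with pytest.raises(ValueError):
        glu(np.ones(5))


@pytest.mark.parametrize("T", [1, 7, 50])
def test_gated_conv_preserves_length(T):
    block = GatedConvBlock(16, kernel=7, dropout=0.0,
                           rng=np.random.default_rng(0))
    block.eval()
    with no_grad():
        out = block(Tensor(rng.normal(size=(2, T, 16)).astype(np.float32)))
    assert out.shape == (2, T, 16)


def test_swish_zero_fixed_point():
    assert Tensor(np.zeros(3)).swish().data.sum() == 0.0


# -- blocks -----------------------------------------------------------------

def test_conformer_block_preserves_shape():
    block = ConformerBlock(tiny_cfg(), rng=np.random.default_rng(0))
    block.eval()
    x = Tensor(rng.normal(size=(2, 13, 64)).astype(np.float32))
    with no_grad():
        assert block(x).shape == (2, 13, 64)


def test_transcall_block_has_no_convolution_module():
    conf = ConformerBlock(tiny_cfg(), rng=np.random.default_rng(0))
    trans = TransformerBlock(tiny_cfg(), rng=np.random.default_rng(0))
    assert any(isinstance(m, GatedConvBlock) for m in conf.modules())
    assert not any(isinstance(m, GatedConvBlock) for m in trans.modules())


# -- encoder / decoder ------------------------------------------------------

def test_encoder_rows_are_log_probabilities_and_deterministic():
    enc = Encoder(tiny_cfg())
    enc.eval()
    x = Tensor(rng.normal(size=(2, 430, 1)).astype(np.float32))
    with no_grad():
        logp1, lengths = enc(x)
        logp2, _ = enc(x)
    assert logp1.shape == (2, 43, 5)
    assert np.abs(np.exp(logp1.data).sum(-1) - 1.0).max() < 1e-5
    assert np.array_equal(logp1.data, logp2.data)
    assert list(lengths) == [43, 43]


@pytest.mark.parametrize("direction,check", [
    ("forward", "prefix"), ("reverse", "suffix")])
def test_decoder_masks_isolate_past_or_future(direction, check):
    cfg = tiny_cfg()
    dec = Decoder(cfg, direction, rng=np.random.default_rng(0))
    dec.eval()
    memory = Tensor(rng.normal(size=(1, 15, cfg.d_model)).astype(np.float32))
    tokens = rng.integers(0, 7, size=(1, 8))
    with no_grad():
        base = dec(memory, tokens).data
    for t in range(8):
        mutated = tokens.copy()
        mutated[0, t] = (mutated[0, t] + 3) % 7
        with no_grad():
            out = dec(memory, mutated).data
        changed = np.abs(out - base).max(axis=(0, 2)) > 1e-7
        if check == "prefix":   # outputs before t stay fixed
            assert not changed[:t].any()
        else:                   # outputs after t stay fixed
            assert not changed[t + 1:].any()


def test_decoder_outputs_normalized_and_empty_rejected():
    cfg = tiny_cfg()
    dec = Decoder(cfg, "forward", rng=np.random.default_rng(0))
    dec.eval()
    memory = Tensor(rng.normal(size=(1, 5, cfg.d_model)).astype(np.float32))
    with no_grad():
        out = dec(memory, np.array([[5, 1, 2]])).data
    assert np.abs(np.exp(out).sum(-1) - 1.0).max() < 1e-5
    with pytest.raises(ValueError):
        dec(memory, np.zeros((1, 0), dtype=int))


# -- parameter counting and checkpoints -------------------------------------

def test_parameter_count_monotone_and_additive():
    small = count_parameters(tiny_cfg(), include_decoders=False)
    bigger = count_parameters(tiny_cfg(n_blocks=4), include_decoders=False)
    assert bigger > small
    model = BasecallerModel(tiny_cfg())
    total = count_parameters(tiny_cfg(), include_decoders=True)
    parts = (model.encoder.n_parameters()
             + model.forward_decoder.n_parameters()
             + model.reverse_decoder.n_parameters())
    assert total == parts


def test_checkpoint_roundtrip_reproduces_outputs(tmp_path):
    model = BasecallerModel(tiny_cfg())
    model.signal_scaling = {"mode": "dataset", "center": 0.5, "scale": 2.0}
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model)
    loaded = load_checkpoint(path)
    x = rng.normal(size=(1, 300, 1)).astype(np.float32)
    a = model.encode(x)
    b = loaded.encode(x)
    assert np.allclose(a.frames, b.frames, atol=1e-6)
    assert loaded.signal_scaling == model.signal_scaling


def test_model_config_validation_and_yaml_roundtrip():
    with pytest.raises(ValueError):
        ModelConfig(d_model=100, n_heads=3)
    with pytest.raises(ValueError):
        ModelConfig(block_type="lstm")
    cfg = tiny_cfg()
    assert ModelConfig.from_yaml(cfg.to_yaml()) == cfg
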