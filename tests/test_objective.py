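"""Loss functions: CTC against enumeration, KL divergence, joint mixing."""

from itertools import product

import numpy as np
import pytest

from gcrtcall.autodiff import Tensor, log_softmax
from gcrtcall.network import FrameLogProbs
from gcrtcall.objective import (LossReport, ctc_forward_backward, ctc_loss,
                                ctc_loss_batch, encode_target, joint_loss,
                                kldiv_loss, smoothed_one_hot, teacher_pairs)

rng = np.random.default_rng(99)


def collapse(path):
    out, prev = [], 0
    for s in path:
        if s != 0 and s != prev:
            out.append(s)
        prev = s
    return tuple(out)


def enumerate_ctc(logp, target):
    """Independent oracle: sum path probabilities over all V^T paths."""
    T, V = logp.shape
    total = -np.inf
    for path in product(range(V), repeat=T):
        if collapse(path) == tuple(target):
            total = np.logaddexp(total,
                                 sum(logp[t, s] for t, s in enumerate(path)))
    return -total


def random_logp(T, V=5):
    x = rng.normal(size=(T, V))
    return x - np.log(np.exp(x).sum(-1, keepdims=True))


class TestCTC:
    def test_two_frame_uniform_worked_example(self):
        # paths (A,-), (-,A), (A,A) collapse to "A": total prob 0.75
        logp = np.log(np.full((2, 2), 0.5))
        loss, _ = ctc_forward_backward(logp, np.array([1]))
        assert abs(loss - (-np.log(0.75))) < 1e-12

    def test_empty_target_is_all_blank_path(self):
        logp = random_logp(4)
        loss, _ = ctc_forward_backward(logp, np.array([], dtype=int))
        assert abs(loss - (-logp[:, 0].sum())) < 1e-12

    def test_forward_recursion_matches_enumeration(self):
        for _ in range(40):
            T = int(rng.integers(1, 7))
            U = int(rng.integers(0, 4))
            logp = random_logp(T)
            target = rng.integers(1, 5, size=U)
            got, _ = ctc_forward_backward(logp, target)
            want = enumerate_ctc(logp, target)
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert abs(got - want) < 1e-9

    def test_gradient_matches_finite_differences(self):
        T = 5
        logits = Tensor(rng.normal(size=(1, T, 5)), requires_grad=True)
        lp = log_softmax(logits, axis=-1)
        loss, _ = ctc_loss_batch(lp, [np.array([1, 2])], np.array([T]))
        loss.backward()
        eps = 1e-6
        for (i, k) in [(0, 0), (2, 1), (4, 3)]:
            d = logits.data.copy()
            d[0, i, k] += eps
            hi, _ = ctc_forward_backward(log_softmax(Tensor(d), -1).data[0],
                                         np.array([1, 2]))
            d[0, i, k] -= 2 * eps
            lo, _ = ctc_forward_backward(log_softmax(Tensor(d), -1).data[0],
                                         np.array([1, 2]))
            assert abs(logits.grad[0, i, k] - (hi - lo) / (2 * eps)) < 1e-6

    def test_infeasible_targets_skipped_and_counted(self):
        lp = Tensor(np.tile(random_logp(2)[None], (2, 1, 1)))
        loss, skipped = ctc_loss_batch(
            lp, [np.array([1]), np.array([1, 2, 3, 4])], np.array([2, 2]))
        assert skipped == 1
        assert np.isfinite(loss.data)

    def test_framelogprobs_interface(self):
        logp = random_logp(6)
        frames = FrameLogProbs(frames=logp[None], valid_lengths=[6])
        assert np.isfinite(ctc_loss(frames, "AC"))

    def test_invalid_target_symbol_rejected(self):
        with pytest.raises(ValueError):
            encode_target("ACGB")


class TestKLDiv:
    def test_zero_when_prediction_equals_smoothed_target(self):
        tokens = np.array([[1, 3, 0]])
        q = smoothed_one_hot(tokens, 7, epsilon=0.1)
        decoded = Tensor(np.log(q))
        assert abs(kldiv_loss(decoded, tokens, epsilon=0.1).data) < 1e-9

    def test_epsilon_zero_reduces_to_cross_entropy(self):
        tokens = np.array([[2, 5]])
        logp = np.log(rng.dirichlet(np.ones(7), size=(1, 2)))
        ce = -(logp[0, 0, 2] + logp[0, 1, 5]) / 2
        got = kldiv_loss(Tensor(logp), tokens, epsilon=0.0).data
        assert abs(got - ce) < 1e-9

    def test_hand_computed_two_position_example(self):
        p = np.array([[[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]]])
        tokens = np.array([[0, 2]])
        eps = 0.3
        q = smoothed_one_hot(tokens, 3, eps)
        direct = float(np.mean([(q[0, i] * (np.log(q[0, i]) -
                                            np.log(p[0, i]))).sum()
                                for i in range(2)]))
        got = kldiv_loss(Tensor(np.log(p)), tokens, epsilon=eps).data
        assert abs(got - direct) < 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kldiv_loss(Tensor(np.zeros((1, 3, 7))), np.array([[1, 2]]))


def make_joint_inputs(B=2, T=6, U=3):
    x_E = log_softmax(Tensor(rng.normal(size=(B, T, 5)),
                             requires_grad=True), axis=-1)
    fwd = log_softmax(Tensor(rng.normal(size=(B, U + 1, 7))), axis=-1)
    rev = log_softmax(Tensor(rng.normal(size=(B, U + 1, 7))), axis=-1)
    ys = [rng.integers(1, 5, size=U) for _ in range(B)]
    targets = {
        "ctc": ys,
        "fwd_labels": np.stack([teacher_pairs(y, "forward")[1] for y in ys]),
        "rev_labels": np.stack([teacher_pairs(y, "reverse")[1] for y in ys]),
    }
    return x_E, (fwd, rev), targets


class TestJointLoss:
    def test_lambda_one_is_pure_ctc(self):
        x_E, x_D, targets = make_joint_inputs()
        rep = joint_loss(x_E, x_D, targets, np.array([6, 6]), lam=1.0)
        assert rep.joint == rep.ctc

    def test_lambda_zero_is_pure_decoder_term(self):
        x_E, x_D, targets = make_joint_inputs()
        rep = joint_loss(x_E, x_D, targets, np.array([6, 6]), lam=0.0)
        assert abs(rep.joint - (rep.kl_forward + rep.kl_reverse) / 2) < 1e-12

    def test_lambda_half_is_arithmetic_mean(self):
        x_E, x_D, targets = make_joint_inputs()
        rep = joint_loss(x_E, x_D, targets, np.array([6, 6]), lam=0.5)
        expected = 0.5 * rep.ctc + 0.5 * (rep.kl_forward + rep.kl_reverse) / 2
        assert abs(rep.joint - expected) < 1e-12

    def test_joint_monotone_in_ctc_component(self):
        x_E, x_D, targets = make_joint_inputs()
        r1 = joint_loss(x_E, x_D, targets, np.array([6, 6]), lam=0.5)
        shifted = LossReport(ctc=r1.ctc + 1.0, kl_forward=r1.kl_forward,
                             kl_reverse=r1.kl_reverse,
                             joint=0.5 * (r1.ctc + 1.0)
                             + 0.25 * (r1.kl_forward + r1.kl_reverse),
                             batch_size=r1.batch_size)
        assert shifted.joint > r1.joint

    def test_invalid_lambda_rejected(self):
        x_E, x_D, targets = make_joint_inputs()
        with pytest.raises(ValueError):
            joint_loss(x_E, x_D, targets, np.array([6, 6]), lam=1.5)


def test_teacher_pairs_token_protocol():
    y = np.array([1, 2, 3])
    fi, fl = teacher_pairs(y, "forward")
    ri, rl = teacher_pairs(y, "reverse")
    assert list(fi) == [5, 1, 2, 3] and list(fl) == [1, 2, 3, 6]
    assert list(ri) == [1, 2, 3, 6] and list(rl) == [5, 1, 2, 3]
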