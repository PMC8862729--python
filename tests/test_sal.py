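"""Structured max-margin alignment learning: margin, decoding, hinge."""

import numpy as np
import pytest

from rnaembed.align import GapParams, alignment_score, enumerate_alignments, nw_affine
from rnaembed.model import ModelConfig, init_params, make_optimizer
from rnaembed.sal import (
    MarginParams,
    TrainConfig,
    loss_augmented_decode,
    margin_delta,
    omega,
    omega_tensor,
    sal_loss,
    train_sal_epoch,
)
from rnaembed.autodiff import Tensor
from rnaembed.seqio import PairwiseAlignment, RnaSequence

from conftest import random_sequence


def random_alignment(n, m, rng):
    alignments = list(enumerate_alignments(n, m))
    return alignments[rng.integers(len(alignments))]


class TestOmega:
    def test_identical_vectors_give_one(self):
        z = np.array([[1.0, 2.0, 3.0]])
        assert omega(z, z)[0, 0] == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert omega(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))[0, 0] == pytest.approx(0.0)

    def test_closed_form_cosine(self):
        om = omega(np.array([[1.0, 1.0]]), np.array([[1.0, 0.0]]))
        assert om[0, 0] == pytest.approx(1 / np.sqrt(2))

    def test_entries_bounded_by_one(self, rng):
        om = omega(rng.normal(size=(6, 4)), rng.normal(size=(5, 4)))
        assert np.abs(om).max() <= 1 + 1e-9

    def test_zero_row_reported_with_position(self):
        z = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="row 2"):
            omega(z, z)

    def test_tensor_path_matches_numpy_path(self, rng):
        a, b = rng.normal(size=(4, 6)), rng.normal(size=(3, 6))
        np.testing.assert_allclose(
            omega_tensor(Tensor(a), Tensor(b)).data, omega(a, b), atol=1e-9
        )


class TestMarginDelta:
    def test_identical_alignments_have_zero_margin(self):
        y = PairwiseAlignment([(1, 1), (2, 2)])
        assert margin_delta(y, y) == 0.0

    def test_printed_defaults_arithmetic(self):
        # 2 missed reference pairs and 2 spurious ones at deltaFN=0.05,
        # deltaFP=0.1 cost 0.3
        y = PairwiseAlignment([(1, 1), (2, 2), (3, 3), (None, 4)])
        yhat = PairwiseAlignment([(1, 1), (None, 2), (2, 3), (3, 4)])
        assert margin_delta(y, yhat) == pytest.approx(0.05 * 2 + 0.1 * 2)

    def test_symmetric_when_penalties_equal(self, rng):
        params = MarginParams(delta_fn=0.07, delta_fp=0.07)
        for _ in range(20):
            n, m = rng.integers(1, 5, size=2)
            y = random_alignment(n, m, rng)
            yhat = random_alignment(n, m, rng)
            assert margin_delta(y, yhat, params) == pytest.approx(
                margin_delta(yhat, y, params)
            )

    def test_matches_independent_set_difference_count(self, rng):
        for _ in range(50):
            n, m = rng.integers(1, 6, size=2)
            y = random_alignment(n, m, rng)
            yhat = random_alignment(n, m, rng)
            ref, pred = y.matched_pairs(), yhat.matched_pairs()
            fn = sum(1 for p in ref if p not in pred)
            fp = sum(1 for p in pred if p not in ref)
            assert margin_delta(y, yhat) == pytest.approx(0.05 * fn + 0.1 * fp)


class TestLossAugmentedDecode:
    def test_zero_margins_reduce_to_plain_alignment(self, rng):
        gaps = GapParams()
        for _ in range(20):
            n, m = rng.integers(1, 5, size=2)
            om = rng.uniform(-1, 1, size=(n, m))
            y = random_alignment(n, m, rng)
            dec = loss_augmented_decode(om, gaps, y, MarginParams(0.0, 0.0))
            assert dec.columns == nw_affine(om, gaps).alignment.columns

    def test_maximises_score_plus_margin_exhaustively(self):
        rng = np.random.default_rng(77)
        gaps, margin = GapParams(), MarginParams()
        for _ in range(200):
            n, m = rng.integers(1, 5, size=2)
            om = rng.uniform(-1, 1, size=(n, m))
            y = random_alignment(n, m, rng)
            yhat = loss_augmented_decode(om, gaps, y, margin)
            achieved = alignment_score(om, gaps, yhat) + margin_delta(y, yhat, margin)
            best = max(
                alignment_score(om, gaps, cand) + margin_delta(y, cand, margin)
                for cand in enumerate_alignments(n, m)
            )
            assert achieved == pytest.approx(best, abs=1e-9)

    def test_large_fn_penalty_keeps_reference_matches(self):
        # missing a diagonal match costs more than its modified score
        y = PairwiseAlignment([(1, 1), (2, 2)])
        om = np.zeros((2, 2))
        yhat = loss_augmented_decode(om, GapParams(), y, MarginParams(delta_fn=0.3, delta_fp=0.1))
        assert yhat.matched_pairs() == {(1, 1), (2, 2)}


class TestHinge:
    def test_nonnegative_on_random_instances(self):
        # y is always a feasible candidate of the exact decoder
        rng = np.random.default_rng(123)
        gaps, margin = GapParams(), MarginParams()
        for _ in range(500):
            n, m = rng.integers(1, 7, size=2)
            om = rng.uniform(-1, 1, size=(n, m))
            y = random_alignment(min(n, 4), min(m, 4), rng) if max(n, m) <= 4 else None
            if y is None:
                # build a random feasible alignment without enumeration
                y = nw_affine(rng.uniform(-1, 1, size=(n, m)), gaps).alignment
            yhat = loss_augmented_decode(om, gaps, y, margin)
            hinge = (
                alignment_score(om, gaps, yhat)
                + margin_delta(y, yhat, margin)
                - alignment_score(om, gaps, y)
            )
            assert hinge >= -1e-9

    def test_separable_scores_give_zero_hinge(self):
        y = PairwiseAlignment([(1, 1), (2, 2), (3, 3)])
        om = np.full((3, 3), -1.0)
        np.fill_diagonal(om, 1.0)
        gaps, margin = GapParams(), MarginParams()
        yhat = loss_augmented_decode(om, gaps, y, margin)
        hinge = (
            alignment_score(om, gaps, yhat)
            + margin_delta(y, yhat, margin)
            - alignment_score(om, gaps, y)
        )
        assert hinge == pytest.approx(0.0, abs=1e-12)


class TestSalLoss:
    def test_report_is_self_consistent(self, tiny_config, tiny_params, rng):
        a, b = random_sequence(rng, 12, "a"), random_sequence(rng, 10, "b")
        y = nw_affine(rng.uniform(-1, 1, size=(12, 10))).alignment
        rep = sal_loss(a, b, y, tiny_params, tiny_config)
        assert rep.hinge == pytest.approx(rep.f_hat + rep.delta - rep.f_ref)
        assert rep.hinge >= -1e-9
        assert rep.reg >= 0
        assert rep.total == pytest.approx(rep.hinge + rep.reg)

    def test_lambda_zero_and_perfect_decode_give_zero_total(self, tiny_config, tiny_params, rng):
        a = random_sequence(rng, 8, "a")
        y = PairwiseAlignment([(i, i) for i in range(1, 9)])
        rep = sal_loss(a, a, y, tiny_params, tiny_config, train=TrainConfig(lambda_reg=0.0))
        # aligning a sequence to itself: the diagonal is optimal (cosine 1)
        assert rep.total == pytest.approx(0.0, abs=1e-9)

    def test_gradient_steps_reduce_mean_hinge(self, rng):
        cfg = ModelConfig(D=16, n_layers=1, H=2, ffn_dim=32)
        params = init_params(cfg, np.random.default_rng(0))
        fams = _tiny_training_pairs(rng)
        opt = make_optimizer(params, lr=3e-3)
        first = train_sal_epoch(fams, params, cfg, opt)
        last = None
        for _ in range(5):
            last = train_sal_epoch(fams, params, cfg, opt)
        assert last < first

    def test_gradients_are_finite(self, tiny_config, tiny_params, rng):
        pairs = _tiny_training_pairs(rng)[:2]
        opt = make_optimizer(tiny_params, lr=0.0)
        train_sal_epoch(pairs, tiny_params, tiny_config, opt)
        # after a zero-lr step the accumulated grads are still inspectable
        for p in tiny_params.values():
            if p.grad is not None:
                assert np.isfinite(p.grad).all()


def _tiny_training_pairs(rng):
    from rnaembed.synthetic import FamilySpec, generate_family, random_structure

    spec = FamilySpec(
        name="t", consensus_structure=random_structure(rng, n_stems=1), n_members=5
    )
    fam = generate_family(spec, rng)
    ids = [m.id for m in fam.members]
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pairs.append((fam.members[i], fam.members[j], fam.truth(ids[i], ids[j])))
    return pairs
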