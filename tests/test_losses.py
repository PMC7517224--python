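"""Loss components against hand-computed values, invariances, and the
analytic gradient against central finite differences."""

import numpy as np
import pytest
from scipy import ndimage

from gwcine import (
    CineSequence,
    DeformationSequence,
    LossConfig,
    RegionMask,
    ncc_loss,
    periodicity_constraint,
    regularization,
    ssd_loss,
    total_loss,
)
from gwcine.losses import ncc_score, total_loss_and_field_grad


def smooth_frames(rng, n, size):
    return np.stack(
        [ndimage.gaussian_filter(rng.random((size, size)), 1.0) for _ in range(n)]
    )


class TestSSD:
    def test_identical_frames_zero(self, textured_image):
        seq = CineSequence(np.stack([textured_image] * 3))
        assert ssd_loss(seq) == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_two_frame_single_pixel(self):
        # values 0 and 1 at one pixel: (1/2)((0-0.5)^2 + (1-0.5)^2) = 0.25
        seq = CineSequence(np.array([[[0.0]], [[1.0]]]))
        assert ssd_loss(seq) == pytest.approx(0.25)

    def test_constant_offset_invariance(self, small_sequence):
        shifted = small_sequence.with_frames(small_sequence.frames + 0.7)
        assert ssd_loss(shifted) == pytest.approx(ssd_loss(small_sequence))

    def test_frame_permutation_invariance(self, small_sequence, rng):
        perm = rng.permutation(small_sequence.n_frames)
        permuted = small_sequence.with_frames(small_sequence.frames[perm])
        assert ssd_loss(permuted) == pytest.approx(ssd_loss(small_sequence))

    def test_region_restriction(self, small_sequence):
        mask = np.zeros((32, 32), dtype=bool)
        mask[:16] = True
        restricted = ssd_loss(small_sequence, RegionMask(mask))
        assert 0 < restricted < ssd_loss(small_sequence)

    def test_single_frame_rejected(self, textured_image):
        with pytest.raises(ValueError):
            ssd_loss(CineSequence(textured_image[None]))


class TestNCC:
    def test_perfect_match_scores_one(self, textured_image):
        assert ncc_score(textured_image, textured_image) == pytest.approx(1.0)
        assert ncc_loss(textured_image, textured_image) == pytest.approx(-1.0)

    def test_affine_intensity_invariance(self, textured_image):
        scaled = 2.5 * textured_image + 0.3
        assert ncc_score(textured_image, scaled) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_scores_low(self):
        # Monte-Carlo oracle: squared local correlation of independent
        # white noise stays near its finite-sample bias level
        scores = []
        for s in range(20):
            r = np.random.default_rng(s)
            scores.append(ncc_score(r.random((64, 64)), r.random((64, 64)), 9))
        assert max(scores) < 0.2

    def test_constant_images_score_zero(self):
        a = np.full((16, 16), 0.5)
        assert ncc_score(a, a) == 0.0

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            ncc_score(rng.random((5, 5)), rng.random((5, 5)), 9)


class TestRegularization:
    def test_constant_field_costs_nothing(self):
        u = np.ones((4, 8, 8, 2)) * 1.7
        cfg = LossConfig(lambda1=1, lambda2=1, lambda3=1, lambda4=1, lambda_c=0)
        assert regularization(DeformationSequence(u), cfg) == 0.0

    def test_temporal_first_difference_hand_case(self):
        # N=2, one pixel, one component alternating +d/-d: circular first
        # differences are -+2d, so R3 = (2d)^2 + (2d)^2 = 8 d^2
        d = 0.3
        u = np.zeros((2, 1, 1, 2))
        u[0, 0, 0, 0] = d
        u[1, 0, 0, 0] = -d
        cfg = LossConfig(lambda3=1.0, lambda_c=0)
        assert regularization(DeformationSequence(u), cfg) == pytest.approx(8 * d**2)

    def test_affine_field_has_zero_second_order_cost(self):
        u = np.zeros((2, 8, 8, 2))
        rr, cc = np.meshgrid(np.arange(8.0), np.arange(8.0), indexing="ij")
        u[..., 0] = 2 * rr - cc
        u[..., 1] = 0.5 * cc
        cfg = LossConfig(lambda2=1.0, lambda3=0, lambda_c=0)
        assert regularization(DeformationSequence(u), cfg) == pytest.approx(0.0)

    def test_temporal_terms_not_permutation_invariant(self, rng):
        u = rng.normal(size=(6, 4, 4, 2))
        cfg = LossConfig(lambda3=1.0, lambda4=0.5, lambda_c=0)
        base = regularization(DeformationSequence(u), cfg)
        perm = rng.permutation(6)
        permuted = regularization(DeformationSequence(u[perm]), cfg)
        assert not np.isclose(base, permuted)

    def test_shuffled_phases_cost_more_than_ordered(self, default_phantom):
        # smooth periodic motion has small circular differences; shuffling
        # the phases creates jumps, raising the temporal penalty
        _, _, gt = default_phantom
        cfg = LossConfig(lambda3=1.0, lambda_c=0)
        ordered = regularization(gt, cfg)
        rng = np.random.default_rng(0)
        worse = 0
        for _ in range(10):
            perm = rng.permutation(gt.n_frames)
            shuffled = regularization(
                DeformationSequence(gt.displacements[perm]), cfg
            )
            worse += shuffled > ordered
        assert worse >= 9


class TestPeriodicityConstraint:
    def test_zero_mean_motion_satisfies_constraint(self, default_phantom):
        _, _, gt = default_phantom
        assert periodicity_constraint(gt, 1.0) == pytest.approx(0.0, abs=1e-18)

    def test_constant_displacement_hand_case(self):
        # N frames with constant displacement d in one component over P
        # pixels: lambda_c * P * d^2
        d, p = 0.4, 6 * 5
        u = np.zeros((3, 6, 5, 2))
        u[..., 1] = d
        assert periodicity_constraint(DeformationSequence(u), 1.0) == pytest.approx(
            p * d**2
        )

    def test_switched_off(self, rng):
        u = rng.normal(size=(3, 4, 4, 2))
        assert periodicity_constraint(DeformationSequence(u), 0.0) == 0.0


class TestTotalLoss:
    def test_static_sequence_zero_fields_zero_loss(self, textured_image):
        seq = CineSequence(np.stack([textured_image] * 3))
        fields = DeformationSequence.identity(3, textured_image.shape)
        cfg = LossConfig(lambda3=0, lambda_c=0)
        assert total_loss(seq, textured_image, fields, cfg) == pytest.approx(
            0.0, abs=1e-20
        )

    @pytest.mark.parametrize("similarity", ["ssd", "ncc"])
    def test_gradient_matches_finite_differences(self, similarity, rng):
        seq = CineSequence(smooth_frames(rng, 2, 8))
        tpl = ndimage.gaussian_filter(rng.random((8, 8)), 1.0)
        u = rng.normal(0, 0.5, (2, 8, 8, 2))
        cfg = LossConfig(
            similarity=similarity,
            ncc_window_px=5,
            lambda1=0.1,
            lambda2=0.05,
            lambda3=0.2,
            lambda4=0.1,
            lambda_c=0.3,
        )
        value, grad = total_loss_and_field_grad(
            seq, tpl, DeformationSequence(u), cfg
        )
        eps = 1e-6
        fd = np.zeros_like(u)
        for idx in np.ndindex(u.shape):
            up, um = u.copy(), u.copy()
            up[idx] += eps
            um[idx] -= eps
            vp, _ = total_loss_and_field_grad(seq, tpl, DeformationSequence(up), cfg)
            vm, _ = total_loss_and_field_grad(seq, tpl, DeformationSequence(um), cfg)
            fd[idx] = (vp - vm) / (2 * eps)
        rel = np.abs(grad - fd).max() / np.abs(fd).max()
        assert rel < 1e-4

    def test_ground_truth_beats_identity_on_noiseless_phantom(self, noiseless_phantom):
        _, seq, gt = noiseless_phantom
        cfg = LossConfig()
        tpl = seq.frames.mean(axis=0)
        zero = DeformationSequence.identity(seq.n_frames, seq.frame_shape)
        # the registering fields are the (first-order) inverse of the
        # generative ones: their negation
        assert total_loss(seq, tpl, gt.negated(), cfg) < total_loss(
            seq, tpl, zero, cfg
        )

    def test_components_nonnegative_except_ncc(self, rng):
        u = rng.normal(size=(3, 8, 8, 2))
        cfg = LossConfig(lambda1=1, lambda2=1, lambda3=1, lambda4=1, lambda_c=0)
        assert regularization(DeformationSequence(u), cfg) >= 0
        seq = CineSequence(smooth_frames(rng, 3, 8))
        assert ssd_loss(seq) >= 0
        loss = ncc_loss(seq.frames[0], seq.frames[1], 5)
        assert -1.0 <= loss <= 0.0
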