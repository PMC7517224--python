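"""Metrics, paired statistics and the forward-selection search."""

import numpy as np
import pytest

from gwcine import (
    forward_select,
    mutual_information,
    paired_tests,
    pearson_cc,
    sample_ssim,
    ser,
    ssim,
)
from gwcine.evaluation import SER_CAP_DB, DEFAULT_GRID, mean_endpoint_error


class TestSSIM:
    def test_identity(self, textured_image):
        assert ssim(textured_image, textured_image) == pytest.approx(1.0)

    def test_inversion_reduces_similarity(self, textured_image):
        assert ssim(textured_image, 1.0 - textured_image) < 1.0

    def test_equal_constants_stabilized(self):
        a = np.full((16, 16), 0.5)
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((8, 8)), rng.random((9, 9)))


class TestScalarMetrics:
    def test_identity_cases(self, textured_image):
        assert ser(textured_image, textured_image) == SER_CAP_DB
        assert pearson_cc(textured_image, textured_image) == pytest.approx(1.0)
        # MI of an image with itself equals its marginal entropy
        joint, _ = np.histogram(textured_image.ravel(), bins=64, range=(0, 1))
        p = joint / joint.sum()
        entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert mutual_information(textured_image, textured_image) == pytest.approx(
            entropy
        )

    def test_independent_noise_has_low_mi(self):
        # the histogram MI of independent noise is upward-biased by about
        # (bins-1)^2 / (2 N ln 2); at 256x256 (N = 65536) that bound is
        # ~0.044 bits, so observed values must stay well under 0.15
        values = []
        for s in range(20):
            r = np.random.default_rng(s)
            values.append(
                mutual_information(r.random((256, 256)), r.random((256, 256)))
            )
        assert max(values) < 0.15

    def test_constant_offset_keeps_cc_one_and_finite_ser(self, textured_image):
        img = textured_image + 0.25
        assert pearson_cc(textured_image, img) == pytest.approx(1.0)
        expected = 10 * np.log10(
            (textured_image**2).sum() / (0.25**2 * textured_image.size)
        )
        assert ser(textured_image, img) == pytest.approx(expected)

    def test_ser_is_asymmetric(self, rng):
        a = rng.random((16, 16))
        b = a + rng.normal(0, 0.1, a.shape)
        assert ser(a, b) != ser(b, a)

    def test_constant_image_cc_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert pearson_cc(np.full((8, 8), 0.3), np.full((8, 8), 0.9)) == 0.0

    def test_endpoint_error(self):
        a = np.zeros((2, 4, 4, 2))
        b = np.zeros((2, 4, 4, 2))
        b[..., 0] = 3.0
        b[..., 1] = 4.0
        assert mean_endpoint_error(a, b) == pytest.approx(5.0)


class TestSampleSSIM:
    @staticmethod
    def static_result(textured_image):
        from gwcine import CineSequence, DeformationSequence
        from gwcine.template import TemplateImage
        from gwcine.trainer import RegistrationResult

        frames = np.stack([textured_image] * 4)
        return RegistrationResult(
            registered=CineSequence(frames),
            fields=DeformationSequence.identity(4, textured_image.shape),
            templates=[TemplateImage(textured_image, ("average", 0))],
            ssd_trace=np.zeros(1),
        )

    def test_static_sequence_scores_one(self, textured_image):
        result = self.static_result(textured_image)
        assert sample_ssim(result, (2, 0)) == pytest.approx((1.0, 1.0))

    def test_equal_indices_give_identical_values(self, textured_image):
        result = self.static_result(textured_image)
        a, b = sample_ssim(result, (1, 1))
        assert a == b

    def test_out_of_range_index_rejected(self, textured_image):
        with pytest.raises(IndexError):
            sample_ssim(self.static_result(textured_image), (0, 9))


class TestPairedTests:
    def test_identical_samples_null_case(self):
        with pytest.warns(UserWarning):
            t_p, sign_p = paired_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t_p == 0.5
        assert sign_p == 1.0

    def test_uniform_improvement_highly_significant(self, rng):
        b = rng.random(20)
        a = b + 1.0 + rng.normal(0, 1e-6, 20)
        t_p, sign_p = paired_tests(a, b)
        assert t_p < 1e-4
        # binomial closed form: P(Bin(20, 1/2) = 20) = 2^-20
        assert sign_p == pytest.approx(2.0**-20)

    def test_sign_test_binomial_closed_form(self):
        # 4 of 5 positive differences: P(Bin(5, 1/2) >= 4) = 6/32
        a = np.array([1.0, 1.0, 1.0, -1.0, 1.0]) + 5.0
        b = np.full(5, 5.0)
        _, sign_p = paired_tests(a, b)
        assert sign_p == pytest.approx(6 / 32)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_tests([1.0], [2.0])


class TestForwardSelect:
    @staticmethod
    def make_train_fn(effects, n=20, noise=1e-3, calls=None):
        """Mock: baseline SSIM 0.8 plus a fixed boost per active weight."""

        def train_fn(active):
            if calls is not None:
                calls.append(dict(active))
            rng = np.random.default_rng(abs(hash(tuple(sorted(active)))) % 2**31)
            boost = sum(effects.get(k, {}).get(v, 0.0) for k, v in active.items())
            return 0.8 + boost + rng.normal(0, noise, n)

        return train_fn

    def test_single_dominant_parameter_selected_then_stops(self):
        calls = []
        effects = {"lambda3": {1e-7: 0.05, 5e-7: 0.02}}
        report = forward_select(self.make_train_fn(effects, calls=calls))
        assert report.selected == {"lambda3": 1e-7}
        assert [s.stage for s in report.stages] == [1, 2]
        assert report.stages[1].selected is None

    def test_stage_network_counts_match_grid_accounting(self):
        calls = []
        effects = {"lambda3": {1e-7: 0.05}}
        report = forward_select(self.make_train_fn(effects, calls=calls))
        # stage 1: 5 weights x 2 values; stage 2: 4 remaining x 2 values
        assert report.stages[0].n_trained == 10
        assert report.stages[1].n_trained == 8
        assert len(calls) == 1 + 10 + 8  # plus the all-zero baseline

    def test_indistinguishable_candidates_select_nothing(self):
        # every configuration returns exactly the baseline sample: zero
        # paired differences can never be significantly positive
        sample = 0.8 + np.linspace(0, 0.01, 20)
        with pytest.warns(UserWarning):
            report = forward_select(lambda active: sample.copy())
        assert report.selected == {}
        assert len(report.stages) == 1

    def test_training_failures_skipped_with_warning(self):
        inner = self.make_train_fn({"lambda3": {1e-7: 0.05}})

        def flaky(active):
            if active.get("lambda1") == 5e-7:
                raise RuntimeError("diverged")
            return inner(active)

        with pytest.warns(UserWarning, match="training failed"):
            report = forward_select(flaky)
        assert report.selected == {"lambda3": 1e-7}
        assert report.stages[0].n_trained == 9

    def test_selected_config_round_trips_to_loss_config(self):
        effects = {"lambda_c": {1e-5: 0.05}}
        report = forward_select(self.make_train_fn(effects))
        cfg = report.to_loss_config(lambda3=0.0)
        assert cfg.lambda_c == 1e-5

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            forward_select(lambda a: np.zeros(5), grid={})

    def test_default_grid_matches_candidate_values(self):
        assert DEFAULT_GRID["lambda3"] == [1e-7, 5e-7]
        assert DEFAULT_GRID["lambda_c"] == [1e-7, 1e-5]
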