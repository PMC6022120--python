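import numpy as np
import pytest

from mff.colorspace import GaussianSpec, gaussian_smooth
from mff.metrics import EdgeMetricConstants, evaluate_fusion, qabf, qmi, qy

from oracles import qabf_loop, qmi_loop, qy_loop


@pytest.fixture()
def image_like(rng):
    """Smooth-plus-detail random plane, statistically closer to a photo."""
    base = gaussian_smooth(rng.uniform(0, 1, (40, 40)), GaussianSpec(sigma=3.0))
    return np.clip(base + 0.1 * rng.standard_normal((40, 40)), 0, 1)


class TestQmi:
    def test_perfect_copy_scores_two(self, image_like):
        assert qmi(image_like, image_like, image_like) == pytest.approx(2.0, abs=1e-6)

    def test_symmetric_in_sources(self, rng, image_like):
        f = np.clip(image_like + 0.05 * rng.standard_normal(image_like.shape), 0, 1)
        other = rng.uniform(0, 1, image_like.shape)
        assert qmi(image_like, other, f) == pytest.approx(qmi(other, image_like, f), abs=1e-12)

    def test_independent_noise_transfers_no_information(self):
        # large images keep the 256-bin histogram MI estimator bias small
        scores = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = gaussian_smooth(r.uniform(0, 1, (512, 512)), GaussianSpec(sigma=2.0))
            y = gaussian_smooth(r.uniform(0, 1, (512, 512)), GaussianSpec(sigma=2.0))
            f = r.uniform(0, 1, (512, 512))
            scores.append(qmi(x, y, f))
        assert np.mean(scores) < 0.1

    def test_matches_transliteration_oracle(self, rng):
        x = rng.uniform(0, 1, (24, 24))
        y = rng.uniform(0, 1, (24, 24))
        f = 0.5 * (x + y)
        assert qmi(x, y, f) == pytest.approx(qmi_loop(x, y, f), abs=1e-6)


class TestQy:
    def test_perfect_copy_scores_one(self, image_like):
        assert qy(image_like, image_like, image_like) == pytest.approx(1.0, abs=1e-6)

    def test_prefers_the_sharp_source(self, small_pair):
        x, y = small_pair.sources
        sharp_choice = qy(x, y, x)
        blurred_choice = qy(x, y, y)
        # both sources carry one sharp half; scores differ but stay high
        assert sharp_choice == pytest.approx(blurred_choice, abs=0.2)
        truth_score = qy(x, y, small_pair.truth)
        blurall = np.dstack(
            [gaussian_smooth(small_pair.truth[..., c], GaussianSpec(sigma=3.0)) for c in range(3)]
        )
        assert truth_score > qy(x, y, blurall)

    def test_swap_invariance(self, rng, image_like):
        f = np.clip(image_like + 0.02 * rng.standard_normal(image_like.shape), 0, 1)
        other = np.clip(image_like + 0.3 * rng.standard_normal(image_like.shape), 0, 1)
        assert qy(image_like, other, f) == pytest.approx(qy(other, image_like, f), abs=1e-9)

    def test_matches_transliteration_oracle(self, rng):
        x = gaussian_smooth(rng.uniform(0, 1, (20, 20)), GaussianSpec(sigma=1.5))
        y = np.clip(x + 0.1 * rng.standard_normal((20, 20)), 0, 1)
        f = np.clip(0.5 * (x + y) + 0.05 * rng.standard_normal((20, 20)), 0, 1)
        assert qy(x, y, f) == pytest.approx(qy_loop(x, y, f), abs=1e-6)


class TestQabf:
    def test_perfect_copy_hits_sigmoid_ceiling(self, image_like):
        c = EdgeMetricConstants()
        expected = (
            c.gamma_g / (1.0 + np.exp(c.k_g * (1.0 - c.sigma_g)))
            * c.gamma_a / (1.0 + np.exp(c.k_a * (1.0 - c.sigma_a)))
        )
        assert expected == pytest.approx(0.975, abs=1e-3)
        assert qabf(image_like, image_like, image_like) == pytest.approx(expected, abs=1e-6)

    def test_uncorrelated_noise_preserves_little_edge_information(self, rng, image_like):
        f = rng.uniform(0, 1, image_like.shape)
        assert qabf(image_like, image_like, f) < 0.2

    def test_bounded_on_random_inputs(self, rng):
        for _ in range(5):
            a, b, f = (rng.uniform(0, 1, (16, 16)) for _ in range(3))
            assert 0.0 <= qabf(a, b, f) <= 1.0

    def test_matches_transliteration_oracle(self, rng):
        a = gaussian_smooth(rng.uniform(0, 1, (20, 20)), GaussianSpec(sigma=1.0))
        b = gaussian_smooth(rng.uniform(0, 1, (20, 20)), GaussianSpec(sigma=1.0))
        f = 0.5 * (a + b)
        assert qabf(a, b, f) == pytest.approx(qabf_loop(a, b, f), abs=1e-6)


class TestReport:
    def test_color_inputs_are_reduced_to_luminance(self, rng):
        img = rng.uniform(0, 1, (24, 24, 3))
        rep = evaluate_fusion(img, img, img)
        assert rep.qmi == pytest.approx(2.0, abs=1e-6)
        assert rep.qy == pytest.approx(1.0, abs=1e-6)
        assert rep.to_dict().keys() == {"qmi", "qy", "qabf"}

    def test_monotone_degradation_under_blur(self, small_pair):
        """All three metrics fall as the fused candidate is blurred harder.

        Scored against the sharp ground truth as both references; against
        partially defocused sources the proximity of the candidate's blur to
        the sources' own defocus confounds the ordering.
        """
        x = y = small_pair.truth
        scores = []
        for sigma in (0, 1, 2, 4):
            f = small_pair.truth
            if sigma > 0:
                f = np.dstack(
                    [gaussian_smooth(f[..., c], GaussianSpec(sigma=sigma)) for c in range(3)]
                )
            rep = evaluate_fusion(x, y, f)
            scores.append((rep.qmi, rep.qy, rep.qabf))
        arr = np.array(scores)
        assert np.all(np.diff(arr, axis=0) <= 1e-9)
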