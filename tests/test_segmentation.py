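"""Online trial segmentation: dF/F statistics, Renyi thresholding, both algorithms."""

import numpy as np
import pytest

from trialcal import (
    Alg1Params,
    Alg2Params,
    ImageStack,
    TrialStructure,
    amplify_runs,
    binarize_stack,
    cumulative_dff_image,
    label_rois,
    pixel_dff,
    renyi_threshold,
    segment_trial_alg1,
    segment_trial_alg2,
    sensitivity_image,
)
from trialcal.segmentation import renyi_threshold_bin

# planted-movie params matched to the synthetic world: the intensity
# threshold is in cumulative-dF/F units and must sit between the noise
# floor (<0.5 for these movies) and the planted response score (>1.5)
PLANTED_ALG1 = Alg1Params(intensity_threshold=1.0)


def brute_force_renyi_bin(hist):
    """Independent evaluation of the three-order entropy criterion."""
    p = np.asarray(hist, float) / np.sum(hist)
    n = p.size

    def entropies(order):
        out = []
        for t in range(n):
            p1 = p[: t + 1].sum()
            p2 = p[t + 1 :].sum()
            if p1 < 1e-12 or p2 < 1e-12:
                out.append(-np.inf)
                continue
            back = [q / p1 for q in p[: t + 1] if q > 0]
            fore = [q / p2 for q in p[t + 1 :] if q > 0]
            if order == 1.0:
                h = -sum(q * np.log(q) for q in back) - sum(q * np.log(q) for q in fore)
            else:
                h = (
                    np.log(sum(q**order for q in back))
                    + np.log(sum(q**order for q in fore))
                ) / (1.0 - order)
            out.append(h)
        return int(np.argmax(out))

    t1, t2, t3 = sorted(entropies(o) for o in (0.5, 1.0, 2.0))
    if abs(t1 - t2) <= 5:
        b1, b2, b3 = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b1, b2, b3 = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    cum = np.cumsum(p)
    omega = cum[t3] - cum[t1]
    return int(
        t1 * (cum[t1] + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * ((1 - cum[t3]) + 0.25 * omega * b3)
    )


class TestPixelDff:
    def test_constant_stack_zero(self):
        stack = ImageStack(np.full((10, 8, 8), 50.0))
        trial = TrialStructure(n_frames=10, baseline_frames=np.arange(3))
        np.testing.assert_array_equal(pixel_dff(stack, trial), 0.0)

    def test_simple_transient(self):
        data = np.full((6, 8, 8), 100.0)
        data[4, 3, 3] = 150.0
        trial = TrialStructure(n_frames=6, baseline_frames=np.arange(3))
        dff = pixel_dff(ImageStack(data), trial)
        assert dff[4, 3, 3] == pytest.approx(0.5)

    def test_matches_direct_recomputation(self, rng):
        data = rng.uniform(10, 200, (12, 9, 9))
        stack = ImageStack(data)
        trial = TrialStructure(n_frames=12, baseline_frames=np.arange(4))
        expected = (data - data[:4].mean(0)) / data[:4].mean(0)
        np.testing.assert_allclose(pixel_dff(stack, trial), expected, atol=1e-12)

    def test_zero_baseline_policy(self):
        data = np.full((6, 8, 8), 100.0)
        data[:, 0, 0] = 0.0
        data[4, 0, 0] = 50.0  # zero baseline, nonzero response
        trial = TrialStructure(n_frames=6, baseline_frames=np.arange(3))
        dff = pixel_dff(ImageStack(data), trial)
        np.testing.assert_array_equal(dff[:, 0, 0], 0.0)


class TestCumulativeDff:
    def test_negative_pixels_floored(self, short_trial):
        dff = np.full((20, 8, 8), -0.2)
        np.testing.assert_array_equal(cumulative_dff_image(dff, short_trial), 0.0)

    def test_transient_beats_flat_of_equal_sum(self, short_trial):
        dff = np.zeros((20, 8, 8))
        resp = short_trial.response_frames
        dff[resp, 2, 2] = 1.5 / resp.size  # flat drift, sum 1.5
        dff[resp[0], 5, 5] = 1.5  # single transient, sum 1.5
        v = cumulative_dff_image(dff, short_trial)
        assert v[5, 5] > v[2, 2]

    def test_matches_direct_recomputation(self, rng, short_trial):
        dff = rng.normal(0, 0.3, (20, 6, 6))
        resp = short_trial.response_frames
        expected = dff[resp].std(axis=0) * np.maximum(0, dff[resp].sum(axis=0))
        np.testing.assert_allclose(
            cumulative_dff_image(dff, short_trial), expected, atol=1e-12
        )


class TestRenyiThreshold:
    def test_bimodal_separator(self, rng):
        img = np.full((50, 50), 10.0)
        img.ravel()[rng.choice(2500, 250, replace=False)] = 200.0
        thr = renyi_threshold(img)
        assert 10.0 < thr < 200.0

    def test_toy_histogram_matches_bruteforce(self):
        hist = np.array([40, 10, 5, 0, 0, 5, 10, 30])
        assert renyi_threshold_bin(hist) == brute_force_renyi_bin(hist)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_histogram_bin_matches_bruteforce_random(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 100, size=64)
        hist[rng.integers(0, 64)] += 500  # ensure some mass
        assert renyi_threshold_bin(hist) == brute_force_renyi_bin(hist)

    def test_affine_intensity_invariance(self, rng):
        img = rng.gamma(2.0, 20.0, size=(64, 64))
        thr = renyi_threshold(img, bins=256)
        a, b = 3.5, 120.0
        thr2 = renyi_threshold(a * img + b, bins=256)
        bin_width = a * (img.max() - img.min()) / 256
        assert abs(thr2 - (a * thr + b)) <= 1.5 * bin_width

    def test_constant_image_raises(self):
        with pytest.raises(Exception, match="no threshold"):
            renyi_threshold(np.full((8, 8), 3.0))


class TestLabelRois:
    def test_empty_binary(self):
        mask = label_rois(np.zeros((16, 16)), np.zeros((16, 16)))
        assert mask.n_rois == 0

    def test_sigma_merges_neighbours(self):
        binary = np.zeros((20, 20))
        binary[4:9, 4:9] = 1
        binary[4:9, 10:15] = 1  # 1-px gap at column 9
        score = np.full((20, 20), 100.0)
        merged = label_rois(binary, score, sigma=1.5, area_threshold=16,
                            intensity_threshold=None)
        split = label_rois(binary, score, sigma=0.0, area_threshold=16,
                           intensity_threshold=None)
        assert merged.n_rois == 1
        assert split.n_rois == 2

    def test_small_component_dropped_at_default_area(self):
        """A 3x3 block (area 9) falls below the default 16-px area threshold."""
        binary = np.zeros((16, 16))
        binary[5:8, 5:8] = 1
        mask = label_rois(binary, np.full((16, 16), 100.0), sigma=0.0)
        assert mask.n_rois == 0

    def test_label_integrity(self, cell_movie):
        spec, stack, _, _ = cell_movie
        mask = segment_trial_alg1(stack, spec.trial, PLANTED_ALG1)
        positive = (mask.labels > 0).sum()
        assert sum(r.area for r in mask.rois) == positive
        for roi in mask.rois:
            assert (mask.labels[roi.pixels[:, 0], roi.pixels[:, 1]] == roi.id).all()


class TestAlgorithm1:
    def test_planted_cells_recovered(self, cell_movie):
        spec, stack, _, truth = cell_movie
        mask = segment_trial_alg1(stack, spec.trial, PLANTED_ALG1)
        centers = truth["centers"]
        assert mask.n_rois >= spec.n_cells
        for c in centers:
            dists = [np.hypot(*(np.array(r.centroid) - c)) for r in mask.rois]
            assert min(dists) <= 2.0
        diameter = 4 * spec.cell_radius
        for r in mask.rois:
            assert min(np.hypot(*(np.array(r.centroid) - c)) for c in centers) <= diameter

    def test_noise_only_movie_empty_at_defaults(self, noise_movie):
        spec, stack = noise_movie
        assert segment_trial_alg1(stack, spec.trial).n_rois == 0

    def test_intensity_threshold_monotone(self, cell_movie):
        spec, stack, _, _ = cell_movie
        n1 = segment_trial_alg1(stack, spec.trial, Alg1Params(intensity_threshold=1.0)).n_rois
        n2 = segment_trial_alg1(stack, spec.trial, Alg1Params(intensity_threshold=2.0)).n_rois
        assert n2 <= n1


class TestBinarize:
    def test_three_sd_rule(self):
        """Baseline mean 100, population SD 5: 116 fires, 114 does not."""
        data = np.full((8, 8, 8), 100.0)
        data[0::2, :, :] = 95.0
        data[1::2, :, :] = 105.0  # baseline mean 100, pop SD 5
        data[6, 2, 2] = 116.0
        data[6, 3, 3] = 114.0
        trial = TrialStructure(n_frames=8, baseline_frames=np.arange(6))
        chi = binarize_stack(ImageStack(data), trial)
        assert chi[6, 2, 2] == 1.0
        assert chi[6, 3, 3] == 0.0

    def test_constant_stack_all_zero(self):
        stack = ImageStack(np.full((10, 8, 8), 42.0))
        trial = TrialStructure(n_frames=10, baseline_frames=np.arange(4))
        assert not binarize_stack(stack, trial).any()

    def test_matches_direct_recomputation(self, rng):
        data = rng.uniform(50, 150, (15, 8, 8))
        trial = TrialStructure(n_frames=15, baseline_frames=np.arange(5))
        chi = binarize_stack(ImageStack(data), trial)
        mu, sd = data[:5].mean(0), data[:5].std(0)
        np.testing.assert_array_equal(chi, (data > mu + 3 * sd).astype(float))


class TestAmplifyRuns:
    def test_closed_form_run(self):
        chi = np.array([1, 1, 1], float).reshape(3, 1, 1)
        out = amplify_runs(chi, alpha=2.0, beta=0.5)
        np.testing.assert_allclose(out.ravel(), [1, 3, 7])

    def test_reset_on_zero(self):
        chi = np.array([1, 0, 1], float).reshape(3, 1, 1)
        np.testing.assert_allclose(amplify_runs(chi, 2.0).ravel(), [1, 0, 1])

    def test_all_zero(self):
        assert not amplify_runs(np.zeros((5, 4, 4)), 2.0).any()

    @pytest.mark.parametrize("alpha", [1.5, 2.0, 3.0])
    def test_general_closed_form(self, alpha):
        n = 8
        chi = np.ones((n, 1, 1))
        out = amplify_runs(chi, alpha)
        expected = [(alpha ** m - 1) / (alpha - 1) for m in range(1, n + 1)]
        np.testing.assert_allclose(out.ravel(), expected, rtol=1e-12)

    def test_contiguous_beats_scattered(self):
        """Equal counts of ones: one contiguous run always outscores scatter."""
        run = np.zeros((12, 1, 1)); run[2:8] = 1
        scatter = np.zeros((12, 1, 1)); scatter[::2] = 1
        assert amplify_runs(run, 2.0).sum() > amplify_runs(scatter, 2.0).sum()


class TestSensitivityImage:
    def test_single_pixel_run_sum(self):
        chi = np.zeros((3, 21, 21)); chi[:, 10, 10] = 1
        amplified = amplify_runs(chi, 2.0)
        assert amplified[:, 10, 10].sum() == pytest.approx(11.0)  # 1 + 3 + 7
        sens = sensitivity_image(amplified, Alg2Params())
        assert sens.sum() == pytest.approx(11.0, abs=1e-9)  # normalised kernel

    def test_matches_direct_recomputation(self, rng):
        from scipy import ndimage

        amplified = rng.random((6, 16, 16))
        params = Alg2Params(smooth_sigma=1.0, cell_window=5)
        ax = np.arange(-2, 3.0)
        k = np.exp(-ax**2 / 2.0)
        kernel = np.outer(k, k); kernel /= kernel.sum()
        expected = ndimage.convolve(amplified.sum(0), kernel, mode="constant")
        np.testing.assert_allclose(sensitivity_image(amplified, params), expected, atol=1e-12)


class TestAlgorithm2:
    def test_planted_cells_recovered(self, cell_movie):
        spec, stack, _, truth = cell_movie
        mask = segment_trial_alg2(stack, spec.trial)
        centers = truth["centers"]
        diameter = 4 * spec.cell_radius
        hits = sum(
            min(np.hypot(*(np.array(r.centroid) - c)) for r in mask.rois) <= 2.0
            for c in centers
        )
        assert hits >= spec.n_cells - 2  # near-minimal-separation pairs may fuse
        for r in mask.rois:
            assert min(np.hypot(*(np.array(r.centroid) - c)) for c in centers) <= diameter

    def test_indicator_frames_monotone(self, cell_movie):
        spec, stack, _, _ = cell_movie
        n_small = segment_trial_alg2(stack, spec.trial, Alg2Params(indicator_frames=3)).n_rois
        n_large = segment_trial_alg2(stack, spec.trial, Alg2Params(indicator_frames=8)).n_rois
        assert n_large <= n_small

    def test_noise_only_movie_empty(self, noise_movie):
        spec, stack = noise_movie
        assert segment_trial_alg2(stack, spec.trial).n_rois == 0

    def test_cross_algorithm_consistency(self, cell_movie):
        """Both algorithms find the same strongly responding planted cells."""
        spec, stack, _, truth = cell_movie
        m1 = segment_trial_alg1(stack, spec.trial, PLANTED_ALG1)
        m2 = segment_trial_alg2(stack, spec.trial)
        for c in truth["centers"]:
            d1 = min(np.hypot(*(np.array(r.centroid) - c)) for r in m1.rois)
            d2 = min(np.hypot(*(np.array(r.centroid) - c)) for r in m2.rois)
            # each planted cell is covered by some ROI from both algorithms
            assert d1 <= 2.0 and d2 <= 2 * spec.cell_radius


class TestSegmentationProperties:
    def test_translation_equivariance(self):
        """Shifting the movie shifts every ROI centroid by the same amount
        (for content that stays clear of the border smoothing zone)."""
        from trialcal import CellMovieSpec, generate_cell_movie

        spec = CellMovieSpec(seed=3, margin=22.0)
        stack, _, _ = generate_cell_movie(spec)
        rolled = ImageStack(np.roll(stack.data, (4, -6), axis=(1, 2)), fps=stack.fps)
        for segment, params in (
            (segment_trial_alg1, PLANTED_ALG1),
            (segment_trial_alg2, Alg2Params()),
        ):
            base = segment(stack, spec.trial, params)
            moved = segment(rolled, spec.trial, params)
            c0 = sorted((r.centroid for r in base.rois))
            c1 = sorted(((r.centroid[0] - 4, r.centroid[1] + 6) for r in moved.rois))
            np.testing.assert_allclose(sorted(c1), sorted(c0), atol=1e-9)

    def test_determinism(self, cell_movie):
        spec, stack, _, _ = cell_movie
        a = segment_trial_alg2(stack, spec.trial)
        b = segment_trial_alg2(stack, spec.trial)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert [r.pixels.tolist() for r in a.rois] == [r.pixels.tolist() for r in b.rois]
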