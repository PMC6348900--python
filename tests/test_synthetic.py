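"""Generator tests: determinism, ground-truth fidelity, noise and depth laws."""

import numpy as np
import pytest
from scipy import stats as sps

from shgtensor.synthetic import (SyntheticParams, circular_mean_axial,
                                 gen_crosshatch, gen_depth_stack, gen_fibers,
                                 gen_frames, gen_isotropic,
                                 sample_axial_angles)


class TestGenFibers:
    def test_degenerate_no_dispersion_all_orientations_equal(self, stripe_params):
        _, gt = gen_fibers(stripe_params)
        ori = gt.fiber_orientations()
        assert ori.size > 0
        assert np.allclose(ori, 30.0)

    def test_isotropic_limit_uniform_orientations(self):
        # per-fiber angles (pixels within one fiber are not independent)
        rng = np.random.default_rng(3)
        draws = sample_axial_angles(2000, 0.0, 0.0, rng)
        res = sps.kstest(draws / 180.0, "uniform")
        assert res.pvalue > 1e-3
        p = SyntheticParams(image_size_px=(384, 384),
                            family_orientations_deg=(0.0,),
                            concentration_kappa=0.0,
                            waviness_amplitude_um=0.0, seed=3)
        _, gt = gen_fibers(p)
        fiber_angles = np.unique(gt.fiber_orientations())
        assert fiber_angles.size > 40
        res = sps.kstest(fiber_angles / 180.0, "uniform")
        assert res.pvalue > 1e-3

    def test_circular_mean_recovers_family_orientation(self):
        p = SyntheticParams(family_orientations_deg=(30.0,),
                            concentration_kappa=4.0, seed=5)
        _, gt = gen_fibers(p)
        mean = circular_mean_axial(gt.fiber_orientations())
        assert min(abs(mean - 30.0), 180 - abs(mean - 30.0)) < 2.0

    def test_requires_exactly_one_family(self):
        p = SyntheticParams(family_orientations_deg=(0.0, 90.0))
        with pytest.raises(ValueError):
            gen_fibers(p)

    @pytest.mark.parametrize("bad", [
        dict(image_size_px=(0, 64)),
        dict(fiber_spacing_um=-1.0),
        dict(concentration_kappa=-2.0),
        dict(disorder_mix=1.5),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticParams(**bad)

    def test_seed_reproducibility_bitwise(self, small_params):
        a, _ = gen_fibers(small_params)
        b, _ = gen_fibers(small_params)
        assert np.array_equal(a.intensity, b.intensity)


class TestGenCrosshatch:
    def test_orthogonal_families_two_modes_90_apart(self):
        p = SyntheticParams(image_size_px=(384, 384),
                            family_orientations_deg=(0.0, 90.0),
                            concentration_kappa=20.0, seed=2)
        _, gt = gen_crosshatch(p)
        ori = gt.fiber_orientations()
        near0 = np.mean((ori < 20) | (ori > 160))
        near90 = np.mean(np.abs(ori - 90) < 20)
        middle = np.mean(np.abs(ori - 45) < 20)
        assert near0 > 0.25 and near90 > 0.25
        assert middle < 0.5 * min(near0, near90)

    def test_zero_density_family_reduces_to_single_family(self):
        p = SyntheticParams(family_orientations_deg=(20.0, 110.0),
                            family_densities=(1.0, 0.0),
                            concentration_kappa=np.inf,
                            waviness_amplitude_um=0.0, seed=4)
        _, gt = gen_crosshatch(p)
        assert np.allclose(gt.fiber_orientations(), 20.0)
        assert set(np.unique(gt.family)) <= {-1, 0}

    def test_ground_truth_modes_match_requested_families(self):
        p = SyntheticParams(image_size_px=(384, 384),
                            family_orientations_deg=(20.0, 110.0),
                            concentration_kappa=24.0, seed=6)
        _, gt = gen_crosshatch(p)
        for fam, expected in ((0, 20.0), (1, 110.0)):
            ori = gt.orientation_deg[gt.family == fam]
            ori = ori[np.isfinite(ori)]
            mean = circular_mean_axial(ori)
            assert min(abs(mean - expected), 180 - abs(mean - expected)) < 2.0


class TestGenIsotropic:
    def test_seed_determinism(self):
        a = gen_isotropic((128, 128), seed=9)
        b = gen_isotropic((128, 128), seed=9)
        assert np.array_equal(a.intensity, b.intensity)

    def test_rotated_copy_has_same_radial_power_spectrum(self):
        img = gen_isotropic((256, 256), seed=1).intensity
        rot = np.rot90(img)

        def radial_spectrum(a):
            f = np.abs(np.fft.fftshift(np.fft.fft2(a - a.mean()))) ** 2
            h, w = a.shape
            yy, xx = np.mgrid[0:h, 0:w]
            r = np.hypot(yy - h / 2, xx - w / 2).astype(int)
            return np.bincount(r.ravel(), f.ravel()) / np.bincount(r.ravel())

        sa, sb = radial_spectrum(img), radial_spectrum(rot)
        m = min(len(sa), len(sb)) // 2
        assert np.allclose(sa[1:m], sb[1:m], rtol=0.25, atol=sa[1:m].max() * 0.01)

    def test_mean_intensity_near_background_level(self):
        img = gen_isotropic((256, 256), seed=2, background=0.3)
        assert img.intensity.mean() == pytest.approx(0.3, rel=0.1)


class TestGenDepthStack:
    def test_no_attenuation_no_rotation_statistically_identical_planes(self):
        p = SyntheticParams(image_size_px=(128, 128), n_planes=4,
                            attenuation_per_um=0.0,
                            rotation_per_plane_deg=0.0,
                            noise_scale=0.0, seed=8)
        stack = gen_depth_stack(p)
        means = [pl.intensity.mean() for pl in stack.planes]
        assert np.allclose(means, means[0], rtol=0.1)

    def test_exponential_intensity_decay(self):
        a, d = 0.005, 20.0
        p = SyntheticParams(image_size_px=(128, 128), n_planes=5,
                            attenuation_per_um=a, plane_spacing_um=d,
                            noise_scale=0.0, seed=8)
        stack = gen_depth_stack(p)
        base = stack.planes[0].intensity.mean()
        for k, plane in enumerate(stack.planes):
            expected = np.exp(-a * k * d)
            assert plane.intensity.mean() / base == pytest.approx(
                expected, rel=0.12)

    def test_rotation_arithmetic_of_family_means(self):
        p = SyntheticParams(image_size_px=(128, 128), n_planes=5,
                            family_orientations_deg=(0.0,),
                            concentration_kappa=np.inf,
                            waviness_amplitude_um=0.0,
                            rotation_per_plane_deg=10.0,
                            noise_scale=0.0, seed=8)
        stack = gen_depth_stack(p)
        gt4 = stack.ground_truth[4]
        assert gt4.family_means_deg[0] == pytest.approx(40.0)
        assert circular_mean_axial(gt4.fiber_orientations()) == pytest.approx(
            40.0, abs=0.5)

    def test_ground_truth_orientations_in_axial_range(self):
        p = SyntheticParams(image_size_px=(96, 96), n_planes=3,
                            rotation_per_plane_deg=75.0, seed=12)
        stack = gen_depth_stack(p)
        for gt in stack.ground_truth:
            ori = gt.fiber_orientations()
            assert np.all((ori >= 0) & (ori < 180))


class TestGenFrames:
    def test_zero_noise_frames_equal_input(self, stripe_params):
        img, _ = gen_fibers(stripe_params)
        fs = gen_frames(img, 3, "gaussian", 0.0, seed=1)
        for f in fs.frames:
            assert np.array_equal(f, img.intensity)

    def test_frame_mean_variance_reduction(self, stripe_params):
        img, _ = gen_fibers(stripe_params)
        sigma, n = 0.2, 3
        fs = gen_frames(img, n, "gaussian", sigma, seed=1)
        mean = np.mean(fs.frames, axis=0)
        resid = mean - img.intensity
        # clipping at zero distorts dark pixels; use bright ones
        bright = img.intensity > 3 * sigma
        assert resid[bright].var() == pytest.approx(sigma ** 2 / n, rel=0.15)

    def test_different_seeds_differ(self, stripe_params):
        img, _ = gen_fibers(stripe_params)
        a = gen_frames(img, 1, "gaussian", 0.1, seed=1).frames[0]
        b = gen_frames(img, 1, "gaussian", 0.1, seed=2).frames[0]
        assert not np.array_equal(a, b)

    def test_poisson_noise_scales_with_counts(self, stripe_params):
        img, _ = gen_fibers(stripe_params)
        fs = gen_frames(img, 1, "poisson", 100.0, seed=3)
        bright = img.intensity > 0.5
        resid = fs.frames[0][bright] - img.intensity[bright]
        expected_var = img.intensity[bright].mean() / 100.0
        assert resid.var() == pytest.approx(expected_var, rel=0.2)


class TestAxialSampling:
    def test_infinite_concentration_collapses_to_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_axial_angles(100, 42.0, np.inf, rng)
        assert np.allclose(draws, 42.0)

    def test_concentration_controls_spread(self):
        rng = np.random.default_rng(0)
        spreads = []
        for kappa in (1.0, 4.0, 16.0):
            draws = sample_axial_angles(4000, 90.0, kappa, rng)
            doubled = np.radians(2 * draws)
            resultant = np.hypot(np.sin(doubled).mean(), np.cos(doubled).mean())
            spreads.append(1 - resultant)  # circular variance
        assert spreads[0] > spreads[1] > spreads[2]
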