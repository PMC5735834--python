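"""The three denoisers: analytic properties, oracle equivalence, per-phase driver."""

import itertools

import numpy as np
import pytest

import cinedenoise.filters as filters_mod
from cinedenoise import (
    AnisoParams,
    OrnlmParams,
    TVParams,
    add_rician_noise,
    anisotropic_diffusion,
    denoise_series,
    ornlm,
    total_variation,
)
from cinedenoise.filters import patch_kernel, total_variation_value
from cinedenoise.noise import rician_sample


def ornlm_bruteforce(u, search_radius, patch_radius, h, sigma):
    """Independent per-voxel recomputation of Rician-corrected NLM.

    Direct loops over voxels and candidates with the patch distance evaluated
    on an edge-replicated padding; candidate patch stacks come from sliding
    windows, keeping the oracle readable yet tractable at 9^3.
    """
    R, P = search_radius, patch_radius
    pad = R + P
    up = np.pad(u, pad, mode="edge")
    win = 2 * P + 1
    patches = np.lib.stride_tricks.sliding_window_view(up, (win, win, win))
    G = patch_kernel(P)
    v = u * u
    out = np.empty_like(u, dtype=np.float64)
    for i in itertools.product(*(range(s) for s in u.shape)):
        lo = [max(0, a - R) for a in i]
        hi = [min(s, a + R + 1) for a, s in zip(i, u.shape)]
        cand = patches[tuple(slice(l + R, h_ + R) for l, h_ in zip(lo, hi))]
        mine = patches[tuple(a + R for a in i)]
        d2 = ((cand - mine) ** 2 * G).sum(axis=(-3, -2, -1))
        w = np.exp(-d2 / h**2)
        values = v[tuple(slice(l, h_) for l, h_ in zip(lo, hi))]
        avg = (w * values).sum() / w.sum()
        out[i] = np.sqrt(max(avg - 2 * sigma**2, 0.0))
    return out


class TestAnisotropicDiffusion:
    def test_constant_volume_is_fixed_point(self):
        vol = np.full((8, 9, 10), 3.7)
        out = anisotropic_diffusion(vol, AnisoParams(kappa=1.0))
        np.testing.assert_array_equal(out, vol)

    def test_intensity_sum_conserved(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(3.0, 1.0, (12, 13, 14))
        out = anisotropic_diffusion(vol, AnisoParams(kappa=0.8, n_iter=20))
        assert abs(out.sum() - vol.sum()) <= 1e-6 * abs(vol.sum())

    def test_step_edge_kept_while_flat_noise_suppressed(self):
        rng = np.random.default_rng(1)
        vol = np.zeros((16, 16, 16))
        vol[8:] = 10.0
        noise = rng.normal(0.0, 0.5, vol.shape)
        out = anisotropic_diffusion(vol + noise, AnisoParams(kappa=1.0))
        edge_height = (out[8] - out[7]).mean()
        assert edge_height >= 0.9 * 10.0
        flat = out[2:6] - vol[2:6]
        assert flat.var() <= 0.5 * noise[2:6].var()

    def test_unstable_time_step_rejected_with_bound(self):
        with pytest.raises(ValueError, match="stability bound"):
            anisotropic_diffusion(np.zeros((4, 4, 4)), AnisoParams(kappa=1.0, dt=0.5))

    def test_spacing_aware_mode_tightens_bound(self):
        params = AnisoParams(kappa=1.0, dt=1.0 / 14.0, spacing=(0.2, 0.2, 1.0))
        with pytest.raises(ValueError, match="stability bound"):
            anisotropic_diffusion(np.zeros((4, 4, 4)), params)


class TestTotalVariation:
    def test_zero_weight_is_identity(self, noisy_cube):
        out = total_variation(noisy_cube, TVParams(weight=0.0))
        np.testing.assert_array_equal(out, noisy_cube)

    def test_constant_volume_is_fixed_point(self):
        vol = np.full((8, 8, 8), 2.0)
        out = total_variation(vol, TVParams(weight=0.5))
        assert np.abs(out - vol).max() < 1e-10

    @pytest.mark.parametrize("weight", [0.05, 0.3, 1.0])
    def test_total_variation_never_increases(self, noisy_cube, weight):
        out = total_variation(noisy_cube, TVParams(weight=weight))
        assert total_variation_value(out) <= total_variation_value(noisy_cube) + 1e-8

    def test_matches_reference_solver(self, noisy_cube):
        from skimage.restoration import denoise_tv_chambolle

        mine = total_variation(noisy_cube, TVParams(weight=0.3, max_iter=3000, tol=1e-8))
        ref = denoise_tv_chambolle(noisy_cube, weight=0.3, max_num_iter=3000, eps=1e-10)
        rms = np.sqrt(((mine - ref) ** 2).mean())
        assert rms < 1e-3

    def test_non_finite_input_rejected(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            total_variation(vol, TVParams(weight=0.1))


class TestOrnlm:
    def test_default_window_sizes_match_protocol(self):
        params = OrnlmParams()
        assert params.search_volume_size == 1331
        assert params.patch_neighborhood_size == 26

    def test_identity_in_degenerate_limit(self):
        # sigma = 0 and h -> 0+: the self weight dominates all-distinct patches
        rng = np.random.default_rng(5)
        vol = np.abs(rng.normal(2.0, 0.5, (7, 7, 7)))
        out = ornlm(vol, OrnlmParams(search_radius=2, sigma=0.0, h=1e-8))
        assert np.abs(out - vol).max() < 1e-10

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        vol = np.abs(rng.normal(2.0, 0.5, (9, 9, 9)))
        params = OrnlmParams(sigma=0.4)  # default 11^3 search, 3^3 patches
        mine = ornlm(vol, params)
        ref = ornlm_bruteforce(vol, params.search_radius, params.patch_radius, 0.4, 0.4)
        assert np.abs(mine - ref).max() < 1e-10

    def test_bias_correction_recenters_constant_region(self):
        # E[M^2] = A^2 + 2 sigma^2: the corrected mean is closer to A than the noisy mean
        A, sigma = 10.0, 2.0
        rng = np.random.default_rng(8)
        noisy = rician_sample(np.full((12, 12, 12), A), sigma, rng)
        out = ornlm(noisy, OrnlmParams(search_radius=3, sigma=sigma))
        assert abs(out.mean() - A) < abs(noisy.mean() - A)

    def test_output_nonnegative_even_with_overestimated_sigma(self):
        rng = np.random.default_rng(9)
        noisy = rician_sample(np.full((8, 8, 8), 0.5), 1.0, rng)
        out = ornlm(noisy, OrnlmParams(search_radius=2, sigma=5.0))
        assert (out >= 0).all()

    def test_auto_sigma_needs_background(self):
        with pytest.raises(ValueError, match="background"):
            ornlm(np.ones((8, 8, 8)), OrnlmParams(search_radius=2, sigma="auto"))

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            OrnlmParams(search_radius=1, patch_radius=2)


class TestRmseReduction:
    @pytest.mark.parametrize("method,params", [
        ("aniso", AnisoParams(kappa=0.4)),
        ("tv", TVParams(weight=0.2)),
        ("ornlm", OrnlmParams(search_radius=3, sigma=0.2)),
    ])
    def test_each_filter_beats_raw_noise(self, small_phantom, method, params):
        series, _ = small_phantom
        clean = series.phase(0)
        rng = np.random.default_rng(12)
        noisy = rician_sample(clean, 0.2, rng)
        out = filters_mod.denoise_volume(noisy, method, params)
        rmse_noisy = np.sqrt(((noisy - clean) ** 2).mean())
        rmse_out = np.sqrt(((out - clean) ** 2).mean())
        assert rmse_out < rmse_noisy


class TestDenoiseSeries:
    def test_one_filter_call_per_phase(self, small_phantom, monkeypatch):
        series, _ = small_phantom
        calls = []
        orig = filters_mod.denoise_volume

        def counting(volume, method, params, background_mask=None):
            calls.append(volume.shape)
            return orig(volume, method, params, background_mask=background_mask)

        monkeypatch.setattr(filters_mod, "denoise_volume", counting)
        denoise_series(series, "aniso", AnisoParams(kappa=0.5, n_iter=1))
        assert len(calls) == series.n_phases
        assert all(shape == series.data.shape[:3] for shape in calls)

    def test_shape_and_spacing_preserved(self, small_phantom):
        series, _ = small_phantom
        out = denoise_series(series, "tv", TVParams(weight=0.1, max_iter=20))
        assert out.data.shape == series.data.shape
        assert out.spacing == series.spacing

    def test_phase_permutation_commutes(self, small_phantom):
        series, _ = small_phantom
        noisy = add_rician_noise(series, 0.2, seed=3)
        perm = np.array([3, 0, 2, 1, 7, 5, 6, 4])
        params = AnisoParams(kappa=0.5, n_iter=3)
        filtered_then_permuted = denoise_series(noisy, "aniso", params).data[..., perm]
        permuted_then_filtered = denoise_series(
            noisy.with_data(noisy.data[..., perm]), "aniso", params
        ).data
        np.testing.assert_allclose(filtered_then_permuted, permuted_then_filtered, atol=1e-12)

    def test_unknown_method_lists_valid_ones(self, small_phantom):
        series, _ = small_phantom
        with pytest.raises(ValueError, match="aniso"):
            denoise_series(series, "gaussian")
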