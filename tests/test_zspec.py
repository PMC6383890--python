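"""Normalization, spline interpolation, B0 correction and MTR asymmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micest.bloch import zspectrum_values
from micest.core import CestStack, ConfigurationError, ImageGeometry, ZSpectrum
from micest.synthetic import PhantomSpec, default_offsets_cest, make_cest_phantom
from micest.wassr import build_b0_map
from micest.zspec import (
    b0_correct,
    interpolate_spectrum,
    mtr_asym,
    mtr_asym_curve,
    mtr_asym_map,
    normalize_stack,
)

OFFSETS = default_offsets_cest()


@pytest.fixture(scope="module")
def three_pool_spectrum(water, hydroxyl, mt_pool, cest_pulse, ctx):
    z = zspectrum_values([water, hydroxyl, mt_pool], cest_pulse, OFFSETS, ctx,
                         "steady_state")
    return ZSpectrum(OFFSETS, z)


class TestNormalize:
    def test_constant_reference_scales_volumes(self):
        geom = ImageGeometry(matrix=(4, 4))
        stack = CestStack(np.full((3, 4, 4), 80.0), [-1, 0, 1],
                          np.full((4, 4), 100.0), geom)
        norm, mask = normalize_stack(stack)
        assert mask.all()
        np.testing.assert_allclose(norm, 0.8)

    def test_zero_reference_voxel_masked(self):
        geom = ImageGeometry(matrix=(4, 4))
        ref = np.full((4, 4), 100.0)
        ref[1, 2] = 0.0
        stack = CestStack(np.full((3, 4, 4), 80.0), [-1, 0, 1], ref, geom)
        norm, mask = normalize_stack(stack)
        assert not mask[1, 2] and mask.sum() == 15
        assert np.isnan(norm[:, 1, 2]).all()

    def test_phantom_round_trip_matches_simulator(self, water, hydroxyl, mt_pool,
                                                  cest_pulse, ctx):
        spec = PhantomSpec(grid=(12, 12), noise_sd=0.0, seed=0,
                           b0_poly=(0.0,), lesion_fraction_scale=1.0)
        cest, _, _ = make_cest_phantom(spec, pools=[water, hydroxyl, mt_pool])
        norm, mask = normalize_stack(cest)
        assert mask.all()
        # uniform noiseless phantom: every voxel equals the direct simulation
        direct = zspectrum_values([water, hydroxyl, mt_pool], cest_pulse,
                                  cest.offsets_ppm, ctx, "steady_state")
        np.testing.assert_allclose(
            norm, direct[:, None, None] * np.ones((1, 12, 12)), atol=1e-12
        )


class TestInterpolation:
    def test_passes_through_input_points(self, three_pool_spectrum):
        dense = interpolate_spectrum(three_pool_spectrum, grid_step=0.01)
        idx = np.abs(dense.offsets[:, None] - three_pool_spectrum.offsets).argmin(axis=0)
        np.testing.assert_allclose(dense.values[idx],
                                   three_pool_spectrum.values, atol=1e-12)

    def test_dense_grid_contains_contrast_offset(self, three_pool_spectrum):
        dense = interpolate_spectrum(three_pool_spectrum, grid_step=0.01)
        assert np.min(np.abs(dense.offsets - 0.6)) < 1e-9

    def test_error_against_simulator_away_from_dip(self, water, hydroxyl,
                                                   mt_pool, cest_pulse, ctx):
        pools = [water, hydroxyl, mt_pool]
        sampled = ZSpectrum(OFFSETS, zspectrum_values(pools, cest_pulse,
                                                      OFFSETS, ctx, "steady_state"))
        dense = interpolate_spectrum(sampled, grid_step=0.01)
        truth = zspectrum_values(pools, cest_pulse, dense.offsets, ctx,
                                 "steady_state")
        away = np.abs(dense.offsets) > 0.3
        assert np.max(np.abs(dense.values - truth)[away]) <= 0.005

    def test_no_large_overshoot_on_monotone_segment(self, three_pool_spectrum):
        dense = interpolate_spectrum(three_pool_spectrum, grid_step=0.01)
        seg = (dense.offsets >= 1.0) & (dense.offsets <= 4.0)  # monotone flank
        lo = three_pool_spectrum.values[three_pool_spectrum.offsets >= 1.0].min()
        hi = three_pool_spectrum.values[three_pool_spectrum.offsets >= 1.0].max()
        margin = 0.02 * (hi - lo)
        assert dense.values[seg].min() >= lo - margin
        assert dense.values[seg].max() <= hi + margin

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(ConfigurationError):
            ZSpectrum([0.0, 0.0, 1.0, 2.0], [1, 1, 1, 1])


class TestB0Correct:
    def test_zero_shift_is_identity(self, three_pool_spectrum):
        out = b0_correct(three_pool_spectrum, 0.0)
        assert out is three_pool_spectrum

    def test_round_trip_recenters_spectrum(self, water, hydroxyl, mt_pool,
                                           cest_pulse, ctx):
        pools = [water, hydroxyl, mt_pool]
        shift = 0.1
        shifted = ZSpectrum(OFFSETS, zspectrum_values(pools, cest_pulse,
                                                      OFFSETS - shift, ctx,
                                                      "steady_state"))
        corrected = b0_correct(interpolate_spectrum(shifted), shift)
        truth = zspectrum_values(pools, cest_pulse, corrected.offsets, ctx,
                                 "steady_state")
        away = np.abs(corrected.offsets) > 0.3
        assert np.max(np.abs(corrected.values - truth)[away]) <= 0.005

    def test_pipeline_round_trip_residual_bounded(self, water, hydroxyl, mt_pool,
                                                  cest_pulse, wassr_pulse, ctx):
        # simulate-with-shift -> WASSR estimate -> correct -> asymmetry stays
        # within the interpolation-limited residual of the 0.2-ppm schedule:
        # ~0.24 pp spline bias on the exchange line plus ~150 pp/ppm
        # sensitivity to the ~0.0015 ppm WASSR estimator bias
        from micest.synthetic import default_offsets_wassr
        from micest.wassr import fit_voxel_shift

        pools = [water, hydroxyl, mt_pool]
        woffs = default_offsets_wassr()
        ref = mtr_asym(
            interpolate_spectrum(
                ZSpectrum(OFFSETS, zspectrum_values(pools, cest_pulse, OFFSETS,
                                                    ctx, "steady_state"))
            ),
            0.6,
        )
        for shift in (-0.3, -0.1, 0.15, 0.3):
            zw = zspectrum_values(pools, wassr_pulse, woffs - shift, ctx,
                                  "steady_state")
            est = fit_voxel_shift(ZSpectrum(woffs, zw), search_range=0.35)
            zc = zspectrum_values(pools, cest_pulse, OFFSETS - shift, ctx,
                                  "steady_state")
            out = mtr_asym(
                b0_correct(interpolate_spectrum(ZSpectrum(OFFSETS, zc)), est), 0.6
            )
            assert abs(out - ref) <= 0.6

    def test_excessive_shift_invalidates_voxel(self, three_pool_spectrum):
        with pytest.raises(ConfigurationError):
            b0_correct(three_pool_spectrum, 0.9)

    def test_wassr_estimate_recenters_dip(self, water, wassr_pulse, ctx):
        from micest.synthetic import default_offsets_wassr
        from micest.wassr import fit_voxel_shift

        offs = default_offsets_wassr()
        true_shift = 0.12
        z = ZSpectrum(offs, zspectrum_values([water], wassr_pulse,
                                             offs - true_shift, ctx,
                                             "steady_state"))
        est = fit_voxel_shift(z)
        corrected = b0_correct(interpolate_spectrum(z, 0.001), est)
        dip = corrected.offsets[np.argmin(corrected.values)]
        assert abs(dip) <= 0.005


class TestAsymmetry:
    def test_direct_substitution(self):
        z = ZSpectrum([-0.6, -0.2, 0.2, 0.6], [0.80, 0.4, 0.4, 0.70])
        assert mtr_asym(z, 0.6) == pytest.approx(10.0)

    def test_symmetric_spectrum_is_null(self, water, cest_pulse, ctx):
        z = ZSpectrum(OFFSETS, zspectrum_values([water], cest_pulse, OFFSETS,
                                                ctx, "steady_state"))
        _, curve = mtr_asym_curve(interpolate_spectrum(z))
        assert np.max(np.abs(curve)) <= 1e-6 * 100

    def test_matches_direct_simulation(self, water, hydroxyl, mt_pool,
                                       cest_pulse, ctx):
        pools = [water, hydroxyl, mt_pool]
        z = ZSpectrum(OFFSETS, zspectrum_values(pools, cest_pulse, OFFSETS,
                                                ctx, "steady_state"))
        direct = zspectrum_values(pools, cest_pulse, np.array([-0.6, 0.6]),
                                  ctx, "steady_state")
        expected = 100.0 * (direct[0] - direct[1])
        assert mtr_asym(interpolate_spectrum(z), 0.6) == pytest.approx(
            expected, abs=0.1
        )
        assert expected > 0

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(delta=st.floats(0.2, 3.8))
    def test_antisymmetric_under_mirroring(self, delta, three_pool_spectrum):
        z = three_pool_spectrum
        mirrored = ZSpectrum(-z.offsets[::-1], z.values[::-1])
        assert mtr_asym(mirrored, delta) == pytest.approx(
            -mtr_asym(z, delta), abs=1e-9
        )

    def test_delta_outside_support_rejected(self, three_pool_spectrum):
        with pytest.raises(ConfigurationError):
            mtr_asym(three_pool_spectrum, 5.0)


class TestAsymmetryMap:
    def test_uniform_phantom_gives_constant_map(self, water, hydroxyl, mt_pool):
        spec = PhantomSpec(grid=(12, 12), noise_sd=0.0, seed=0,
                           b0_poly=(0.0,), lesion_fraction_scale=1.0)
        cest, wassr, _ = make_cest_phantom(spec, pools=[water, hydroxyl, mt_pool])
        amap, valid = mtr_asym_map(cest, build_b0_map(wassr))
        assert valid.all()
        assert np.nanstd(amap) <= 1e-3

    def test_lesion_exceeds_control(self):
        spec = PhantomSpec(grid=(24, 24), noise_sd=0.0, seed=0)
        cest, wassr, truth = make_cest_phantom(spec)
        amap, _ = mtr_asym_map(cest, build_b0_map(wassr))
        geom = spec.geometry
        rl, cl = spec.lesion_roi.to_slices(geom)
        rc, cc = spec.control_roi.to_slices(geom)
        assert np.nanmean(amap[rl, cl]) > np.nanmean(amap[rc, cc])
        assert truth.asym_difference_percent > 0

    def test_artifact_region_flagged_invalid(self):
        spec = PhantomSpec(grid=(24, 24), noise_sd=0.0, seed=0,
                           b0_artifact=(0.8, 2.0, 2.0, 2.0))
        cest, wassr, truth = make_cest_phantom(spec)
        amap, valid = mtr_asym_map(cest, build_b0_map(wassr))
        bad = truth.b0_field > 0.35
        assert bad.any() and not valid[bad].any()
        assert valid[truth.b0_field < 0.25].all()

    def test_matches_per_voxel_composition(self, water, hydroxyl, mt_pool):
        # the vectorized map equals interpolate -> correct -> asym per voxel
        spec = PhantomSpec(grid=(8, 8), noise_sd=0.0, seed=0)
        cest, wassr, truth = make_cest_phantom(spec, pools=[water, hydroxyl, mt_pool])
        b0 = build_b0_map(wassr)
        amap, valid = mtr_asym_map(cest, b0)
        norm, _ = normalize_stack(cest)
        for (r, c) in [(0, 0), (3, 4), (7, 7)]:
            z = ZSpectrum(cest.offsets_ppm, norm[:, r, c])
            expected = mtr_asym(
                b0_correct(interpolate_spectrum(z, 0.01), b0.shift[r, c]), 0.6
            )
            assert amap[r, c] == pytest.approx(expected, abs=5e-3)
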