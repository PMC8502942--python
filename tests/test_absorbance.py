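import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from thzvol import (
    AbsorbanceMap,
    AcquisitionConfig,
    PhantomSpec,
    PowerRaster,
    average_replicates,
    build_phantom,
    calibrate_skin_background,
    compute_absorbance,
    estimate_skin_background,
    simulate_scan,
)
from conftest import noiseless_alpha_map


def make_raster(power, background=1.0):
    return PowerRaster(
        power_grid=np.asarray(power, dtype=float),
        background_power=background,
        frequency_ghz=108.0,
        pitch_mm=0.1,
    )


def make_map(alpha, **kw):
    defaults = dict(thickness_mm=0.5, pitch_mm=0.1, frequency_ghz=108.0)
    defaults.update(kw)
    return AbsorbanceMap(alpha_grid=np.asarray(alpha, dtype=float), **defaults)


class TestComputeAbsorbance:
    def test_unit_transmission_gives_zero_alpha(self):
        amap = compute_absorbance(make_raster(np.ones((4, 4))), 0.5)
        assert np.all(amap.alpha_grid == 0.0)

    def test_closed_form_inversion(self):
        amap = compute_absorbance(
            make_raster(np.full((3, 3), math.exp(-0.75))), 0.5
        )
        assert np.allclose(amap.alpha_grid, 1.5)

    def test_doubling_thickness_halves_alpha(self):
        r = make_raster(np.full((2, 2), 0.3))
        a1 = compute_absorbance(r, 0.5).alpha_grid
        a2 = compute_absorbance(r, 1.0).alpha_grid
        assert np.allclose(a2, a1 / 2)

    def test_attenuating_sample_yields_positive_alpha(self):
        amap = compute_absorbance(make_raster(np.full((2, 2), 0.5)), 0.5)
        assert np.all(amap.alpha_grid > 0)

    def test_rejects_nonpositive_thickness(self):
        with pytest.raises(ValueError, match="thickness"):
            compute_absorbance(make_raster(np.ones((2, 2))), 0.0)

    def test_raster_type_rejects_nonpositive_power_with_pixel_location(self):
        with pytest.raises(ValueError, match=r"\(1, 0\)|> 0"):
            make_raster([[1.0, 1.0], [0.0, 1.0]])

    @settings(max_examples=30, deadline=None)
    @given(
        powers=hnp.arrays(
            float, (3, 4), elements=st.floats(1e-6, 1.0, exclude_min=True)
        ),
        other=hnp.arrays(
            float, (3, 4), elements=st.floats(1e-6, 1.0, exclude_min=True)
        ),
    )
    def test_log_linearity_geometric_mean(self, powers, other):
        """alpha of the geometric mean of two rasters equals the mean of
        the two alpha maps (log identity)."""
        d = 0.5
        a1 = compute_absorbance(make_raster(powers), d).alpha_grid
        a2 = compute_absorbance(make_raster(other), d).alpha_grid
        geo = compute_absorbance(make_raster(np.sqrt(powers * other)), d).alpha_grid
        assert np.allclose(geo, (a1 + a2) / 2, rtol=1e-9, atol=1e-9)


class TestAverageReplicates:
    def test_mean_of_single_map_is_identity(self):
        m = make_map(np.random.default_rng(0).uniform(1, 2, (5, 5)))
        avg = average_replicates([m])
        np.testing.assert_array_equal(avg.alpha_grid, m.alpha_grid)
        assert avg.n_replicates_averaged == 1

    def test_pixelwise_arithmetic_mean(self):
        avg = average_replicates([make_map([[1.4]]), make_map([[1.6]])])
        assert avg.alpha_grid[0, 0] == pytest.approx(1.5)
        assert avg.n_replicates_averaged == 2

    def test_three_replicates_reduce_noise_sd_by_sqrt3(self):
        """Monte-Carlo: SD over pixels of 3-replicate means vs single scans."""
        tissue = build_phantom(PhantomSpec())
        acq = AcquisitionConfig(snr=1e3, n_replicates=3, rng_seed=11)
        maps = [compute_absorbance(r, 0.5) for r in simulate_scan(tissue, acq)]
        avg = average_replicates(maps)
        sd_single = (maps[0].alpha_grid - 1.42).std()
        sd_avg = (avg.alpha_grid - 1.42).std()
        assert sd_avg / sd_single == pytest.approx(1 / math.sqrt(3), rel=0.10)

    @pytest.mark.parametrize(
        "other",
        [
            make_map(np.ones((3, 3))),  # shape mismatch
            make_map(np.ones((2, 2)), thickness_mm=1.0),
            make_map(np.ones((2, 2)), frequency_ghz=120.0),
            make_map(np.ones((2, 2)), skin_corrected=True),
        ],
    )
    def test_rejects_metadata_mismatch(self, other):
        with pytest.raises(ValueError, match="mismatch"):
            average_replicates([make_map(np.ones((2, 2))), other])

    def test_rejects_empty_list(self):
        with pytest.raises(ValueError):
            average_replicates([])


class TestSkinCalibration:
    def test_zero_depth_leaves_map_unchanged(self):
        m = make_map([[1.5, 1.6]])
        out = calibrate_skin_background(m, 0.0)
        np.testing.assert_array_equal(out.alpha_grid, m.alpha_grid)
        assert out.skin_corrected

    def test_uniform_subtraction_in_alpha_units(self):
        out = calibrate_skin_background(make_map([[1.7]], thickness_mm=0.5), 0.1)
        assert out.alpha_grid[0, 0] == pytest.approx(1.5)

    def test_double_correction_is_an_error(self):
        once = calibrate_skin_background(make_map([[1.7]]), 0.05)
        with pytest.raises(ValueError, match="already"):
            calibrate_skin_background(once, 0.05)

    def test_roundtrip_recovers_phantom_ground_truth(self, tumor_spec):
        tissue, amap = noiseless_alpha_map(tumor_spec)
        np.testing.assert_allclose(
            amap.alpha_grid, tissue.alpha_grid, rtol=1e-10, atol=0
        )

    def test_averaging_then_correcting_equals_correcting_then_averaging(self):
        rng = np.random.default_rng(5)
        maps = [make_map(rng.uniform(1.4, 1.7, (6, 6))) for _ in range(3)]
        a = calibrate_skin_background(average_replicates(maps), 0.08)
        b = average_replicates([calibrate_skin_background(m, 0.08) for m in maps])
        np.testing.assert_allclose(a.alpha_grid, b.alpha_grid, rtol=1e-12)
        assert a.skin_corrected == b.skin_corrected


class TestEstimateSkinBackground:
    def test_zero_when_mask_mean_matches_expected(self):
        m = make_map(np.full((4, 4), 1.42))
        mask = np.ones((4, 4), dtype=bool)
        assert estimate_skin_background(m, mask, 1.42) == 0.0

    def test_arithmetic_example(self):
        m = make_map(np.full((4, 4), 1.62), thickness_mm=0.5)
        mask = np.ones((4, 4), dtype=bool)
        assert estimate_skin_background(m, mask, 1.42) == pytest.approx(0.1)

    def test_recovers_generating_depth_on_noise_free_phantom(self, tumor_spec):
        _, amap = noiseless_alpha_map(tumor_spec, skin_corrected=False)
        mask = np.zeros(amap.shape, dtype=bool)
        mask[:5, :] = True  # border rows, outside the central tumor
        depth = estimate_skin_background(amap, mask, tumor_spec.fat_alpha)
        assert depth == pytest.approx(tumor_spec.skin_optical_depth, rel=1e-12)

    def test_negative_excess_is_floored_at_zero(self):
        m = make_map(np.full((2, 2), 1.30))
        assert estimate_skin_background(m, np.ones((2, 2), bool), 1.42) == 0.0

    def test_empty_mask_is_an_error(self):
        m = make_map(np.ones((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            estimate_skin_background(m, np.zeros((2, 2), bool), 1.42)
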