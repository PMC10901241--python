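import math

import numpy as np
import pytest

from pamarker import (
    Absorber,
    AcquisitionParams,
    ChannelData,
    Image,
    ImageGrid,
    InvalidParameterError,
    NoPeakError,
    OpticalModel,
    Phantom,
    Pose,
    Scatterer,
    WeightingSpec,
    apply_pose,
    das_reconstruct,
    feature_extent,
    lateral_fwhm,
    locate_peak,
    make_arc_array,
    make_linear_array,
    multi_view_reconstruct,
    reconstruct_volume,
    rf_envelope,
    simulate_pa_channels,
    simulate_us_channels,
    us_bmode,
)

from _oracles import naive_das


def _rotate_phantom(phantom, angle):
    c, s = math.cos(angle), math.sin(angle)
    rotated = []
    for a in phantom.absorbers:
        x, y, z = a.position
        rotated.append(Absorber((c * x - s * z, y, s * x + c * z), a.amplitude))
    return Phantom(absorbers=rotated, optics=phantom.optics)


class TestDasOracleEquivalence:
    """The vectorized beamformer must agree with a literal triple loop."""

    def test_pa_delays_match_oracle(self, acq_short):
        rng = np.random.default_rng(0)
        geom = make_linear_array(n_elements=16, pitch=0.6e-3)
        channels = ChannelData(
            rng.normal(size=(16, 1024)), 40e6, 0.0, "PA", geom
        )
        grid = ImageGrid(-3e-3, 3e-3, 5e-3, 11e-3, 0.25e-3)
        image = das_reconstruct(channels, grid, 1500.0)
        oracle = naive_das(
            channels.samples, 40e6, 0.0, geom.element_positions,
            geom.element_normals, grid.x, grid.z, 1500.0,
        )
        scale = np.abs(oracle).max()
        assert np.abs(image.values - oracle).max() <= 1e-6 * scale

    def test_us_delays_match_oracle(self):
        rng = np.random.default_rng(1)
        geom = make_linear_array(n_elements=8, pitch=0.6e-3)
        channels = ChannelData(rng.normal(size=(8, 1024)), 40e6, 0.0, "US", geom)
        grid = ImageGrid(-2e-3, 2e-3, 3e-3, 8e-3, 0.25e-3)
        image = das_reconstruct(channels, grid, 1540.0)
        oracle = naive_das(
            channels.samples, 40e6, 0.0, geom.element_positions,
            geom.element_normals, grid.x, grid.z, 1540.0, delay_factor=2.0,
        )
        scale = np.abs(oracle).max()
        assert np.abs(image.values - oracle).max() <= 1e-6 * scale

    @pytest.mark.parametrize("exponent,max_angle", [(0.0, 1.0), (2.0, 0.5)])
    def test_weighting_variants_match_oracle(self, exponent, max_angle):
        rng = np.random.default_rng(2)
        geom = make_arc_array(radius=30e-3, span=120.0, n_elements=12)
        channels = ChannelData(rng.normal(size=(12, 1024)), 40e6, 0.0, "PA", geom)
        grid = ImageGrid(-3e-3, 3e-3, -3e-3, 3e-3, 0.5e-3)
        weights = WeightingSpec(angular_exponent=exponent, max_angle=max_angle)
        image = das_reconstruct(channels, grid, 1500.0, weights)
        oracle = naive_das(
            channels.samples, 40e6, 0.0, geom.element_positions,
            geom.element_normals, grid.x, grid.z, 1500.0,
            angular_exponent=exponent, max_angle=max_angle,
        )
        scale = max(np.abs(oracle).max(), 1e-30)
        assert np.abs(image.values - oracle).max() <= 1e-6 * scale


class TestDasBasics:
    def test_zero_channels_give_zero_image(self, small_array, point_grid):
        channels = ChannelData(np.zeros((16, 512)), 40e6, 0.0, "PA", small_array)
        image = das_reconstruct(channels, point_grid)
        assert not np.any(image.values)

    def test_point_source_localized_within_wavelength(
        self, linear_array, acq, point_phantom, point_grid
    ):
        channels = simulate_pa_channels(point_phantom, linear_array, acq)
        image = das_reconstruct(channels, point_grid)
        peak = locate_peak(image)
        assert math.hypot(peak.x - 0.0, peak.z - 20e-3) <= 0.3e-3

    def test_reconstruction_linear_in_channels(self, linear_array, acq, point_phantom, point_grid):
        channels = simulate_pa_channels(point_phantom, linear_array, acq)
        scaled = channels.copy()
        scaled.samples *= 1.09
        a = das_reconstruct(channels, point_grid)
        b = das_reconstruct(scaled, point_grid)
        nz = np.abs(a.values) > 0
        assert np.allclose(b.values[nz] / a.values[nz], 1.09, rtol=1e-6)

    def test_lateral_translation_equivariance(self, linear_array, acq):
        # shifting the source by a whole number of pixels shifts the peak
        shift = 1e-3  # 10 pixels at 0.1 mm
        grid = ImageGrid(-5e-3, 5e-3, 16e-3, 24e-3, 0.1e-3)
        optics = OpticalModel(mu_eff=0.0)
        p0 = Phantom(absorbers=[Absorber((0.0, 0.0, 20e-3), 1.0)], optics=optics)
        p1 = Phantom(absorbers=[Absorber((shift, 0.0, 20e-3), 1.0)], optics=optics)
        i0 = das_reconstruct(simulate_pa_channels(p0, linear_array, acq), grid)
        i1 = das_reconstruct(simulate_pa_channels(p1, linear_array, acq), grid)
        pk0, pk1 = locate_peak(i0), locate_peak(i1)
        assert pk1.x - pk0.x == pytest.approx(shift, abs=0.05e-3)
        # the bipolar PSF's |peak| may land on either axial lobe, so depth
        # agreement is only guaranteed to within one wavelength
        assert pk1.z == pytest.approx(pk0.z, abs=0.3e-3)

    def test_us_modality_uses_round_trip_delay(self, linear_array, acq, point_scatterer_phantom, point_grid):
        channels = simulate_us_channels(point_scatterer_phantom, linear_array, acq)
        image = das_reconstruct(channels, point_grid)
        assert image.modality == "US_rf"
        peak = locate_peak(image)
        assert math.hypot(peak.x, peak.z - 20e-3) <= 0.3e-3


class TestBmode:
    def test_zero_image_gives_zero_bmode(self, point_grid):
        rf = Image(np.zeros(point_grid.shape), point_grid, "US_rf")
        bmode = us_bmode(rf)
        assert not np.any(bmode.values)

    def test_output_range(self, linear_array, acq, point_scatterer_phantom, point_grid):
        channels = simulate_us_channels(point_scatterer_phantom, linear_array, acq)
        bmode = us_bmode(das_reconstruct(channels, point_grid), dynamic_range=40.0)
        assert bmode.values.min() >= 0.0 and bmode.values.max() <= 1.0
        assert bmode.modality == "US_bmode"

    def test_scatterer_localized_in_bmode(self, linear_array, acq, point_scatterer_phantom, point_grid):
        channels = simulate_us_channels(point_scatterer_phantom, linear_array, acq)
        bmode = us_bmode(das_reconstruct(channels, point_grid))
        iz, ix = np.unravel_index(np.argmax(bmode.values), bmode.values.shape)
        x, z = point_grid.x[ix], point_grid.z[iz]
        assert math.hypot(x, z - 20e-3) <= 0.3e-3

    def test_wrong_modality_rejected(self, point_grid):
        pa = Image(np.zeros(point_grid.shape), point_grid, "PA")
        with pytest.raises(InvalidParameterError):
            us_bmode(pa)


class TestMultiView:
    @pytest.fixture
    def arc(self):
        return make_arc_array(radius=55e-3, span=178.0, n_elements=64)

    @pytest.fixture
    def arc_grid(self):
        return ImageGrid(-3e-3, 3e-3, -3e-3, 3e-3, 0.1e-3)

    def _views(self, arc, angles_deg, phantom, acq):
        views = []
        for angle_deg in angles_deg:
            pose = Pose(rotation_angle=math.radians(angle_deg))
            posed = apply_pose(arc, pose)
            cd = simulate_pa_channels(phantom, posed, acq)
            local = ChannelData(cd.samples, cd.sampling_rate, cd.t0, cd.modality, arc)
            views.append((local, pose))
        return views

    def test_single_identity_view_equals_plain_das(self, arc, arc_grid, acq):
        phantom = Phantom(
            absorbers=[Absorber((0.5e-3, 0.0, 0.5e-3), 1.0)], optics=OpticalModel(mu_eff=0.0)
        )
        channels = simulate_pa_channels(phantom, arc, acq)
        direct = das_reconstruct(channels, arc_grid)
        joint = multi_view_reconstruct([(channels, Pose())], arc_grid)
        assert np.array_equal(joint.values, direct.values)

    def test_four_views_do_not_widen_psf(self, arc, arc_grid, acq):
        phantom = Phantom(
            absorbers=[Absorber((0.5e-3, 0.0, 0.5e-3), 1.0)], optics=OpticalModel(mu_eff=0.0)
        )
        views = self._views(arc, [0, 45, 90, 135], phantom, acq)
        single = multi_view_reconstruct(views[:1], arc_grid)
        multi = multi_view_reconstruct(views, arc_grid)
        assert lateral_fwhm(multi) <= lateral_fwhm(single)

    def test_joint_rotation_equivariance(self, arc, arc_grid, acq):
        # rotating phantom and every pose together leaves the image unchanged
        phantom = Phantom(
            absorbers=[Absorber((0.8e-3, 0.0, -0.4e-3), 1.0)], optics=OpticalModel(mu_eff=0.0)
        )
        extra = math.radians(30.0)
        views_a = self._views(arc, [0, 90], phantom, acq)
        rotated = _rotate_phantom(phantom, extra)
        views_b = []
        for angle_deg in [0, 90]:
            pose = Pose(rotation_angle=math.radians(angle_deg) + extra)
            posed = apply_pose(arc, pose)
            cd = simulate_pa_channels(rotated, posed, acq)
            views_b.append(
                (ChannelData(cd.samples, cd.sampling_rate, cd.t0, cd.modality, arc), pose)
            )
        img_a = multi_view_reconstruct(views_a, arc_grid)
        img_b = multi_view_reconstruct(views_b, arc_grid)
        # compare the rotated image against the original rotated by the grid
        # symmetry: peaks must coincide after undoing the rotation
        pa, pb = locate_peak(img_a), locate_peak(img_b)
        c, s = math.cos(extra), math.sin(extra)
        xb_expected = c * pa.x - s * pa.z
        zb_expected = s * pa.x + c * pa.z
        assert pb.x == pytest.approx(xb_expected, abs=0.15e-3)
        assert pb.z == pytest.approx(zb_expected, abs=0.15e-3)
        assert abs(pb.amplitude) == pytest.approx(abs(pa.amplitude), rel=0.1)

    def test_empty_views_rejected(self, arc_grid):
        with pytest.raises(InvalidParameterError):
            multi_view_reconstruct([], arc_grid)


class TestVolume:
    def test_single_slice_volume_equals_2d_image(self, small_array, acq_short, point_grid):
        rng = np.random.default_rng(3)
        channels = ChannelData(rng.normal(size=(16, 1024)), 40e6, 0.0, "PA", small_array)
        image = das_reconstruct(channels, point_grid)
        volume = reconstruct_volume([(0.0, [(channels, Pose())])], point_grid)
        assert volume.values.shape[0] == 1
        assert np.array_equal(volume.values[0], image.values)

    def test_empty_channels_give_zero_volume(self, small_array, point_grid):
        channels = ChannelData(np.zeros((16, 512)), 40e6, 0.0, "PA", small_array)
        volume = reconstruct_volume(
            [(0.0, [(channels, Pose())]), (1e-3, [(channels, Pose())])], point_grid
        )
        assert not np.any(volume.values)

    def test_duplicate_slice_positions_rejected(self, small_array, point_grid):
        channels = ChannelData(np.zeros((16, 512)), 40e6, 0.0, "PA", small_array)
        with pytest.raises(InvalidParameterError):
            reconstruct_volume(
                [(0.0, [(channels, Pose())]), (0.0, [(channels, Pose())])], point_grid
            )


class TestPeakAndExtent:
    def _single_pixel_image(self, point_grid, iz=10, ix=20, value=2.0):
        values = np.zeros(point_grid.shape)
        values[iz, ix] = value
        return Image(values, point_grid, "PA")

    def test_single_pixel_peak_coordinates(self, point_grid):
        image = self._single_pixel_image(point_grid)
        peak = locate_peak(image)
        assert peak.x == pytest.approx(point_grid.x[20], abs=1e-15)
        assert peak.z == pytest.approx(point_grid.z[10], abs=1e-15)
        assert peak.amplitude == 2.0

    def test_tie_breaks_toward_smaller_depth(self, point_grid):
        values = np.zeros(point_grid.shape)
        values[5, 8] = 1.0
        values[30, 8] = 1.0
        peak = locate_peak(Image(values, point_grid, "PA"))
        assert peak.z == pytest.approx(point_grid.z[5], abs=1e-12)

    def test_negative_peak_found_by_magnitude(self, point_grid):
        values = np.zeros(point_grid.shape)
        values[7, 3] = -5.0
        values[9, 4] = 2.0
        peak = locate_peak(Image(values, point_grid, "PA"))
        assert peak.amplitude == -5.0

    def test_all_zero_image_raises(self, point_grid):
        with pytest.raises(NoPeakError):
            locate_peak(Image(np.zeros(point_grid.shape), point_grid, "PA"))

    def test_subpixel_recovery_of_off_grid_point(self, linear_array, acq):
        phantom = Phantom(
            absorbers=[Absorber((2.5e-3, 0.0, 17.5e-3), 1.0)], optics=OpticalModel(mu_eff=0.0)
        )
        grid = ImageGrid(-1e-3, 6e-3, 14e-3, 21e-3, 0.1e-3)
        image = das_reconstruct(simulate_pa_channels(phantom, linear_array, acq), grid)
        peak = locate_peak(image)
        assert math.hypot(peak.x - 2.5e-3, peak.z - 17.5e-3) <= 0.3e-3

    def test_single_pixel_extent_is_one_spacing(self, point_grid):
        image = self._single_pixel_image(point_grid)
        dx, dz = feature_extent(image, 0.5)
        assert dx == pytest.approx(point_grid.pixel_spacing)
        assert dz == pytest.approx(point_grid.pixel_spacing)

    def test_extent_of_horizontal_bar(self, point_grid):
        values = np.zeros(point_grid.shape)
        values[10, 5:15] = 1.0
        dx, dz = feature_extent(Image(values, point_grid, "PA"), 0.5)
        assert dx == pytest.approx(10 * point_grid.pixel_spacing)
        assert dz == pytest.approx(point_grid.pixel_spacing)

    def test_extent_ignores_disconnected_clutter(self, point_grid):
        values = np.zeros(point_grid.shape)
        values[10, 5:15] = 1.0
        values[40, 70] = 0.9  # disconnected, above threshold
        dx, _ = feature_extent(Image(values, point_grid, "PA"), 0.5)
        assert dx == pytest.approx(10 * point_grid.pixel_spacing)

    def test_envelope_requires_rf_image(self, point_grid):
        bmode = Image(np.zeros(point_grid.shape), point_grid, "US_bmode")
        with pytest.raises(InvalidParameterError):
            rf_envelope(bmode)
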