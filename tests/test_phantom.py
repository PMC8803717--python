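"""Phantom geometry, gradient schemes, rotation, and DWI simulation."""

import dataclasses

import numpy as np
import pytest

from dtialps import alps as alps_mod
from dtialps import phantom as ph
from dtialps import tensorfit as tf
from dtialps.directions import MIN_LINE_ANGLE_DEG, direction_set, min_pairwise_line_angle_deg


def isotropic_spec(grid=(24, 24, 12), d=1.0e-3) -> ph.PhantomSpec:
    comps = {
        "background": (0.0, 0.0, 0.0),
        "csf": (d, d, d),
        "projection": (d, d, d),
        "association": (d, d, d),
    }
    return ph.PhantomSpec(grid_shape=grid, voxel_size_mm=(1.0, 1.0, 1.0),
                          compartment_diffusivities=comps, pvs_fraction=0.0)


class TestBuildPhantom:
    def test_degenerate_spec_is_isotropic_in_tissue(self):
        field = ph.build_corona_radiata_phantom(isotropic_spec())
        tissue = field.labels >= ph.LABEL_CODES["projection"]
        t = field.tensors[tissue]
        assert np.allclose(t, 1.0e-3 * np.eye(3))

    def test_projection_principal_axis_is_z(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        proj = field.tensors[field.labels == ph.LABEL_CODES["projection"]]
        vals, vecs = np.linalg.eigh(proj)
        principal = np.abs(vecs[..., -1])  # eigenvector of largest eigenvalue
        assert np.all(np.abs(principal - [0, 0, 1]) < 1e-6)

    def test_association_principal_axis_is_y(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        assoc = field.tensors[field.labels == ph.LABEL_CODES["association"]]
        _, vecs = np.linalg.eigh(assoc)
        assert np.all(np.abs(np.abs(vecs[..., -1]) - [0, 1, 0]) < 1e-6)

    def test_roi_centers_mirror_symmetric(self, default_spec):
        centers = default_spec.resolved_roi_centers()
        mid = (default_spec.grid_shape[0] - 1) / 2
        for (hemi, region), c in centers.items():
            other = centers[("left" if hemi == "right" else "right", region)]
            assert c[0] - mid == pytest.approx(mid - other[0])
            assert c[1:] == other[1:]

    def test_roi_center_outside_region_rejected(self, small_spec):
        # centers placed into the anterior CSF slab: mirror-symmetric, wrong region
        bad = {
            ("right", "projection"): (8.5, 1.0, 5.5),
            ("left", "projection"): (14.5, 1.0, 5.5),
            ("right", "association"): (2.5, 1.0, 5.5),
            ("left", "association"): (20.5, 1.0, 5.5),
        }
        spec = dataclasses.replace(small_spec, roi_centers=bad)
        with pytest.raises(ph.GeometryError):
            ph.build_corona_radiata_phantom(spec)

    def test_ground_truth_alps_matches_pipeline_on_noiseless_field(self, small_spec):
        """Closed-form index from the compartment table equals the full
        phantom -> fit -> ROI pipeline on noiseless data."""
        field = ph.build_corona_radiata_phantom(small_spec)
        scheme = ph.make_scheme(12, 1, 85)
        acq = ph.simulate_dwi(field, scheme, snr_b0=float("inf"))
        maps = tf.maps_from_tensor(tf.fit_tensor_loglinear(acq))
        rois = alps_mod.build_pattern_rois(field.roi_centers, "sphere", 6)
        res = alps_mod.compute_alps(
            alps_mod.measure_rois(maps, rois, pixel_spacing=small_spec.voxel_size_mm)
        )
        assert res.alps_bil == pytest.approx(ph.ground_truth_alps(small_spec), rel=1e-9)

    def test_ground_truth_alps_invariant_under_common_scaling(self, default_spec):
        scaled_comps = {
            k: tuple(np.asarray(v) * 0.8)
            for k, v in default_spec.compartment_diffusivities.items()
        }
        scaled = dataclasses.replace(
            default_spec,
            compartment_diffusivities=scaled_comps,
            pvs_diffusivities=tuple(np.asarray(default_spec.pvs_diffusivities) * 0.8),
        )
        assert ph.ground_truth_alps(scaled) == pytest.approx(
            ph.ground_truth_alps(default_spec), rel=1e-12
        )


class TestMakeScheme:
    def test_three_axis_scheme_is_orthogonal_axes(self):
        s = ph.make_scheme(3, 4, 85, 1000)
        weighted = s.directions[s.bvalues > 0]
        assert {tuple(g) for g in weighted} == {(1, 0, 0), (0, 1, 0), (0, 0, 1)}
        assert s.averages == 4
        assert s.diffusion_time_ms == pytest.approx(35.7)

    def test_te_pairs_with_diffusion_time(self):
        assert ph.make_scheme(12, 2, 100).diffusion_time_ms == pytest.approx(40.7)
        assert ph.make_scheme(12, 2, 65).diffusion_time_ms == pytest.approx(29.0)

    @pytest.mark.parametrize("n_axes", [12, 30])
    def test_pairwise_line_angles_meet_documented_minimum(self, n_axes):
        """Brute-force recomputation of the frozen minimum pairwise angle."""
        dirs = direction_set(n_axes)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        assert min_pairwise_line_angle_deg(dirs) >= MIN_LINE_ANGLE_DEG[n_axes]

    def test_unsupported_parameters_raise(self):
        with pytest.raises(ph.ParameterError):
            ph.make_scheme(6, 1, 85)
        with pytest.raises(ph.ParameterError):
            ph.make_scheme(12, 1, 70)

    def test_scheme_requires_b0_and_unit_directions(self):
        with pytest.raises(ph.ParameterError):
            ph.GradientScheme(directions=np.eye(3), bvalues=np.full(3, 1000.0), n_axes=3)
        dirs = np.vstack([np.zeros(3), 2 * np.eye(3)])
        with pytest.raises(ph.ParameterError):
            ph.GradientScheme(directions=dirs, bvalues=np.array([0, 1000, 1000, 1000.0]),
                              n_axes=3)


class TestHeadRotation:
    def test_zero_pitch_is_identity(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        rotated = ph.apply_head_rotation(field, 0.0)
        assert np.array_equal(rotated.tensors, field.tensors)
        assert np.array_equal(rotated.labels, field.labels)

    def test_isotropic_field_invariant(self):
        field = ph.build_corona_radiata_phantom(isotropic_spec())
        rotated = ph.apply_head_rotation(field, 17.0)
        tissue = rotated.labels >= ph.LABEL_CODES["projection"]
        assert np.allclose(rotated.tensors[tissue], 1.0e-3 * np.eye(3), atol=1e-15)

    def test_pitch_matches_explicit_conjugation(self, small_spec):
        """Pitch mixes Dyy/Dzz as the cos^2/sin^2 combination of R D R^T."""
        field = ph.build_corona_radiata_phantom(small_spec)
        pitch = 20.0
        rotated = ph.apply_head_rotation(field, pitch)
        a = np.deg2rad(pitch)
        R = np.array([[1, 0, 0],
                      [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        # compare at the grid-center voxel, which maps onto itself
        c = tuple(s // 2 for s in small_spec.grid_shape)
        expected = R @ field.tensors[c] @ R.T
        assert np.allclose(rotated.tensors[c], expected, atol=1e-18)
        d = field.tensors[c]
        assert rotated.tensors[c][1, 1] == pytest.approx(
            np.cos(a) ** 2 * d[1, 1] + np.sin(a) ** 2 * d[2, 2]
        )

    @pytest.mark.parametrize("pitch", [-30.0, 8.5, 20.0, 44.0])
    def test_rotation_preserves_eigenvalues(self, small_spec, pitch):
        """Conjugation is a similarity transform: each rotated voxel keeps
        the eigenvalues of its (region-determined) source tensor."""
        field = ph.build_corona_radiata_phantom(small_spec)
        rotated = ph.apply_head_rotation(field, pitch)
        for region in ("projection", "association"):
            code = ph.LABEL_CODES[region]
            ref = np.sort(np.linalg.eigvalsh(field.tensors[field.labels == code][0]))
            got = np.sort(np.linalg.eigvalsh(rotated.tensors[rotated.labels == code]), axis=-1)
            assert np.all(np.abs(got - ref) < 1e-12)

    def test_excessive_pitch_rejected(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        with pytest.raises(ph.ParameterError):
            ph.apply_head_rotation(field, 60.0)


class TestSimulateDwi:
    def test_b0_infinite_snr_equals_s0(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        scheme = ph.make_scheme(12, 1, 85)
        acq = ph.simulate_dwi(field, scheme, snr_b0=float("inf"))
        b0 = acq.signals[..., scheme.bvalues == 0][..., 0]
        s0 = (field.labels != ph.LABEL_CODES["background"]).astype(float)
        assert np.array_equal(b0, s0)

    def test_isotropic_closed_form(self):
        d = 0.7e-3
        field = ph.build_corona_radiata_phantom(isotropic_spec(d=d))
        scheme = ph.make_scheme(12, 1, 85)
        acq = ph.simulate_dwi(field, scheme, snr_b0=float("inf"))
        tissue = field.labels >= ph.LABEL_CODES["projection"]
        st, _ = field.time_scales(scheme.diffusion_time_ms)
        expected = np.exp(-1000.0 * d * st)
        weighted = acq.signals[tissue][:, scheme.bvalues > 0]
        assert np.allclose(weighted, expected, rtol=1e-12)

    def test_background_magnitude_matches_rician_mean(self, default_spec):
        """A zero-signal region's mean magnitude is the Rayleigh/Rician mean
        sigma*sqrt(pi/2), within 3 standard errors (Monte Carlo)."""
        field = ph.build_corona_radiata_phantom(default_spec)
        scheme = ph.make_scheme(3, 1, 85)
        snr = 40.0
        acq = ph.simulate_dwi(field, scheme, snr_b0=snr, seed=123)
        bg = acq.signals[field.labels == ph.LABEL_CODES["background"]]
        n = bg.size
        assert n >= 10_000
        sigma = 1.0 / snr
        mean_expect = sigma * np.sqrt(np.pi / 2)
        sd_expect = sigma * np.sqrt(2 - np.pi / 2)
        assert abs(bg.mean() - mean_expect) < 3 * sd_expect / np.sqrt(n)

    def test_same_seed_reproducible_different_seed_not(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        scheme = ph.make_scheme(12, 2, 85)
        a = ph.simulate_dwi(field, scheme, snr_b0=40, seed=5)
        b = ph.simulate_dwi(field, scheme, snr_b0=40, seed=5)
        c = ph.simulate_dwi(field, scheme, snr_b0=40, seed=6)
        assert np.array_equal(a.signals, b.signals)
        assert not np.array_equal(a.signals, c.signals)

    def test_averaging_reduces_roi_signal_scatter(self, small_spec):
        """Empirical SD of ROI-mean signals strictly drops when the number
        of averages increases (20+ realizations, fixed seed set)."""
        field = ph.build_corona_radiata_phantom(small_spec)
        center = field.roi_centers[("right", "projection")]
        sl = tuple(slice(int(c) - 2, int(c) + 3) for c in center)
        sds = []
        for averages in (1, 2, 4):
            scheme = ph.make_scheme(12, averages, 85)
            vol = np.flatnonzero(scheme.bvalues > 0)[0]
            means = [
                ph.simulate_dwi(field, scheme, snr_b0=15, seed=s).signals[sl + (vol,)].mean()
                for s in range(25)
            ]
            sds.append(np.std(means))
        assert sds[0] > sds[1] > sds[2]

    def test_scanner_profile_scales_noise(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        scheme = ph.make_scheme(3, 1, 85)
        bg = field.labels == ph.LABEL_CODES["background"]
        sd_c = ph.simulate_dwi(field, scheme, 40, seed=1, scanner_profile="centurian").signals[bg].std()
        sd_p = ph.simulate_dwi(field, scheme, 40, seed=1, scanner_profile="prisma").signals[bg].std()
        factor = ph.SCANNER_SNR_FACTOR["centurian"] / ph.SCANNER_SNR_FACTOR["prisma"]
        assert sd_p / sd_c == pytest.approx(factor, rel=0.05)

    def test_raw_storage_keeps_every_average(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        scheme = ph.make_scheme(3, 4, 85)
        raw = ph.simulate_dwi(field, scheme, 40, seed=2, store_averaged=False)
        assert raw.signals.shape[-1] == scheme.n_volumes * scheme.averages
        assert np.allclose(raw.averaged_signals().shape[-1], scheme.n_volumes)

    def test_invalid_parameters(self, small_spec):
        field = ph.build_corona_radiata_phantom(small_spec)
        scheme = ph.make_scheme(3, 1, 85)
        with pytest.raises(ph.ParameterError):
            ph.simulate_dwi(field, scheme, snr_b0=0.0)
        with pytest.raises(ph.ParameterError):
            ph.simulate_dwi(field, scheme, 40, scanner_profile="nonesuch")
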