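"""Tilt angle, penetration depth, leaflet assignment and histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memprobe import geometry as mg
from tests.conftest import BOX, make_probe_frame


class TestBilayerNormal:
    def test_is_lab_z_unit_vector(self, small_trajectory):
        n = mg.bilayer_normal(small_trajectory.frames[0])
        assert np.allclose(n, [0, 0, 1])
        assert np.isclose(np.linalg.norm(n), 1.0)

    def test_leaflet_oriented_normal_flips_for_lower_leaflet(self):
        frame = make_probe_frame([3, 3, 3], [3, 3, 2.5])
        assert np.allclose(mg.leaflet_normal(frame, "lower"), [0, 0, -1])

    def test_lower_leaflet_probe_with_nitrogen_toward_water_has_zero_tilt(self):
        # N displaced from C along -z, probe in the lower leaflet: still 0 deg
        frame = make_probe_frame([3, 3, 2.0], [3, 3, 1.5])
        assert mg.assign_leaflet(frame, frame.select(resnames="PRB")) == "lower"
        assert mg.probe_tilt_angle(frame, leaflet="lower") == pytest.approx(0.0, abs=1e-9)


class TestProbeTilt:
    @pytest.mark.parametrize(
        "c,n,expected",
        [
            ([3, 3, 4.0], [3, 3, 4.5], 0.0),  # parallel, N toward water
            ([3, 3, 4.0], [3.5, 3, 4.0], 90.0),  # in the membrane plane
            ([3, 3, 4.5], [3, 3, 4.0], 180.0),  # bent back toward the interior
        ],
    )
    def test_stated_semantics(self, c, n, expected):
        frame = make_probe_frame(c, n)
        assert mg.probe_tilt_angle(frame, leaflet="upper") == pytest.approx(expected)

    def test_missing_atom_raises(self):
        frame = make_probe_frame([3, 3, 4], [3, 3, 4.5])
        with pytest.raises(mg.SelectionError):
            mg.probe_tilt_angle(frame, carbonyl_name="CX")

    @given(
        theta=st.floats(1.0, 179.0),
        phi=st.floats(0.0, 2 * np.pi),
        shift=st.floats(-1.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_swap_complements_to_180_and_translation_invariance(self, theta, phi, shift):
        t = np.radians(theta)
        d = 0.5 * np.array([np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.cos(t)])
        c = np.array([3.0, 3.0, 4.0]) + shift
        frame = make_probe_frame(c, c + d)
        fwd = mg.probe_tilt_angle(frame, "C1", "N1")
        rev = mg.probe_tilt_angle(frame, "N1", "C1")
        assert fwd + rev == pytest.approx(180.0, abs=1e-9)
        assert fwd == pytest.approx(theta, abs=1e-9)

    def test_invariant_under_rotation_about_normal(self):
        rng = np.random.default_rng(0)
        d = np.array([0.3, 0.1, 0.35])
        c = np.array([3.0, 3.0, 4.0])
        ref = mg.probe_tilt_angle(make_probe_frame(c, c + d))
        for ang in rng.uniform(0, 2 * np.pi, 10):
            rot = np.array(
                [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
            )
            assert mg.probe_tilt_angle(make_probe_frame(c, c + rot @ d)) == pytest.approx(
                ref, abs=1e-9
            )

    def test_isotropic_orientations_have_zero_mean_cos(self):
        """Uniform-on-sphere directions: mean cos(tilt) = 0 within 3 SE."""
        rng = np.random.default_rng(7)
        n = 10**5
        cos_t = rng.uniform(-1, 1, n)  # cos(theta) uniform <=> isotropic
        phi = rng.uniform(0, 2 * np.pi, n)
        sin_t = np.sqrt(1 - cos_t**2)
        # angle of these vectors against +z recomputed through the observable
        tilts = np.array(
            [
                mg.probe_tilt_angle(
                    make_probe_frame(
                        [3, 3, 4], [3 + 0.5 * sin_t[i] * np.cos(phi[i]),
                                    3 + 0.5 * sin_t[i] * np.sin(phi[i]),
                                    4 + 0.5 * cos_t[i]],
                    )
                )
                for i in range(0, n, 50)  # observable path on a systematic subsample
            ]
        )
        assert np.allclose(np.cos(np.radians(tilts)), cos_t[::50], atol=1e-9)
        mean = cos_t.mean()
        se = cos_t.std(ddof=1) / np.sqrt(n)
        assert abs(mean) < 3 * se + 1e-12 or abs(mean) < 0.01


class TestPenetrationDepth:
    def test_probe_below_phosphates_is_positive(self):
        frame = make_probe_frame([3, 3, 4.7], [3, 3, 4.7])
        upper = frame.select(names="P")[:2]  # z = 5.5
        probe = frame.select(resnames="PRB")
        # probe COM z = 4.7, phosphate plane 5.5 -> depth +0.8
        assert mg.penetration_depth(frame, probe, upper, "upper") == pytest.approx(0.8)

    def test_coincident_coms_give_zero(self):
        frame = make_probe_frame([3, 3, 5.5], [3, 3, 5.5])
        upper = frame.select(names="P")[:2]
        probe = frame.select(resnames="PRB")
        assert mg.penetration_depth(frame, probe, upper, "upper") == pytest.approx(0.0)

    def test_probe_above_phosphates_is_negative(self):
        frame = make_probe_frame([3, 3, 5.8], [3, 3, 5.8])
        upper = frame.select(names="P")[:2]
        probe = frame.select(resnames="PRB")
        assert mg.penetration_depth(frame, probe, upper, "upper") == pytest.approx(-0.3)

    def test_sign_flips_under_mirror_through_phosphate_plane(self):
        plane = 5.5
        for dz in (0.4, -0.25):
            f1 = make_probe_frame([3, 3, plane - dz], [3, 3, plane - dz])
            f2 = make_probe_frame([3, 3, plane + dz], [3, 3, plane + dz])
            upper = f1.select(names="P")[:2]
            probe = f1.select(resnames="PRB")
            d1 = mg.penetration_depth(f1, probe, upper, "upper")
            d2 = mg.penetration_depth(f2, probe, upper, "upper")
            assert d1 == pytest.approx(-d2)

    def test_empty_selection_raises(self):
        frame = make_probe_frame([3, 3, 4], [3, 3, 4.5])
        with pytest.raises(mg.SelectionError):
            mg.penetration_depth(frame, np.array([], dtype=int), frame.select(names="P"))


class TestLeafletAssignment:
    def test_above_midplane_is_upper(self):
        frame = make_probe_frame([3, 3, 4.5], [3, 3, 5.0])  # midplane at 3.5
        assert mg.assign_leaflet(frame, frame.select(resnames="PRB")) == "upper"

    def test_below_midplane_is_lower(self):
        frame = make_probe_frame([3, 3, 2.0], [3, 3, 2.5])
        assert mg.assign_leaflet(frame, frame.select(resnames="PRB")) == "lower"

    def test_exactly_at_midplane_raises(self):
        frame = make_probe_frame([3, 3, 3.5], [4, 3, 3.5])
        with pytest.raises(mg.AmbiguousLeafletError):
            mg.assign_leaflet(frame, frame.select(resnames="PRB"))


class TestChainTilt:
    def test_chain_toward_midplane_is_zero(self):
        frame = make_probe_frame([3, 3, 5.0], [3, 3, 4.0])
        idx = frame.select(resnames="PRB")  # C at 5.0, N at 4.0: along -z
        assert mg.chain_tilt_angle(frame, idx, "upper") == pytest.approx(0.0)

    def test_chain_in_membrane_plane_is_90(self):
        frame = make_probe_frame([3, 3, 4.0], [3.7, 3, 4.0])
        idx = frame.select(resnames="PRB")
        assert mg.chain_tilt_angle(frame, idx, "upper") == pytest.approx(90.0)

    def test_folding_makes_polarity_irrelevant(self):
        f1 = make_probe_frame([3, 3, 5.0], [3.2, 3, 4.0])
        idx = f1.select(resnames="PRB")
        assert mg.chain_tilt_angle(f1, idx) == mg.chain_tilt_angle(f1, idx[::-1])

    def test_single_atom_raises(self):
        frame = make_probe_frame([3, 3, 4], [3, 3, 4.5])
        with pytest.raises(mg.SelectionError):
            mg.chain_tilt_angle(frame, np.array([0]))


class TestHistogram:
    def test_point_mass_mode_and_normalisation(self):
        h = mg.build_histogram(np.full(100, 28.0), 5.0, (0.0, 180.0))
        assert abs(h.mode() - 28.0) <= h.bin_width / 2
        assert np.sum(h.density * np.diff(h.edges)) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_samples_are_flat(self):
        rng = np.random.default_rng(1)
        h = mg.build_histogram(rng.uniform(0, 180, 10**5), 5.0, (0.0, 180.0))
        assert h.density.max() / h.density.min() < 1.2

    def test_bimodal_ground_truth_recovered(self, bimodal_trajectory):
        gt = bimodal_trajectory.ground_truth["tilt_deg"].to_numpy()
        h = mg.build_histogram(gt, 5.0, (0.0, 180.0))
        maxima = h.local_maxima(min_rel_height=0.3)
        assert any(abs(m - 28.0) <= 5.0 for m in maxima)
        assert any(abs(m - 120.0) <= 5.0 for m in maxima)

    def test_empty_samples_raise(self):
        with pytest.raises(ValueError):
            mg.build_histogram(np.array([]), 5.0, (0.0, 180.0))

    @given(n=st.integers(2, 500), width=st.floats(0.5, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_density_always_integrates_to_one(self, n, width):
        rng = np.random.default_rng(n)
        h = mg.build_histogram(rng.uniform(0, 180, n), width, (0.0, 180.0))
        assert np.sum(h.density * np.diff(h.edges)) == pytest.approx(1.0, abs=1e-9)
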