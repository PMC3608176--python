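"""Packing energy term E', projection geometry and the surrogate score."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from gpcrbundle.fixtures import BundleSpec, make_ideal_bundle
from gpcrbundle.moves import spin_helix
from gpcrbundle.packing import (
    EnergyModel,
    MembraneScoreParams,
    PackingParams,
    calibrate_area_bounds,
    membrane_intersections,
    packing_areas,
    packing_energy_term,
    surrogate_membrane_score,
    total_energy,
)
from gpcrbundle.structure import HelixSegment, MembraneFrame, fit_helix_axis

Z = np.array([0.0, 0.0, 1.0])
FRAME = MembraneFrame(normal=Z, midplane_point=np.zeros(3))


def heptagon(radius=1.0):
    t = 2 * np.pi * np.arange(7) / 7
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(7)])


def shoelace_fan_area(points):
    """Independent oracle: sum of cross-product triangle areas about the centroid."""
    o = points.mean(axis=0)
    total = 0.0
    for i in range(7):
        a = points[i] - o
        b = points[(i + 1) % 7] - o
        total += 0.5 * np.linalg.norm(np.cross(a, b))
    return total


def segment(index, axis, centroid):
    axis = np.asarray(axis, float)
    return HelixSegment(
        index=index, range=(1, 10), axis=axis / np.linalg.norm(axis),
        centroid=np.asarray(centroid, float),
    )


class TestIntersections:
    def test_axis_along_normal_from_midplane(self):
        seg = segment(1, Z, [3.0, 4.0, 0.0])
        pts = membrane_intersections([seg], FRAME)
        np.testing.assert_allclose(pts[0], [3, 4, 0], atol=1e-12)

    def test_axis_along_normal_above_plane(self):
        seg = segment(1, Z, [3.0, 4.0, 10.0])
        pts = membrane_intersections([seg], FRAME)
        np.testing.assert_allclose(pts[0], [3, 4, 0], atol=1e-12)

    def test_tilted_axis_closed_form(self):
        # axis tilted 30 deg in the xz-plane, centroid at (0,0,5):
        # the line meets z=0 at x = -5 tan(30)
        axis = [np.sin(np.deg2rad(30)), 0.0, np.cos(np.deg2rad(30))]
        pts = membrane_intersections([segment(1, axis, [0, 0, 5.0])], FRAME)
        np.testing.assert_allclose(
            pts[0], [-5 * np.tan(np.deg2rad(30)), 0, 0], atol=1e-9
        )

    def test_in_plane_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate intersection"):
            membrane_intersections([segment(3, [1, 0, 0], [0, 0, 5.0])], FRAME)


class TestPackingAreas:
    def test_regular_heptagon_closed_form(self):
        geom = packing_areas(heptagon())
        expected = 0.5 * np.sin(2 * np.pi / 7)
        np.testing.assert_allclose(geom.areas, expected, atol=1e-12)
        assert geom.total_area == pytest.approx(3.5 * np.sin(2 * np.pi / 7), abs=1e-12)

    def test_coincident_points_zero_area(self):
        geom = packing_areas(np.ones((7, 3)))
        assert geom.total_area == 0.0

    def test_area_scales_quadratically(self):
        s1 = packing_areas(heptagon(1.0)).total_area
        s3 = packing_areas(heptagon(3.0)).total_area
        assert s3 == pytest.approx(9 * s1, rel=1e-12)

    def test_center_is_centroid(self, rng):
        pts = rng.normal(size=(7, 3))
        geom = packing_areas(pts)
        np.testing.assert_allclose(geom.center, pts.mean(axis=0), atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_shoelace_oracle(self, seed):
        pts = np.random.default_rng(seed).normal(scale=10.0, size=(7, 3))
        geom = packing_areas(pts)
        assert geom.total_area == pytest.approx(shoelace_fan_area(pts), abs=1e-9)
        assert geom.total_area == pytest.approx(geom.areas.sum(), abs=1e-9)


class TestPackingEnergyTerm:
    PARAMS = PackingParams(s_min=100.0, s_max=150.0, weight=1.0)

    def test_zero_on_open_band(self):
        for s_val in (100.0, 112.0, 125.0, 150.0):
            assert packing_energy_term(s_val, self.PARAMS) == 0.0

    def test_substitution_values(self):
        assert packing_energy_term(50.0, self.PARAMS) == pytest.approx(0.25)
        assert packing_energy_term(300.0, self.PARAMS) == pytest.approx(1.0)

    def test_continuity_at_bounds(self):
        for bound in (100.0, 150.0):
            for eps in (1e-6, 1e-9):
                assert packing_energy_term(bound - eps, self.PARAMS) < 1e-9
                assert packing_energy_term(bound + eps, self.PARAMS) < 1e-9

    def test_strictly_monotone_outside_band(self):
        below = [packing_energy_term(v, self.PARAMS) for v in (90, 70, 50, 20)]
        above = [packing_energy_term(v, self.PARAMS) for v in (160, 200, 260, 400)]
        assert all(b1 < b2 for b1, b2 in zip(below, below[1:]))
        assert all(a1 < a2 for a1, a2 in zip(above, above[1:]))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            packing_energy_term(-1.0, self.PARAMS)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PackingParams(s_min=150.0, s_max=100.0)
        with pytest.raises(ValueError):
            PackingParams(s_min=0.0, s_max=100.0)


class TestInvarianceProperties:
    def test_packing_invariant_under_in_plane_motion(self, bundle, energy_model):
        """E' depends only on centroid-relative areas, so rotating the bundle
        about the membrane normal or sliding it in the plane changes nothing."""
        s, topo, frame = bundle
        base = energy_model.evaluate(s)
        rot = Rotation.from_rotvec(np.deg2rad(73.0) * Z).as_matrix()
        moved = s.copy()
        moved.coords = moved.coords @ rot.T + np.array([17.0, -4.0, 0.0])
        after = energy_model.evaluate(moved)
        assert after.packing == pytest.approx(base.packing, abs=1e-9)
        assert after.total_area == pytest.approx(base.total_area, abs=1e-9)

    def test_surrogate_invariant_under_helix_spin(self, bundle, energy_model):
        """Every surrogate term is deliberately spin-blind: a backbone-only
        score has no basis for ranking the azimuthal phase of a helix."""
        s, topo, frame = bundle
        base = energy_model.evaluate(s).total
        for h, angle in [(1, 45.0), (4, -120.0), (7, 170.0)]:
            seg = fit_helix_axis(s, topo.tm_ranges[h - 1], index=h)
            spun = spin_helix(s, seg, angle)
            assert energy_model.evaluate(spun).total == pytest.approx(base, abs=1e-9)


class TestSurrogateScore:
    def test_ca_clash_zero_beyond_contact(self):
        s, topo, frame = make_ideal_bundle(BundleSpec(helix_length=12))
        params = MembraneScoreParams(
            clash_model="ca", d_clash=4.0, depth_weight=0, cohesion_weight=0,
            anchor_weight=0,
        )
        # the ideal bundle's helices are spaced well beyond 4 Å, and with
        # clash_region="tm" loop turns do not contribute
        assert surrogate_membrane_score(s, topo, frame, params) == 0.0

    def test_coincident_cas_pay_full_overlap(self, bundle):
        s, topo, frame = bundle
        params = MembraneScoreParams(
            clash_model="ca", d_clash=4.0, clash_region="all",
            depth_weight=0, cohesion_weight=0, anchor_weight=0,
        )
        base = surrogate_membrane_score(s, topo, frame, params)
        squashed = s.copy()
        # move one loop CA exactly onto a far-away helix CA
        li, hj = topo.loop_ranges[0][0], topo.tm_ranges[4][0]
        squashed.coords[li - 1, 1] = squashed.coords[hj - 1, 1]
        after = surrogate_membrane_score(squashed, topo, frame, params)
        assert after - base >= 4.0**2 - 1e-6

    def test_ideal_bundle_inside_slab_has_zero_depth(self, bundle):
        s, topo, frame = bundle
        params = MembraneScoreParams(
            clash_weight=0, cohesion_weight=0, anchor_weight=0, depth_weight=1.0,
        )
        assert surrogate_membrane_score(s, topo, frame, params) == 0.0

    def test_deterministic(self, bundle):
        s, topo, frame = bundle
        a = surrogate_membrane_score(s, topo, frame)
        b = surrogate_membrane_score(s, topo, frame)
        assert a == b


class TestTotalEnergy:
    def test_zero_weight_reduces_to_surrogate(self, bundle):
        s, topo, frame = bundle
        params = PackingParams(s_min=1.0, s_max=2.0, weight=0.0)  # S far outside
        rep = total_energy(s, topo, frame, params)
        assert rep.total == pytest.approx(rep.surrogate_membrane, abs=1e-12)
        assert rep.packing == 0.0

    def test_report_identity(self, bundle, energy_model):
        s, _, _ = bundle
        rep = energy_model.evaluate(s)
        assert rep.total == pytest.approx(rep.surrogate_membrane + rep.packing, abs=1e-9)

    def test_weight_linearity(self, bundle):
        s, topo, frame = bundle
        area = total_energy(s, topo, frame, PackingParams(1.0, 2.0, weight=0.0)).total_area
        p1 = PackingParams(s_min=area * 2, s_max=area * 3, weight=1.0)
        p2 = PackingParams(s_min=area * 2, s_max=area * 3, weight=2.0)
        r1, r2 = total_energy(s, topo, frame, p1), total_energy(s, topo, frame, p2)
        assert r2.packing == pytest.approx(2 * r1.packing, rel=1e-9)
        assert r2.total - r2.surrogate_membrane == pytest.approx(
            2 * (r1.total - r1.surrogate_membrane), rel=1e-9
        )

    def test_relaxed_bundle_scores_zero(self, bundle):
        """A clash-free pose with S inside the band, helices in the slab and
        all wells satisfied has exactly zero total energy."""
        s, topo, frame = bundle
        params = PackingParams(s_min=300.0, s_max=500.0, weight=100.0)
        rep = total_energy(s, topo, frame, params)
        assert rep.packing == 0.0
        assert rep.total < 1.0  # small residual from construction tolerances


class TestCalibration:
    def test_min_max_over_references(self):
        refs = []
        areas = []
        for radius in (10.0, 14.0, 12.0):
            spec = BundleSpec(helix_length=12, ring_radius=radius)
            s, topo, frame = make_ideal_bundle(spec)
            refs.append((s, topo, frame))
            areas.append(total_energy(s, topo, frame, PackingParams(1, 2, 0)).total_area)
        params = calibrate_area_bounds(refs)
        assert params.s_min == pytest.approx(min(areas))
        assert params.s_max == pytest.approx(max(areas))

    def test_single_reference_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="at least 2"):
            calibrate_area_bounds([small_bundle])

    def test_degenerate_bounds_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="degenerate bounds"):
            calibrate_area_bounds([small_bundle, small_bundle])
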