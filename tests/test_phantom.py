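import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwchamber import phantom as ph


class TestTissuePermittivity:
    def test_muscle_baseline(self):
        v = ph.tissue_permittivity("muscle", 0.0)
        assert v.value == pytest.approx(54.8 - 17.43j)

    def test_muscle_dehydrated(self):
        v = ph.tissue_permittivity("muscle", -0.09)
        assert v.eps_real == pytest.approx(49.868)
        assert v.eps_imag == pytest.approx(15.8613)

    def test_bone_plus9(self):
        v = ph.tissue_permittivity("bone", 0.09)
        assert v.eps_real == pytest.approx(13.516)
        assert v.eps_imag == pytest.approx(3.0411)

    def test_deterministic(self):
        assert ph.tissue_permittivity("skin", 0.0) == ph.tissue_permittivity("skin", 0.0)

    def test_unknown_tissue(self):
        with pytest.raises(ValueError, match="unknown tissue"):
            ph.tissue_permittivity("cartilage", 0.0)

    def test_hderr_out_of_range(self):
        with pytest.raises(ValueError, match="hderr"):
            ph.tissue_permittivity("muscle", 0.25)

    def test_sf_baselines(self):
        nominal = ph.tissue_permittivity("synovial_fluid", 0.0)
        rounded = ph.tissue_permittivity("synovial_fluid", 0.0, sf_baseline="rounded")
        assert nominal.value == pytest.approx(68.42 - 29.12j)
        assert rounded.value == pytest.approx(68.0 - 29.0j)

    @given(st.sampled_from(sorted(ph.BASE_TISSUES)),
           st.floats(-0.2, 0.2, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_scaling_linear(self, tissue, h):
        base = ph.tissue_permittivity(tissue, 0.0)
        scaled = ph.tissue_permittivity(tissue, h)
        assert scaled.eps_real == pytest.approx(base.eps_real * (1 + h), rel=1e-12)
        assert scaled.eps_imag == pytest.approx(base.eps_imag * (1 + h), rel=1e-12)


# The dehydration sweep as printed: some cells are rounded, some truncated,
# so agreement is asserted to within one unit of the printed precision.
PRINTED_DEHYDRATION = {
    "bone": ((11.28, 2.5), (12.4, 2.79), (13.5, 3.04)),
    "skin": ((37.2, 14.7), (40.9, 16.17), (44.58, 17.6)),
    "tendon": ((41.5, 12.43), (45.6, 13.66), (49.7, 14.88)),
    "muscle": ((49.8, 15.86), (54.8, 17.43), (59.73, 19.0)),
    "synovial_fluid": ((61.8, 26.3), (68.0, 29.0), (74.1, 31.6)),
}


@pytest.mark.parametrize("tissue", sorted(PRINTED_DEHYDRATION))
@pytest.mark.parametrize("col,hderr", [(0, -0.09), (1, 0.0), (2, 0.09)])
def test_dehydration_table_reconstruction(tissue, col, hderr):
    re_p, im_p = PRINTED_DEHYDRATION[tissue][col]
    v = ph.tissue_permittivity(tissue, hderr, sf_baseline="rounded")
    for got, want in ((v.eps_real, re_p), (v.eps_imag, im_p)):
        s = repr(want)
        ulp = 10.0 ** -(len(s.split(".")[1]) if "." in s else 0)
        assert abs(got - want) <= ulp + 1e-12


class TestRigidTransform:
    def test_identity_roundtrip(self):
        t = ph.RigidTransform(dx=1.2, dz=-0.7, theta=33.0, pivot=(0.5, -0.2))
        pts = np.random.default_rng(0).uniform(-5, 5, size=(50, 2))
        back = t.inverse_apply(t.apply(pts))
        assert np.max(np.abs(back - pts)) < 1e-12

    def test_inverse_composition(self):
        t = ph.RigidTransform(dx=2.0, dz=1.0, theta=-17.0, pivot=(1.0, 0.0))
        inv = t.inverse()
        pts = np.random.default_rng(1).uniform(-5, 5, size=(20, 2))
        assert np.max(np.abs(inv.apply(t.apply(pts)) - pts)) < 1e-12

    def test_distances_preserved(self):
        t = ph.RigidTransform(dx=0.3, dz=-1.1, theta=47.0)
        p = ph.build_phantom(injured=True, transform=t)
        centers0 = np.array([r.center for r in p.regions])
        moved = t.apply(centers0)
        d0 = np.linalg.norm(centers0[:, None] - centers0[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-10


class TestBuildPhantom:
    def test_healthy_injury_is_muscle(self):
        g = ph.DEFAULT_GEOMETRY
        for h in (0.0, -0.09, 0.09):
            p = ph.build_phantom(injured=False, hderr_muscle=h, hderr_sf=0.05)
            v = ph.permittivity_at(p, g.injury_center)
            want = ph.tissue_permittivity("muscle", h)
            assert v.value == pytest.approx(want.value)

    def test_injured_injury_is_sf(self):
        g = ph.DEFAULT_GEOMETRY
        p = ph.build_phantom(injured=True, hderr_sf=0.0)
        v = ph.permittivity_at(p, g.injury_center)
        assert v.value == pytest.approx(68.42 - 29.12j)

    def test_identity_transform_centers(self):
        p = ph.build_phantom(injured=True)
        g = ph.DEFAULT_GEOMETRY
        by_name = {r.name: r for r in p.regions}
        assert by_name["bone"].center == g.bone_center
        assert by_name["synovial_fluid"].center == g.injury_center

    def test_transform_out_of_chamber_rejected(self):
        with pytest.raises(ValueError, match="outside the chamber"):
            ph.build_phantom(injured=False, transform=ph.RigidTransform(dx=6.0))

    def test_zero_contrast_maps_identical(self):
        muscle = ph.tissue_permittivity("muscle", 0.03)
        healthy = ph.build_phantom(injured=False, hderr_muscle=0.03)
        injured = ph.build_phantom(
            injured=True, hderr_muscle=0.03, injury_override=muscle
        )
        pts = np.random.default_rng(2).uniform(-11, 11, size=(500, 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < 11.9]
        vh = ph.permittivity_values_at(healthy, pts)
        vi = ph.permittivity_values_at(injured, pts)
        assert np.array_equal(vh, vi)


class TestPermittivityAt:
    def test_matching_medium_far_outside(self):
        p = ph.build_phantom(injured=False)
        v = ph.permittivity_at(p, (-11.0, 0.0))
        assert v.value == pytest.approx(54.8 - 17.43j)

    def test_bone_center(self):
        p = ph.build_phantom(injured=False)
        v = ph.permittivity_at(p, ph.DEFAULT_GEOMETRY.bone_center)
        assert v.value == pytest.approx(12.4 - 2.79j)

    def test_point_outside_chamber(self):
        p = ph.build_phantom(injured=False)
        with pytest.raises(ValueError, match="outside"):
            ph.permittivity_at(p, (20.0, 0.0))

    def test_full_rotation_invariance(self):
        p0 = ph.build_phantom(injured=True)
        p360 = ph.build_phantom(injured=True, transform=ph.RigidTransform(theta=360.0))
        pts = np.random.default_rng(3).uniform(-8, 8, size=(300, 2))
        v0 = ph.permittivity_values_at(p0, pts)
        v1 = ph.permittivity_values_at(p360, pts)
        assert np.allclose(v0, v1)

    def test_precedence_stack(self):
        # tendon annulus point (between bone and injury)
        p = ph.build_phantom(injured=True)
        g = ph.DEFAULT_GEOMETRY
        v = ph.permittivity_at(p, (g.bone_center[0], g.bone_center[1] + 2.1))
        assert v.value == pytest.approx(45.6 - 13.66j)


def test_rasterize_shapes():
    p = ph.build_phantom(injured=True)
    x, z, eps = ph.rasterize(p, n=64)
    assert eps.shape == (64, 64)
    assert np.isnan(eps.real[0, 0])          # corner outside chamber
    assert np.isfinite(eps[32, 32].real)     # center inside
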