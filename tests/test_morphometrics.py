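"""Shape-metric closed forms, invariances, and rosette/lumen geometry."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse, polygon
from skimage.transform import rotate

from oracles import ramanujan_ellipse_perimeter, shoelace_area
from organoidqpi.morphometrics import (
    compute_rosette_metrics,
    compute_shape_metrics,
    count_rosettes,
)


def _disk_mask(radius, pad=10, center=None):
    n = 2 * (radius + pad)
    m = np.zeros((n, n), bool)
    c = (n // 2, n // 2) if center is None else center
    rr, cc = disk(c, radius, shape=m.shape)
    m[rr, cc] = True
    return m


class TestClosedForms:
    def test_ideal_disk(self):
        sm = compute_shape_metrics(_disk_mask(50), pixel_size=1.0)
        assert sm.circularity >= 0.99
        assert sm.solidity >= 0.98
        assert sm.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert sm.equivalent_diameter == pytest.approx(100, rel=0.02)

    def test_rectangle_100_by_50(self):
        m = np.zeros((120, 170), bool)
        m[10:60, 20:120] = True
        sm = compute_shape_metrics(m, pixel_size=1.0)
        assert sm.aspect_ratio == pytest.approx(2.0, abs=0.05)
        assert sm.circularity == pytest.approx(4 * np.pi * 5000 / 300**2, abs=0.03)
        assert sm.area == pytest.approx(5000)

    def test_star_solidity_matches_shoelace_oracle(self):
        # 5-pointed star: polygon area / convex hull area via shoelace
        t_outer = np.pi / 2 + 2 * np.pi * np.arange(5) / 5
        t_inner = t_outer + np.pi / 5
        r_out, r_in = 80.0, 32.0
        verts = []
        for to, ti in zip(t_outer, t_inner):
            verts.append((100 - r_out * np.sin(to), 100 + r_out * np.cos(to)))
            verts.append((100 - r_in * np.sin(ti), 100 + r_in * np.cos(ti)))
        verts = np.array(verts)
        m = np.zeros((200, 200), bool)
        rr, cc = polygon(verts[:, 0], verts[:, 1], shape=m.shape)
        m[rr, cc] = True
        star_area = shoelace_area(verts)
        hull_area = shoelace_area(verts[::2])  # outer points form the hull
        sm = compute_shape_metrics(m, pixel_size=1.0)
        assert sm.solidity == pytest.approx(star_area / hull_area, abs=0.02)

    def test_micron_scaling_of_area_and_diameter(self):
        sm1 = compute_shape_metrics(_disk_mask(40), pixel_size=1.0)
        sm2 = compute_shape_metrics(_disk_mask(40), pixel_size=2.0)
        assert sm2.area == pytest.approx(4 * sm1.area)
        assert sm2.equivalent_diameter == pytest.approx(2 * sm1.equivalent_diameter)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_shape_metrics(np.zeros((10, 10), bool))

    def test_multi_component_keeps_largest_with_warning(self):
        m = _disk_mask(30)
        m[2:5, 2:5] = True
        with pytest.warns(UserWarning, match="components"):
            sm = compute_shape_metrics(m)
        assert sm.area == pytest.approx(np.pi * 30**2, rel=0.05)


class TestInvariances:
    @pytest.fixture(scope="class")
    def blob(self):
        m = np.zeros((160, 160), bool)
        rr, cc = ellipse(80, 80, 30, 55, rotation=0.3)
        m[rr, cc] = True
        return m

    def test_scale_invariance_of_dimensionless_metrics(self, blob):
        up = np.kron(blob, np.ones((2, 2), dtype=bool))
        a = compute_shape_metrics(blob)
        b = compute_shape_metrics(up)
        for attr in ("circularity", "solidity", "aspect_ratio"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=0.02)

    def test_rotation_invariance_within_two_percent(self, blob):
        a = compute_shape_metrics(blob)
        rot = rotate(blob.astype(float), 30, resize=True, order=1) > 0.5
        b = compute_shape_metrics(rot)
        for attr in ("circularity", "solidity", "aspect_ratio"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=0.02)

    def test_area_additive_over_disjoint_masks(self):
        m1 = np.zeros((60, 140), bool)
        rr, cc = disk((30, 30), 20)
        m1[rr, cc] = True
        m2 = np.zeros_like(m1)
        rr, cc = disk((30, 100), 20)
        m2[rr, cc] = True
        assert not (m1 & m2).any()
        assert (m1 | m2).sum() == m1.sum() + m2.sum()


class TestRosettes:
    def test_concentric_disks_have_zero_centeredness(self):
        ros = _disk_mask(40)
        lum = _disk_mask(15, pad=35)
        rec = compute_rosette_metrics(ros, lum)
        assert rec.centeredness_um == pytest.approx(0.0, abs=0.05)

    def test_three_four_five_offset(self):
        ros = _disk_mask(40)
        n = ros.shape[0]
        lum = _disk_mask(10, pad=40, center=(n // 2 + 3, n // 2 + 4))
        rec = compute_rosette_metrics(ros, lum, pixel_size=1.0)
        assert rec.centeredness_um == pytest.approx(5.0, abs=1e-6)
        assert rec.centeredness_normalized == pytest.approx(5.0 / 40.0, rel=0.02)

    def test_elongated_rosette_less_circular_than_disk_lumen(self):
        m = np.zeros((200, 200), bool)
        rr, cc = ellipse(100, 100, 30, 60)
        m[rr, cc] = True
        lum = _disk_mask(12, pad=88)
        rec = compute_rosette_metrics(m, lum)
        assert rec.rosette_circularity < rec.lumen_circularity
        # cross-check the ellipse perimeter against Ramanujan's closed form
        from organoidqpi.morphometrics import boundary_perimeter

        assert boundary_perimeter(m) == pytest.approx(
            ramanujan_ellipse_perimeter(60, 30), rel=0.01
        )

    def test_lumen_outside_rosette_rejected(self):
        ros = _disk_mask(30)
        lum = np.zeros_like(ros)
        lum[2:6, 2:6] = True
        with pytest.raises(ValueError, match="outside"):
            compute_rosette_metrics(ros, lum)


class TestCounting:
    def test_empty_field_counts_zero(self):
        assert count_rosettes(np.zeros((50, 50), bool)) == 0

    def test_phantom_built_with_ten_rosettes_counts_ten(self):
        from organoidqpi.phantoms import PhantomSpec, generate_organoid_phantom

        spec = PhantomSpec(image_size=512, rosette_count=10, seed=5)
        phantom = generate_organoid_phantom(spec)
        rosette_region = phantom.label_mask("rosette") | phantom.label_mask("lumen")
        assert count_rosettes(rosette_region) == 10

    def test_touching_components_merge_under_default_connectivity(self):
        m = np.zeros((60, 120), bool)
        rr, cc = disk((30, 40), 15)
        m[rr, cc] = True
        rr, cc = disk((30, 69), 15)  # touches the first disk
        m[rr, cc] = True
        assert count_rosettes(m) == 1
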