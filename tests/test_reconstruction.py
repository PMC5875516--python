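"""Field detection, edge corrections, TMR ratios, and dose reconstruction."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import erf

from epidose.commissioning import EdgeCurve, EpidImage, build_commissioning_table
from epidose.geometry import BeamGeometry, RadiologicalDepthMaps
from epidose.reconstruction import (
    EdgeDistanceMaps,
    TmrTable,
    detect_field,
    edge_correction_map,
    edge_distances,
    equivalent_square,
    reconstruct_dose,
    reconstruct_dose_homogeneous,
    tmr_ratio,
)
from epidose.synthetic import (
    make_tmr_table,
    simulate_epid_image,
    simulate_tps_dose,
    slab_radiological_depths,
)


def step_image(geom, half_x=5.0, half_y=None, plateau=100.0):
    half_y = half_x if half_y is None else half_y
    yy, xx = geom.pixel_grid()
    px = np.where((np.abs(xx) <= half_x) & (np.abs(yy) <= half_y), plateau, 0.0)
    return EpidImage(pixels=px, geom=geom)


def flat_table():
    """Table with constant F_CAX = 2 and unit edge curves."""
    fcax = [(w, l, 2.0) for w in (6.0, 12.0, 16.0, 20.0, 26.0)
            for l in (5.0, 10.0, 15.0, 20.0)]
    f = [(d, l, 1.0) for d in (-10.0, -5.0, 0.0, 5.0, 10.0)
         for l in (5.0, 10.0, 15.0, 20.0)]
    x = np.linspace(0, 2.76, 53)
    curves = {l: EdgeCurve(x=x, k=np.ones(53)) for l in (5.0, 10.0, 15.0)}
    return build_commissioning_table(fcax, f, curves)


class TestDetectField:
    def test_ideal_step_field(self, geom):
        img = step_image(geom)
        mask = detect_field(img)
        yy, xx = geom.pixel_grid()
        expected = (np.abs(xx) <= 5.0) & (np.abs(yy) <= 5.0)
        assert np.array_equal(mask.inside, expected)
        r = geom.n_rows // 2
        # crossings midway between the last in-field and first out-of-field pixel
        assert mask.row_right[r] == pytest.approx(5.0, abs=geom.pitch_x)
        assert mask.row_left[r] == pytest.approx(-5.0, abs=geom.pitch_x)
        assert mask.threshold == pytest.approx(50.0)

    def test_sigmoid_penumbra_width_within_one_pixel(self, geom, model_nf):
        dm = slab_radiological_depths(12.0, 0.0, geom)
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        mask = detect_field(img)
        r = geom.n_rows // 2
        width = mask.row_right[r] - mask.row_left[r]
        assert width == pytest.approx(10.0, abs=geom.pitch_x)
        c = geom.n_cols // 2
        assert mask.col_bottom[c] - mask.col_top[c] == pytest.approx(10.0, abs=geom.pitch_y)

    def test_uniform_image_has_no_field(self, geom):
        img = EpidImage(pixels=np.ones((geom.n_rows, geom.n_cols)), geom=geom)
        with pytest.raises(ValueError, match="no field"):
            detect_field(img)

    def test_largest_component_wins(self, geom):
        img = step_image(geom)
        img.pixels[5:8, 5:8] = 200.0  # small spurious blob in a corner
        mask = detect_field(img)
        assert not mask.inside[6, 6]


class TestEdgeDistances:
    def test_center_of_square_field(self, geom):
        mask = detect_field(step_image(geom))
        dist = edge_distances(mask, geom)
        r, c = geom.n_rows // 2, geom.n_cols // 2
        assert dist.x[r, c] == pytest.approx(5.0, abs=geom.pitch_x)
        assert dist.y[r, c] == pytest.approx(5.0, abs=geom.pitch_y)

    def test_pixel_one_cm_from_right_edge(self, geom):
        mask = detect_field(step_image(geom))
        r = geom.n_rows // 2
        x_edge = mask.row_right[r]
        xx = (np.arange(geom.n_cols) - (geom.n_cols - 1) / 2) * geom.pitch_x
        c = int(np.argmin(np.abs(xx - (x_edge - 1.0))))
        dist = edge_distances(mask, geom)
        assert dist.x[r, c] == pytest.approx(x_edge - xx[c], rel=1e-12)

    def test_random_blob_matches_exhaustive_search(self, geom, rng):
        # union of random rectangles on a plateau; brute-force per-row/column scan
        px = np.zeros((geom.n_rows, geom.n_cols))
        yy, xx = geom.pixel_grid()
        for _ in range(3):
            cx, cy = rng.uniform(-3, 3, 2)
            hx, hy = rng.uniform(2.0, 5.0, 2)
            px[(np.abs(xx - cx) <= hx) & (np.abs(yy - cy) <= hy)] = 100.0
        img = EpidImage(pixels=px, geom=geom)
        mask = detect_field(img)
        dist = edge_distances(mask, geom)
        xv = xx[0]
        yv = yy[:, 0]
        rows = np.flatnonzero(mask.inside.any(axis=1))
        for r in rows[:: max(1, rows.size // 10)]:
            cols = np.flatnonzero(mask.inside[r])
            seg = px[r]
            idx_lo, idx_hi = cols[0], cols[-1]
            left = xv[idx_lo] - 0.5 * geom.pitch_x if idx_lo > 0 else xv[0]
            right = xv[idx_hi] + 0.5 * geom.pitch_x if idx_hi < geom.n_cols - 1 else xv[-1]
            for c in cols:
                expected = min(xv[c] - left, right - xv[c])
                assert dist.x[r, c] == pytest.approx(expected, abs=1e-9)


class TestEdgeCorrectionMap:
    def test_far_from_edges_is_unity(self, table_nf, geom):
        dist = EdgeDistanceMaps(x=np.full((4, 4), 3.0), y=np.full((4, 4), 2.8))
        assert np.allclose(edge_correction_map(dist, table_nf, 10.0), 1.0)

    def test_corner_is_product_of_manual_lookups(self, table_nf):
        curve = table_nf.k_curves[10.0]
        x, y = 0.31, 0.87
        dist = EdgeDistanceMaps(x=np.array([[x]]), y=np.array([[y]]))
        manual = np.interp(x, curve.x, curve.k) * np.interp(y, curve.x, curve.k)
        assert edge_correction_map(dist, table_nf, 10.0)[0, 0] == pytest.approx(manual, rel=1e-12)

    def test_unit_curves_give_unit_map(self):
        table = flat_table()
        dist = EdgeDistanceMaps(x=np.full((3, 3), 0.5), y=np.full((3, 3), 0.1))
        assert np.allclose(edge_correction_map(dist, table, 10.0), 1.0)

    def test_negative_distance_rejected(self, table_nf):
        dist = EdgeDistanceMaps(x=np.array([[-0.1]]), y=np.array([[1.0]]))
        with pytest.raises(ValueError):
            edge_correction_map(dist, table_nf, 10.0)

    def test_small_field_warns(self, table_nf):
        dist = EdgeDistanceMaps(x=np.ones((2, 2)), y=np.ones((2, 2)))
        with pytest.warns(UserWarning, match="5.5"):
            edge_correction_map(dist, table_nf, 4.0)


class TestEquivalentSquare:
    def test_square_field(self, geom):
        mask = detect_field(step_image(geom))
        # digitization makes the inclusive mask ~1 pixel wider than 10 cm
        assert equivalent_square(mask, geom) == pytest.approx(10.0, rel=0.015)

    def test_rectangle_sterling(self, geom):
        mask = detect_field(step_image(geom, half_x=10.0, half_y=5.0))
        assert equivalent_square(mask, geom) == pytest.approx(4 * 200 / 60, rel=0.02)

    def test_disk(self, geom):
        yy, xx = geom.pixel_grid()
        r = 4.0
        px = np.where(xx ** 2 + yy ** 2 <= r ** 2, 100.0, 0.0)
        mask = detect_field(EpidImage(pixels=px, geom=geom))
        assert equivalent_square(mask, geom) == pytest.approx(2 * r, rel=0.02)


class TestTmrRatio:
    def test_zero_displacement_is_exactly_one(self, tmr_table):
        assert tmr_ratio(16.0, 0.0, 10.0, tmr_table) == 1.0

    def test_exponential_tmr_closed_form(self):
        mu = 0.06
        depths = np.linspace(0.0, 30.0, 121)
        # log-spaced exactly exponential between nodes would need fine steps;
        # evaluate at node depths so bilinear lookup is exact
        table = TmrTable(depths=depths, field_sizes=np.array([5.0, 10.0, 15.0, 20.0]),
                         values=np.exp(-mu * depths)[:, None] * np.ones((1, 4)))
        w, d = 20.0, 2.5  # w/2 and w/2 - d fall on table nodes
        assert tmr_ratio(w, d, 10.0, table) == pytest.approx(np.exp(mu * d), rel=1e-12)

    def test_decreasing_tmr_and_positive_d_gives_ratio_above_one(self, tmr_table):
        assert tmr_ratio(20.0, 3.0, 10.0, tmr_table) > 1.0

    def test_depth_outside_table_rejected(self, tmr_table):
        with pytest.raises(ValueError, match="range"):
            tmr_ratio(80.0, 0.0, 10.0, tmr_table)


class TestHomogeneousReconstruction:
    def test_unit_k_and_uniform_signal(self, geom):
        table = flat_table()
        img = step_image(geom, plateau=80.0)
        dose, mask = reconstruct_dose_homogeneous(img, table, 16.0, 10.0)
        assert np.allclose(dose.dose[mask.inside], 80.0 / 2.0)
        assert np.all(dose.dose[~mask.inside] == 0.0)

    def test_out_of_range_thickness_rejected(self, geom, table_nf):
        img = step_image(geom)
        with pytest.raises(ValueError, match="range"):
            reconstruct_dose_homogeneous(img, table_nf, 30.0, 10.0)

    def test_round_trip_matches_generator_dose(self, geom, model_nf, table_nf):
        """Commission -> reconstruct on the same fixture family reproduces the
        generator's planar dose away from edges (corners, where two edges
        interact diagonally, are the method's acknowledged blind spot)."""
        dm = slab_radiological_depths(16.0, 0.0, geom)
        img = simulate_epid_image(None, geom, 15.0, model_nf, depths=dm)
        tps = simulate_tps_dose(None, geom, 15.0, model_nf, depths=dm)
        rec, mask = reconstruct_dose_homogeneous(img, table_nf, 16.0, 15.0)
        edt = ndimage.distance_transform_edt(mask.inside)
        dist = edge_distances(mask, geom)
        corner = (dist.x < 1.5) & (dist.y < 1.5)
        sel = mask.inside & (edt > 2) & ~corner
        rel = np.abs(rec.dose[sel] / tps.dose[sel] - 1)
        assert np.max(rel) < 0.01

    def test_linearity_in_signal(self, geom, model_nf, table_nf):
        dm = slab_radiological_depths(12.0, 0.0, geom)
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        scaled = EpidImage(pixels=3.0 * img.pixels, geom=geom)
        d1, _ = reconstruct_dose_homogeneous(img, table_nf, 12.0, 10.0)
        d3, _ = reconstruct_dose_homogeneous(scaled, table_nf, 12.0, 10.0)
        assert np.allclose(d3.dose, 3.0 * d1.dose, rtol=1e-12, atol=0.0)

    def test_edge_correction_lowers_dose_where_k_above_one(self, geom, model_nf, table_nf):
        dm = slab_radiological_depths(12.0, 0.0, geom)
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        corrected, mask = reconstruct_dose_homogeneous(img, table_nf, 12.0, 10.0)
        dist = edge_distances(mask, geom)
        kmap = edge_correction_map(dist, table_nf, 10.0)
        uncorrected = np.where(mask.inside, img.pixels / table_nf.fcax(12.0, 10.0), 0.0)
        above = mask.inside & (kmap > 1.0)
        assert np.all(corrected.dose[above] < uncorrected[above])


class TestGeneralReconstruction:
    def test_reduces_to_homogeneous_for_centered_slab(self, geom, model_nf, table_nf, tmr_table):
        dm = slab_radiological_depths(16.0, 0.0, geom)
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        uniform = RadiologicalDepthMaps(
            t_up=np.full(img.pixels.shape, 8.0), t_down=np.full(img.pixels.shape, 8.0),
            geom=geom)
        d6, mask = reconstruct_dose_homogeneous(img, table_nf, 16.0, 10.0)
        d8, _ = reconstruct_dose(img, uniform, table_nf, tmr_table, 10.0)
        inside = mask.inside
        assert np.max(np.abs(d8.dose[inside] / d6.dose[inside] - 1)) < 1e-6

    def test_displaced_slab_round_trip(self, geom, model_nf, table_nf, tmr_table):
        dm = slab_radiological_depths(16.0, 5.0, geom)
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        tps = simulate_tps_dose(None, geom, 10.0, model_nf, depths=dm)
        rec, mask = reconstruct_dose(img, dm, table_nf, tmr_table, 10.0)
        edt = ndimage.distance_transform_edt(mask.inside)
        dist = edge_distances(mask, geom)
        sel = mask.inside & (edt > 2) & ~((dist.x < 1.5) & (dist.y < 1.5))
        assert np.max(np.abs(rec.dose[sel] / tps.dose[sel] - 1)) < 0.02

    def test_step_phantom_shows_plateaus_at_projected_boundary(
            self, geom, model_nf, table_nf, tmr_table):
        from epidose.geometry import trace_radiological_depths
        from epidose.synthetic import PhantomSpec, make_phantom_ct
        ct = make_phantom_ct(PhantomSpec(kind="step", thickness=12.0, thickness2=20.0),
                             spacing=(4.0, 4.0, 2.0))
        dm = trace_radiological_depths(ct, geom)
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        tps = simulate_tps_dose(None, geom, 10.0, model_nf, depths=dm)
        rec, mask = reconstruct_dose(img, dm, table_nf, tmr_table, 10.0)
        yy, xx = geom.pixel_grid()
        dist = edge_distances(mask, geom)
        # the asymmetric transmission shifts the global-threshold edge
        # crossings, so compare plateaus clear of the edge-correction span
        # and of the projected step boundary
        sel = mask.inside & (dist.x > 2.0) & (dist.y > 2.0) & (np.abs(xx) > 0.8)
        rel = np.abs(rec.dose[sel] / tps.dose[sel] - 1)
        assert np.max(rel) < 0.02
        # the reconstructed dose exhibits the step: thicker side is colder
        r = geom.n_rows // 2
        thin = rec.dose[r, (xx[r] > -4.0) & (xx[r] < -1.0)].mean()
        thick = rec.dose[r, (xx[r] > 1.0) & (xx[r] < 4.0)].mean()
        assert thick < thin
        assert thick / thin == pytest.approx(model_nf.tmr(10.0) / model_nf.tmr(6.0), rel=0.03)

    def test_out_of_range_thickness_reported(self, geom, table_nf, tmr_table, model_nf):
        dm = slab_radiological_depths(4.0, 0.0, geom)  # below the 6 cm node
        img = simulate_epid_image(None, geom, 10.0, model_nf, depths=dm)
        with pytest.raises(ValueError, match="commissioned range"):
            reconstruct_dose(img, dm, table_nf, tmr_table, 10.0)
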