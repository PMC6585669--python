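"""Geometry generators, transforms and measurements."""

from __future__ import annotations

import math

import numpy as np
import pytest

from myelinsim import GridSpec, circular_mask
from myelinsim.geometry import (
    EXTRA,
    INTRA,
    MYELIN,
    AxonRecord,
    AxonSet,
    EllipseSpec,
    LabelMap,
    PackingConfig,
    _circle_record,
    erode_myelin,
    make_single_ellipse_axon,
    measure,
    orientation_map,
    pack_circles,
    rasterize,
    synthesize_irregular_axons,
    warp_geometry,
)


def measured_g(lmap: LabelMap) -> float:
    n_i = int((lmap.labels == INTRA).sum())
    n_m = int((lmap.labels == MYELIN).sum())
    return math.sqrt(n_i / (n_i + n_m))


# ------------------------------------------------------------------ ellipses


class TestSingleEllipseAxon:
    def test_concentric_circles_hit_requested_g(self):
        lmap = make_single_ellipse_axon(EllipseSpec(0.0), 0.7, GridSpec(500, 3.0))
        assert 0.69 <= measured_g(lmap) <= 0.71

    def test_circle_is_rotation_invariant(self):
        grid = GridSpec(300, 3.0)
        a = make_single_ellipse_axon(EllipseSpec(0.0, rotation=0.0), 0.7, grid)
        b = make_single_ellipse_axon(EllipseSpec(0.0, rotation=1.1), 0.7, grid)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("e", [0.66, 0.80, 0.87])
    def test_areas_conserved_across_eccentricity(self, e):
        grid = GridSpec(500, 3.0)
        ref = make_single_ellipse_axon(EllipseSpec(0.0), 0.7, grid)
        lm = make_single_ellipse_axon(EllipseSpec(e), 0.7, grid)
        for label in (INTRA, MYELIN):
            n0 = (ref.labels == label).sum()
            n1 = (lm.labels == label).sum()
            assert abs(n1 - n0) / n0 < 0.01
        a_t0 = (ref.labels != EXTRA).sum()
        a_t1 = (lm.labels != EXTRA).sum()
        assert abs(a_t1 - a_t0) / a_t0 < 0.01

    def test_oversized_ellipse_reports_required_extent(self):
        with pytest.raises(ValueError, match="extent"):
            make_single_ellipse_axon(EllipseSpec(0.87), 0.7, GridSpec(100, 3.0),
                                     r_outer=1.2)


# ------------------------------------------------------------------- packing


class TestPackCircles:
    def test_deterministic_for_fixed_seed(self, small_packing):
        again = pack_circles(PackingConfig(n_axons=120, seed=3), n_pixels=600)
        for a, b in zip(small_packing.axons, again.axons):
            assert np.array_equal(a.outer_boundary, b.outer_boundary)

    def test_no_pair_overlaps(self, small_packing):
        centers = np.array([a.center for a in small_packing.axons])
        r = np.array([a.circle_radii[1] for a in small_packing.axons])
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        need = r[:, None] + r[None, :]
        np.fill_diagonal(d, np.inf)
        assert (d >= need - 1e-9).all()

    def test_radii_match_gamma_moments(self):
        cfg = PackingConfig(n_axons=1434, seed=9)
        axons = pack_circles(cfg, n_pixels=400)
        r = np.array([a.circle_radii[1] for a in axons.axons])
        se = cfg.mean_radius / math.sqrt(cfg.gamma_shape * cfg.n_axons)
        assert abs(r.mean() - cfg.mean_radius) < 3 * se

    def test_single_axon_packs_trivially(self):
        axons = pack_circles(PackingConfig(n_axons=1, seed=0), n_pixels=128)
        assert len(axons) == 1

    def test_extra_axonal_fraction_near_36_percent(self, small_packed_map):
        frac = measure(small_packed_map)["volume_fractions"]["extra"]
        assert 0.33 <= frac <= 0.39

    def test_infeasible_density_raises(self):
        from myelinsim.geometry import PackingError

        grid = GridSpec(200, 10.0)  # far too small for 1434 fibers
        with pytest.raises(PackingError):
            pack_circles(PackingConfig(n_axons=1434, seed=0), grid=grid)


# ---------------------------------------------------------------- rasterize


class TestRasterize:
    def test_annulus_pixel_count_matches_analytic(self):
        grid = GridSpec(64, 64.0)  # 1 um pixels
        rec = _circle_record((32.0, 32.0), 7.0, 10.0)
        lmap = rasterize(AxonSet([rec], grid))
        expected = math.pi * (10.0**2 - 7.0**2)
        assert abs((lmap.labels == MYELIN).sum() - expected) / expected < 0.05

    def test_empty_set_is_all_extra(self):
        grid = GridSpec(32, 3.0)
        lmap = rasterize(AxonSet([], grid))
        assert (lmap.labels == EXTRA).all()

    def test_tangent_circles_share_no_pixel(self):
        grid = GridSpec(200, 20.0)
        a = _circle_record((7.0, 10.0), 2.1, 3.0)
        b = _circle_record((13.0, 10.0), 2.1, 3.0)
        lmap = rasterize(AxonSet([a, b], grid))
        n_fiber = (lmap.labels != EXTRA).sum()
        only_a = rasterize(AxonSet([a], grid))
        only_b = rasterize(AxonSet([b], grid))
        assert n_fiber == (only_a.labels != EXTRA).sum() + (only_b.labels != EXTRA).sum()

    def test_refinement_converges_to_analytic_area(self):
        # relative area error < 5% at r ~ 10 px and < 1% at r ~ 30 px
        for n, tol in ((64, 0.05), (192, 0.01)):
            grid = GridSpec(n, 6.4)
            rec = _circle_record((3.2, 3.2), 0.7, 1.0)
            lmap = rasterize(AxonSet([rec], grid))
            area = (lmap.labels != EXTRA).sum() * grid.pixel_size**2
            assert abs(area - math.pi) / math.pi < tol


# --------------------------------------------------------------------- warp


class TestWarp:
    def test_zero_amplitude_is_identity(self, small_packing):
        assert warp_geometry(small_packing, {"amplitude": 0.0}) is small_packing

    def test_conserves_g_density_and_area(self, small_packing):
        warped = warp_geometry(small_packing)
        rel_g = np.abs(warped.g_ratios - small_packing.g_ratios) / small_packing.g_ratios
        assert rel_g.max() < 0.02
        assert abs(warped.fiber_density - small_packing.fiber_density) \
            / small_packing.fiber_density < 0.02
        for w, c in zip(warped.axons, small_packing.axons):
            assert abs(w.A_t - c.A_t) / c.A_t < 0.02

    def test_outlines_become_noncircular(self):
        axons = pack_circles(PackingConfig(n_axons=602, seed=5), n_pixels=1000)
        warped = warp_geometry(axons)
        circ = np.array([a.circularity() for a in warped.axons])
        assert (circ < 0.95).mean() >= 0.80


# ---------------------------------------------------------- irregular axons


class TestIrregularAxons:
    def test_zero_roughness_returns_packing(self, small_packing):
        irr = synthesize_irregular_axons(
            PackingConfig(n_axons=120, seed=3), {"amplitude_sd": 0.0},
            n_pixels=600,
        )
        for a, b in zip(irr.axons, small_packing.axons):
            assert np.array_equal(a.outer_boundary, b.outer_boundary)

    def test_population_statistics(self):
        irr = synthesize_irregular_axons(
            PackingConfig(n_axons=602, seed=5), {"amplitude_sd": 0.15},
            n_pixels=1000,
        )
        circ = np.array([a.circularity() for a in irr.axons])
        assert circ.mean() < 0.95
        g = irr.g_ratios
        assert 0.68 <= g.mean() <= 0.72
        assert 0.62 <= irr.fiber_density <= 0.66

    def test_deterministic(self):
        kwargs = dict(roughness={"amplitude_sd": 0.15}, n_pixels=600)
        a = synthesize_irregular_axons(PackingConfig(n_axons=60, seed=8), **kwargs)
        b = synthesize_irregular_axons(PackingConfig(n_axons=60, seed=8), **kwargs)
        for ra, rb in zip(a.axons, b.axons):
            assert np.array_equal(ra.outer_boundary, rb.outer_boundary)
            assert np.array_equal(ra.inner_boundary, rb.inner_boundary)


# ----------------------------------------------------------------- erosion


class TestErodeMyelin:
    def test_same_target_is_unchanged(self, small_packing):
        out = erode_myelin(small_packing, 0.70)
        assert np.allclose(out.g_ratios, small_packing.g_ratios, atol=5e-3)
        for a, b in zip(out.axons, small_packing.axons):
            assert np.array_equal(a.outer_boundary, b.outer_boundary)

    def test_raster_annulus_area_algebra(self):
        # r_o = 20 px, g 0.70 -> 0.98: myelin area ratio (1-.98^2)/(1-.7^2)
        grid = GridSpec(128, 128.0)
        rec = _circle_record((64.0, 64.0), 14.0, 20.0)
        lmap = rasterize(AxonSet([rec], grid))
        m0 = (lmap.labels == MYELIN).sum()
        eroded = erode_myelin(lmap, 0.98)
        m1 = (eroded.labels == MYELIN).sum()
        expected = (1 - 0.98**2) / (1 - 0.70**2)
        ring = 2 * math.pi * 20  # one pixel-layer of the sheath
        assert abs(m1 - expected * m0) <= ring

    def test_outer_boundary_untouched_on_raster(self, small_packed_map):
        eroded = erode_myelin(small_packed_map, 0.9)
        assert np.array_equal(eroded.labels != EXTRA,
                              small_packed_map.labels != EXTRA)

    def test_nine_stage_sequence_strictly_increasing(self, small_packing):
        gs = np.linspace(0.70, 0.98, 9)
        measured = []
        for g in gs:
            lm = rasterize(erode_myelin(small_packing, g))
            measured.append(measured_g(lm))
        assert np.all(np.diff(measured) > 0)
        assert np.allclose(measured, gs, atol=0.01)

    def test_remyelination_rejected(self, small_packing):
        with pytest.raises(ValueError, match="target g"):
            erode_myelin(small_packing, 0.5)


# ---------------------------------------------------------------- measure


class TestMeasure:
    def test_all_extra_fractions(self):
        grid = GridSpec(32, 3.0)
        m = measure(LabelMap(grid, np.zeros(grid.shape, dtype=np.uint8)))
        assert m["volume_fractions"] == {"extra": 1.0, "intra": 0.0, "myelin": 0.0}

    def test_fractions_sum_to_one(self, small_packed_map):
        vf = measure(small_packed_map)["volume_fractions"]
        assert abs(sum(vf.values()) - 1.0) < 1e-12

    def test_single_axon_g_from_raster(self):
        grid = GridSpec(100, 100.0)
        rec = _circle_record((50.0, 50.0), 14.0, 20.0)
        m = measure(rasterize(AxonSet([rec], grid)))
        # one pixel-layer quantum on g at r_o = 20 px is ~0.015
        assert abs(m["axon_g"][0] - 0.7) < 0.02
        assert abs(m["axon_r_effective"][0] - 14.0) < 0.5


# ------------------------------------------------------------- orientation


class TestOrientationMap:
    def test_continuous_azimuth_convention(self, single_axon_map):
        om = orientation_map(single_axon_map, mode="continuous")
        grid = single_axon_map.grid
        cx, cy = grid.center
        iy = int(cy / grid.pixel_size)
        my_cols = np.nonzero(single_axon_map.labels[iy] == MYELIN)[0]
        east = my_cols[my_cols > grid.n // 2]
        phi = om.phi[iy, east]
        assert np.all((phi < 0.02) | (phi > 2 * np.pi - 0.02))

    def test_wedge_mode_quantizes(self, single_axon_map):
        om = orientation_map(single_axon_map, mode="wedge", n_wedges=4)
        phi = om.phi[single_axon_map.labels == MYELIN]
        values = np.unique(phi)
        assert len(values) == 4
        assert np.allclose(np.sort(values),
                           np.pi / 4 + np.arange(4) * np.pi / 2)

    def test_phi_defined_exactly_on_myelin(self, small_packed_map, small_packing):
        om = orientation_map(small_packed_map, small_packing)
        my = small_packed_map.labels == MYELIN
        assert not np.isnan(om.phi[my]).any()
        assert np.isnan(om.phi[~my]).all()
        assert (om.phi[my] >= 0).all() and (om.phi[my] < 2 * np.pi).all()
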