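"""Susceptibility tensors and the Fourier field solver.

The brute-force naive-DFT oracle and the analytic hollow-cylinder solution
are the two independent checks of the spectral implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from myelinsim import GridSpec, circular_mask
from myelinsim.field import (
    CompartmentProperties,
    FieldConfig,
    TensorField,
    analytic_hollow_cylinder,
    build_tensor_map,
    compartment_histograms,
    direct_convolution_oracle,
    forward_field,
    reference_to_extra,
)
from myelinsim.geometry import EXTRA, INTRA, MYELIN, EllipseSpec, make_single_ellipse_axon, orientation_map


def rotate_tensor(phi, chi_i, chi_a):
    local = np.diag([chi_i + chi_a, chi_i - chi_a / 2, chi_i - chi_a / 2])
    c, s = math.cos(phi), math.sin(phi)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return R @ local @ R.T


class TestBuildTensorMap:
    def test_phi_zero_pixel_matches_local_form(self, single_axon_map, wm_props):
        om = orientation_map(single_axon_map, mode="continuous")
        tf = build_tensor_map(single_axon_map, om, wm_props)
        grid = single_axon_map.grid
        iy = int(grid.center[1] / grid.pixel_size)
        ix = np.nonzero(single_axon_map.labels[iy] == MYELIN)[0].max()  # east
        got = tf.full_tensor()[iy, ix]
        want = rotate_tensor(om.phi[iy, ix], wm_props.chi_i, wm_props.chi_a)
        assert np.allclose(got, want, atol=1e-6)
        # with literature values the radial eigenvalue is chi_i + chi_a = -180
        assert abs(got[0, 0] - (-180.0)) < 0.5

    def test_trace_is_rotation_invariant(self, single_axon_map, wm_props):
        om = orientation_map(single_axon_map, mode="continuous")
        tf = build_tensor_map(single_axon_map, om, wm_props)
        my = single_axon_map.labels == MYELIN
        assert np.allclose(tf.trace()[my], 3 * wm_props.chi_i, atol=1e-9)
        assert np.allclose(tf.trace()[~my], 0.0)

    def test_isotropic_chi_has_no_off_diagonal(self, single_axon_map):
        props = CompartmentProperties(chi_i=-100.0, chi_a=0.0)
        om = orientation_map(single_axon_map, mode="continuous")
        tf = build_tensor_map(single_axon_map, om, props)
        assert "xy" not in tf.components
        my = single_axon_map.labels == MYELIN
        for key in ("xx", "yy", "zz"):
            assert np.allclose(tf.components[key][my], -100.0)

    def test_undefined_phi_on_myelin_raises(self, single_axon_map, wm_props):
        from myelinsim.geometry import OrientationMap

        bad = OrientationMap(single_axon_map.grid,
                             np.full(single_axon_map.grid.shape, np.nan))
        with pytest.raises(ValueError, match="orientation"):
            build_tensor_map(single_axon_map, bad, wm_props)


def random_tensor_field(grid, rng, n_sources=40):
    comps = {}
    for key in ("xx", "yy", "zz", "xy"):
        arr = np.zeros(grid.shape)
        iy = rng.integers(0, grid.ny, n_sources)
        ix = rng.integers(0, grid.n, n_sources)
        arr[iy, ix] = rng.normal(0, 100, n_sources)
        comps[key] = arr
    return TensorField(grid, comps)


class TestForwardField:
    def test_zero_tensor_gives_zero_field(self, perp_7t):
        grid = GridSpec(32, 3.0)
        fm = forward_field(TensorField(grid, {}), perp_7t)
        assert np.all(fm.delta_f == 0.0)

    def test_zero_spatial_mean(self, single_axon_field):
        assert abs(single_axon_field.delta_f.mean()) < 1e-9

    def test_matches_analytic_hollow_cylinder(self, single_axon_map,
                                              single_axon_field, wm_props, perp_7t):
        intra = single_axon_map.labels == INTRA
        extra = single_axon_map.labels == EXTRA
        got = single_axon_field.delta_f[intra].mean() \
            - single_axon_field.delta_f[extra].mean()
        want = analytic_hollow_cylinder(0.7, wm_props, perp_7t)
        assert want == pytest.approx(-9.568, abs=0.01)
        assert abs(got - want) / abs(want) < 0.03

    def test_analytic_theta_and_chi_scaling(self, wm_props, perp_7t):
        assert analytic_hollow_cylinder(0.7, wm_props, FieldConfig(theta=0.0)) == 0.0
        alt = CompartmentProperties.alt_chi()
        assert analytic_hollow_cylinder(0.7, alt, perp_7t) == pytest.approx(-5.58, abs=0.02)

    def test_agrees_with_naive_dft_oracle(self, perp_7t):
        rng = np.random.default_rng(0)
        grid = GridSpec(64, 4.0)
        chi = random_tensor_field(grid, rng)
        fast = forward_field(chi, perp_7t).delta_f
        slow = direct_convolution_oracle(chi, perp_7t).delta_f
        scale = np.abs(fast).max()
        assert np.abs(fast - slow).max() <= 1e-6 * scale

    def test_oracle_on_single_pixel_isotropic_source(self, perp_7t):
        grid = GridSpec(64, 4.0)
        comps = {k: np.zeros(grid.shape) for k in ("xx", "yy", "zz")}
        for k in comps:
            comps[k][20, 30] = -100.0
        chi = TensorField(grid, comps)
        fast = forward_field(chi, perp_7t).delta_f
        slow = direct_convolution_oracle(chi, perp_7t).delta_f
        assert np.abs(fast - slow).max() <= 1e-6 * np.abs(fast).max()

    def test_linearity(self, perp_7t):
        rng = np.random.default_rng(1)
        grid = GridSpec(48, 3.0)
        a = random_tensor_field(grid, rng)
        b = random_tensor_field(grid, rng)
        combo = TensorField(grid, {k: 2.0 * a.component(k) - 0.5 * b.component(k)
                                   for k in ("xx", "yy", "zz", "xy")})
        fa = forward_field(a, perp_7t).delta_f
        fb = forward_field(b, perp_7t).delta_f
        fc = forward_field(combo, perp_7t).delta_f
        scale = np.abs(fc).max()
        assert np.abs(fc - (2.0 * fa - 0.5 * fb)).max() <= 1e-10 * scale

    def test_two_pixel_source_additivity(self, perp_7t):
        grid = GridSpec(64, 4.0)

        def single(iy, ix):
            comps = {"xx": np.zeros(grid.shape)}
            comps["xx"][iy, ix] = -120.0
            return forward_field(TensorField(grid, comps), perp_7t).delta_f

        comps = {"xx": np.zeros(grid.shape)}
        comps["xx"][10, 10] = -120.0
        comps["xx"][40, 25] = -120.0
        both = forward_field(TensorField(grid, comps), perp_7t).delta_f
        parts = single(10, 10) + single(40, 25)
        assert np.abs(both - parts).max() <= 1e-10 * np.abs(both).max()

    def test_parallel_fiber_leaves_aqueous_uniform(self, single_axon_map):
        # theta = 0: the dipole term vanishes and only the pointwise
        # (1/3) chi_zz term on myelin survives (up to the zero-mean gauge)
        props = CompartmentProperties(chi_i=-100.0, chi_a=0.0)
        om = orientation_map(single_axon_map, mode="continuous")
        fm = forward_field(build_tensor_map(single_axon_map, om, props),
                           FieldConfig(theta=0.0))
        aqueous = single_axon_map.labels != MYELIN
        assert fm.delta_f[aqueous].std() < 1e-9
        contrast = fm.delta_f[~aqueous].mean() - fm.delta_f[aqueous].mean()
        want = (1.0 / 3.0) * (-100e-9) * FieldConfig().f0_hz
        assert contrast == pytest.approx(want, rel=1e-9)

    def test_oracle_rejects_large_grids(self, perp_7t):
        with pytest.raises(ValueError, match="128"):
            direct_convolution_oracle(TensorField(GridSpec(256, 3.0), {}), perp_7t)


class TestHistogramsAndReference:
    def test_uniform_zero_field_peaks_at_zero(self, small_packed_map, perp_7t):
        from myelinsim.field import FieldMap

        fm = FieldMap(small_packed_map.grid,
                      np.zeros(small_packed_map.grid.shape))
        h = compartment_histograms(fm, small_packed_map)
        assert h.peaks["intra"] == 0.0
        assert h.peaks["extra"] == 0.0
        assert h.peaks["myelin"] == 0.0

    def test_counts_partition_the_mask(self, small_packed_map, small_packed_field,
                                       half_mask):
        h = compartment_histograms(small_packed_field, small_packed_map, half_mask)
        total = sum(h.counts[name].sum() for name in ("intra", "extra", "myelin"))
        assert total == half_mask.mask.sum()
        assert np.array_equal(
            h.counts["total"],
            h.counts["intra"] + h.counts["extra"] + h.counts["myelin"],
        )

    def test_empty_compartment_reports_absent_peak(self, perp_7t):
        from myelinsim.field import FieldMap
        from myelinsim.geometry import LabelMap

        grid = GridSpec(32, 3.0)
        lmap = LabelMap(grid, np.zeros(grid.shape, dtype=np.uint8))
        h = compartment_histograms(FieldMap(grid, np.zeros(grid.shape)), lmap)
        assert h.peaks["intra"] is None
        assert h.peaks["extra"] == 0.0

    def test_extra_reference_moves_extra_mode_to_zero(
        self, small_packed_map, small_packed_field, half_mask
    ):
        ref = reference_to_extra(small_packed_field, small_packed_map)
        h = compartment_histograms(ref, small_packed_map, half_mask)
        assert abs(h.peaks["extra"]) <= 0.5
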