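"""Bragg curve, pencil-beam dose superposition and PVDR analysis."""

import numpy as np
import pytest

from minibeam import (
    DoseGrid,
    GridLayout,
    PhantomSpec,
    analyze_dose,
    bragg_depth_dose,
    build_nozzle,
    compute_dose_grid,
    find_homogenisation_spacing,
    make_source,
)
from minibeam.beam_source import BeamMoments, PlaneMoments
from minibeam.dose_engine import (
    proton_range_cm,
    range_sigma_cm,
    water_sigma_profile,
)
from minibeam.synthetic_data import gen_pvdr_fixture


def flat_entrance(sigma_mm=1.0, div_mrad=2.0):
    pm = PlaneMoments(var_pos=sigma_mm**2, cov_pos_ang=0.0, var_ang=div_mrad**2)
    return BeamMoments(z=0.0, x=pm, y=pm)


def square_layout(n, spacing):
    half = (n - 1) / 2
    offs = np.array([((i - half) * spacing, (j - half) * spacing)
                     for i in range(n) for j in range(n)])
    return GridLayout(n=n, spacing_mm=spacing, offsets_mm=offs,
                      angles_mrad=np.zeros_like(offs))


class TestBraggCurve:
    def test_peak_depth_near_7_5_cm_at_100MeV(self):
        z = np.linspace(0, 9, 1801)
        d = bragg_depth_dose(100.0, 0.01, z)
        assert z[np.argmax(d)] == pytest.approx(7.5, abs=0.3)

    def test_zero_beyond_range_plus_straggling(self):
        zfar = proton_range_cm(100.0) + 5 * range_sigma_cm(100.0, 0.01) + 0.2
        assert bragg_depth_dose(100.0, 0.01, zfar) < 1e-4 * bragg_depth_dose(100.0, 0.01, 0.0)

    def test_peak_to_entrance_above_one(self):
        z = np.linspace(0, 9, 901)
        d = bragg_depth_dose(100.0, 0.01, z)
        assert d.max() / d[0] > 1.0

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bragg_depth_dose(100.0, 0.01, -1.0)

    def test_broader_energy_spread_lowers_the_peak(self):
        z = np.linspace(6.5, 8.5, 400)
        sharp = bragg_depth_dose(100.0, 0.001, z).max()
        broad = bragg_depth_dose(100.0, 0.03, z).max()
        assert broad < sharp


class TestPhantomAndLayout:
    def test_voxels_must_divide_phantom(self):
        with pytest.raises(ValueError):
            PhantomSpec(width_cm=2.0, voxel_mm=(0.3, 0.05, 1.0))

    def test_grid_beyond_phantom_rejected(self):
        layout = square_layout(5, 8.0)
        with pytest.raises(ValueError):
            compute_dose_grid(
                None, make_source(100, 0.01, 4, 4, 3, 3, 0, 0), layout,
                PhantomSpec(voxel_mm=(0.5, 0.5, 1.0)), entrance=flat_entrance(),
            )

    def test_five_by_five_grid_covers_two_by_two_cm(self):
        noz = build_nozzle("optimized", air_gap_cm=10.0)
        layout = GridLayout.from_nozzle(noz, 2.9)
        span = layout.offsets_mm.max() - layout.offsets_mm.min()
        assert 10.0 <= span <= 20.0  # ~2 x 2 cm^2 including beam margins
        assert layout.angles_mrad[layout.central_index()] == pytest.approx((0.0, 0.0))

    def test_off_centre_beams_propagate_at_an_angle(self):
        noz = build_nozzle("optimized", air_gap_cm=10.0)
        layout = GridLayout.from_nozzle(noz, 2.9)
        corner = np.argmax(np.abs(layout.offsets_mm).sum(axis=1))
        assert abs(layout.angles_mrad[corner, 0]) > 1.0  # mrad, away from axis


class TestAnalyticEngine:
    @pytest.fixture(scope="class")
    def small_setup(self):
        ph = PhantomSpec(width_cm=2, height_cm=2, depth_cm=8, voxel_mm=(0.2, 0.2, 2.0))
        src = make_source(100.0, 0.01, 4, 4, 3, 3, 0, 0)
        return ph, src

    def test_dose_linear_in_primaries(self, small_setup):
        ph, src = small_setup
        layout = square_layout(3, 5.0)
        g1 = compute_dose_grid(None, src, layout, ph, n=1000, entrance=flat_entrance())
        g2 = compute_dose_grid(None, src, layout, ph, n=2000, entrance=flat_entrance())
        np.testing.assert_allclose(2.0 * g1.dose, g2.dose, rtol=1e-6)

    def test_grid_equals_sum_of_single_beams(self, small_setup):
        ph, src = small_setup
        layout = square_layout(2, 6.0)
        full = compute_dose_grid(None, src, layout, ph, entrance=flat_entrance())
        total = np.zeros_like(full.dose)
        for b in range(4):
            single = GridLayout(
                n=1, spacing_mm=6.0,
                offsets_mm=layout.offsets_mm[b : b + 1],
                angles_mrad=layout.angles_mrad[b : b + 1],
            )
            total += compute_dose_grid(None, src, single, ph, entrance=flat_entrance()).dose
        np.testing.assert_allclose(full.dose, total, rtol=1e-5)

    def test_single_axis_beam_is_radially_symmetric(self, small_setup):
        ph, src = small_setup
        single = GridLayout(n=1, spacing_mm=5.0, offsets_mm=np.zeros((1, 2)),
                            angles_mrad=np.zeros((1, 2)))
        g = compute_dose_grid(None, src, single, ph, entrance=flat_entrance())
        ix, iy = g.axis_index(0.0, 0.0)
        np.testing.assert_allclose(g.dose[:, iy, 0], g.dose[ix, :, 0], rtol=1e-5)


class TestAnalysis:
    def test_uniform_dose_gives_pvdr_one(self):
        ph = PhantomSpec(depth_cm=0.5, voxel_mm=(0.5, 0.5, 1.0))
        grid = DoseGrid(dose=np.ones((*ph.shape,), dtype=np.float32), phantom=ph)
        ana = analyze_dose(grid, square_layout(5, 4.0))
        assert np.allclose(ana.pvdr, 1.0)

    def test_zero_valley_reported_as_undefined(self):
        ph = PhantomSpec(depth_cm=0.5, voxel_mm=(0.5, 0.5, 1.0))
        dose = np.zeros((*ph.shape,), dtype=np.float32)
        ix = ph.shape[0] // 2
        dose[ix, ix, :] = 5.0
        ana = analyze_dose(DoseGrid(dose=dose, phantom=ph), square_layout(5, 4.0))
        assert np.all(np.isnan(ana.pvdr))

    def test_gaussian_comb_fixture_reproduces_closed_form(self):
        grid, layout, expected = gen_pvdr_fixture(1.0, 4.0)
        ana = analyze_dose(grid, layout)
        assert ana.pvdr[0] == pytest.approx(expected, rel=0.01)

    def test_central_beam_fwhm_profile_increases_with_depth(self):
        ph = PhantomSpec(depth_cm=8, voxel_mm=(0.1, 0.1, 2.0))
        src = make_source(100.0, 0.01, 4, 4, 3, 3, 0, 0)
        single = GridLayout(n=1, spacing_mm=5.0, offsets_mm=np.zeros((1, 2)),
                            angles_mrad=np.zeros((1, 2)))
        entrance = flat_entrance(sigma_mm=0.5, div_mrad=2.0)
        g = compute_dose_grid(None, src, single, ph, entrance=entrance)
        ana = analyze_dose(g, single, single_beam_grid=g)
        ok = np.isfinite(ana.fwhm_mm)
        assert np.all(np.diff(ana.fwhm_mm[ok]) > -0.05)

    def test_water_broadening_slower_at_200MeV(self):
        z = np.array([75.0])
        ent = flat_entrance(sigma_mm=0.3, div_mrad=2.0)
        s100 = water_sigma_profile(ent, 100.0, 0.01, z)[0][0]
        s200 = water_sigma_profile(ent, 200.0, 0.01, z)[0][0]
        assert s200 < s100


class TestMonteCarloEngine:
    def test_mc_agrees_with_analytic_pvdr_at_moderate_depth(self):
        ph = PhantomSpec(depth_cm=8, voxel_mm=(0.5, 0.5, 2.0))
        src = make_source(100.0, 0.01, 4, 4, 3, 3, 0, 0)
        layout = square_layout(3, 5.0)
        ent = flat_entrance(sigma_mm=1.0, div_mrad=2.0)
        ga = compute_dose_grid(None, src, layout, ph, mode="analytic", entrance=ent)
        gm = compute_dose_grid(None, src, layout, ph, mode="monte_carlo",
                               n=30_000, repeats=8, seed=3, entrance=ent)
        aa, am = analyze_dose(ga, layout), analyze_dose(gm, layout)
        sel = (aa.pvdr < 30) & np.isfinite(am.pvdr)
        assert sel.sum() >= 5
        rel = np.abs(am.pvdr[sel] - aa.pvdr[sel]) / aa.pvdr[sel]
        assert np.median(rel) < 0.25

    def test_mc_uncertainty_attached_and_positive(self):
        ph = PhantomSpec(depth_cm=4, voxel_mm=(1.0, 1.0, 2.0))
        src = make_source(100.0, 0.01, 4, 4, 3, 3, 0, 0)
        layout = square_layout(1, 5.0)
        gm = compute_dose_grid(None, src, layout, ph, mode="monte_carlo",
                               n=5_000, repeats=5, seed=1, entrance=flat_entrance())
        ana = analyze_dose(gm, layout)
        assert ana.global_rel_uncertainty is not None
        assert 0 < ana.global_rel_uncertainty < 1.0


class TestHomogenisationSpacing:
    def test_uniform_slab_has_zero_flatness(self):
        from minibeam.dose_engine import lateral_flatness

        ph = PhantomSpec(depth_cm=0.5, voxel_mm=(0.5, 0.5, 1.0))
        grid = DoseGrid(dose=np.ones((*ph.shape,), dtype=np.float32), phantom=ph)
        assert lateral_flatness(grid, square_layout(5, 4.0), 0.0) == 0.0

    def test_wider_beams_need_larger_spacing(self):
        noz = build_nozzle("optimized", air_gap_cm=10.0)
        src = make_source(100.0, 0.01, 4, 4, 3, 3, -1, -1)
        ph = PhantomSpec(depth_cm=10.0, voxel_mm=(0.1, 0.1, 1.0))
        narrow = find_homogenisation_spacing(
            noz, src, ph, entrance=flat_entrance(0.3, 2.0), criterion="optimal"
        )
        wide = find_homogenisation_spacing(
            noz, src, ph, entrance=flat_entrance(2.0, 2.0), criterion="optimal"
        )
        assert wide > narrow

    def test_unreachable_band_names_closest_candidate(self):
        noz = build_nozzle("optimized", air_gap_cm=10.0)
        src = make_source(100.0, 0.01, 4, 4, 3, 3, -1, -1)
        ph = PhantomSpec(depth_cm=10.0, voxel_mm=(0.1, 0.1, 1.0))
        with pytest.raises(ValueError, match="closest candidate"):
            find_homogenisation_spacing(
                noz, src, ph, flatness_band_pct=(0.0001, 0.0002),
                entrance=flat_entrance(0.3, 2.0),
            )

    def test_optimal_spacing_near_published_value(self, table1_scans):
        scan = table1_scans["100MeV_10cm"]
        cfg = scan["config"]
        s = find_homogenisation_spacing(
            scan["nozzle"], scan["source"], PhantomSpec(depth_cm=10.0),
            quad_fields=(cfg["B1"], cfg["B2"]), arrangement=cfg["arrangement"],
            criterion="optimal",
        )
        assert s == pytest.approx(2.9, abs=0.5)
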