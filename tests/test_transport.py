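"""Beamline transport: transfer maps, scattering, envelope vs Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minibeam import (
    build_nozzle,
    make_source,
    propagate_moments,
    quad_matrix,
    sample_particles,
    scattering_theta0,
    source_moments,
    track_particles,
)
from minibeam.beam_source import bundle_moments
from minibeam.metrics import FWHM_FACTOR, fit_gaussian_fwhm
from minibeam.synthetic_data import gen_toy_beamline
from minibeam.transport import RADIATION_LENGTH_CM, quadrupole


class TestQuadMatrix:
    @given(
        field=st.floats(0.01, 4.0),
        length=st.floats(1.0, 60.0),
        energy=st.floats(70.0, 250.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symplectic_unit_determinant(self, field, length, energy):
        q = quadrupole(length, field_T=field, aperture_cm=5.0)
        mx, my = quad_matrix(q, energy)
        assert np.linalg.det(mx) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.det(my) == pytest.approx(1.0, abs=1e-9)

    def test_zero_field_is_drift(self):
        q = quadrupole(30.0, field_T=0.0)
        mx, my = quad_matrix(q, 100.0)
        expected = np.array([[1.0, 0.3], [0.0, 1.0]])
        np.testing.assert_allclose(mx, expected)
        np.testing.assert_allclose(my, expected)

    def test_thin_lens_limit_matches_segment_composition(self):
        # a thick quad equals the product of many short segments
        energy, field = 120.0, 1.4
        thick = quad_matrix(quadrupole(30.0, field_T=field), energy)[0]
        n = 300
        seg = quad_matrix(quadrupole(30.0 / n, field_T=field), energy)[0]
        composed = np.linalg.matrix_power(seg, n)
        np.testing.assert_allclose(thick, composed, rtol=1e-9)
        # and the focal strength approaches 1/f = k * L as length -> 0
        from minibeam.transport import quad_strength

        k = quad_strength(quadrupole(0.1, field_T=field), energy)
        short = quad_matrix(quadrupole(0.1, field_T=field), energy)[0]
        assert -short[1, 0] == pytest.approx(k * 0.001, rel=1e-5)

    def test_zero_aperture_rejected(self):
        with pytest.raises(ValueError):
            quadrupole(30.0, field_T=1.0, aperture_cm=0.0)


class TestScattering:
    def test_zero_thickness(self):
        assert scattering_theta0(100.0, "air", 0.0) == 0.0

    def test_highland_oracle_value(self):
        # independent hand evaluation of the Highland formula at 100 MeV, 1 m air
        pv = 100.0 * (100.0 + 2 * 938.272) / (100.0 + 938.272)
        t = 100.0 / RADIATION_LENGTH_CM["air"]
        expected = (13.6 / pv) * np.sqrt(t) * (1 + 0.038 * np.log(t)) * 1e3
        assert scattering_theta0(100.0, "air", 100.0) == pytest.approx(expected)

    @pytest.mark.parametrize("material,thickness", [("air", 50.0), ("water", 0.1)])
    def test_monotone_decreasing_in_energy(self, material, thickness):
        assert scattering_theta0(200.0, material, thickness) < scattering_theta0(
            100.0, material, thickness
        )

    def test_unknown_material(self):
        with pytest.raises(ValueError):
            scattering_theta0(100.0, "lead", 1.0)


class TestNozzlePresets:
    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            build_nozzle("not_a_nozzle")

    def test_negative_air_gap(self):
        with pytest.raises(ValueError):
            build_nozzle("optimized", air_gap_cm=-5.0)

    @pytest.mark.parametrize("gap", [10.0, 30.0])
    def test_optimized_focal_length_in_design_band(self, gap):
        noz = build_nozzle("optimized", air_gap_cm=gap)
        starts = noz.element_entrances_cm()
        q2 = [i for i, e in enumerate(noz.elements) if e.name == "Q2"][0]
        q2_exit = starts[q2] + noz.elements[q2].length_cm
        assert 90.0 <= noz.target_z_cm - q2_exit <= 110.0

    def test_optimized_order_and_air_gap(self):
        noz = build_nozzle("optimized", air_gap_cm=10.0)
        names = [e.name for e in noz.elements if e.name]
        assert names[:5] == ["Q1", "Q2", "SM1", "SM2", "IC"]
        assert noz.target_z_cm - noz.monitors["IC"] == pytest.approx(10.0)

    def test_mod1_is_evacuated_current_geometry(self):
        cur = build_nozzle("icpo_current")
        mod = build_nozzle("icpo_mod1")
        assert all(e.medium == "vacuum" for e in mod.elements if e.kind == "drift")
        # identical layout otherwise: same element kinds, lengths and slabs
        assert [(e.kind, e.length_cm, e.thickness_mm) for e in cur.elements] == [
            (e.kind, e.length_cm, e.thickness_mm) for e in mod.elements
        ]

    def test_current_five_target_positions_addressable(self):
        noz = build_nozzle("icpo_current", target_offset_cm=40.0)
        for off in (-40, -20, 0, 20, 40):
            assert f"pos_{off:+.0f}" in noz.monitors

    def test_mod3_extra_quad_pair_scanned_to_4T(self):
        noz = build_nozzle("icpo_mod3")
        scanned = [noz.elements[i] for i in noz.scannable_quads()]
        assert [e.name for e in scanned] == ["XQ1", "XQ2"]
        assert all(e.max_field_T == 4.0 for e in scanned)
        names = [e.name for e in noz.elements if e.name]
        assert names.index("IC2") > names.index("XQ2")


class TestEnvelopeTransport:
    def test_pure_drift_closed_form(self):
        src = make_source(100.0, 0.0, 4.0, 4.0, 3.0, 3.0, 0.0, 0.0)
        noz, expected = gen_toy_beamline("pure_drift", length_cm=100.0, sigma_mm=4.0,
                                         div_mrad=3.0, r=0.0)
        m = propagate_moments(source_moments(src), noz, 100.0)[-1]
        assert m.x.var_pos == pytest.approx(expected["var_pos"])
        assert m.x.cov_pos_ang == pytest.approx(expected["cov_pos_ang"])

    def test_emittance_conserved_through_vacuum_optics(self):
        src = make_source(150.0, 0.0, 5.0, 3.0, 2.0, 1.0, -0.6, 0.4)
        noz, _ = gen_toy_beamline("doublet", length_cm=80.0, field_T=1.2, energy=150.0)
        m0 = source_moments(src)
        m1 = propagate_moments(m0, noz, 150.0)[-1]
        assert m1.x.emittance == pytest.approx(m0.x.emittance, rel=1e-12)
        assert m1.y.emittance == pytest.approx(m0.y.emittance, rel=1e-12)

    def test_doublet_matches_matrix_composition_oracle(self):
        src = make_source(150.0, 0.0, 5.0, 3.0, 2.0, 1.0, -0.6, 0.4)
        noz, expected = gen_toy_beamline("doublet", length_cm=80.0, field_T=1.2,
                                         sigma_mm=5.0, div_mrad=2.0, r=-0.6, energy=150.0)
        m = propagate_moments(source_moments(src), noz, 150.0)[-1]
        assert m.x.var_pos == pytest.approx(expected["x"][0, 0], rel=1e-10)
        assert m.x.var_ang == pytest.approx(expected["x"][1, 1], rel=1e-10)

    def test_air_exceeds_vacuum_and_matches_fermi_eyges_oracle(self):
        src = make_source(100.0, 0.0, 4.0, 4.0, 3.0, 3.0, 0.0, 0.0)
        vac, _ = gen_toy_beamline("pure_drift", length_cm=200.0)
        air, expected = gen_toy_beamline("air_drift", length_cm=200.0, sigma_mm=4.0,
                                         div_mrad=3.0, energy=100.0)
        mv = propagate_moments(source_moments(src), vac, 100.0)[-1]
        ma = propagate_moments(source_moments(src), air, 100.0)[-1]
        assert ma.x.var_pos > mv.x.var_pos
        assert ma.x.var_pos == pytest.approx(expected["var_pos"], rel=1e-12)
        assert ma.x.var_ang == pytest.approx(expected["var_ang"], rel=1e-12)

    def test_material_slab_never_decreases_final_spread(self):
        src = make_source(100.0, 0.0, 4.0, 4.0, 3.0, 3.0, -0.9, -0.9)
        noz = build_nozzle("optimized", air_gap_cm=10.0).with_quad_settings((1.0, 0.8), 0)
        base = propagate_moments(source_moments(src), noz, 100.0)[-1]
        from dataclasses import replace
        from minibeam.transport import slab

        thicker = replace(
            noz,
            elements=tuple(
                replace(e, thickness_mm=e.thickness_mm + 2.0) if e.kind == "slab" else e
                for e in noz.elements
            ),
        )
        more = propagate_moments(source_moments(src), thicker, 100.0)[-1]
        assert more.x.var_pos >= base.x.var_pos

    def test_plane_decoupling(self):
        a = make_source(100.0, 0.0, 4.0, 4.0, 3.0, 3.0, -0.5, -0.5)
        b = make_source(100.0, 0.0, 4.0, 9.0, 3.0, 0.7, -0.5, 0.8)
        noz = build_nozzle("optimized", air_gap_cm=10.0).with_quad_settings((1.2, 0.6), 0)
        ma = propagate_moments(source_moments(a), noz, 100.0)[-1]
        mb = propagate_moments(source_moments(b), noz, 100.0)[-1]
        assert ma.x.var_pos == pytest.approx(mb.x.var_pos, rel=1e-12)
        assert ma.x.var_ang == pytest.approx(mb.x.var_ang, rel=1e-12)


class TestMonteCarloTracking:
    def test_vacuum_fwhm_matches_envelope_within_three_se(self):
        n = 100_000
        src = make_source(100.0, 0.0, 4.0, 4.0, 3.0, 3.0, -0.5, 0.3)
        noz, _ = gen_toy_beamline("doublet", length_cm=80.0, field_T=1.0, energy=100.0)
        env = propagate_moments(source_moments(src), noz, 100.0)[-1]
        final = track_particles(sample_particles(src, n, seed=5), noz, seed=6)[-1]
        for plane, arr in (("x", final.x), ("y", final.y)):
            prof = fit_gaussian_fwhm(arr)
            expected = FWHM_FACTOR * np.sqrt(getattr(env, plane).var_pos)
            se = max(prof.fwhm_err, expected / np.sqrt(2 * n))
            assert abs(prof.fwhm - expected) < 3 * se + 0.01 * expected

    def test_air_mc_matches_envelope_moments(self):
        n = 100_000
        src = make_source(100.0, 0.0, 4.0, 4.0, 3.0, 3.0, 0.0, 0.0)
        noz, _ = gen_toy_beamline("air_drift", length_cm=200.0)
        env = propagate_moments(source_moments(src), noz, 100.0)[-1]
        final = track_particles(sample_particles(src, n, seed=9), noz, seed=10)[-1]
        est = bundle_moments(final)
        assert est.x.var_pos == pytest.approx(env.x.var_pos, rel=5 / np.sqrt(n) * 3)
        assert est.x.var_ang == pytest.approx(env.x.var_ang, rel=5 / np.sqrt(n) * 3)

    def test_zero_emittance_on_axis_beam_stays_on_axis(self):
        from minibeam.beam_source import ParticleBundle

        n = 100
        bundle = ParticleBundle(
            z=0.0, x=np.zeros(n), x_prime=np.zeros(n), y=np.zeros(n),
            y_prime=np.zeros(n), energy=np.full(n, 100.0),
        )
        noz, _ = gen_toy_beamline("doublet", length_cm=100.0, field_T=1.5)
        final = track_particles(bundle, noz, seed=1)[-1]
        assert np.all(final.x == 0.0) and np.all(final.y == 0.0)

    def test_chromatic_aberration_grows_with_energy_spread(self):
        n = 50_000
        noz = build_nozzle("optimized", air_gap_cm=10.0).with_quad_settings((1.28, 0.84), 1)
        fwhms = {}
        for spread in (1e-5, 0.01):
            src = make_source(100.0, spread, 4.0, 4.0, 3.0, 3.0, -1.0, -1.0)
            final = track_particles(sample_particles(src, n, seed=2), noz, seed=3)[-1]
            fwhms[spread] = fit_gaussian_fwhm(final.x).fwhm
        assert fwhms[0.01] > fwhms[1e-5]

    def test_tracking_reproducible_for_fixed_seed(self):
        src = make_source(100.0, 0.01, 4.0, 4.0, 3.0, 3.0, 0.0, 0.0)
        noz = build_nozzle("optimized", air_gap_cm=10.0)
        b = sample_particles(src, 1000, seed=4)
        f1 = track_particles(b, noz, seed=8)[-1]
        f2 = track_particles(b, noz, seed=8)[-1]
        assert np.array_equal(f1.x, f2.x)
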