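"""Shared fixtures: the three published beam configurations and their
scan/dose results, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from minibeam import (
    GridLayout,
    PhantomSpec,
    analyze_dose,
    build_nozzle,
    compute_dose_grid,
    make_source,
    scan_quadrupoles,
    select_minimum,
)
from minibeam.optimizer import QuadScanSpec

#: the three (energy, air-gap) configurations with their reference minima
TABLE1 = {
    "100MeV_10cm": {
        "source": dict(energy=100.0, energy_spread=0.01, sigma_x=4.0, sigma_y=4.0,
                       div_x=3.0, div_y=3.0, r_xx=-1.0, r_yy=-1.0),
        "air_gap_cm": 10.0,
        "spacing_mm": 2.9,
        "depth_cm": 10.0,
        "ref_h": 0.66, "ref_v": 0.68,
        "ref_h_unc": (0.11, 0.001), "ref_v_unc": (0.11, 0.001),
        "ref_peak_to_entrance": 0.19,
        "minibeam": True,
    },
    "200MeV_30cm": {
        "source": dict(energy=200.0, energy_spread=0.01, sigma_x=5.0, sigma_y=3.5,
                       div_x=1.0, div_y=0.5, r_xx=1.0, r_yy=-1.0),
        "air_gap_cm": 30.0,
        "spacing_mm": 3.7,
        "depth_cm": 30.0,
        "ref_h": 0.87, "ref_v": 0.85,
        "ref_h_unc": (0.14, 0.001), "ref_v_unc": (0.07, 0.001),
        "ref_peak_to_entrance": 0.11,
        "minibeam": True,
    },
    "100MeV_30cm": {
        "source": dict(energy=100.0, energy_spread=0.01, sigma_x=6.5, sigma_y=10.0,
                       div_x=5.0, div_y=5.0, r_xx=-1.0, r_yy=-1.0),
        "air_gap_cm": 30.0,
        "spacing_mm": 3.7,
        "depth_cm": 10.0,
        "ref_h": 1.67, "ref_v": 1.65,
        "ref_h_unc": (0.19, 0.001), "ref_v_unc": (0.40, 0.001),
        "ref_peak_to_entrance": 0.82,
        "minibeam": False,
    },
}


@pytest.fixture(scope="session")
def table1_cases():
    return TABLE1


@pytest.fixture(scope="session")
def table1_scans():
    """Full 51x51x2 grid scans with Monte-Carlo refinement, one per case."""
    out = {}
    for name, case in TABLE1.items():
        nozzle = build_nozzle("optimized", air_gap_cm=case["air_gap_cm"])
        source = make_source(**case["source"])
        spec = QuadScanSpec(n_particles=100_000, refine_fraction=0.01, base_seed=1)
        result = scan_quadrupoles(nozzle, source, spec)
        cfg, h, v = select_minimum(result)
        out[name] = {
            "nozzle": nozzle, "source": source, "result": result,
            "config": cfg, "h": h, "v": v,
        }
    return out


@pytest.fixture(scope="session")
def table1_doses(table1_scans):
    """Analytic 5x5 minibeam-grid dose runs at the scan minima."""
    out = {}
    for name, case in TABLE1.items():
        scan = table1_scans[name]
        phantom = PhantomSpec(depth_cm=case["depth_cm"])
        layout = GridLayout.from_nozzle(scan["nozzle"], case["spacing_mm"])
        grid = compute_dose_grid(
            scan["nozzle"], scan["source"], layout, phantom,
            quad_fields=(scan["config"]["B1"], scan["config"]["B2"]),
            arrangement=scan["config"]["arrangement"],
        )
        out[name] = {
            "grid": grid, "layout": layout, "phantom": phantom,
            "analysis": analyze_dose(grid, layout),
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
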