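"""Synthetic inputs with known ground truth.

No measured beam-size data are published for the clinical nozzle, so the
calibration and analysis stages are exercised on synthetic stand-ins:

* measured-size tables with the structure of the clinical commissioning
  data (13 energies from 100 to 220 MeV, five positions around the
  isocentre, horizontal + vertical sigma, relative Gaussian noise),
  generated from a known per-energy source model;
* toy beamlines whose transported second moments have closed forms;
* Gaussian-comb dose grids whose peak-to-valley dose ratio has a
  closed-form lattice-sum value.

The default per-energy generating parameters interpolate the published
clinical ranges linearly in energy (sizes 13 -> 3.2 mm, divergences
2.25 -> 0.3 mrad, correlations -1 -> +1 from 100 to 220 MeV); the true
energy-dependent functions are not public.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam_source import BeamSource, make_source, source_moments
from .benchmark_calibration import MeasuredSizeTable
from .dose_engine import DoseGrid, GridLayout, PhantomSpec
from .transport import (
    NozzleConfig,
    drift,
    monitor,
    propagate_moments,
    quadrupole,
    scattering_theta0,
)

__all__ = [
    "SyntheticSpec",
    "default_icpo_sources",
    "gen_measured_sizes",
    "gen_toy_beamline",
    "gen_pvdr_fixture",
]

DEFAULT_ENERGIES = tuple(np.linspace(100.0, 220.0, 13))


def default_icpo_sources(
    energies: tuple[float, ...] = DEFAULT_ENERGIES,
) -> dict[float, BeamSource]:
    """Per-energy generating sources interpolating the published ranges."""
    out = {}
    for e in energies:
        f = (e - 100.0) / 120.0
        sigma = 13.0 + f * (3.2 - 13.0)
        div = 2.25 + f * (0.3 - 2.25)
        r = -1.0 + 2.0 * f
        out[float(e)] = make_source(float(e), 0.0, sigma, sigma, div, div, r, r)
    return out


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for synthetic measured-size tables and dose fixtures."""

    seed: int
    noise_rel: float = 0.01
    energies: tuple[float, ...] = DEFAULT_ENERGIES
    sources: dict[float, BeamSource] | None = None
    comb_sigma_mm: float = 1.0
    comb_spacing_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise sigma must be >= 0")

    def generating_sources(self) -> dict[float, BeamSource]:
        return self.sources if self.sources is not None else default_icpo_sources(self.energies)


def gen_measured_sizes(spec: SyntheticSpec, nozzle: NozzleConfig) -> MeasuredSizeTable:
    """Propagate the generating sources and record noisy sigmas.

    Sizes are recorded at the five monitored positions around the
    isocentre (-40 ... +40 cm) with relative Gaussian noise ``noise_rel``;
    the same seed always yields the same table.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    positions = (-40.0, -20.0, 0.0, 20.0, 40.0)
    iso = 250.0
    for e, src in sorted(spec.generating_sources().items()):
        mons = propagate_moments(source_moments(src), nozzle, src.energy)
        zs = np.array([m.z for m in mons])
        for pos in positions:
            i = int(np.argmin(np.abs(zs - (iso + pos))))
            if abs(zs[i] - (iso + pos)) > 1.0:
                raise ValueError(f"nozzle lacks a monitor at {pos:+.0f} cm")
            sx = math.sqrt(mons[i].x.var_pos)
            sy = math.sqrt(mons[i].y.var_pos)
            noise = rng.normal(0.0, spec.noise_rel, 2) if spec.noise_rel > 0 else (0.0, 0.0)
            rows.append(
                {
                    "energy_MeV": e,
                    "position_cm": pos,
                    "sigma_x_mm": sx * (1.0 + noise[0]),
                    "sigma_y_mm": sy * (1.0 + noise[1]),
                    "sigma_err_mm": sx * spec.noise_rel,
                }
            )
    return MeasuredSizeTable(pd.DataFrame(rows))


def gen_toy_beamline(
    kind: str,
    length_cm: float = 100.0,
    sigma_mm: float = 4.0,
    div_mrad: float = 3.0,
    r: float = 0.0,
    energy: float = 100.0,
    field_T: float = 1.0,
) -> tuple[NozzleConfig, dict]:
    """Toy beamline plus closed-form expected moments at its target.

    Kinds: ``pure_drift`` (vacuum drift, exact quadratic envelope),
    ``doublet`` (two thin-ish quads; expectation from numeric 2x2 matrix
    composition), ``air_drift`` (drift in air; Fermi-Eyges increments from
    the closed-form Highland integrals).
    """
    L_m = length_cm * 1e-2
    var0 = sigma_mm**2
    cov0 = r * sigma_mm * div_mrad
    ang0 = div_mrad**2
    if kind == "pure_drift":
        nozzle = NozzleConfig(
            elements=(drift(length_cm, "vacuum"), monitor("end")),
            target_z_cm=length_cm,
            target_medium="vacuum",
        )
        expected = {
            "var_pos": var0 + 2 * cov0 * L_m + ang0 * L_m**2,
            "cov_pos_ang": cov0 + ang0 * L_m,
            "var_ang": ang0,
        }
        return nozzle, expected
    if kind == "air_drift":
        nozzle = NozzleConfig(
            elements=(drift(length_cm, "air"), monitor("end")),
            target_z_cm=length_cm,
            target_medium="air",
        )
        t0 = float(scattering_theta0(energy, "air", length_cm))
        expected = {
            "var_pos": var0 + 2 * cov0 * L_m + ang0 * L_m**2 + t0**2 * L_m**2 / 3.0,
            "cov_pos_ang": cov0 + ang0 * L_m + t0**2 * L_m / 2.0,
            "var_ang": ang0 + t0**2,
        }
        return nozzle, expected
    if kind == "doublet":
        q_len = 5.0
        gap = 10.0
        q1 = quadrupole(q_len, field_T=field_T, focus_plane="horizontal", name="Q1")
        q2 = quadrupole(q_len, field_T=field_T, focus_plane="vertical", name="Q2")
        nozzle = NozzleConfig(
            elements=(q1, drift(gap, "vacuum"), q2, drift(length_cm, "vacuum"), monitor("end")),
            target_z_cm=2 * q_len + gap + length_cm,
            target_medium="vacuum",
        )
        from .transport import quad_matrix

        Mx1, My1 = quad_matrix(q1, energy)
        Mx2, My2 = quad_matrix(q2, energy)
        D = lambda l: np.array([[1.0, l * 1e-2], [0.0, 1.0]])
        Mx = D(length_cm) @ Mx2 @ D(gap) @ Mx1
        My = D(length_cm) @ My2 @ D(gap) @ My1
        S0 = np.array([[var0, cov0], [cov0, ang0]])
        expected = {
            "x": Mx @ S0 @ Mx.T,
            "y": My @ S0 @ My.T,
            # thin-lens focal strengths 1/f = k * L_quad per quad
            "Mx": Mx,
            "My": My,
        }
        return nozzle, expected
    raise ValueError(f"unknown toy beamline kind {kind!r}")


def comb_pvdr(sigma_mm: float, spacing_mm: float, n_beams: int = 5) -> float:
    """Closed-form PVDR of an ``n x n`` Gaussian comb by direct lattice sum.

    Peak at the central beam position, valley at the diagonal midpoint of
    the central 2 x 2 sub-grid.
    """
    half = (n_beams - 1) / 2.0
    centres = [
        ((i - half) * spacing_mm, (j - half) * spacing_mm)
        for i in range(n_beams)
        for j in range(n_beams)
    ]

    def total(px: float, py: float) -> float:
        return sum(
            math.exp(-((px - cx) ** 2 + (py - cy) ** 2) / (2.0 * sigma_mm**2))
            for cx, cy in centres
        )

    peak = total(0.0, 0.0)
    valley = total(spacing_mm / 2.0, spacing_mm / 2.0)
    return peak / valley


def gen_pvdr_fixture(
    sigma_mm: float,
    spacing_mm: float,
    n_beams: int = 5,
    phantom: PhantomSpec | None = None,
) -> tuple[DoseGrid, GridLayout, float]:
    """Depth-constant Gaussian-comb dose grid with its closed-form PVDR.

    The transverse dose is a sum of identical 2-D Gaussians on an
    ``n x n`` square grid, identical in every depth slab; the attached
    expected PVDR comes from :func:`comb_pvdr` (independent lattice sum).
    """
    if sigma_mm <= 0 or spacing_mm <= 0:
        raise ValueError("sigma and spacing must be > 0")
    phantom = phantom or PhantomSpec(depth_cm=0.5, voxel_mm=(0.05, 0.05, 1.0))
    x, y, z = phantom.axes_mm()
    half = (n_beams - 1) / 2.0
    slab = np.zeros((len(x), len(y)))
    offs = []
    for i in range(n_beams):
        for j in range(n_beams):
            cx, cy = (i - half) * spacing_mm, (j - half) * spacing_mm
            offs.append((cx, cy))
            slab += np.outer(
                np.exp(-0.5 * ((x - cx) / sigma_mm) ** 2),
                np.exp(-0.5 * ((y - cy) / sigma_mm) ** 2),
            )
    dose = np.repeat(slab[:, :, None], len(z), axis=2).astype(np.float32)
    layout = GridLayout(
        n=n_beams,
        spacing_mm=spacing_mm,
        offsets_mm=np.array(offs),
        angles_mrad=np.zeros((n_beams * n_beams, 2)),
    )
    return DoseGrid(dose=dose, phantom=phantom), layout, comb_pvdr(sigma_mm, spacing_mm, n_beams)
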