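"""Exhaustive quadrupole-configuration scan and Omega-argmin selection.

The beam size at the target is minimised by brute force over a grid of
pole-tip fields for the two scannable quadrupoles (default 0-2 T in 0.04 T
steps, i.e. 51 values each) and the two focus-plane assignments, 51*51*2 =
5202 configurations.  Every configuration is evaluated in a fast analytic
envelope mode (vectorised over the whole grid, chromatic via Gauss-Hermite
quadrature); a configurable top fraction is then re-evaluated with full
Monte-Carlo tracking and Gaussian profile fits, from which the final
minimum-Omega configuration is selected.

The uncertainty on the minimum combines, by root-sum-square per side,
(i) the spread of the minima over variations of the beam-source
parameters, (ii) the local beam-size variation around the minimum grid
cell — which can only overestimate the true minimum and therefore counts
on the upper side only — and (iii) the profile-fit error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .beam_source import BeamSource, sample_particles, source_moments
from .metrics import FWHM_FACTOR, fit_gaussian_fwhm, omega
from .transport import (
    NozzleConfig,
    gauss_hermite_energies,
    quad_strength,
    scattering_theta0,
    track_particles,
)

__all__ = [
    "QuadScanSpec",
    "QuadScanResult",
    "ScanUncertainty",
    "default_field_grid",
    "scan_quadrupoles",
    "select_minimum",
    "estimate_uncertainty",
    "default_source_variations",
]


def default_field_grid(max_field_T: float = 2.0, step_T: float = 0.04) -> np.ndarray:
    """Pole-tip field grid 0 .. max in fixed steps (0-2 T / 0.04 T -> 51 values)."""
    n = int(round(max_field_T / step_T)) + 1
    return np.linspace(0.0, max_field_T, n)


@dataclass(frozen=True)
class QuadScanSpec:
    """Scan grid specification.

    ``field_values`` holds one sorted array of pole-tip fields per
    scannable quadrupole; ``None`` derives the default 0.04 T grid up to
    each quadrupole's rated maximum field.
    """

    field_values: tuple[np.ndarray, ...] | None = None
    arrangements: tuple[int, ...] = (0, 1)
    n_particles: int = 100_000
    refine_fraction: float = 0.01
    n_energy_nodes: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.arrangements) < 1:
            raise ValueError("need at least one focus-plane arrangement")
        if self.field_values is not None:
            for vals in self.field_values:
                v = np.asarray(vals, float)
                if v.size == 0:
                    raise ValueError("empty field grid")
                if np.any(v < 0):
                    raise ValueError("field values must be non-negative")
                if np.any(np.diff(v) <= 0):
                    raise ValueError("field values must be sorted and unique")

    def grids_for(self, nozzle: NozzleConfig) -> tuple[np.ndarray, ...]:
        idx = nozzle.scannable_quads()
        if len(idx) != 2:
            raise ValueError("nozzle must have exactly 2 scannable quadrupoles")
        if self.field_values is not None:
            if len(self.field_values) != 2:
                raise ValueError("need one field grid per scannable quadrupole")
            return tuple(np.asarray(v, float) for v in self.field_values)
        return tuple(
            default_field_grid(nozzle.elements[i].max_field_T) for i in idx
        )


def _quad_plane_update(vp, cv, va, k, L_m, focusing):
    """Sigma-matrix update through a hard-edge quad, vectorised over k."""
    k = np.asarray(k, float)
    rk = np.sqrt(np.maximum(k, 1e-30))
    phi = rk * L_m
    if focusing:
        a, s = np.cos(phi), np.sin(phi)
        b, c = s / rk, -rk * s
    else:
        a, s = np.cosh(phi), np.sinh(phi)
        b, c = s / rk, rk * s
    free = k <= 0
    a = np.where(free, 1.0, a)
    b = np.where(free, L_m, b)
    c = np.where(free, 0.0, c)
    d = a
    vp2 = a * a * vp + 2 * a * b * cv + b * b * va
    cv2 = a * c * vp + (a * d + b * c) * cv + b * d * va
    va2 = c * c * vp + 2 * c * d * cv + d * d * va
    return vp2, cv2, va2


def envelope_target_fwhms(
    nozzle: NozzleConfig,
    source: BeamSource,
    fields: tuple[np.ndarray, np.ndarray],
    arrangement: int,
    n_energy_nodes: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope-mode (hFWHM, vFWHM) at the target for a whole field grid.

    ``fields`` are the two per-quad field arrays; the result has shape
    ``(len(B1)*len(B2),)`` in row-major (B1-outer) order.
    """
    idx = nozzle.scannable_quads()
    if len(idx) != 2:
        raise ValueError("nozzle must have exactly 2 scannable quadrupoles")
    g1, g2 = np.meshgrid(fields[0], fields[1], indexing="ij")
    scanned = {idx[0]: g1.ravel(), idx[1]: g2.ravel()}
    n_cfg = g1.size

    energies, weights = gauss_hermite_energies(
        source.energy, source.energy_spread, n_energy_nodes
    )
    mom = source_moments(source)
    mix = {"x": np.zeros(n_cfg), "y": np.zeros(n_cfg)}
    planes = ("horizontal", "vertical")

    from .transport import drift as _drift  # local alias to build the gap

    elements = list(nozzle.elements)
    gap = nozzle.target_z_cm - nozzle.length_cm
    if gap > 1e-12:
        elements.append(_drift(gap, nozzle.target_medium))

    for e_node, w in zip(energies, weights):
        state = {
            "x": [np.full(n_cfg, mom.x.var_pos), np.full(n_cfg, mom.x.cov_pos_ang),
                  np.full(n_cfg, mom.x.var_ang)],
            "y": [np.full(n_cfg, mom.y.var_pos), np.full(n_cfg, mom.y.cov_pos_ang),
                  np.full(n_cfg, mom.y.var_ang)],
        }
        quad_counter = 0
        for el in elements:
            if el.kind == "drift":
                L = el.length_cm * 1e-2
                t2 = 0.0
                if el.medium != "vacuum":
                    t0 = float(scattering_theta0(float(e_node), el.medium, el.length_cm))
                    t2 = t0 * t0
                for pl in ("x", "y"):
                    vp, cv, va = state[pl]
                    state[pl] = [
                        vp + 2 * cv * L + va * L * L + t2 * L * L / 3.0,
                        cv + va * L + t2 * L / 2.0,
                        va + t2,
                    ]
            elif el.kind == "slab":
                t0 = float(
                    scattering_theta0(float(e_node), el.material, el.thickness_mm * 0.1)
                )
                for pl in ("x", "y"):
                    state[pl][2] = state[pl][2] + t0 * t0
            elif el.kind == "quadrupole":
                L = el.length_cm * 1e-2
                if el.scannable:
                    B = scanned[idx[quad_counter]]
                    focus = planes[(quad_counter + arrangement) % 2]
                    quad_counter += 1
                else:
                    B = el.field_T
                    focus = el.focus_plane
                k = quad_strength(replace(el, field_T=1.0), float(e_node)) * np.asarray(B, float)
                for pl, name in (("x", "horizontal"), ("y", "vertical")):
                    vp, cv, va = state[pl]
                    state[pl] = list(
                        _quad_plane_update(vp, cv, va, k, L, focusing=(focus == name))
                    )
            # dipole kicks / monitors: no envelope effect
        for pl in ("x", "y"):
            mix[pl] = mix[pl] + w * state[pl][0]
    h = FWHM_FACTOR * np.sqrt(np.maximum(mix["x"], 0.0))
    v = FWHM_FACTOR * np.sqrt(np.maximum(mix["y"], 0.0))
    return h, v


@dataclass
class QuadScanResult:
    """Complete scan record: one row per (B1, B2, arrangement) configuration."""

    table: pd.DataFrame
    fields: tuple[np.ndarray, np.ndarray]
    nozzle: NozzleConfig
    source: BeamSource
    spec: QuadScanSpec

    @property
    def argmin_row(self) -> pd.Series:
        refined = self.table[self.table["refined"]]
        pool = refined if len(refined) else self.table
        om = pool["omega"].to_numpy()
        best = om.min()
        # ties toward the lowest (B1, B2) pair
        cand = pool[np.isclose(pool["omega"], best, rtol=0, atol=1e-12)]
        cand = cand.sort_values(["B1", "B2", "arrangement"])
        return cand.iloc[0]


def _config_seed(base_seed: int, i1: int, i2: int, arrangement: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(i1, i2, arrangement))


def _mc_fwhms(
    nozzle: NozzleConfig,
    source: BeamSource,
    n: int,
    seed: np.random.SeedSequence,
) -> tuple[float, float, float, float]:
    child = seed.spawn(2)
    bundle = sample_particles(source, n, child[0])
    final = track_particles(bundle, nozzle, child[1])[-1]
    ph = fit_gaussian_fwhm(final.x, "horizontal", final.z)
    pv = fit_gaussian_fwhm(final.y, "vertical", final.z)
    return ph.fwhm, pv.fwhm, ph.fwhm_err, pv.fwhm_err


def scan_quadrupoles(
    nozzle: NozzleConfig, source: BeamSource, spec: QuadScanSpec | None = None
) -> QuadScanResult:
    """Evaluate every quadrupole configuration and refine the best by MC.

    The envelope mode ranks all configurations; the top
    ``spec.refine_fraction`` (at least one, always including the envelope
    argmin) are re-simulated with ``spec.n_particles`` tracked protons and
    Gaussian-fitted widths.  Per-configuration random seeds derive from
    ``(base_seed, i1, i2, arrangement)``, so the scan is reproducible and
    the streams are uncorrelated.
    """
    spec = spec or QuadScanSpec()
    grids = spec.grids_for(nozzle)
    n1, n2 = len(grids[0]), len(grids[1])

    rows = []
    for arr in spec.arrangements:
        h, v = envelope_target_fwhms(nozzle, source, grids, arr, spec.n_energy_nodes)
        i1, i2 = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "i1": i1.ravel(),
                    "i2": i2.ravel(),
                    "arrangement": arr,
                    "B1": grids[0][i1.ravel()],
                    "B2": grids[1][i2.ravel()],
                    "h_fwhm_env": h,
                    "v_fwhm_env": v,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["omega_env"] = table["h_fwhm_env"] ** 2 + table["v_fwhm_env"] ** 2
    table["refined"] = False
    table["h_fwhm"] = table["h_fwhm_env"]
    table["v_fwhm"] = table["v_fwhm_env"]
    table["h_err"] = 0.0
    table["v_err"] = 0.0
    table["omega"] = table["omega_env"]

    n_refine = 0
    if spec.refine_fraction > 0 and spec.n_particles > 0:
        n_refine = max(1, int(math.ceil(spec.refine_fraction * len(table))))
    if n_refine:
        order = np.argsort(table["omega_env"].to_numpy(), kind="stable")[:n_refine]
        for ridx in order:
            row = table.iloc[ridx]
            cfg = nozzle.with_quad_settings(
                (row["B1"], row["B2"]), int(row["arrangement"])
            )
            seed = _config_seed(
                spec.base_seed, int(row["i1"]), int(row["i2"]), int(row["arrangement"])
            )
            hf, vf, he, ve = _mc_fwhms(cfg, source, spec.n_particles, seed)
            table.loc[table.index[ridx], ["h_fwhm", "v_fwhm", "h_err", "v_err"]] = (
                hf, vf, he, ve,
            )
            table.loc[table.index[ridx], "refined"] = True
            table.loc[table.index[ridx], "omega"] = omega(hf, vf)
    return QuadScanResult(table=table, fields=grids, nozzle=nozzle, source=source, spec=spec)


def select_minimum(result: QuadScanResult) -> tuple[dict, float, float]:
    """Minimum-Omega configuration and its (hFWHM, vFWHM).

    Ties are broken toward the lowest (B1, B2) pair.
    """
    if len(result.table) == 0:
        raise ValueError("empty scan result")
    row = result.argmin_row
    config = {
        "B1": float(row["B1"]),
        "B2": float(row["B2"]),
        "arrangement": int(row["arrangement"]),
    }
    return config, float(row["h_fwhm"]), float(row["v_fwhm"])


def default_source_variations(source: BeamSource, fraction: float = 0.1) -> list[BeamSource]:
    """Default beam-model variations: divergences scaled by +-10%."""
    out = []
    for f in (1.0 - fraction, 1.0 + fraction):
        out.append(replace(source, div_x=source.div_x * f, div_y=source.div_y * f))
    return out


@dataclass(frozen=True)
class ScanUncertainty:
    """Asymmetric (lower, upper) uncertainty on the minimum FWHM, per plane."""

    h: tuple[float, float]
    v: tuple[float, float]


def _grid_neighbour_variation(result: QuadScanResult, col: str) -> float:
    """Max |FWHM difference| over the 8 grid neighbours of the argmin cell."""
    row = result.argmin_row
    i1, i2, arr = int(row["i1"]), int(row["i2"]), int(row["arrangement"])
    t = result.table
    base = float(row[f"{col}_env"])
    best = 0.0
    for d1 in (-1, 0, 1):
        for d2 in (-1, 0, 1):
            if d1 == 0 and d2 == 0:
                continue
            m = (t["i1"] == i1 + d1) & (t["i2"] == i2 + d2) & (t["arrangement"] == arr)
            if m.any():
                best = max(best, abs(float(t.loc[m, f"{col}_env"].iloc[0]) - base))
    return best


def estimate_uncertainty(
    result: QuadScanResult,
    source_variations: list[BeamSource] | None = None,
    fit_errors: tuple[float, float] | None = None,
) -> ScanUncertainty:
    """Three-contribution uncertainty on the minimum beam size.

    Contributions per plane: (i) spread of the scan minima over the
    source-parameter variations (both sides), (ii) local envelope beam-size
    variation around the minimum grid cell (upper side only — the discrete
    grid can only overestimate the true minimum), (iii) profile-fit error
    (both sides).  Sides combine as the root of the sum of squares.
    """
    if source_variations is None:
        source_variations = default_source_variations(result.source)
    row = result.argmin_row
    if fit_errors is None:
        fit_errors = (float(row["h_err"]), float(row["v_err"]))

    # (i): envelope-only scans for each varied source (fast, same grid)
    base = {"h": float(row["h_fwhm"]), "v": float(row["v_fwhm"])}
    lows = {"h": 0.0, "v": 0.0}
    highs = {"h": 0.0, "v": 0.0}
    env_spec = replace(result.spec, refine_fraction=0.0)
    for s in source_variations:
        r = scan_quadrupoles(result.nozzle, s, env_spec)
        _, hv, vv = select_minimum(r)
        for key, val in (("h", hv), ("v", vv)):
            lows[key] = max(lows[key], max(base[key] - val, 0.0))
            highs[key] = max(highs[key], max(val - base[key], 0.0))

    out = {}
    for key, col, ferr in (("h", "h_fwhm", fit_errors[0]), ("v", "v_fwhm", fit_errors[1])):
        grid = _grid_neighbour_variation(result, col)
        lower = math.sqrt(lows[key] ** 2 + ferr**2)
        upper = math.sqrt(highs[key] ** 2 + grid**2 + ferr**2)
        out[key] = (lower, upper)
    return ScanUncertainty(h=out["h"], v=out["v"])
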