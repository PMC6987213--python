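"""Source-parametrisation feasibility benchmark and beam-model calibration.

Two desk-scale reimplementations of the beam-model studies:

* **Feasibility benchmark** — enumerate bi-Gaussian source parametrisations
  (sizes x divergences^2 x correlations^2; the full default grid holds
  9 * 8 * 8 * 11 * 11 = 69 696 sources) and, for each (divergence,
  correlation) cell of one transverse plane, find the minimum achievable
  FWHM at the target over the quadrupole grid scan, minimised over the
  remaining axes.  Cells at or below 1 mm form the minibeam-feasible mask.
* **Calibration** — given a table of measured beam sizes at five positions
  around the isocentre for a set of energies (sizes at the first
  monitoring chamber fixing sigma), grid-search divergence and correlation
  per plane to minimise the mean squared relative deviation between
  simulated and measured sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam_source import BeamSource, make_source, source_moments
from .optimizer import QuadScanSpec, envelope_target_fwhms
from .transport import NozzleConfig, propagate_moments

__all__ = [
    "ParametrisationGrid",
    "FeasibilityMap",
    "MeasuredSizeTable",
    "CalibrationResult",
    "enumerate_parametrisations",
    "feasibility_map",
    "calibrate_source",
]


def _default_size_pairs() -> tuple[tuple[float, float], ...]:
    vals = (3.0, 9.0, 15.0)
    return tuple(itertools.product(vals, vals))


@dataclass(frozen=True)
class ParametrisationGrid:
    """Axes of the source-parametrisation benchmark.

    Defaults reproduce the full benchmark: nine (sigma_x, sigma_y) pairs
    spanning 3-15 mm, eight divergence values log-evenly covering
    0.1-15 mrad and eleven evenly spaced correlation coefficients in
    [-1, +1] — 69 696 parametrisations in total.  Use :meth:`small` for a
    desk-scale grid.
    """

    size_pairs_mm: tuple[tuple[float, float], ...] = field(default_factory=_default_size_pairs)
    divergences_mrad: tuple[float, ...] = tuple(np.geomspace(0.1, 15.0, 8).round(4))
    correlations: tuple[float, ...] = tuple(np.linspace(-1.0, 1.0, 11).round(10))

    def __post_init__(self) -> None:
        if not (self.size_pairs_mm and self.divergences_mrad and self.correlations):
            raise ValueError("every benchmark axis needs at least one value")
        for sx, sy in self.size_pairs_mm:
            if not (3.0 <= sx <= 15.0 and 3.0 <= sy <= 15.0):
                raise ValueError("beam sizes must lie in 3-15 mm")
        for d in self.divergences_mrad:
            if not 0.1 <= d <= 15.0:
                raise ValueError("divergences must lie in 0.1-15 mrad")
        for r in self.correlations:
            if abs(r) > 1:
                raise ValueError("correlations must lie in [-1, +1]")

    @classmethod
    def small(cls) -> "ParametrisationGrid":
        """Scaled-down grid (3 x 4 x 4 x 5 x 5) for quick runs and CI."""
        sizes = ((3.0, 3.0), (9.0, 9.0), (15.0, 15.0))
        return cls(
            size_pairs_mm=sizes,
            divergences_mrad=tuple(np.geomspace(0.1, 15.0, 4).round(4)),
            correlations=tuple(np.linspace(-1.0, 1.0, 5).round(10)),
        )

    @property
    def count(self) -> int:
        return (
            len(self.size_pairs_mm)
            * len(self.divergences_mrad) ** 2
            * len(self.correlations) ** 2
        )


def enumerate_parametrisations(
    grid: ParametrisationGrid, energy: float = 100.0, energy_spread: float = 0.01
) -> list[BeamSource]:
    """Full Cartesian product of the benchmark axes, in deterministic order
    (sizes, div_x, div_y, r_x, r_y innermost-last)."""
    out = []
    for (sx, sy), dx, dy, rx, ry in itertools.product(
        grid.size_pairs_mm,
        grid.divergences_mrad,
        grid.divergences_mrad,
        grid.correlations,
        grid.correlations,
    ):
        out.append(
            make_source(energy, energy_spread, sx, sy, dx, dy, rx, ry)
        )
    return out


@dataclass
class FeasibilityMap:
    """Minimum achievable FWHM per (divergence, correlation) cell, one plane."""

    plane: str
    divergences_mrad: np.ndarray
    correlations: np.ndarray
    min_fwhm_mm: np.ndarray  # shape (n_div, n_corr)

    @property
    def minibeam_mask(self) -> np.ndarray:
        return self.min_fwhm_mm <= 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.min_fwhm_mm,
            index=pd.Index(self.divergences_mrad, name="divergence_mrad"),
            columns=pd.Index(self.correlations, name="correlation"),
        )


def feasibility_map(
    nozzle: NozzleConfig,
    energy: float,
    grid: ParametrisationGrid,
    scan_spec: QuadScanSpec | None = None,
    energy_spread: float = 0.01,
) -> dict[str, FeasibilityMap]:
    """Minimum-FWHM maps over (divergence, correlation), per plane.

    Because the horizontal and vertical planes are uncoupled, each plane's
    map is computed from that plane's source parameters alone, minimising
    over the initial beam sizes and the full quadrupole field grid (fast
    envelope mode; both focus-plane arrangements).
    """
    scan_spec = scan_spec or QuadScanSpec()
    grids = scan_spec.grids_for(nozzle)
    out: dict[str, FeasibilityMap] = {}
    for plane in ("horizontal", "vertical"):
        sizes = sorted({p[0] if plane == "horizontal" else p[1] for p in grid.size_pairs_mm})
        nd, nc = len(grid.divergences_mrad), len(grid.correlations)
        fmap = np.full((nd, nc), np.inf)
        for i, d in enumerate(grid.divergences_mrad):
            for j, r in enumerate(grid.correlations):
                best = np.inf
                for s in sizes:
                    src = make_source(energy, energy_spread, s, s, d, d, r, r)
                    for arr in scan_spec.arrangements:
                        h, v = envelope_target_fwhms(
                            nozzle, src, grids, arr, scan_spec.n_energy_nodes
                        )
                        vals = h if plane == "horizontal" else v
                        best = min(best, float(vals.min()))
                fmap[i, j] = best
        out[plane] = FeasibilityMap(
            plane=plane,
            divergences_mrad=np.asarray(grid.divergences_mrad),
            correlations=np.asarray(grid.correlations),
            min_fwhm_mm=fmap,
        )
    return out


@dataclass
class MeasuredSizeTable:
    """Measured Gaussian beam sizes at positions around the isocentre.

    Wraps a complete (energy x position) grid with columns ``energy_MeV``,
    ``position_cm``, ``sigma_x_mm``, ``sigma_y_mm`` and optional
    ``sigma_err_mm``.
    """

    data: pd.DataFrame

    REQUIRED = ("energy_MeV", "position_cm", "sigma_x_mm", "sigma_y_mm")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"measured-size table missing column {col!r}")
        if (self.data[["sigma_x_mm", "sigma_y_mm"]] <= 0).any().any():
            raise ValueError("measured sigmas must be > 0")
        counts = self.data.groupby("energy_MeV")["position_cm"].nunique()
        if counts.nunique() != 1:
            raise ValueError("incomplete table: every energy needs the same positions")

    @property
    def energies(self) -> np.ndarray:
        return np.sort(self.data["energy_MeV"].unique())

    @property
    def positions(self) -> np.ndarray:
        return np.sort(self.data["position_cm"].unique())

    @classmethod
    def from_csv(cls, path) -> "MeasuredSizeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class CalibrationResult:
    """Best-fit source and per-plane goodness of fit for one energy."""

    source: BeamSource
    mean_rel_dev_x_pct: float
    mean_rel_dev_y_pct: float
    objective: float  # mean squared relative deviation, both planes


def _monitor_sigmas(
    source: BeamSource, nozzle: NozzleConfig, positions_cm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model sigma_x, sigma_y at the monitors nearest the given positions."""
    mons = propagate_moments(source_moments(source), nozzle, source.energy)
    zs = np.array([m.z for m in mons])
    sx = np.array([math.sqrt(m.x.var_pos) for m in mons])
    sy = np.array([math.sqrt(m.y.var_pos) for m in mons])
    # positions are relative to the isocentre; monitors carry absolute z
    iso = nozzle.target_z_cm if nozzle.preset == "custom" else 250.0
    want = iso + np.asarray(positions_cm, float)
    idx = [int(np.argmin(np.abs(zs - w))) for w in want]
    if max(abs(zs[i] - w) for i, w in zip(idx, want)) > 1.0:
        raise ValueError("nozzle lacks monitor planes at the measured positions")
    return sx[idx], sy[idx]


def calibrate_source(
    measured: MeasuredSizeTable,
    nozzle: NozzleConfig,
    search_space: ParametrisationGrid,
    source_sigmas: dict[float, tuple[float, float]],
) -> dict[float, CalibrationResult]:
    """Best-fit divergence and correlation per plane and energy.

    ``source_sigmas`` fixes the source sizes (taken as given from the
    monitoring-chamber measurement); the (divergence, correlation) pair of
    each plane is grid-searched over ``search_space`` to minimise the mean
    squared relative deviation between the simulated and measured sigmas
    at the five positions.  Quadrupoles stay at their configured fields.
    """
    results: dict[float, CalibrationResult] = {}
    positions = measured.positions
    for energy in measured.energies:
        sub = measured.data[measured.data["energy_MeV"] == energy].sort_values("position_cm")
        meas_x = sub["sigma_x_mm"].to_numpy()
        meas_y = sub["sigma_y_mm"].to_numpy()
        if float(energy) not in source_sigmas:
            raise ValueError(f"source_sigmas missing energy {energy}")
        sx0, sy0 = source_sigmas[float(energy)]
        best = {"x": (None, np.inf), "y": (None, np.inf)}
        for d in search_space.divergences_mrad:
            for r in search_space.correlations:
                src = make_source(float(energy), 0.0, sx0, sy0, d, d, r, r)
                mx, my = _monitor_sigmas(src, nozzle, positions)
                ox = float(np.mean(((mx - meas_x) / meas_x) ** 2))
                oy = float(np.mean(((my - meas_y) / meas_y) ** 2))
                if ox < best["x"][1]:
                    best["x"] = ((d, r), ox)
                if oy < best["y"][1]:
                    best["y"] = ((d, r), oy)
        (dx, rx), obj_x = best["x"]
        (dy, ry), obj_y = best["y"]
        fit = make_source(float(energy), 0.0, sx0, sy0, dx, dy, rx, ry)
        mx, my = _monitor_sigmas(fit, nozzle, positions)
        results[float(energy)] = CalibrationResult(
            source=fit,
            mean_rel_dev_x_pct=100.0 * float(np.mean(np.abs(mx - meas_x) / meas_x)),
            mean_rel_dev_y_pct=100.0 * float(np.mean(np.abs(my - meas_y) / meas_y)),
            objective=(obj_x + obj_y) / 2.0,
        )
    return results
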