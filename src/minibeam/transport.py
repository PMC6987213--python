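"""Nozzle beamline transport: quadrupole optics, scattering media, tracking.

The beamline is an ordered sequence of elements (drifts in vacuum or air,
hard-edge quadrupoles, thin dipole kicks, thin material slabs and
zero-length monitor planes).  Two transport engines operate on it:

* :func:`propagate_moments` — analytic second-moment (sigma-matrix /
  Fermi-Eyges) transport.  Vacuum elements act through their transfer
  matrices; media add the Highland multiple-Coulomb-scattering moment
  increments.  Chromatic effects of a finite energy spread are handled by
  Gauss-Hermite quadrature over the energy distribution.
* :func:`track_particles` — Monte-Carlo tracking of sampled bundles with
  per-particle (chromatic) transfer maps and correlated Gaussian
  scattering kicks.

Energy loss in air is negligible for the optics (< 0.3 MeV per metre) and
is ignored here; it is modelled inside the water phantom by the dose
engine.

The geometry of the clinical-centre nozzle is not public; the presets in
:func:`build_nozzle` encode an assumed geometry with stated element
positions and material budgets (see ``docs/methods.md``), all overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .beam_source import (
    BeamMoments,
    ParticleBundle,
    PlaneMoments,
    beta_pc_mev,
    momentum_mev,
)

__all__ = [
    "BeamlineElement",
    "NozzleConfig",
    "RADIATION_LENGTH_CM",
    "build_nozzle",
    "quad_matrix",
    "scattering_theta0",
    "propagate_moments",
    "track_particles",
    "drift",
    "quadrupole",
    "dipole_kick",
    "slab",
    "monitor",
]

#: Radiation lengths in cm (PDG values; air at sea-level density 1.205 mg/cm^3).
RADIATION_LENGTH_CM: dict[str, float] = {
    "air": 30390.0,
    "water": 36.08,
    "polyimide": 28.6,
}

_SPEED_FACTOR = 299.792458  # B*rho [T m] = pc [MeV] / this


@dataclass(frozen=True)
class BeamlineElement:
    """One element of the nozzle beamline.

    ``length_cm`` is the geometric length along the axis.  Slabs are thin:
    they carry a material and thickness for scattering but zero geometric
    length (fold any real extent into the neighbouring drift).
    """

    kind: str  # drift | quadrupole | dipole_kick | slab | monitor
    name: str = ""
    length_cm: float = 0.0
    medium: str = "vacuum"  # for drifts: vacuum | air
    # quadrupole
    field_T: float = 0.0
    aperture_cm: float = 5.0
    focus_plane: str = "horizontal"
    scannable: bool = False
    max_field_T: float = 2.0
    # dipole kick
    kick_x_mrad: float = 0.0
    kick_y_mrad: float = 0.0
    # slab
    material: str = "water"
    thickness_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"drift", "quadrupole", "dipole_kick", "slab", "monitor"}:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.length_cm < 0:
            raise ValueError("length must be >= 0")
        if self.kind == "quadrupole":
            if self.field_T < 0:
                raise ValueError("pole-tip field must be >= 0")
            if not self.aperture_cm > 0:
                raise ValueError("aperture radius must be > 0")
            if self.focus_plane not in {"horizontal", "vertical"}:
                raise ValueError("focus_plane must be horizontal or vertical")
        if self.kind == "drift" and self.medium not in RADIATION_LENGTH_CM and self.medium != "vacuum":
            raise ValueError(f"unknown drift medium {self.medium!r}")
        if self.kind == "slab" and self.material not in RADIATION_LENGTH_CM:
            raise ValueError(f"unknown slab material {self.material!r}")


def drift(length_cm: float, medium: str = "vacuum", name: str = "") -> BeamlineElement:
    return BeamlineElement(kind="drift", length_cm=length_cm, medium=medium, name=name)


def quadrupole(
    length_cm: float = 30.0,
    field_T: float = 0.0,
    aperture_cm: float = 5.0,
    focus_plane: str = "horizontal",
    name: str = "Q",
    scannable: bool = True,
    max_field_T: float = 2.0,
) -> BeamlineElement:
    return BeamlineElement(
        kind="quadrupole",
        length_cm=length_cm,
        field_T=field_T,
        aperture_cm=aperture_cm,
        focus_plane=focus_plane,
        name=name,
        scannable=scannable,
        max_field_T=max_field_T,
    )


def dipole_kick(kick_x_mrad: float = 0.0, kick_y_mrad: float = 0.0, name: str = "SM") -> BeamlineElement:
    return BeamlineElement(kind="dipole_kick", kick_x_mrad=kick_x_mrad, kick_y_mrad=kick_y_mrad, name=name)


def slab(thickness_mm: float, material: str = "water", name: str = "") -> BeamlineElement:
    return BeamlineElement(kind="slab", thickness_mm=thickness_mm, material=material, name=name)


def monitor(name: str) -> BeamlineElement:
    return BeamlineElement(kind="monitor", name=name)


@dataclass(frozen=True)
class NozzleConfig:
    """Ordered beamline with a target plane.

    ``target_z_cm`` must lie at or after the end of the last element; the
    region between the last element and the target is treated as a drift in
    ``target_medium``.
    """

    elements: tuple[BeamlineElement, ...]
    target_z_cm: float
    target_medium: str = "air"
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.target_z_cm < self.length_cm - 1e-9:
            raise ValueError("target_z must lie at or after the last element")

    @property
    def length_cm(self) -> float:
        return float(sum(e.length_cm for e in self.elements))

    def element_entrances_cm(self) -> np.ndarray:
        """z position (cm) at which each element starts."""
        lengths = [e.length_cm for e in self.elements]
        return np.concatenate([[0.0], np.cumsum(lengths)[:-1]])

    @property
    def monitors(self) -> dict[str, float]:
        out = {}
        for z, e in zip(self.element_entrances_cm(), self.elements):
            if e.kind == "monitor":
                out[e.name] = float(z)
        out["target"] = self.target_z_cm
        return out

    def scannable_quads(self) -> list[int]:
        return [i for i, e in enumerate(self.elements) if e.kind == "quadrupole" and e.scannable]

    def dipole_positions_cm(self) -> dict[str, float]:
        return {
            e.name: float(z)
            for z, e in zip(self.element_entrances_cm(), self.elements)
            if e.kind == "dipole_kick"
        }

    def with_quad_settings(
        self, fields_T: tuple[float, ...], arrangement: int
    ) -> "NozzleConfig":
        """Copy with scannable-quad fields set and focus planes assigned.

        ``arrangement`` 0: first scannable quad focusses horizontally, next
        vertically (alternating); 1: the opposite assignment.
        """
        idx = self.scannable_quads()
        if len(fields_T) != len(idx):
            raise ValueError(f"expected {len(idx)} field values, got {len(fields_T)}")
        planes = ["horizontal", "vertical"]
        new = list(self.elements)
        for j, (i, b) in enumerate(zip(idx, fields_T)):
            if b < 0:
                raise ValueError("pole-tip field must be >= 0")
            plane = planes[(j + arrangement) % 2]
            new[i] = replace(new[i], field_T=float(b), focus_plane=plane)
        return replace(self, elements=tuple(new))

    def with_dipole_kicks(self, kicks: dict[str, tuple[float, float]]) -> "NozzleConfig":
        """Copy with named dipole kicks (kick_x, kick_y in mrad) applied."""
        new = list(self.elements)
        for i, e in enumerate(new):
            if e.kind == "dipole_kick" and e.name in kicks:
                kx, ky = kicks[e.name]
                new[i] = replace(e, kick_x_mrad=kx, kick_y_mrad=ky)
        return replace(self, elements=tuple(new))


# ---------------------------------------------------------------------------
# Nozzle presets (assumed geometry, see docs/methods.md)
# ---------------------------------------------------------------------------

_PRESETS = ("icpo_current", "icpo_mod1", "icpo_mod2", "icpo_mod3", "optimized")

#: water-equivalent thickness of one transmission ionisation chamber (mm)
IC_WET_MM = 1.0
#: polyimide vacuum-window thickness (mm)
VW_MM = 0.1
#: combined exit-window + thin transmission IC of the compact optimised
#: nozzle (mm water-equivalent)
OPTIMIZED_IC_WET_MM = 0.5


def build_nozzle(
    preset: str,
    air_gap_cm: float = 10.0,
    target_offset_cm: float = 0.0,
    focal_length_cm: float = 100.0,
    quad_length_cm: float = 30.0,
    aperture_cm: float = 5.0,
) -> NozzleConfig:
    """Build one of the nozzle-geometry presets.

    Presets
    -------
    ``icpo_current``
        Clinical pencil-beam-scanning nozzle: beam exits vacuum at the
        entrance window and travels ~2.5 m in air through the quadrupole
        doublet, scanning magnets and two ionisation chambers to the
        isocentre.  ``target_offset_cm`` places the target relative to the
        isocentre (-40 ... +40 cm are the monitored positions).
    ``icpo_mod1``
        Same, with every drift evacuated (the IC gas volumes remain).
    ``icpo_mod2``
        Snout and field mirror removed; shortened path, target 20 cm after
        the last monitoring chamber.
    ``icpo_mod3``
        Extra quadrupole pair (XQ1/XQ2, pole-tip fields up to 4 T) close to
        the target; the second chamber moves downstream of them.  Only the
        extra pair is scanned.
    ``optimized``
        Compact design: evacuated tank with the doublet and scanning
        magnets, one thin exit chamber and a short air gap (10 or 30 cm).
        The focal length — exit plane of Q2 to target — defaults to 100 cm
        (middle of the 90-110 cm design band).
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    if air_gap_cm < 0:
        raise ValueError("air gap must be >= 0")

    if preset == "optimized":
        if not 90.0 <= focal_length_cm <= 110.0:
            raise ValueError("focal length must lie in the 90-110 cm design band")
        if air_gap_cm not in (10.0, 30.0) and air_gap_cm > focal_length_cm - 25.0:
            raise ValueError("air gap too long for the focal-length band")
        # The tank upstream of Q1 is long enough that clinical correlated
        # beams (|r| ~ 1, waist at sigma/x' ~ 1.3-2 m from the entrance)
        # pass their waist inside the tank; the doublet then images the
        # waist onto the target.  The beam leaves vacuum only at the thin
        # exit window + transmission chamber at the start of the air gap.
        tank_cm = 160.0
        q2_exit = tank_cm + 2 * quad_length_cm + 10.0
        target_z = q2_exit + focal_length_cm
        vac_after_sm2 = target_z - air_gap_cm - (q2_exit + 25.0)
        if vac_after_sm2 < 0:
            raise ValueError("air gap overlaps the scanning magnets")
        elements = (
            drift(tank_cm, "vacuum"),
            quadrupole(quad_length_cm, aperture_cm=aperture_cm, name="Q1"),
            drift(10.0, "vacuum"),
            quadrupole(quad_length_cm, aperture_cm=aperture_cm, name="Q2"),
            drift(10.0, "vacuum"),
            dipole_kick(name="SM1"),
            drift(15.0, "vacuum"),
            dipole_kick(name="SM2"),
            drift(vac_after_sm2, "vacuum"),
            slab(OPTIMIZED_IC_WET_MM, "water", name="IC"),
            monitor("IC"),
        )
        return NozzleConfig(
            elements=elements,
            target_z_cm=target_z + target_offset_cm,
            target_medium="air",
            preset=preset,
        )

    # --- clinical nozzle family -------------------------------------------
    medium = "vacuum" if preset == "icpo_mod1" else "air"
    iso = 250.0
    head = [
        slab(VW_MM, "polyimide", name="VW"),
        drift(10.0, medium),
        quadrupole(quad_length_cm, aperture_cm=aperture_cm, name="Q1",
                   scannable=preset != "icpo_mod3"),
        drift(10.0, medium),
        quadrupole(quad_length_cm, aperture_cm=aperture_cm, name="Q2",
                   scannable=preset != "icpo_mod3"),
        drift(20.0, medium),
        dipole_kick(name="SM1"),
        drift(15.0, medium),
        dipole_kick(name="SM2"),
        drift(15.0, medium),
        slab(IC_WET_MM, "water", name="IC1"),
        monitor("IC1"),
    ]
    head_len = 130.0  # z after IC1 for quad_length_cm = 30

    if preset == "icpo_mod3":
        tail = [
            drift(30.0, medium),
            quadrupole(quad_length_cm, aperture_cm=aperture_cm, name="XQ1",
                       scannable=True, max_field_T=4.0),
            drift(10.0, medium),
            quadrupole(quad_length_cm, aperture_cm=aperture_cm, name="XQ2",
                       scannable=True, max_field_T=4.0),
            drift(10.0, medium),
            slab(IC_WET_MM, "water", name="IC2"),
            monitor("IC2"),
        ]
        tail_end = head_len + 110.0
        target_z = iso + target_offset_cm
    elif preset == "icpo_mod2":
        tail = [
            drift(70.0, medium),
            slab(IC_WET_MM, "water", name="IC2"),
            monitor("IC2"),
        ]
        tail_end = head_len + 70.0
        # snout removed: target only 20 cm after IC2
        target_z = tail_end + 20.0 + target_offset_cm
    else:
        tail = [
            drift(70.0, medium),
            slab(IC_WET_MM, "water", name="IC2"),
            monitor("IC2"),
        ]
        tail_end = head_len + 70.0
        target_z = iso + target_offset_cm

    elements = head + tail
    z = tail_end
    # monitored positions around the isocentre that fit before the target
    if preset in ("icpo_current", "icpo_mod1", "icpo_mod3"):
        for off in (-40.0, -20.0, 0.0, 20.0, 40.0):
            pos = iso + off
            if z < pos <= target_z + 1e-9:
                elements.append(drift(pos - z, medium))
                elements.append(monitor(f"pos_{off:+.0f}"))
                z = pos
    if target_z < z - 1e-9:
        raise ValueError("target offset places the target inside the beamline")
    return NozzleConfig(
        elements=tuple(elements),
        target_z_cm=target_z,
        target_medium=medium,
        preset=preset,
    )


# ---------------------------------------------------------------------------
# Element physics
# ---------------------------------------------------------------------------

def quad_strength(element: BeamlineElement, energy: float | np.ndarray) -> float | np.ndarray:
    """Quadrupole strength k (1/m^2): gradient over magnetic rigidity.

    The gradient is pole-tip field / aperture radius; rigidity is pc/q.
    """
    if not element.aperture_cm > 0:
        raise ValueError("aperture radius must be > 0")
    gradient = element.field_T / (element.aperture_cm * 1e-2)  # T/m
    rigidity = momentum_mev(energy) / _SPEED_FACTOR  # T m
    return gradient / rigidity


def _plane_matrix(k: float, length_m: float, focusing: bool) -> np.ndarray:
    if k <= 0:
        return np.array([[1.0, length_m], [0.0, 1.0]])
    rk = math.sqrt(k)
    phi = rk * length_m
    if focusing:
        return np.array(
            [[math.cos(phi), math.sin(phi) / rk], [-rk * math.sin(phi), math.cos(phi)]]
        )
    return np.array(
        [[math.cosh(phi), math.sinh(phi) / rk], [rk * math.sinh(phi), math.cosh(phi)]]
    )


def quad_matrix(element: BeamlineElement, energy: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-plane 2x2 hard-edge quadrupole transfer maps ``(Mx, My)``.

    Units: positions mm, angles mrad, so matrix off-diagonals carry metres.
    The focussing plane uses the cos/sin form, the defocussing plane
    cosh/sinh; each has unit determinant.
    """
    if element.kind != "quadrupole":
        raise ValueError("element is not a quadrupole")
    if not energy > 0:
        raise ValueError("energy must be > 0")
    k = float(quad_strength(element, energy))
    L = element.length_cm * 1e-2
    horizontal_focus = element.focus_plane == "horizontal"
    return (
        _plane_matrix(k, L, focusing=horizontal_focus),
        _plane_matrix(k, L, focusing=not horizontal_focus),
    )


def scattering_theta0(
    energy: float | np.ndarray, material: str, thickness_cm: float
) -> float | np.ndarray:
    """Highland RMS multiple-scattering angle (mrad) for protons.

    ``theta0 = (13.6 MeV / pv) * sqrt(t/X0) * (1 + 0.038 ln(t/X0))``, with
    the logarithmic factor clamped at zero for extremely thin layers.
    Returns 0 for zero thickness.
    """
    if thickness_cm < 0:
        raise ValueError("thickness must be >= 0")
    if material not in RADIATION_LENGTH_CM:
        raise ValueError(f"unknown material {material!r}")
    if thickness_cm == 0:
        return 0.0 if np.isscalar(energy) else np.zeros_like(np.asarray(energy, float))
    t = thickness_cm / RADIATION_LENGTH_CM[material]
    log_factor = max(1.0 + 0.038 * math.log(t), 0.0)
    theta = (13.6 / beta_pc_mev(energy)) * math.sqrt(t) * log_factor * 1e3
    return theta


# ---------------------------------------------------------------------------
# Envelope transport (Fermi-Eyges)
# ---------------------------------------------------------------------------

def _apply_matrix(m: PlaneMoments, M: np.ndarray) -> PlaneMoments:
    a, b = M[0]
    c, d = M[1]
    return PlaneMoments(
        var_pos=a * a * m.var_pos + 2 * a * b * m.cov_pos_ang + b * b * m.var_ang,
        cov_pos_ang=a * c * m.var_pos + (a * d + b * c) * m.cov_pos_ang + b * d * m.var_ang,
        var_ang=c * c * m.var_pos + 2 * c * d * m.cov_pos_ang + d * d * m.var_ang,
    )


def _scattering_drift(m: PlaneMoments, L_m: float, theta0: float) -> PlaneMoments:
    """Drift of length L (m) through a uniform scatterer with total RMS
    angle ``theta0`` (mrad): exact Gaussian (Fermi-Eyges) moment update."""
    t2 = theta0 * theta0
    return PlaneMoments(
        var_pos=m.var_pos + 2 * m.cov_pos_ang * L_m + m.var_ang * L_m**2 + t2 * L_m**2 / 3.0,
        cov_pos_ang=m.cov_pos_ang + m.var_ang * L_m + t2 * L_m / 2.0,
        var_ang=m.var_ang + t2,
    )


def _walk_moments(
    moments: BeamMoments, nozzle: NozzleConfig, energy: float
) -> list[BeamMoments]:
    """Monochromatic envelope walk; records moments at monitors + target."""
    mx, my = moments.x, moments.y
    z = 0.0
    out: list[BeamMoments] = []
    elements = list(nozzle.elements)
    gap = nozzle.target_z_cm - nozzle.length_cm
    if gap > 1e-12:
        elements.append(drift(gap, nozzle.target_medium))
    for e in elements:
        if e.kind == "drift":
            L = e.length_cm * 1e-2
            if e.medium == "vacuum":
                M = np.array([[1.0, L], [0.0, 1.0]])
                mx, my = _apply_matrix(mx, M), _apply_matrix(my, M)
            else:
                t0 = float(scattering_theta0(energy, e.medium, e.length_cm))
                mx = _scattering_drift(mx, L, t0)
                my = _scattering_drift(my, L, t0)
            z += e.length_cm
        elif e.kind == "quadrupole":
            Mx, My = quad_matrix(e, energy)
            mx, my = _apply_matrix(mx, Mx), _apply_matrix(my, My)
            z += e.length_cm
        elif e.kind == "slab":
            t0 = float(scattering_theta0(energy, e.material, e.thickness_mm * 0.1))
            mx = PlaneMoments(mx.var_pos, mx.cov_pos_ang, mx.var_ang + t0 * t0)
            my = PlaneMoments(my.var_pos, my.cov_pos_ang, my.var_ang + t0 * t0)
        elif e.kind == "monitor":
            out.append(BeamMoments(z=z, x=mx, y=my))
        # dipole_kick: zero-length, no effect on central moments
    out.append(BeamMoments(z=nozzle.target_z_cm, x=mx, y=my))
    return out


def gauss_hermite_energies(
    energy: float, spread: float, n_nodes: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for a Gaussian energy distribution."""
    if spread <= 0 or n_nodes == 1:
        return np.array([energy]), np.array([1.0])
    xi, wi = np.polynomial.hermite.hermgauss(n_nodes)
    energies = energy * (1.0 + math.sqrt(2.0) * spread * xi)
    weights = wi / math.sqrt(math.pi)
    keep = energies > 0
    return energies[keep], weights[keep] / weights[keep].sum()


def propagate_moments(
    moments: BeamMoments,
    nozzle: NozzleConfig,
    energy: float,
    energy_spread: float = 0.0,
    n_energy_nodes: int = 5,
) -> list[BeamMoments]:
    """Envelope transport through the nozzle.

    Returns the beam moments at every monitor plane and, last, at the
    target.  A finite fractional ``energy_spread`` is treated by
    Gauss-Hermite quadrature: the (zero-mean) mixture second moments are
    the weighted average of the monochromatic envelopes.
    """
    energies, weights = gauss_hermite_energies(energy, energy_spread, n_energy_nodes)
    walks = [_walk_moments(moments, nozzle, float(e)) for e in energies]
    out: list[BeamMoments] = []
    for i in range(len(walks[0])):
        zs = walks[0][i].z
        planes = []
        for plane in ("x", "y"):
            vp = sum(w * getattr(wk[i], plane).var_pos for w, wk in zip(weights, walks))
            cv = sum(w * getattr(wk[i], plane).cov_pos_ang for w, wk in zip(weights, walks))
            va = sum(w * getattr(wk[i], plane).var_ang for w, wk in zip(weights, walks))
            planes.append(PlaneMoments(float(vp), float(cv), float(va)))
        out.append(BeamMoments(z=zs, x=planes[0], y=planes[1]))
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo tracking
# ---------------------------------------------------------------------------

def track_particles(
    bundle: ParticleBundle,
    nozzle: NozzleConfig,
    seed: int | np.random.SeedSequence,
    max_step_cm: float = 100.0,
) -> list[ParticleBundle]:
    """Track a bundle through the nozzle; returns bundles at monitors + target.

    Magnetic elements act through per-particle transfer maps evaluated at
    each particle's own momentum (chromatic).  In scattering media a
    correlated Gaussian (angle, displacement) pair is sampled per sub-step
    of at most ``max_step_cm``; the Highland angle for the full element
    thickness is split in quadrature over sub-steps so the total scattering
    matches the single-slab Highland value.
    """
    if max_step_cm <= 0:
        raise ValueError("step must be > 0")
    rng = np.random.default_rng(seed)
    x = bundle.x.astype(float).copy()
    xp = bundle.x_prime.astype(float).copy()
    y = bundle.y.astype(float).copy()
    yp = bundle.y_prime.astype(float).copy()
    e = bundle.energy.astype(float).copy()
    n = bundle.count
    pc = momentum_mev(e) if n else np.array([])
    pv = beta_pc_mev(e) if n else np.array([])
    z = 0.0
    out: list[ParticleBundle] = []

    def record(zc: float) -> None:
        out.append(
            ParticleBundle(z=zc, x=x.copy(), x_prime=xp.copy(), y=y.copy(),
                           y_prime=yp.copy(), energy=e.copy())
        )

    elements = list(nozzle.elements)
    gap = nozzle.target_z_cm - nozzle.length_cm
    if gap > 1e-12:
        elements.append(drift(gap, nozzle.target_medium))

    for el in elements:
        if el.kind == "drift":
            n_sub = max(1, int(math.ceil(el.length_cm / max_step_cm)))
            Ls = el.length_cm / n_sub * 1e-2
            if el.medium == "vacuum" or n == 0:
                L = el.length_cm * 1e-2
                x = x + xp * L
                y = y + yp * L
            else:
                t0_full = scattering_theta0(float(np.mean(e)), el.medium, el.length_cm)
                # per-particle chromatic scaling of the mean-energy Highland angle
                scale = beta_pc_mev(float(np.mean(e))) / pv
                t0 = t0_full * scale / math.sqrt(n_sub)
                for _ in range(n_sub):
                    for u, up in ((0, 1), (2, 3)):
                        z1 = rng.standard_normal(n)
                        z2 = rng.standard_normal(n)
                        dx = t0 * Ls * (z1 / math.sqrt(12.0) + z2 / 2.0)
                        dth = t0 * z2
                        if u == 0:
                            x = x + xp * Ls + dx
                            xp = xp + dth
                        else:
                            y = y + yp * Ls + dx
                            yp = yp + dth
            z += el.length_cm
        elif el.kind == "quadrupole":
            if n:
                k = np.asarray(quad_strength(el, e), float)
                L = el.length_cm * 1e-2
                rk = np.sqrt(np.maximum(k, 1e-300))
                phi = rk * L
                with np.errstate(over="ignore"):
                    cf, sf = np.cos(phi), np.sin(phi)
                    ch, sh = np.cosh(phi), np.sinh(phi)
                free = k <= 0
                # focusing plane: cos/sin; defocusing: cosh/sinh
                def apply(u, up, focusing):
                    a = np.where(focusing, cf, ch)
                    b = np.where(focusing, sf, sh) / rk
                    c = np.where(focusing, -rk * sf, rk * sh)
                    u2 = a * u + b * up
                    up2 = c * u + a * up
                    u2 = np.where(free, u + up * L, u2)
                    up2 = np.where(free, up, up2)
                    return u2, up2

                hfoc = el.focus_plane == "horizontal"
                x, xp = apply(x, xp, hfoc)
                y, yp = apply(y, yp, not hfoc)
            z += el.length_cm
        elif el.kind == "dipole_kick":
            if n and (el.kick_x_mrad or el.kick_y_mrad):
                # magnetic deflection scales with 1/pc
                scale = momentum_mev(float(np.mean(e))) / pc
                xp = xp + el.kick_x_mrad * scale
                yp = yp + el.kick_y_mrad * scale
        elif el.kind == "slab":
            if n and el.thickness_mm > 0:
                t0_mean = scattering_theta0(float(np.mean(e)), el.material, el.thickness_mm * 0.1)
                t0 = t0_mean * beta_pc_mev(float(np.mean(e))) / pv
                xp = xp + t0 * rng.standard_normal(n)
                yp = yp + t0 * rng.standard_normal(n)
        elif el.kind == "monitor":
            record(z)
    record(nozzle.target_z_cm)
    return out
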