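"""Emittance-parametrised proton beam source.

The beam at the nozzle entrance is described by six transverse parameters —
horizontal/vertical position spreads ``sigma_x``, ``sigma_y`` (mm), angular
spreads ``div_x``, ``div_y`` (mrad) and the position-angle correlation
coefficients ``r_xx``, ``r_yy`` — plus the kinetic energy (MeV) and a
fractional Gaussian energy spread.  Positions and angles in each transverse
plane are jointly Gaussian ("bi-Gaussian" beam); the two planes are
independent.

Unit conventions used throughout the package:

* transverse positions in **mm**, angles in **mrad**
* longitudinal positions and element lengths in **cm**
* kinetic energies in **MeV**, magnetic fields in **T**

With these units a drift of length ``L`` metres maps ``x -> x + x' * L``,
i.e. transfer-matrix elements carry lengths in metres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PROTON_MASS_MEV",
    "BeamSource",
    "ParticleBundle",
    "BeamMoments",
    "make_source",
    "emittance",
    "sample_particles",
    "source_moments",
    "momentum_mev",
    "beta_pc_mev",
]

PROTON_MASS_MEV = 938.272


def momentum_mev(energy: float | np.ndarray) -> float | np.ndarray:
    """Proton momentum ``p*c`` in MeV for kinetic energy in MeV."""
    return np.sqrt(energy * (energy + 2.0 * PROTON_MASS_MEV))


def beta_pc_mev(energy: float | np.ndarray) -> float | np.ndarray:
    """``beta * p * c`` (a.k.a. ``pv``) in MeV — the multiple-scattering scale."""
    return energy * (energy + 2.0 * PROTON_MASS_MEV) / (energy + PROTON_MASS_MEV)


@dataclass(frozen=True)
class BeamSource:
    """Validated bi-Gaussian beam source at the nozzle entrance."""

    energy: float
    energy_spread: float
    sigma_x: float
    sigma_y: float
    div_x: float
    div_y: float
    r_xx: float
    r_yy: float

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValueError(f"energy must be > 0 MeV, got {self.energy}")
        if self.energy_spread < 0:
            raise ValueError(f"energy_spread must be >= 0, got {self.energy_spread}")
        for name in ("sigma_x", "sigma_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 mm, got {getattr(self, name)}")
        for name in ("div_x", "div_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 mrad, got {getattr(self, name)}")
        for name in ("r_xx", "r_yy"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, +1], got {getattr(self, name)}")


@dataclass
class ParticleBundle:
    """Sampled phase-space record at a longitudinal plane ``z`` (cm)."""

    z: float
    x: np.ndarray
    x_prime: np.ndarray
    y: np.ndarray
    y_prime: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("x_prime", "y", "y_prime", "energy"):
            if len(getattr(self, name)) != n:
                raise ValueError("all per-particle arrays must have equal length")

    @property
    def count(self) -> int:
        return len(self.x)


@dataclass
class PlaneMoments:
    """Second moments of one transverse plane: ``<x^2>``, ``<x x'>``, ``<x'^2>``."""

    var_pos: float  # mm^2
    cov_pos_ang: float  # mm * mrad
    var_ang: float  # mrad^2

    def __post_init__(self) -> None:
        if self.var_pos < -1e-12 or self.var_ang < -1e-12:
            raise ValueError("variances must be non-negative")
        # Cauchy-Schwarz with a numerical margin: transfer-map round-trips on
        # degenerate (zero-emittance) beams land exactly on the boundary
        if self.cov_pos_ang**2 > self.var_pos * self.var_ang * (1 + 1e-6) + 1e-9:
            raise ValueError("cov^2 must not exceed var_pos * var_ang")

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.var_pos, self.cov_pos_ang], [self.cov_pos_ang, self.var_ang]]
        )

    @property
    def emittance(self) -> float:
        """RMS emittance sqrt(det Sigma) in mm*mrad."""
        return float(np.sqrt(max(self.var_pos * self.var_ang - self.cov_pos_ang**2, 0.0)))


@dataclass
class BeamMoments:
    """Envelope (sigma-matrix) representation of the beam at plane ``z`` (cm)."""

    z: float
    x: PlaneMoments
    y: PlaneMoments


def make_source(
    energy: float,
    energy_spread: float,
    sigma_x: float,
    sigma_y: float,
    div_x: float,
    div_y: float,
    r_xx: float,
    r_yy: float,
) -> BeamSource:
    """Build and validate a :class:`BeamSource` (see class invariants)."""
    return BeamSource(
        energy=energy,
        energy_spread=energy_spread,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        div_x=div_x,
        div_y=div_y,
        r_xx=r_xx,
        r_yy=r_yy,
    )


def emittance(sigma: float, div: float, r: float) -> float:
    """RMS emittance of one plane, ``sigma * div * sqrt(1 - r^2)`` (mm*mrad).

    The proportionality constant is fixed to 1 (RMS product, no factor pi);
    the emittance vanishes for a perfectly correlated (convergent or
    divergent) beam, ``|r| = 1``.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if div < 0:
        raise ValueError(f"div must be >= 0, got {div}")
    if abs(r) > 1:
        raise ValueError(f"correlation must lie in [-1, +1], got {r}")
    return sigma * div * float(np.sqrt(1.0 - r * r))


def _sample_plane(
    rng: np.random.Generator, n: int, sigma: float, div: float, r: float
) -> tuple[np.ndarray, np.ndarray]:
    # |r| = 1 is a degenerate (rank-1) Gaussian: sample the position and place
    # the angle exactly on the correlation line to avoid a singular Cholesky.
    x = rng.normal(0.0, sigma, n)
    if abs(r) == 1.0 or div == 0.0:
        xp = np.sign(r) * (div / sigma) * x if div > 0 else np.zeros(n)
        return x, xp
    xp = r * (div / sigma) * x + div * np.sqrt(1.0 - r * r) * rng.normal(0.0, 1.0, n)
    return x, xp


def sample_particles(source: BeamSource, n: int, seed: int | np.random.SeedSequence) -> ParticleBundle:
    """Draw ``n`` particles from the bi-Gaussian source at ``z = 0``.

    Energies are Gaussian with sigma ``energy * energy_spread``; non-positive
    energies are resampled (physically the spectrum is positive; at the
    typical 1% spread the truncation is negligible).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    x, xp = _sample_plane(rng, n, source.sigma_x, source.div_x, source.r_xx)
    y, yp = _sample_plane(rng, n, source.sigma_y, source.div_y, source.r_yy)
    e = rng.normal(source.energy, source.energy * source.energy_spread, n)
    while np.any(e <= 0):
        bad = e <= 0
        e[bad] = rng.normal(source.energy, source.energy * source.energy_spread, bad.sum())
    return ParticleBundle(z=0.0, x=x, x_prime=xp, y=y, y_prime=yp, energy=e)


def source_moments(source: BeamSource) -> BeamMoments:
    """Analytic second moments of the source at ``z = 0``."""
    return BeamMoments(
        z=0.0,
        x=PlaneMoments(
            var_pos=source.sigma_x**2,
            cov_pos_ang=source.r_xx * source.sigma_x * source.div_x,
            var_ang=source.div_x**2,
        ),
        y=PlaneMoments(
            var_pos=source.sigma_y**2,
            cov_pos_ang=source.r_yy * source.sigma_y * source.div_y,
            var_ang=source.div_y**2,
        ),
    )


def bundle_moments(bundle: ParticleBundle) -> BeamMoments:
    """Sample second moments of a bundle (ddof=0, about the sample mean)."""
    if bundle.count < 2:
        raise ValueError("need at least 2 particles for sample moments")

    def plane(u: np.ndarray, up: np.ndarray) -> PlaneMoments:
        c = np.cov(np.vstack([u, up]), ddof=0)
        return PlaneMoments(var_pos=c[0, 0], cov_pos_ang=c[0, 1], var_ang=c[1, 1])

    return BeamMoments(
        z=bundle.z,
        x=plane(bundle.x, bundle.x_prime),
        y=plane(bundle.y, bundle.y_prime),
    )
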