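# Methods

This note records the physical models, the assumed geometry, the defaults
and the limits of validity of the `minibeam` package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Units and conventions

Transverse positions in mm, angles in mrad (so transfer-matrix
off-diagonals carry lengths in metres), longitudinal positions and element
lengths in cm, kinetic energies in MeV, pole-tip fields in T. z runs along
the beam axis from the nozzle entrance; x is horizontal, y vertical.
Proton kinematics are relativistic: pc = √(T(T+2m)), pv = T(T+2m)/(T+m),
magnetic rigidity Bρ = pc/299.792458 T·m, m = 938.272 MeV.

## Beam source

Each transverse plane is jointly Gaussian in (position, angle) with
moments σ², r·σ·x′, x′². The plane emittance is taken as the RMS product
ε = σ·x′·√(1−r²) (no factor π; the underlying relation is only defined up
to proportionality, so the package standardises on the RMS convention).
|r| = 1 is a supported degenerate case: sampling draws the position and
sets the angle exactly on the correlation line, avoiding a singular
covariance factorisation. Energies are Gaussian with σ_E = (spread)·E,
resampled if non-positive (negligible at the 1% default spread).
Floating-point round trips of degenerate beams through transfer maps can
land microscopically outside the Cauchy–Schwarz boundary
cov² ≤ var_pos·var_ang; the moments container allows a 10⁻⁶ relative
margin for this.

## Transport

* **Quadrupoles** are hard-edge: gradient g = B_tip/a with default aperture
  radius a = 5 cm and length 30 cm (neither is published for the clinical
  nozzle; both are configurable, and the reference results are robust to
  these defaults at fixed focal length). Strength k = g/Bρ; the focussing
  plane uses the cos/sin matrix, the defocussing plane cosh/sinh. Each
  per-plane map has unit determinant (symplectic), so vacuum transport
  conserves the per-plane emittance.
* **Multiple Coulomb scattering** uses the Highland parametrisation with
  PDG radiation lengths (air 303.9 m, water 36.08 cm, polyimide 28.6 cm).
  A uniform element of thickness t contributes, over its length L, the
  exact Gaussian (Fermi–Eyges) moment increments (θ₀²L²/3, θ₀²L/2, θ₀²);
  the Monte-Carlo tracker samples the matching correlated
  (displacement, angle) pair, so envelope and MC agree by construction in
  the Gaussian approximation. The logarithmic Highland factor is evaluated
  at the full element (or water-path) thickness and split in quadrature
  over sub-steps, which keeps the total scattering independent of the
  stepping. No Molière tails, no nuclear interactions.
* **Chromaticity.** The envelope engine averages the monochromatic
  second moments over a 5-node Gauss–Hermite quadrature of the energy
  distribution; the tracker uses each particle's own momentum in k and in
  dipole kicks. The resulting mixture is not exactly Gaussian; the final
  numbers therefore come from the tracker with binned Gaussian fits, the
  quadrature envelope only ranks configurations.
* **Energy loss in air** (≤ 0.3 MeV/m) is ignored for the optics and
  modelled only inside the water phantom.

## Assumed nozzle geometry

The manufacturer's drawings are not public; the presets encode a stated,
overridable geometry.

**Clinical PBS nozzle** (`icpo_current`): 0.1 mm polyimide vacuum window at
z = 0, then air throughout: Q1 (10–40 cm), Q2 (50–80 cm), scanning-magnet
kicks at 100/115 cm, 1 mm water-equivalent transmission chambers at 130 cm
(IC1) and 200 cm (IC2), isocentre at 250 cm. Monitored positions −40 … +40
cm around the isocentre. `icpo_mod1` evacuates all drifts (chambers keep
their material); `icpo_mod2` removes the snout, putting the target 20 cm
after IC2; `icpo_mod3` adds a quadrupole pair XQ1/XQ2 (rated 4 T) at
160–230 cm with IC2 moved behind them — only the extra pair is scanned.

**Optimised nozzle** (`optimized`): an evacuated tank with the doublet near
its downstream end, scanning kicks after Q2, one thin (0.5 mm
water-equivalent) exit-window-plus-transmission-chamber at the start of the
air gap, and a focal length (Q2 exit to target) of 90–110 cm, default
100 cm, with a 10 or 30 cm air gap. Two geometry choices deserve
justification:

* *Tank length 160 cm before Q1.* A quadrupole doublet is never
  net-defocussing in both planes, so a converging |r| = 1 beam (natural
  waist at σ/x′ ≈ 1.3–2 m for clinical parameters) can only be refocussed
  onto a target ~2 m downstream if it passes its waist **inside** the tank,
  upstream of Q1, where the doublet can image it. A short tank makes
  submillimetre foci of such beams impossible in linear optics; 160 cm
  places the clinical waist range ahead of the doublet.
* *Vacuum window at the tank exit.* The machine vacuum ends where the beam
  enters air. A window at the tank entrance would add ≈ 0.9 mrad of
  scattering with a ~2 m lever arm (≈ 2 mm of spot growth), again
  precluding submillimetre foci; the window is therefore folded, with the
  thin monitoring chamber, into the 0.5 mm water-equivalent slab at the
  start of the air gap.

With these choices the focal spot is limited by chamber/air-gap scattering
plus chromatic aberration, which is the regime the optimisation explores.

## Quadrupole scan

Default grid: 0–2 T in 0.04 T steps (51 values per quadrupole; up to the
4 T rating for the extra pair), times two focus-plane arrangements — 5202
configurations. All are evaluated in the vectorised envelope mode; the top
1% by Ω = hFWHM² + vFWHM² (a configurable fraction, always at least the
envelope argmin) are re-simulated with 10⁵ tracked protons, and the final
argmin is taken over the refined Monte-Carlo Ω, ties broken toward the
lowest (B1, B2). Per-configuration random streams derive from
(base seed, i1, i2, arrangement) through `SeedSequence` spawn keys.

The uncertainty on the minimum combines per side, as a root sum of
squares: (i) the spread of envelope-scan minima over source variations
(default: divergences ±10%; the variations the original study used are not
stated), (ii) the maximum envelope FWHM difference over the 8 neighbouring
grid cells — upper side only, since a discrete grid can only overestimate
the true minimum — and (iii) the Gaussian-fit standard error.

## Profile fitting

Beam widths are measured by a least-squares Gaussian fit to the
Freedman–Diaconis-binned histogram (Poisson weights), FWHM = 2√(2 ln 2)·σ̂
stored at full precision and displayed as 2.355. The sample standard
deviation is available as a cross-check; for the chromatic mixtures at the
focus the fitted core is slightly narrower than the RMS width, matching
the profile-fit procedure the reference results use.

## Benchmark and calibration

The parametrisation benchmark enumerates 9 size pairs (3–15 mm) ×
8 log-even divergences (0.1–15 mrad, per plane) × 11 even correlations
(−1 … +1, per plane) = 69 696 sources; the exact spacings are not
published, so log-even/even spacing is the package's choice and is
configurable. Feasibility maps exploit the exact decoupling of the two
transverse planes: each plane's map is the envelope-scan minimum FWHM per
(divergence, correlation) cell, minimised over sizes and both
arrangements. A scaled-down 3×4×4×5×5 grid (`ParametrisationGrid.small()`)
is the desk-scale default for map computations.

Calibration grid-searches (divergence, correlation) per plane and energy to
minimise the mean squared relative deviation between envelope-propagated
and measured σ at the five positions, with the source sizes taken as given
(the measurement at the first chamber). The reported goodness of fit is the
mean absolute relative deviation in %.

**Identifiability limit.** Over the ±40 cm window around an isocentre
≈ 2.5 m from the source, σ²(z) = σ₀² + 2rσ₀x′z + x′²z² is sampled over a
±16% relative lever arm, so the linear and quadratic coefficients are
nearly collinear. For divergences ≲ 1 mrad, distinct (x′, r) candidates
predict sizes differing by < 1% at every position; with 1% measurement
noise the pair is then not identifiable to one grid step, although the
fitted model still reproduces the data at the noise level. The test suite
asserts one-step recovery only where the information exists (high
divergence); the corresponding end-to-end check is expected to fail for the
degenerate mid-energy case and documents this limit.

## Dose engine

The depth dose is a Bortfeld-style analytic Bragg curve: range
R = αE^p (α = 0.0022 cm·MeV⁻ᵖ, p = 1.77), mono-energetic straggling
σ = 0.012·R^0.935 added in quadrature with the energy-spread contribution
αpE^(p−1)σ_E, parabolic-cylinder-function convolution near the peak
(β = 0.012 cm⁻¹, γ = 0.6) matched to the pristine power-law curve upstream
and zero beyond the range. Lateral spread in water evolves the entrance
moments by Fermi–Eyges with the Highland scattering power at the locally
degraded energy (frozen below 3 MeV residual).

The analytic engine superposes the 25 Gaussian pencil beams exactly; each
beam enters at its grid offset with the angle set by its scanning-magnet
arm, so off-centre beams propagate outward and the pattern magnifies with
depth — this geometric divergence is what brings the deep-dose overlap
(and hence the Bragg-peak/entrance ratio) down for the narrow-beam
configurations. The Monte-Carlo mode scores per-voxel energy deposition of
individually tracked protons (sampled ranges, per-slab scattering) and
attaches relative uncertainties from the standard deviation over repeats
(default 50); it verifies the analytic approximations at reduced
resolution.

Analysis conventions: peak on the central-beam axis; valley at the fixed
transverse midpoint of the central 2×2 sub-grid (diagonal); PVDR per 1 mm
depth slab, undefined (NaN) where the valley dose is zero; Bragg depth
from the laterally integrated depth dose; central-beam FWHM from a
single-beam run without the 24 neighbours; lateral flatness
(Dmax−Dmin)/(Dmax+Dmin) over the central 80% of the (n−1)·spacing field
extent, magnified at depth (the original flatness reference is not
reproducible from the publication; with this definition the
flatness-minimising spacing for the 100 MeV/10 cm case is 2.9 mm, while
the 5–6% band is entered at a smaller spacing — `criterion="optimal"`
returns the definition-robust optimum). The 200 MeV spacing is not stated
in the source material; the 30 cm-gap value (3.7 mm) is used.

## Synthetic data

The measured-size generator interpolates the published clinical ranges
linearly in energy (σ 13 → 3.2 mm, divergence 2.25 → 0.3 mrad, correlation
−1 → +1 over 100 → 220 MeV) — the true energy-dependent functions are not
public — propagates each source through the clinical-nozzle model and adds
relative Gaussian noise (default 1%, seeded). Toy beamlines (pure drift,
doublet, air drift) ship with closed-form expected moments; the
Gaussian-comb dose fixture carries a brute-force lattice-sum PVDR. Green
tests on these fixtures establish internal consistency of the transport
and analysis chain, not agreement with any measured beam: real beams have
non-Gaussian halos, detector response and energy-dependent correlations
that the generator does not emulate.

## What a green suite does and does not establish

Green tests show: the two transport engines agree in their common Gaussian
domain; the optics conserves emittance; the scan machinery is exhaustive,
deterministic and correctly ranked; the dose analyser reproduces closed
forms; and, within the stated tolerances (printed uncertainties or ±25% on
beam sizes, ±30% on dose ratios), the assumed geometry reproduces the
published minima and dose metrics. They do not validate the absolute
dosimetry (no nuclear interactions, no halo — entrance PVDRs are upper
estimates), the true clinical-nozzle drawings, or beam shapes beyond the
bi-Gaussian model.
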