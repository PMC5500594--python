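# Methods

This package reimplements, at desk scale, the structural-analysis machinery
used to characterize dense columnar DNA arrays: lattice geometry,
positional/azimuthal Lindemann statistics, water orientational, tetrahedral
and dielectric order parameters, and a membrane-based osmotic equation of
state, together with the synthetic generators and toy simulators that make
every stage testable without molecular dynamics. This note records the
model definitions, the parameter choices, and the numerical decisions.

## Lattice geometry and conversions

Parallel DNA helices pack on a centered-rectangular lattice with parameters
a and b; sites are generated as `(c*a + (r mod 2)*a/2, r*b/2)`. The
hexagonal (hex) packing is the special case b/a = sqrt(3), with interaxial
spacing d = a and 6 equidistant first neighbors; the orthorhombic (orto)
distortion studied here uses b/a = 1.43, giving d = (a/2)*sqrt(1+(b/a)^2)
and 4 first neighbors. The array angles arctan(b/a) are 60 deg (hex) and
55.0 deg (orto). First-neighbor shells are defined by distance ties within
a relative tolerance (default 1e-6), not k-nearest: all equidistant sites
belong to the shell.

Interaxial spacing maps to DNA mass concentration through the B-DNA linear
mass density, 660 g/mol per base pair over a 0.34 nm rise
(1941 g mol^-1 nm^-1), and the cross-sectional area per molecule
((sqrt(3)/2) d^2 for hex). Bare DNA mass is used, with no counterion
contribution; this choice reproduces both conventional reference pairs,
2.37 nm <-> ~670 mg/ml and 3.15 nm <-> ~380 mg/ml, to better than 2%.
The inverse Debye length is kappa = sqrt(2 N_A e^2 I / (eps eps0 kB T));
at 1 M, 300 K, eps = 80 it evaluates to 3.25 nm^-1.

## Fluctuation statistics and Lindemann classification

Positional order: sigma_r is, per molecule, the RMS over frames of the 2D
deviation of its center of mass from its own time mean, averaged over
molecules and normalized by a. No array-wide drift is removed by default
(only per-molecule means are subtracted); an optional drift-removal flag
exists but defaults off, so collective modes count as disorder.

Azimuthal order: the azimuth of a base pair is the angle of its
C8-proxy -> C6-proxy marker vector against the x axis. The relative
azimuth of two molecules averages over base pairs k

    wrap( phi_k1 - phi_k2 + 2*pi*(z_k1 - z_k2)/L_z ),

wrapped to (-pi, pi]. The z term is the azimuthal advance per unit height
of a helix of pitch L_z = 3.4 nm: it maps both molecules to a common
height, so a rigid screw displacement (coupled translation dz and rotation
-2*pi*dz/L_z; the helix convention here is phi(z) = phi0 - 2*pi*z/L_z)
cancels identically. Dimensional analysis requires dividing by L_z; a
multiplicative placement of L_z would carry units of angle*length and is
not meaningful. sigma_phi is the per-pair RMS of this quantity about its
own time mean, averaged over all first-shell pairs (interior-only pairs are
available as an option) and normalized by pi. Each pair's time series is
unwrapped before the mean is taken so branch jumps of the wrap cannot
inflate the RMS.

Classification uses the empirical threshold 0.1 for both statistics, with
the boundary convention that exactly 0.1 is disordered (arbitrary but
fixed and tested). Threshold crossings along a density series are located
by linear interpolation between the bracketing concentrations, scanning
from high to low concentration since fluctuations grow toward low density.

## Synthetic trajectory generator

`gen_array` emulates the statistical structure the analysis assumes, not
the dynamics that produce it: per frame, molecular centers of mass are
lattice sites plus i.i.d. Gaussian noise per component; each molecule is a
rigid helical ladder of n_bp = 10 base-pair marker pairs (markers at
0.6 nm from the axis — only their azimuth enters the analysis, so the
radius is a free documented constant); molecular azimuths are a preferred
neighbor pattern plus Gaussian noise; and optional screw coupling applies
a per-molecule z offset uniform in [0, L_z) jointly with the matching
helical rotation. Closed-form oracles follow: isotropic 2D noise of
s.d. sigma gives sigma_r = sigma*sqrt(2); independent azimuthal noise
sigma gives pair fluctuation sqrt(2)*sigma. What the generator does not
emulate: temporal correlations, anharmonic and collective modes, coupling
between positional and azimuthal order, and density dependence — passing
recovery tests therefore validates the estimators, not any claim about
real trajectories.

`gen_water_between_pair` fills the inter-DNA cuboid (length = interaxial
spacing, width = 2.0 nm, the standard B-DNA diameter, height = L_z) with
waters uniform in space whose dipole cosine against the pair axis is drawn
from an exponential (Boltzmann) tilt exp(kappa*x) on [-1, 1], with kappa
solved so the mean follows the antisymmetric double-exponential surface
profile A*[exp(-s/lambda) - exp(-(d-s)/lambda)]. The exponential tilt is
the dipole-in-field distribution and represents any target mean |m| < 1;
a linear tilt was rejected because it cannot express mean cosines above
1/3, which surface-contact values reach.

`gen_counterions` assigns each DNA one pitch of 20 phosphate charges
(10 bp x 2 strands), neutralizes with Spd3+ (6 per DNA by default, i.e.
below the condensation threshold) plus Na+, and adds neutral NaCl pairs;
ions are placed uniformly outside an excluded radius. Placement is
deliberately unbiased: ion bridging between helices is a *result* in the
real system, not a generative rule, so a bridging-biased placement is
exposed only as an option with no default.

All generators are pure functions of (params, seed) and bitwise
reproducible.

## Water order parameters

alpha convention. The orientation profiles are computed with alpha taken
against the fixed pair-axis unit vector pointing from the first to the
second DNA of the pair. A reference that flips at the midpoint (vector to
the *nearer* axis) would make eta1 of any symmetric system symmetric about
the midpoint; the antisymmetric shape these profiles are meant to exhibit
for identical apposed surfaces requires the fixed axis, and with it the
pair-swap identities (eta1 negated, eta2/eta3 unchanged, bins mirrored)
hold exactly, not just statistically. eta1 = <cos alpha> and
eta2 = <(3 cos^2 alpha - 1)/2> per bin of the scaled coordinate
r/d_DNA in [0, 1] (default 20 bins); empty bins are reported with
population 0 and NaN, never interpolated. Error bars are bootstrap
standard deviations over frames (200 resamples).

eta3 is the diagonal pair-axis component of the molecular quadrupole about
the molecular center of mass. Point-dipole waters carry no charge sites,
so the quadrupole is reconstructed from an SPC-like 3-site geometry
(q_H = +0.41 e, r_OH = 0.1 nm, 109.47 deg) oriented along the dipole and
averaged analytically over the azimuth about the dipole axis:
Q_ee = f*(A0 cos^2 alpha + B0 (1 - cos^2 alpha)) with A0, B0 the axial and
transverse second moments and f the ratio of the particle's dipole to the
geometry's. This is nonzero for isotropic dipoles, as a physical
quadrupole density is. The multipole origin (center of mass) is a
convention; shifting it changes eta3 by terms proportional to the dipole,
which matters only where eta1 is large.

Tetrahedrality: q4 = 1 - (3/8) sum_{j<k} (cos psi_jk + 1/3)^2 over the 6
angles subtended at a center by its 4 nearest candidates, with z-periodic
minimum-image distances. Candidates mix waters and electronegative DNA
sites irrespective of identity; since no atom list exists for the
synthetic topology, electronegative DNA sites are those flagged
`is_acceptor` (negative-charge dna sites by construction). q4 = 1 for the
perfect tetrahedron, -3 for four coincident directions, and its mean over
uniformly random directions is 0 (checked by direct Monte Carlo).

Local dielectric: the Kirkwood factor G_k = <mu_i . sum_{j in sphere} mu_j>
/ <mu^2> (self term included, so uncorrelated dipoles give G_k = 1) over
probe spheres of default radius 0.6 nm, converted through the
Kirkwood-Froehlich relation (eps-1)(2eps+1)/(9eps) = rho mu^2 G_k /
(9 eps0 kB T), solved by bracketed root finding on [1, 200]. The relation
is quadratic in eps, so an independent closed form exists and is used as
the test oracle. Bulk-water-like inputs (33.4 nm^-3, 2.35 D, G_k = 2.9)
give eps ~ 81.

Occupancy/residence: occupancy is the time-averaged count of selected
particles within a cutoff of any reference site; residence is the mean
dwell time of continuous within-cutoff intervals, merging gaps up to a
tolerance, with the gap-sensitivity reported for every tolerance up to the
requested one. Binding-site chemistry (grooves vs phosphates) is out of
scope; shells are geometric.

## Toy rod-array simulator

The array is reduced to N point rods in the x-y plane carrying an
azimuthal spin. Pair repulsion is Yukawa A exp(-kappa r)/r with
kappa = 3.25 nm^-1 (the 1 M screening) plus an optional exponential
hydration term. The semipermeable membrane is a rounded rhombus tilted at
the lattice angle — a parallelogram core dilated by a rounding radius
(0.2 nm), so corners are radial caps and the outward normal is defined
everywhere — acting on rods only through a harmonic half-space force
(default stiffness 1e4 pN/nm). Units are nm/ps/(g/mol)/(kJ/mol);
pressures are reported in pN/nm^2 = MPa.

The membrane, not the initial lattice, fixes the density: its area is set
by bisection to N times the per-molecule area at the nominal spacing,
which is the osmotic-stress geometry. A loosely fitted membrane lets the
whole array translate collectively and dominates sigma_r; sizing the
membrane to the density removes that artifact and makes the Lindemann
statistics density-controlled.

Integration is BAOAB Langevin (T = 300 K, friction 5 ps^-1, the standard
thermostat settings for this kind of system); with zero friction it
reduces to velocity Verlet, and the default system holds NVE energy drift
below 1e-4 relative per 1e4 steps at the default dt = 0.005 ps. Per-step
displacements above 0.5 nm raise a stability error advising a smaller dt.
Spins evolve by overdamped Euler-Maruyama in the cosine coupling
-J cos(n(dphi - dphi_pref)) summed over the fixed first-shell topology.
Two choices matter here. First, the multiplicity n equals the packing
symmetry (3 for hex, 4 for orto) so both signs of the preferred neighbor
rotation are equivalent minima; with n = 1 the checkerboard pattern is
geometrically frustrated and the spin subsystem wanders. Second, the
rotational friction default (100 kJ/mol ps) keeps the explicit Euler spin
step stable (dt * n^2 J coord / friction << 1) at the strongest couplings
used. The coupling amplitude optionally decays exponentially with the
shell distance, J(d) = J0 exp(-d/lambda_J), since azimuthal interactions
between helices weaken with separation like the pair forces do.

Study defaults (`dnarray.presets`): 4x4 hex array, spacing grid 1.8-3.4 nm
in 0.4 nm steps, A = 1e5 kJ/mol nm, J0 = 2000 kJ/mol with
lambda_J = 0.45 nm, rod mass 20 g/mol, dt = 0.008 ps, wall 2000 pN/nm,
50000 steps per spacing sampled every 10, first 20% discarded. With these
conditions the osmotic pressure is strictly monotone in spacing, the
positional Lindemann crossing falls between 1.8 and 2.2 nm, and the
rotational crossing between 2.6 and 3.0 nm. Note the toy's rotational
order is lost at *lower* density than its positional order — the reverse
of the real system — because the spin sector is independent of the
translational stiffness here; the phase-assembly logic handles either
ordering. Absolute pressures are not comparable to the atomistic system
and are not meant to be.

Osmotic pressure is the mean total outward-normal wall force divided by
the membrane area (perimeter x L_z), after discarding the first 10% of
samples, with the s.d. from 5-block averaging. The dilute
(non-interacting) limit reproduces the ideal-gas law; measuring it
accurately requires starting from a uniform scatter (the gas otherwise
equilibrates diffusively over far longer than the run) and a wall soft
enough that the harmonic contact is well resolved by the timestep
(omega*dt <~ 0.1) — with a stiff wall and coarse dt the contact force is
integrated inaccurately and the pressure biases by ~10%.

## Adaptive-resolution toy fluid

A single-species 2D fluid (294 particles in a 12 nm periodic box) has a
rounded-rhombic atomistic region (WCA, eps = 2.5 kJ/mol, sigma = 0.35 nm)
inside a coarse-grained bath (Gaussian core, eps = 3 kJ/mol,
sigma = 0.45 nm), coupled by the pair-force interpolation
w_i w_j F_ex + (1 - w_i w_j) F_cg with the cos^2 sigmoid
w = cos^2(pi s / 2W) of the signed normal coordinate s across the hybrid
layer (W = 1.8 nm); the sigmoid shape is a documented, swappable choice.
The pair part is antisymmetric and conserves momentum exactly; the
thermodynamic (TD) force is a radial table (40 bins over the hybrid
layer) applied along the outward normal.

Calibration iterates: run (12000 steps, first 3000 discarded), bin the
hybrid density, fit log rho with a degree-6 polynomial anchored by the
atomistic and coarse-grained region densities, and update
F_TD <- F_TD - gain * kT * d(log rho_fit)/ds with gain 0.6. The smooth
fit is essential: per-bin finite differences are dominated by counting
noise and the update then diverges. Equally essential is that density
relaxation across the box fit inside one iteration, hence the light
particles (5 g/mol) and weak friction (0.5 ps^-1); with slow diffusion
the update chases stale density and oscillates. Convergence is declared
when the maximum relative density deviation across the three resolution
regions — atomistic, hybrid as a whole, coarse-grained — falls below 3%.
That three-region balance is the quantity the TD force exists to restore,
and it is measurable well below its ~0.5% counting noise at this system
size, whereas a fine-binned profile has a 3-5% noise floor here; the
binned profile is still reported as a diagnostic. Non-convergence returns
the table with a warning, never silently. With identical potentials the
procedure converges at iteration 0 with a zero table. The inner/outer
dielectric treatment of coarse-grained ions in the real multi-species
setup is noted but not reproduced in this single-species toy.

## Equation of state and phase assembly

The EoS is fitted as Pi = Pi0 exp(-d/lambda) against spacing (or
Pi = Pi0 exp(c/c0) against concentration — both abscissas are supported
since either may be the natural one) by weighted least squares in log Pi,
weights (Pi/sd)^2, excluding non-positive rows with a warning and
requiring three usable points. The fit is exact on noiseless exponential
data and shows < 2% parameter bias under 5% multiplicative noise.

The phase report evaluates the fitted EoS at each Lindemann crossing
rather than interpolating raw pressures (smoothing noise), and classifies
densities into three bands by the two crossings. Band labels are
explicitly proxies — positional/rotational Lindemann bands — not
thermodynamic phase identifications.

## Problem sizes and determinism

Default problem sizes were chosen so the full pipeline (tests plus
analysis scripts) runs in minutes on one core: 16 rods, 2000-frame
synthetic arrays, 400 waters x 60 frames, 294-particle fluid, 5-point
density sweeps. Every stochastic stage takes an explicit integer seed and
is bitwise reproducible; sweeps derive per-point seeds by offset.

## Known limitations

- The synthetic array is an i.i.d. Gaussian ensemble; it cannot test
  estimator behavior under correlated or non-Gaussian fluctuations.
- The toy rod model has no solvent or ions; its pressures are not
  comparable to atomistic values, and its rotational/positional melting
  order is inverted relative to the real system (see above).
- eta3 rests on a reconstructed charge geometry; alternative contractions
  of the quadrupole tensor and other multipole origins are noted in the
  code but not implemented.
- The TD-force toy is single-species; calibration produces one table per
  fluid (so a multi-species system would carry one table per molecule
  type, each calibrated the same way), but only one species is exercised.
- Lindemann thresholds are empirical proxies; no free-energy computation
  is attempted.
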