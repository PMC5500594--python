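"""2D Langevin dynamics of interacting rods in a semipermeable membrane.

The full-scale system (atomistic DNA in explicit solvent) is reduced to
its structural essentials: N rods are points in the x-y plane carrying an
azimuthal spin, interacting through a screened-Coulomb (Yukawa) repulsion
A exp(-kappa r)/r and an optional exponential hydration term H exp(-r/l),
confined by a rounded rhombic membrane acting only on rods via a harmonic
half-space force.  The third dimension enters through the z-period L_z in
the membrane area, exactly as the osmotic pressure definition requires.

Integration is velocity Verlet with a Langevin thermostat in the BAOAB
splitting (B: half kick, A: half drift, O: Ornstein-Uhlenbeck velocity
refresh, then A, B); with zero friction it reduces to plain velocity
Verlet, which is how the NVE energy-drift check runs.  Spins evolve by
overdamped (Euler-Maruyama) rotation in a cosine coupling over the fixed
first-neighbor-shell topology.

Internal units: nm, ps, g/mol, kJ/mol; wall stiffness is accepted in
pN/nm and forces are reported in pN.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from . import constants as c
from .errors import DomainError, StabilityError
from .geometry import RoundedRhombus, fit_membrane
from .io import Frame, Topology, Trajectory
from .lattice import LatticeSpec, build_lattice, first_neighbor_shell, spacing_to_concentration
from .synth import MARKER_RADIUS_NM

MAX_STEP_NM = 0.5  # per-step displacement beyond which integration is declared divergent


@dataclasses.dataclass
class PairPotential:
    yukawa_amplitude: float = 0.0     # A, kJ/mol nm (U = A exp(-kr)/r)
    kappa: float = 3.25               # nm^-1
    hydration_amplitude: float = 0.0  # H, kJ/mol (U = H exp(-r/l))
    hydration_decay: float = 0.29     # l, nm

    def __post_init__(self):
        if self.kappa <= 0 or self.hydration_decay <= 0:
            raise DomainError("decay constants must be positive")


@dataclasses.dataclass
class SpinCoupling:
    amplitude: float = 0.0            # J0, kJ/mol
    preferred_delta_phi: float = 2.0 * math.pi / 3.0
    multiplicity: int = 1             # n in -J cos(n (dphi - preferred))
    rot_friction: float = 100.0       # kJ/mol ps (overdamped mobility = 1/this);
                                      # large enough that the Euler spin step stays
                                      # stable (dt * n^2 J coord / rot_friction << 1)
    decay: Optional[float] = None     # nm; J(d) = J0 exp(-d/decay) at the shell distance

    def effective_amplitude(self, shell_distance: float) -> float:
        """Coupling strength at the first-shell distance (azimuthal interactions
        between helices weaken with separation like the pair forces do)."""
        if self.decay is None:
            return self.amplitude
        return self.amplitude * math.exp(-shell_distance / self.decay)


@dataclasses.dataclass
class RodSystem:
    positions: np.ndarray             # (N,2) nm
    azimuths: np.ndarray              # (N,) rad
    lattice: LatticeSpec
    membrane: RoundedRhombus
    pair_potential: PairPotential
    spin_coupling: SpinCoupling
    wall_stiffness: float = 1.0e4     # pN/nm
    temperature: float = 300.0        # K
    friction: float = 5.0             # ps^-1
    mass: float = 100.0               # g/mol (toy rod mass)
    dt: float = 0.005                 # ps; keeps the NVE energy drift of the
                                      # default system below 1e-4 per 1e4 steps
    z_period: float = c.HELICAL_PITCH_NM

    def __post_init__(self):
        self.positions = np.array(self.positions, float)
        self.azimuths = np.array(self.azimuths, float)
        if self.wall_stiffness <= 0 or self.dt <= 0:
            raise DomainError("wall stiffness and dt must be positive")
        if not np.all(self.membrane.contains(self.positions)):
            raise DomainError("membrane must enclose all initial rod positions")


@dataclasses.dataclass
class WallForceTrace:
    """Total outward-normal force on the membrane per sampled frame, pN."""

    forces: np.ndarray
    membrane_area: float              # perimeter x L_z, nm^2
    cross_section: float              # enclosed x-y area, nm^2

    def __post_init__(self):
        if self.membrane_area <= 0:
            raise DomainError("membrane area must be positive")


def membrane_for_density(lattice: LatticeSpec, rounding: float = 0.2) -> RoundedRhombus:
    """Membrane whose enclosed area realizes the lattice's nominal density.

    The membrane, not the initial lattice, fixes the array density (the
    osmotic-stress geometry): its area is set to n_sites times the
    cross-sectional area per molecule at the lattice spacing, found by a
    bisection on the fit margin.
    """
    from .lattice import area_per_molecule

    target = lattice.n_sites * area_per_molecule(
        lattice.spacing, lattice.kind, lattice.b_over_a)
    lo, hi = 1e-3, 2.0 * lattice.spacing
    if fit_membrane(lattice.sites, lattice.angle, lo, rounding).area > target:
        raise DomainError("lattice hull already exceeds the target density area")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if fit_membrane(lattice.sites, lattice.angle, mid, rounding).area < target:
            lo = mid
        else:
            hi = mid
    return fit_membrane(lattice.sites, lattice.angle, 0.5 * (lo + hi), rounding)


def default_system(lattice: LatticeSpec,
                   pair_potential: Optional[PairPotential] = None,
                   spin_coupling: Optional[SpinCoupling] = None,
                   margin: Optional[float] = None,
                   **kwargs) -> RodSystem:
    """Rods frozen on the lattice sites inside a fitted membrane.

    Without an explicit margin the membrane is sized to realize the
    lattice's nominal density (see membrane_for_density).
    """
    if margin is None:
        membrane = membrane_for_density(lattice)
    else:
        membrane = fit_membrane(lattice.sites, lattice.angle, margin=margin)
    n = lattice.n_sites
    sc = spin_coupling or SpinCoupling()
    rows = np.arange(n) // lattice.n_cols
    cols = np.arange(n) % lattice.n_cols
    return RodSystem(
        positions=lattice.sites.copy(),
        azimuths=sc.preferred_delta_phi * (rows + cols),
        lattice=lattice,
        membrane=membrane,
        pair_potential=pair_potential or PairPotential(),
        spin_coupling=sc,
        **kwargs,
    )


def scatter_positions(membrane: RoundedRhombus, n: int, seed: int = 0,
                      clearance: float = 0.0) -> np.ndarray:
    """n positions uniform over the membrane interior (rejection sampling).

    Useful to start dilute (gas-like) systems in spatial equilibrium rather
    than on lattice sites; ``clearance`` keeps points away from the wall.
    """
    rng = np.random.default_rng(seed)
    corners = np.concatenate([
        membrane._corners - membrane.rounding, membrane._corners + membrane.rounding])
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(lo, hi, size=(max(4 * n, 64), 2))
        ok = cand[membrane.signed_boundary_coordinate(cand) <= -clearance]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def pair_forces(pos: np.ndarray, pot: PairPotential) -> tuple[np.ndarray, float]:
    """All-pair forces (kJ/mol/nm) and potential energy (kJ/mol)."""
    n = len(pos)
    f = np.zeros_like(pos)
    energy = 0.0
    if (pot.yukawa_amplitude == 0.0 and pot.hydration_amplitude == 0.0) or n < 2:
        return f, energy
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.sum(diff ** 2, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    r = np.sqrt(r2[iu, ju])
    mag = np.zeros_like(r)
    if pot.yukawa_amplitude != 0.0:
        ey = np.exp(-pot.kappa * r)
        energy += float(np.sum(pot.yukawa_amplitude * ey / r))
        mag += pot.yukawa_amplitude * ey * (1.0 + pot.kappa * r) / r ** 2
    if pot.hydration_amplitude != 0.0:
        eh = np.exp(-r / pot.hydration_decay)
        energy += float(np.sum(pot.hydration_amplitude * eh))
        mag += pot.hydration_amplitude / pot.hydration_decay * eh
    fij = (mag / r)[:, None] * diff[iu, ju]   # force on i from j (repulsive)
    np.add.at(f, iu, fij)
    np.add.at(f, ju, -fij)
    return f, energy


def wall_forces(pos: np.ndarray, membrane: RoundedRhombus,
                k_wall_kj: float) -> tuple[np.ndarray, float, float]:
    """Wall force on rods (kJ/mol/nm), wall energy, total normal force magnitude."""
    pen, normal = membrane.penetration(pos)
    f = -k_wall_kj * pen[:, None] * normal
    energy = 0.5 * k_wall_kj * float(np.sum(pen ** 2))
    total = k_wall_kj * float(np.sum(pen))
    return f, energy, total


def spin_torques(phi: np.ndarray, pairs: Sequence[tuple[int, int]],
                 sc: SpinCoupling) -> np.ndarray:
    """-dE/dphi for E = -J sum_pairs cos(n (phi_i - phi_j - preferred))."""
    t = np.zeros_like(phi)
    if sc.amplitude == 0.0 or not pairs:
        return t
    nmult = sc.multiplicity
    for i, j in pairs:
        s = math.sin(nmult * (phi[i] - phi[j] - sc.preferred_delta_phi))
        t[i] -= sc.amplitude * nmult * s
        t[j] += sc.amplitude * nmult * s
    return t


def total_energy(system: RodSystem, velocities: np.ndarray) -> float:
    """Kinetic + pair + wall energy, kJ/mol (for NVE drift checks)."""
    _, epair = pair_forces(system.positions, system.pair_potential)
    k_kj = system.wall_stiffness / c.KJ_MOL_NM_TO_PN
    _, ewall, _ = wall_forces(system.positions, system.membrane, k_kj)
    ekin = 0.5 * system.mass * float(np.sum(velocities ** 2))
    return ekin + epair + ewall


def simulate(system: RodSystem, n_steps: int, sample_every: int = 10,
             seed: int = 0, velocities: Optional[np.ndarray] = None,
             energies: Optional[list] = None,
             ) -> tuple[Trajectory, WallForceTrace]:
    """Run BAOAB Langevin dynamics; returns sampled trajectory + wall-force trace.

    Rods are emitted as one base-pair marker pair each (C8/C6 proxies at
    the rod azimuth), so the positional and azimuthal Lindemann statistics
    read the output directly.  Raises StabilityError when any per-step
    displacement exceeds 0.5 nm.
    """
    rng = np.random.default_rng(seed)
    pos = system.positions.copy()
    phi = system.azimuths.copy()
    n = len(pos)
    m = system.mass
    kt = c.KB_KJ_MOL_K * system.temperature
    dt = system.dt
    k_kj = system.wall_stiffness / c.KJ_MOL_NM_TO_PN
    gamma = system.friction

    if velocities is not None:
        vel = np.array(velocities, float)
    elif system.temperature > 0:
        vel = rng.normal(0.0, math.sqrt(kt / m), size=(n, 2))
    else:
        vel = np.zeros((n, 2))

    if gamma > 0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(kt / m * (1.0 - c1 * c1))
    else:
        c1, c2 = 1.0, 0.0

    shell_pairs = []
    j_eff = 0.0
    if system.spin_coupling.amplitude != 0.0:
        shell = first_neighbor_shell(system.lattice)
        shell_pairs = shell.pairs
        j_eff = system.spin_coupling.effective_amplitude(shell.shell_distance)
    sc_eff = dataclasses.replace(system.spin_coupling, amplitude=j_eff, decay=None)
    mob = 1.0 / system.spin_coupling.rot_friction
    spin_noise = math.sqrt(2.0 * kt * mob * dt)

    def force(p):
        fp, _ = pair_forces(p, system.pair_potential)
        fw, _, wtot = wall_forces(p, system.membrane, k_kj)
        return fp + fw, wtot

    f, wtot = force(pos)
    frames, wall = [], []
    lz = system.z_period
    box = np.array([
        2.0 * system.membrane.half_u + 2.0 * system.membrane.half_v + 4.0,
        2.0 * system.membrane.half_u + 2.0 * system.membrane.half_v + 4.0,
        lz,
    ])

    ids = np.arange(2 * n)
    top = Topology(
        ids=ids,
        kinds=np.full(2 * n, "dna_site", dtype=object),
        mol_ids=np.repeat(np.arange(n), 2),
        charges=np.zeros(2 * n),
        roles=np.tile(np.array(["c8", "c6"], dtype=object), n),
        bps=np.zeros(2 * n, dtype=int),
    )

    def emit(step):
        ux, uy = np.cos(phi), np.sin(phi)
        p = np.empty((2 * n, 3))
        p[0::2, 0] = pos[:, 0] + MARKER_RADIUS_NM * ux
        p[0::2, 1] = pos[:, 1] + MARKER_RADIUS_NM * uy
        p[1::2, 0] = pos[:, 0] - MARKER_RADIUS_NM * ux
        p[1::2, 1] = pos[:, 1] - MARKER_RADIUS_NM * uy
        p[:, 2] = 0.0
        frames.append(Frame(time=step * dt, box=box.copy(), pos=p))
        wall.append(wtot * c.KJ_MOL_NM_TO_PN)
        if energies is not None:
            _, epair = pair_forces(pos, system.pair_potential)
            _, ewall, _ = wall_forces(pos, system.membrane, k_kj)
            energies.append(0.5 * m * float(np.sum(vel ** 2)) + epair + ewall)

    emit(0)
    for step in range(1, n_steps + 1):
        old = pos.copy()
        vel += 0.5 * dt / m * f
        pos = pos + 0.5 * dt * vel
        if c2 > 0.0:
            vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        else:
            vel = c1 * vel
        pos = pos + 0.5 * dt * vel
        f, wtot = force(pos)
        vel += 0.5 * dt / m * f

        # spins: overdamped rotation; free rotational diffusion when uncoupled
        if j_eff != 0.0:
            phi = phi + mob * dt * spin_torques(phi, shell_pairs, sc_eff)
        if system.temperature > 0:
            phi = phi + spin_noise * rng.normal(size=phi.shape)

        if np.max(np.linalg.norm(pos - old, axis=1)) > MAX_STEP_NM:
            raise StabilityError(
                f"step {step}: displacement exceeded {MAX_STEP_NM} nm; reduce dt")
        if step % sample_every == 0:
            emit(step)

    traj = Trajectory(topology=top, frames=frames, z_period=lz,
                      metadata={"generator": "toy_simulator", "seed": seed,
                                "n_steps": n_steps, "dt": dt})
    trace = WallForceTrace(forces=np.asarray(wall),
                           membrane_area=system.membrane.perimeter * lz,
                           cross_section=system.membrane.area)
    return traj, trace


@dataclasses.dataclass
class SweepPoint:
    spacing: float                  # nm
    concentration: float            # mg/ml
    pressure: float                 # pN/nm^2 (MPa)
    pressure_sd: float
    trajectory: Trajectory
    trace: WallForceTrace


def rescale_lattice(lattice: LatticeSpec, spacing: float) -> LatticeSpec:
    """Same lattice topology at a new interaxial spacing."""
    if lattice.kind == "hex":
        a = spacing
    else:
        a = 2.0 * spacing / math.hypot(1.0, lattice.b_over_a)
    return build_lattice(lattice.kind, a, lattice.b_over_a,
                         lattice.n_rows, lattice.n_cols)


def sweep_density(base_system: RodSystem, spacing_grid: Sequence[float],
                  n_steps: int, seed: int = 0, sample_every: int = 10,
                  margin: Optional[float] = None) -> list[SweepPoint]:
    """One simulation per interaxial spacing; each point is independent.

    The lattice and membrane are rescaled per spacing; pressure comes from
    the wall-force trace (10% equilibration discard, 5-block s.d.).
    """
    grid = list(spacing_grid)
    diffs = np.diff(grid)
    if len(grid) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise DomainError("spacing grid must be strictly monotone")
    from .eos import osmotic_pressure  # local import to avoid a cycle

    out = []
    for k, d in enumerate(grid):
        lat = rescale_lattice(base_system.lattice, d)
        sys_k = default_system(
            lat,
            pair_potential=base_system.pair_potential,
            spin_coupling=base_system.spin_coupling,
            margin=margin,
            wall_stiffness=base_system.wall_stiffness,
            temperature=base_system.temperature,
            friction=base_system.friction,
            mass=base_system.mass,
            dt=base_system.dt,
            z_period=base_system.z_period,
        )
        traj, trace = simulate(sys_k, n_steps, sample_every=sample_every,
                               seed=seed + k)
        p, sd = osmotic_pressure(trace)
        out.append(SweepPoint(spacing=d,
                              concentration=spacing_to_concentration(
                                  d, lat.kind, lat.b_over_a),
                              pressure=p, pressure_sd=sd,
                              trajectory=traj, trace=trace))
    return out
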