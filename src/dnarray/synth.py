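"""Synthetic trajectory generators.

These produce trajectories with the statistical structure the analysis
stages assume, so every stage is exercisable at desk scale without MD:

* ``gen_array`` -- a 16-molecule-style DNA array on a hex/orto lattice with
  Gaussian positional and azimuthal fluctuations, each molecule a rigid
  helical ladder of base-pair marker pairs, optionally screw-coupled
  (a z-offset applied jointly with the matching helical azimuth shift).
* ``gen_water_between_pair`` -- dipolar waters filling the cuboid between a
  DNA pair with a prescribed antisymmetric dipole-orientation profile.
* ``gen_counterions`` -- charge-neutralizing Spd3+/Na+ complements plus
  added NaCl pairs.
* ``gen_tetrahedral_fixture`` -- geometric fixture for the tetrahedrality
  order parameter.

All generators are pure functions of (params, seed): the same seed gives a
bitwise-identical trajectory.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from . import constants as c
from .errors import DomainError
from .io import Frame, Topology, Trajectory
from .lattice import LatticeSpec

#: radius of the synthetic C8/C6 base-pair marker sites from the helix axis, nm.
#: Only the marker azimuth enters the analysis, so the value is a free,
#: documented constant.
MARKER_RADIUS_NM = 0.6


@dataclasses.dataclass
class ArrayFluctuationParams:
    lattice: LatticeSpec
    sigma_pos: float            # nm, per-component Gaussian COM s.d.
    sigma_phi: float            # rad, per-molecule Gaussian azimuth s.d.
    preferred_delta_phi: float  # rad; 2pi/3 (hex) or pi/2 (orto)
    screw_coupling: bool = False
    n_frames: int = 100
    n_bp: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sigma_pos < 0 or self.sigma_phi < 0:
            raise DomainError("fluctuation amplitudes must be >= 0")
        if self.n_frames < 1 or self.n_bp < 1:
            raise DomainError("n_frames and n_bp must be >= 1")


@dataclasses.dataclass
class WaterProfileParams:
    pair_axis: tuple[int, int]    # two lattice site indices
    n_water: int                  # waters per frame
    eta1_surface: float           # <cos alpha> at contact, in [-1, 1]
    decay_length: float           # nm
    dipole_magnitude: float = c.WATER_DIPOLE_E_NM
    n_frames: int = 50
    seed: int = 0

    def __post_init__(self):
        if abs(self.eta1_surface) > 1:
            raise DomainError("|eta1_surface| must be <= 1")
        if self.decay_length <= 0:
            raise DomainError("decay_length must be positive")


def gen_array(params: ArrayFluctuationParams) -> Trajectory:
    """Fluctuating DNA array as a trajectory of base-pair marker sites.

    Each molecule is a rigid helical ladder of ``n_bp`` marker pairs
    (C8-proxy, C6-proxy at +-MARKER_RADIUS_NM from the axis), azimuth
    advancing by -2*pi*z/L_z over the 0.34 nm rise (pitch L_z); the
    molecular azimuth is the preferred neighbor pattern plus Gaussian noise,
    the COM is the lattice site plus i.i.d. Gaussian noise per component.
    With ``screw_coupling`` a per-molecule, per-frame z-offset uniform in
    [0, L_z) is applied jointly with the matching azimuthal shift
    -2*pi*u/L_z, so the height-normalized relative azimuth is unaffected.
    """
    rng = np.random.default_rng(params.seed)
    lat = params.lattice
    n_mol = lat.n_sites
    n_bp = params.n_bp
    lz = c.HELICAL_PITCH_NM
    rise = lz / n_bp

    rows = np.arange(n_mol) // lat.n_cols
    cols = np.arange(n_mol) % lat.n_cols
    phi0 = params.preferred_delta_phi * (rows + cols)  # preferred pattern

    n_part = n_mol * n_bp * 2
    ids = np.arange(n_part)
    kinds = np.full(n_part, "dna_site", dtype=object)
    mol_ids = np.repeat(np.arange(n_mol), n_bp * 2)
    charges = np.zeros(n_part)
    roles = np.tile(np.array(["c8", "c6"] * n_bp, dtype=object), n_mol)
    bps = np.tile(np.repeat(np.arange(n_bp), 2), n_mol)
    top = Topology(ids=ids, kinds=kinds, mol_ids=mol_ids, charges=charges,
                   roles=roles, bps=bps)

    span = lat.sites.max(axis=0) - lat.sites.min(axis=0)
    box = np.array([span[0] + 4 * lat.a, span[1] + 4 * lat.a, lz])

    k = np.arange(n_bp)
    frames = []
    for t in range(params.n_frames):
        com = lat.sites + rng.normal(0.0, params.sigma_pos, size=(n_mol, 2))
        phi_mol = phi0 + rng.normal(0.0, params.sigma_phi, size=n_mol)
        if params.screw_coupling:
            u = rng.uniform(0.0, lz, size=n_mol)
        else:
            u = np.zeros(n_mol)
        # (n_mol, n_bp) marker heights and azimuths
        z_raw = k[None, :] * rise + u[:, None]
        z = np.mod(z_raw, lz)
        phi = phi_mol[:, None] - 2.0 * np.pi * z_raw / lz
        ux, uy = np.cos(phi), np.sin(phi)
        c8 = np.empty((n_mol, n_bp, 3))
        c8[..., 0] = com[:, None, 0] + MARKER_RADIUS_NM * ux
        c8[..., 1] = com[:, None, 1] + MARKER_RADIUS_NM * uy
        c8[..., 2] = z
        c6 = c8.copy()
        c6[..., 0] = com[:, None, 0] - MARKER_RADIUS_NM * ux
        c6[..., 1] = com[:, None, 1] - MARKER_RADIUS_NM * uy
        pos = np.stack([c8, c6], axis=2).reshape(n_part, 3)
        frames.append(Frame(time=float(t), box=box.copy(), pos=pos))

    return Trajectory(topology=top, frames=frames, z_period=lz,
                      metadata={"generator": "gen_array", "seed": params.seed,
                                "lattice_kind": lat.kind, "a": lat.a})


def _langevin_mean(kappa: float) -> float:
    """Mean of pdf on [-1,1] proportional to exp(kappa*x) (Langevin function)."""
    if abs(kappa) < 1e-6:
        return kappa / 3.0
    return 1.0 / math.tanh(kappa) - 1.0 / kappa


def _solve_tilt(m: float) -> float:
    """Invert the Langevin function: kappa such that mean cos = m."""
    m = float(np.clip(m, -0.999, 0.999))
    if abs(m) < 1e-12:
        return 0.0
    hi = 3.0
    while _langevin_mean(hi) < abs(m):
        hi *= 2.0
    k = brentq(lambda x: _langevin_mean(x) - abs(m), 1e-9, hi)
    return math.copysign(k, m)


def _sample_tilted_cos(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample cos(alpha) on [-1,1] from exp(kappa*x) tilts with means m.

    The exponential (Boltzmann, dipole-in-field) tilt supports any target
    mean |m| < 1; inverse-CDF sampling keeps the draw vectorizable.
    """
    kap = np.array([_solve_tilt(v) for v in np.asarray(m, dtype=float)])
    u = rng.uniform(size=kap.shape)
    out = np.empty_like(kap)
    small = np.abs(kap) < 1e-8
    out[small] = 2.0 * u[small] - 1.0
    ks = kap[~small]
    us = u[~small]
    # inverse CDF of exp(k x)/Z on [-1,1]
    out[~small] = np.log(np.exp(-ks) + us * (np.exp(ks) - np.exp(-ks))) / ks
    return out


def imposed_eta1(s: np.ndarray, d: float, amplitude: float, decay: float) -> np.ndarray:
    """Target <cos alpha>(s): antisymmetric double-exponential surface profile."""
    s = np.asarray(s, dtype=float)
    return amplitude * (np.exp(-s / decay) - np.exp(-(d - s) / decay))


def gen_water_between_pair(params: WaterProfileParams, lattice: LatticeSpec) -> Trajectory:
    """Dipolar waters filling the cuboid between one DNA pair.

    Waters are uniform in the cuboid (length = interaxial spacing of the
    pair, width = DNA diameter, height = L_z).  Each dipole's cosine with
    the fixed pair-axis unit vector (first -> second site) is drawn from an
    exponential tilt whose mean follows ``imposed_eta1`` at the water's
    axial distance s from the first DNA axis.
    """
    i1, i2 = params.pair_axis
    if i1 == i2:
        raise DomainError("pair sites must be distinct")
    s1 = lattice.sites[i1]
    s2 = lattice.sites[i2]
    d = float(np.linalg.norm(s2 - s1))
    e = (s2 - s1) / d                                  # pair axis (xy)
    perp = np.array([-e[1], e[0]])
    lz = c.HELICAL_PITCH_NM

    n = params.n_water
    rng = np.random.default_rng(params.seed)
    top = Topology(
        ids=np.arange(n),
        kinds=np.full(n, "water", dtype=object),
        mol_ids=np.arange(n),
        charges=np.zeros(n),
    )
    box = np.array([d + 4.0, d + 4.0, lz])
    e3 = np.array([e[0], e[1], 0.0])
    p3 = np.array([perp[0], perp[1], 0.0])
    z3 = np.array([0.0, 0.0, 1.0])

    frames = []
    for t in range(params.n_frames):
        s = rng.uniform(0.0, d, size=n)
        w = rng.uniform(-c.DNA_DIAMETER_NM / 2.0, c.DNA_DIAMETER_NM / 2.0, size=n)
        z = rng.uniform(0.0, lz, size=n)
        xy = s1[None, :] + np.outer(s, e) + np.outer(w, perp)
        pos = np.column_stack([xy, z])
        m = imposed_eta1(s, d, params.eta1_surface, params.decay_length)
        x = _sample_tilted_cos(m, rng)
        psi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        sin_a = np.sqrt(np.clip(1.0 - x ** 2, 0.0, None))
        dirs = (x[:, None] * e3[None, :]
                + (sin_a * np.cos(psi))[:, None] * p3[None, :]
                + (sin_a * np.sin(psi))[:, None] * z3[None, :])
        dip = params.dipole_magnitude * dirs
        frames.append(Frame(time=float(t), box=box.copy(), pos=pos, dipole=dip))

    return Trajectory(topology=top, frames=frames, z_period=lz,
                      metadata={"generator": "gen_water_between_pair",
                                "seed": params.seed, "pair": [int(i1), int(i2)],
                                "spacing": d})


def gen_counterions(n_dna: int, spd_per_dna: int, nacl_pairs: int,
                    box, seed: int = 0,
                    dna_sites: Optional[np.ndarray] = None,
                    excluded_radius: float = 1.2) -> Trajectory:
    """Charge-neutralizing ion complement for an array of n_dna molecules.

    Each DNA (one pitch) carries 20 phosphate charges; spd_per_dna Spd3+
    per molecule plus Na+ make the system neutral, and nacl_pairs neutral
    salt pairs are added.  Ions are placed uniformly outside the excluded
    radius around each DNA axis.
    """
    nphos = c.PHOSPHATES_PER_PITCH
    if spd_per_dna * 3 > nphos:
        raise DomainError(
            f"{spd_per_dna} Spd3+ per DNA would overfill the {nphos} phosphates")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)

    if dna_sites is None:
        # DNA axes on a square grid inside the box
        side = math.ceil(math.sqrt(n_dna))
        gx = (np.arange(side) + 0.5) * box[0] / side
        gy = (np.arange(side) + 0.5) * box[1] / side
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        dna_sites = np.column_stack([xx.ravel(), yy.ravel()])[:n_dna]
    dna_sites = np.asarray(dna_sites, dtype=float)[:, :2]

    n_spd = n_dna * spd_per_dna
    n_na_counter = n_dna * (nphos - 3 * spd_per_dna)
    n_na = n_na_counter + nacl_pairs
    n_cl = nacl_pairs

    kinds, mol_ids, charges, positions = [], [], [], []
    mol = 0
    # phosphate sites: helix of radius 1.0 nm around each axis
    ang = np.linspace(0.0, 2.0 * np.pi, nphos, endpoint=False)
    for i in range(n_dna):
        px = dna_sites[i, 0] + 1.0 * np.cos(ang)
        py = dna_sites[i, 1] + 1.0 * np.sin(ang)
        pz = np.linspace(0.0, box[2], nphos, endpoint=False)
        positions.append(np.column_stack([px, py, pz]))
        kinds += ["dna_site"] * nphos
        mol_ids += [mol] * nphos
        charges += [-1.0] * nphos
        mol += 1

    def place(n_ions):
        out = np.empty((n_ions, 3))
        filled = 0
        while filled < n_ions:
            cand = rng.uniform(0.0, 1.0, size=(max(n_ions, 64), 3)) * box
            d2 = np.min(
                (cand[:, None, 0] - dna_sites[None, :, 0]) ** 2
                + (cand[:, None, 1] - dna_sites[None, :, 1]) ** 2,
                axis=1,
            )
            ok = cand[d2 > excluded_radius ** 2]
            take = min(len(ok), n_ions - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out

    for kind, charge, count in (("spd", 3.0, n_spd), ("na", 1.0, n_na),
                                ("cl", -1.0, n_cl)):
        if count == 0:
            continue
        positions.append(place(count))
        kinds += [kind] * count
        charges += [charge] * count
        mol_ids += list(range(mol, mol + count))
        mol += count

    pos = np.vstack(positions)
    n = len(pos)
    kinds_arr = np.array(kinds, dtype=object)
    charges_arr = np.array(charges)
    top = Topology(ids=np.arange(n), kinds=kinds_arr,
                   mol_ids=np.array(mol_ids), charges=charges_arr,
                   # phosphate sites are hydrogen-bond acceptors; Q4 counts
                   # them among a water's candidate neighbors
                   flags={"is_acceptor": (kinds_arr == "dna_site") & (charges_arr < 0)})
    frame = Frame(time=0.0, box=box.copy(), pos=pos)
    return Trajectory(topology=top, frames=[frame], z_period=float(box[2]),
                      metadata={"generator": "gen_counterions", "seed": seed,
                                "n_spd": n_spd, "n_na": n_na, "n_cl": n_cl})


#: ideal tetrahedron vertex directions
TETRA_DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3.0)


def gen_tetrahedral_fixture(noise: float = 0.0, seed: int = 0,
                            degenerate: bool = False,
                            bond_length: float = 0.28) -> Frame:
    """Central site with four neighbors at tetrahedral vertices + Gaussian noise.

    With ``degenerate`` all four neighbors sit in one direction (the
    collinear limit of the tetrahedrality parameter).
    """
    if noise < 0:
        raise DomainError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    center = np.array([5.0, 5.0, 5.0])
    if degenerate:
        dirs = np.tile(np.array([[0.0, 0.0, 1.0]]), (4, 1))
        offsets = dirs * bond_length * (1.0 + 0.05 * np.arange(4))[:, None]
    else:
        offsets = TETRA_DIRS * bond_length
    neighbors = center + offsets + rng.normal(0.0, noise, size=(4, 3))
    pos = np.vstack([center, neighbors])
    return Frame(time=0.0, box=np.array([10.0, 10.0, 10.0]), pos=pos)
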