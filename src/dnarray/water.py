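"""Water structural observables between DNA pairs.

Profiles are computed along the scaled axis of a DNA pair: r/d_DNA = 0 and
1 are the centers of mass of the first and second molecule.  Only waters in
the inter-DNA cuboid (length = interaxial spacing, width = DNA diameter,
height = L_z) are binned.

Order parameters per bin:

* eta1 = <cos alpha>, eta2 = <(3 cos^2 alpha - 1)/2> with alpha the angle
  between the water dipole and the fixed pair-axis unit vector pointing
  from the first to the second DNA.  The fixed axis makes eta1 exactly
  antisymmetric and eta2 symmetric under swap of the pair, matching the
  symmetry the profiles are meant to exhibit for apposed identical
  surfaces.
* eta3 = <Q_ee>, the diagonal pair-axis component of the molecular
  quadrupole tensor about the molecular center of mass.  For point-dipole
  waters the charge geometry is reconstructed as an SPC-like 3-site
  molecule oriented along the dipole, azimuthally averaged in closed form
  (see ``quadrupole_axis_component``); eta3 is nonzero even for isotropic
  dipoles, as a real quadrupole density is.
* q4 tetrahedrality of the 4 nearest neighbors irrespective of identity
  (waters and electronegative DNA sites alike), 1 for a perfect
  tetrahedron, ensemble mean 0 for random directions.
* local dielectric constant from the Kirkwood factor of a probe sphere via
  the Kirkwood-Froehlich relation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from . import constants as c
from .errors import DegenerateInputError, DomainError, NumericalError
from .io import Frame, Trajectory
from .lattice import LatticeSpec

# --- SPC-like charge geometry used to reconstruct a quadrupole from a
# point dipole: q_H = +0.41 e at r(OH) = 0.1 nm, HOH angle 109.47 deg,
# moments taken about the molecular COM, azimuthally averaged about the
# dipole (symmetry) axis.  A0 is the axial, B0 the transverse second
# moment; MU0 the geometry's dipole (e nm), used to scale charges so the
# reconstructed dipole matches the particle's.
_R_OH = 0.1
_HALF_HOH = math.radians(109.47 / 2.0)
_Q_H = 0.41
_M_O, _M_H = 15.999, 1.008
_ZH = _R_OH * math.cos(_HALF_HOH)
_RHOH = _R_OH * math.sin(_HALF_HOH)
_ZCOM = 2.0 * _M_H * _ZH / (_M_O + 2.0 * _M_H)
MU0_E_NM = 2.0 * _Q_H * _ZH  # dipole about any origin (neutral molecule)
A0_E_NM2 = -2.0 * _Q_H * _ZCOM ** 2 + 2.0 * _Q_H * (_ZH - _ZCOM) ** 2
B0_E_NM2 = _Q_H * _RHOH ** 2


@dataclasses.dataclass
class PairAxisFrame:
    """Geometry of one DNA pair's inter-molecular cuboid."""

    origin: np.ndarray          # xy of first DNA axis, nm
    axis: np.ndarray            # unit vector first -> second DNA, xy
    spacing: float              # d, nm
    width: float = c.DNA_DIAMETER_NM
    height: float = c.HELICAL_PITCH_NM
    pair: tuple[int, int] = (0, 1)

    @classmethod
    def from_lattice(cls, lattice: LatticeSpec, i1: int, i2: int) -> "PairAxisFrame":
        s1, s2 = lattice.sites[i1], lattice.sites[i2]
        d = float(np.linalg.norm(s2 - s1))
        if d == 0:
            raise DomainError("pair sites coincide")
        return cls(origin=np.asarray(s1, float), axis=(s2 - s1) / d, spacing=d,
                   pair=(i1, i2))

    def swapped(self) -> "PairAxisFrame":
        """Same cuboid viewed from the other DNA (mirror of the scaled axis)."""
        return PairAxisFrame(
            origin=self.origin + self.axis * self.spacing, axis=-self.axis,
            spacing=self.spacing, width=self.width, height=self.height,
            pair=(self.pair[1], self.pair[0]))


@dataclasses.dataclass
class WaterProfiles:
    bin_centers: np.ndarray     # scaled r/d_DNA
    eta1: np.ndarray
    eta2: np.ndarray
    eta3: np.ndarray
    eta1_sd: np.ndarray
    eta2_sd: np.ndarray
    eta3_sd: np.ndarray
    population: np.ndarray      # total waters binned, per bin
    q4: Optional[np.ndarray] = None
    q4_sd: Optional[np.ndarray] = None
    epsilon_local: Optional[np.ndarray] = None


def quadrupole_axis_component(cos_alpha: np.ndarray, dipole_magnitude: np.ndarray) -> np.ndarray:
    """Azimuth-averaged Q_ee of an SPC-like water with dipole at angle alpha.

    Q_ee = f * (A0 * cos^2 alpha + B0 * (1 - cos^2 alpha)), f = mu / mu0.
    """
    f = np.asarray(dipole_magnitude, float) / MU0_E_NM
    c2 = np.asarray(cos_alpha, float) ** 2
    return f * (A0_E_NM2 * c2 + B0_E_NM2 * (1.0 - c2))


def _select_waters(traj: Trajectory, pair_frame: PairAxisFrame):
    """Per frame: scaled axial coords and dipole cosines of cuboid waters."""
    top = traj.topology
    wsel = np.flatnonzero(top.kinds == "water")
    if wsel.size == 0:
        raise DomainError("trajectory contains no waters")
    e = np.asarray(pair_frame.axis, float)
    e3 = np.array([e[0], e[1], 0.0])
    scaled, cosa, mags = [], [], []
    for fr in traj.frames:
        if fr.dipole is None:
            raise DomainError("waters carry no dipoles")
        xy = fr.pos[wsel, :2] - pair_frame.origin
        s = xy @ e
        perp = xy @ np.array([-e[1], e[0]])
        inside = (s >= 0) & (s <= pair_frame.spacing) & (np.abs(perp) <= pair_frame.width / 2.0)
        dip = fr.dipole[wsel][inside]
        mag = np.linalg.norm(dip, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ca = np.where(mag > 0, dip @ e3 / np.where(mag > 0, mag, 1.0), 0.0)
        scaled.append(s[inside] / pair_frame.spacing)
        cosa.append(ca)
        mags.append(mag)
    return scaled, cosa, mags


def eta_profiles(traj: Trajectory, pair_frame: PairAxisFrame, n_bins: int = 20,
                 n_boot: int = 200, seed: int = 0) -> WaterProfiles:
    """Binned eta1/eta2/eta3 profiles along the scaled pair axis.

    Error bars are bootstrap standard deviations over frames (n_boot
    resamples).  Empty bins are reported with population 0 and NaN values,
    never fabricated.
    """
    scaled, cosa, mags = _select_waters(traj, pair_frame)
    n_frames = len(scaled)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # per frame, per bin sums -> frame-resampled bootstrap
    sums = np.zeros((n_frames, n_bins, 4))  # cos, cos^2, Qee, count
    for t in range(n_frames):
        idx = np.clip(np.digitize(scaled[t], edges) - 1, 0, n_bins - 1)
        if len(idx) == 0:
            continue
        qee = quadrupole_axis_component(cosa[t], mags[t])
        np.add.at(sums[t, :, 0], idx, cosa[t])
        np.add.at(sums[t, :, 1], idx, cosa[t] ** 2)
        np.add.at(sums[t, :, 2], idx, qee)
        np.add.at(sums[t, :, 3], idx, 1.0)

    def profile(frame_sums):
        tot = frame_sums.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = np.where(tot[:, 3] > 0, tot[:, 0] / tot[:, 3], np.nan)
            m2 = np.where(tot[:, 3] > 0, tot[:, 1] / tot[:, 3], np.nan)
            m3 = np.where(tot[:, 3] > 0, tot[:, 2] / tot[:, 3], np.nan)
        return m1, 0.5 * (3.0 * m2 - 1.0), m3, tot[:, 3]

    eta1, eta2, eta3, pop = profile(sums)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3, n_bins))
    for b in range(n_boot):
        pick = rng.integers(0, n_frames, size=n_frames)
        b1, b2, b3, _ = profile(sums[pick])
        boots[b] = (b1, b2, b3)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (empty) bins
        sd = np.nanstd(boots, axis=0)
    return WaterProfiles(bin_centers=centers, eta1=eta1, eta2=eta2, eta3=eta3,
                         eta1_sd=sd[0], eta2_sd=sd[1], eta3_sd=sd[2],
                         population=pop)


def acceptor_candidates(topology) -> np.ndarray:
    """Indices eligible as Q4 neighbors: waters plus electronegative DNA sites.

    Electronegative DNA sites are those flagged ``is_acceptor`` in the
    topology; when the flag is absent, negatively charged dna sites are
    used.
    """
    waters = topology.kinds == "water"
    if topology.flags is not None and "is_acceptor" in topology.flags:
        acceptors = np.asarray(topology.flags["is_acceptor"], dtype=bool)
    else:
        acceptors = (topology.kinds == "dna_site") & (topology.charges < 0)
    return np.flatnonzero(waters | acceptors)


def q4_tetrahedrality(frame: Frame, centers: Sequence[int],
                      candidates: Sequence[int],
                      z_period: Optional[float] = None) -> np.ndarray:
    """Tetrahedrality q4 of each center from its 4 nearest candidates.

    q4 = 1 - (3/8) * sum_{j<k} (cos psi_jk + 1/3)^2 over the 6 angle pairs
    at the center; neighbors are the 4 nearest candidates irrespective of
    identity, with z-periodic minimum-image distances when ``z_period`` is
    given.  Centers with fewer than 4 candidates get NaN.
    """
    centers = np.asarray(centers, dtype=int)
    candidates = np.asarray(candidates, dtype=int)
    out = np.full(len(centers), np.nan)
    for n, ci in enumerate(centers):
        others = candidates[candidates != ci]
        if len(others) < 4:
            continue
        d = frame.pos[others] - frame.pos[ci]
        if z_period is not None:
            d[:, 2] -= z_period * np.round(d[:, 2] / z_period)
        r = np.linalg.norm(d, axis=1)
        four = np.argsort(r)[:4]
        v = d[four] / r[four, None]
        s = 0.0
        for j in range(3):
            for k in range(j + 1, 4):
                s += (v[j] @ v[k] + 1.0 / 3.0) ** 2
        out[n] = 1.0 - 3.0 / 8.0 * s
    return out


def q4_random_gas(n_trials: int, seed: int = 0) -> np.ndarray:
    """q4 of 4 uniformly random neighbor directions, n_trials samples.

    Monte-Carlo realization of the ideal disordered-gas limit (mean 0).
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_trials, 4, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    dots = np.einsum("nid,njd->nij", v, v)
    iu, ju = np.triu_indices(4, k=1)
    return 1.0 - 3.0 / 8.0 * np.sum((dots[:, iu, ju] + 1.0 / 3.0) ** 2, axis=1)


def kirkwood_gk(traj: Trajectory, probe_radius: float,
                region: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                z_period: Optional[float] = None) -> float:
    """Kirkwood factor G_k of probe waters (self term included).

    G_k = <mu_i . sum_{j in sphere(i)} mu_j> / <mu^2>, averaged over probe
    molecules whose positions satisfy ``region`` (all waters by default).
    """
    top = traj.topology
    wsel = np.flatnonzero(top.kinds == "water")
    if wsel.size == 0:
        raise DomainError("no waters in trajectory")
    num, den, count = 0.0, 0.0, 0
    for fr in traj.frames:
        if fr.dipole is None:
            raise DomainError("waters carry no dipoles")
        pos = fr.pos[wsel]
        mu = fr.dipole[wsel]
        probes = np.arange(len(wsel)) if region is None else np.flatnonzero(region(pos))
        if len(probes) == 0:
            continue
        d = pos[probes, None, :] - pos[None, :, :]
        if z_period is not None:
            d[..., 2] -= z_period * np.round(d[..., 2] / z_period)
        within = np.sum(d ** 2, axis=2) <= probe_radius ** 2
        msum = within @ mu                       # (n_probes, 3) incl. self
        num += np.sum(np.einsum("ij,ij->i", mu[probes], msum))
        den += np.sum(np.sum(mu[probes] ** 2, axis=1))
        count += len(probes)
    if count == 0:
        raise DomainError("no probe waters in region")
    if den == 0.0:
        return 0.0
    return float(num / den)


def kf_rhs(number_density_nm3: float, dipole_e_nm: float, gk: float,
           temperature: float = 300.0) -> float:
    """y = rho mu^2 G_k / (9 eps0 kB T) of the Kirkwood-Froehlich relation."""
    mu_si = dipole_e_nm * c.E_CHARGE * 1e-9
    rho_si = number_density_nm3 * 1e27
    return rho_si * mu_si ** 2 * gk / (9.0 * c.EPS0_SI * c.KB_SI * temperature)


def epsilon_from_gk(number_density_nm3: float, dipole_e_nm: float, gk: float,
                    temperature: float = 300.0) -> float:
    """Solve (eps-1)(2 eps+1)/(9 eps) = y for eps by bracketed root finding."""
    if dipole_e_nm == 0.0 or gk == 0.0:
        return 1.0
    y = kf_rhs(number_density_nm3, dipole_e_nm, gk, temperature)

    def f(eps):
        return (eps - 1.0) * (2.0 * eps + 1.0) / (9.0 * eps) - y

    lo, hi = 1.0, 200.0
    if f(lo) * f(hi) > 0:
        raise NumericalError(
            f"no dielectric root in [{lo}, {hi}] for y={y:.4g} "
            f"(rho={number_density_nm3:.4g} nm^-3, mu={dipole_e_nm:.4g} e nm, Gk={gk:.4g})")
    return float(brentq(f, lo, hi, xtol=1e-10))


def kirkwood_local_epsilon(traj: Trajectory, probe_radius: float = 0.6,
                           region: Optional[Callable] = None,
                           number_density: Optional[float] = None,
                           temperature: float = 300.0,
                           z_period: Optional[float] = None) -> float:
    """Local dielectric constant of waters in a region.

    When ``number_density`` (nm^-3) is not given it is estimated as waters
    per box volume of the first frame, which is only meaningful when waters
    fill the box.
    """
    gk = kirkwood_gk(traj, probe_radius, region=region, z_period=z_period)
    top = traj.topology
    wsel = np.flatnonzero(top.kinds == "water")
    if number_density is None:
        box = np.asarray(traj.frames[0].box, float)
        number_density = len(wsel) / float(np.prod(box))
    mags = np.linalg.norm(traj.frames[0].dipole[wsel], axis=1)
    mu = float(np.mean(mags))
    return epsilon_from_gk(number_density, mu, gk, temperature)


@dataclasses.dataclass
class OccupancyResult:
    mean_occupancy: float
    mean_residence_ps: float
    n_intervals: int
    residence_by_gap: dict[int, float]   # gap tolerance -> mean residence (ps)


def occupancy_residence(traj: Trajectory, reference_sites: np.ndarray,
                        cutoff: float, gap_tolerance: int = 0,
                        selection: Optional[np.ndarray] = None,
                        z_period: Optional[float] = None) -> OccupancyResult:
    """Time-averaged occupancy and mean residence time near reference sites.

    Occupancy is the mean count of selected particles within ``cutoff`` of
    any reference site.  Residence is the mean duration of continuous
    within-cutoff intervals, merging gaps of at most ``gap_tolerance``
    frames; sensitivity is reported for every gap from 0 up to the
    requested tolerance.
    """
    if len(traj) < 2:
        raise DegenerateInputError("occupancy_residence needs >= 2 frames")
    ref = np.atleast_2d(np.asarray(reference_sites, float))
    if ref.shape[1] == 2:
        ref = np.column_stack([ref, np.zeros(len(ref))])
    sel = np.arange(traj.n_particles) if selection is None else np.asarray(selection)

    inside = np.empty((len(traj), len(sel)), dtype=bool)
    for t, fr in enumerate(traj.frames):
        d = fr.pos[sel][:, None, :] - ref[None, :, :]
        if z_period is not None:
            d[..., 2] -= z_period * np.round(d[..., 2] / z_period)
        inside[t] = np.any(np.sum(d ** 2, axis=2) <= cutoff ** 2, axis=1)

    times = np.array([fr.time for fr in traj.frames])
    dts = np.diff(times)
    dt = float(dts.mean()) if np.all(dts > 0) else 1.0

    def intervals(series, gap):
        runs, start = [], None
        missing = 0
        for t, v in enumerate(series):
            if v:
                if start is None:
                    start = t
                missing = 0
            elif start is not None:
                missing += 1
                if missing > gap:
                    runs.append((start, t - missing))
                    start, missing = None, 0
        if start is not None:
            runs.append((start, len(series) - 1 - missing))
        return runs

    by_gap = {}
    main_runs = 0
    for g in range(gap_tolerance + 1):
        durations = []
        for p in range(inside.shape[1]):
            for s, e in intervals(inside[:, p], g):
                durations.append((e - s + 1) * dt)
        by_gap[g] = float(np.mean(durations)) if durations else 0.0
        if g == gap_tolerance:
            main_runs = len(durations)

    return OccupancyResult(
        mean_occupancy=float(inside.sum(axis=1).mean()),
        mean_residence_ps=by_gap[gap_tolerance],
        n_intervals=main_runs,
        residence_by_gap=by_gap,
    )
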