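"""Positional and azimuthal orientational order of the DNA array.

Two normalized fluctuation statistics drive the Lindemann-style phase
classification:

* sigma_r / a  -- per molecule, the RMS of the 2D deviation of its center
  of mass from its own time mean, averaged over molecules and divided by
  the lattice parameter a.
* sigma_phi / pi -- per nearest-neighbor pair, the RMS of the
  height-normalized relative azimuth Delta_phi about its own time mean,
  averaged over pairs and divided by pi.

Delta_phi between two molecules averages, over base pairs k,

    phi_{k,1} - phi_{k,2} + 2*pi*(z_{k,1} - z_{k,2}) / L_z,

wrapped to (-pi, pi]: the z term maps both azimuths to a common height
using the helical advance per unit height, so a rigid screw displacement
(coupled translation + rotation with pitch L_z) contributes nothing.  The
azimuth of a base pair is the angle of its C8-proxy -> C6-proxy marker
vector against the x axis.

A lattice melts (positionally or rotationally) when the corresponding
statistic exceeds the empirical threshold 0.1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ConsistencyError, DegenerateInputError, DomainError, NoCrossingError
from .io import Trajectory
from .lattice import LatticeSpec, NeighborShell

LINDEMANN_THRESHOLD = 0.1


@dataclasses.dataclass
class OrderSeriesPoint:
    concentration: float        # mg/ml
    spacing: float              # nm
    sigma_r_over_a: float
    sigma_phi_over_pi: float
    n_frames: int

    def __post_init__(self):
        if self.sigma_r_over_a < 0 or self.sigma_phi_over_pi < 0:
            raise DomainError("fluctuation statistics must be >= 0")


def _dna_coms(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, n_mol, 2) DNA COM xy positions and the molecule ids."""
    top = traj.topology
    sel = np.flatnonzero(top.kinds == "dna_site")
    if sel.size == 0:
        raise DomainError("trajectory contains no dna_site particles")
    mols = np.unique(top.mol_ids[sel])
    pos = traj.positions()[:, sel, :2]          # (T, n_sel, 2)
    coms = np.empty((pos.shape[0], len(mols), 2))
    for j, m in enumerate(mols):
        msel = top.mol_ids[sel] == m
        coms[:, j, :] = pos[:, msel, :].mean(axis=1)
    return coms, mols


def discard_equilibration(traj: Trajectory, fraction: float = 0.1) -> Trajectory:
    """Trajectory view without the first ``fraction`` of frames."""
    skip = int(np.floor(len(traj) * fraction))
    return Trajectory(topology=traj.topology, frames=traj.frames[skip:],
                      z_period=traj.z_period, metadata=traj.metadata)


def sigma_r(traj: Trajectory, lattice: LatticeSpec, remove_drift: bool = False) -> float:
    """Normalized positional RMS fluctuation sigma_r / a.

    Per molecule the RMS (over frames) of the 2D deviation from that
    molecule's own time mean; averaged over molecules, divided by a.  By
    default no array-wide drift is removed (only per-molecule means are
    subtracted); ``remove_drift`` subtracts the per-frame array COM first.
    """
    if len(traj) < 2:
        raise DegenerateInputError("sigma_r needs at least 2 frames")
    coms, _ = _dna_coms(traj)
    if remove_drift:
        coms = coms - coms.mean(axis=1, keepdims=True)
    dev = coms - coms.mean(axis=0, keepdims=True)     # (T, M, 2)
    per_mol_rms = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    return float(per_mol_rms.mean() / lattice.a)


def _wrap(angle):
    """Wrap to (-pi, pi]."""
    return -np.mod(-np.asarray(angle) + np.pi, 2.0 * np.pi) + np.pi


def _bp_azimuth_height(traj: Trajectory, mol: int) -> tuple[np.ndarray, np.ndarray]:
    """(T, n_bp) azimuths (C8->C6 vector vs x axis) and heights of one molecule."""
    top = traj.topology
    if top.roles is None or top.bps is None:
        raise ConsistencyError("topology lacks base-pair marker roles")
    sel = (top.kinds == "dna_site") & (top.mol_ids == mol)
    c8 = np.flatnonzero(sel & (top.roles == "c8"))
    c6 = np.flatnonzero(sel & (top.roles == "c6"))
    if len(c8) == 0 or len(c8) != len(c6):
        raise ConsistencyError(f"molecule {mol}: unmatched c8/c6 markers")
    c8 = c8[np.argsort(top.bps[c8])]
    c6 = c6[np.argsort(top.bps[c6])]
    if not np.array_equal(top.bps[c8], top.bps[c6]):
        raise ConsistencyError(f"molecule {mol}: c8/c6 base-pair indices differ")
    pos = traj.positions()
    vec = pos[:, c6, :2] - pos[:, c8, :2]
    phi = np.arctan2(vec[..., 1], vec[..., 0])
    z = pos[:, c8, 2]
    return phi, z


def delta_phi_pair(traj: Trajectory, mol_1: int, mol_2: int) -> np.ndarray:
    """Height-normalized relative azimuth of a molecule pair, per frame (rad).

    Mean over base pairs of wrap(phi_k1 - phi_k2 + 2*pi*(z_k1 - z_k2)/L_z).
    """
    phi1, z1 = _bp_azimuth_height(traj, mol_1)
    phi2, z2 = _bp_azimuth_height(traj, mol_2)
    if phi1.shape[1] != phi2.shape[1]:
        raise ConsistencyError(
            f"molecules {mol_1} and {mol_2} have different base-pair counts")
    term = _wrap(phi1 - phi2 + 2.0 * np.pi * (z1 - z2) / traj.z_period)
    return term.mean(axis=1)


def sigma_phi(traj: Trajectory, neighbor_shell: NeighborShell,
              mol_ids: Sequence[int] | None = None) -> float:
    """Normalized azimuthal RMS fluctuation sigma_phi / pi over NN pairs.

    Each pair's Delta_phi time series is unwrapped before subtracting its
    own time mean, so branch jumps of the wrap do not corrupt the RMS.
    ``mol_ids`` maps shell site indices to molecule ids (identity default).
    """
    if len(traj) < 2:
        raise DegenerateInputError("sigma_phi needs at least 2 frames")
    if not neighbor_shell.pairs:
        raise DomainError("neighbor shell is empty")
    rms = []
    for i, j in neighbor_shell.pairs:
        mi = mol_ids[i] if mol_ids is not None else i
        mj = mol_ids[j] if mol_ids is not None else j
        series = np.unwrap(delta_phi_pair(traj, mi, mj))
        rms.append(np.sqrt(np.mean((series - series.mean()) ** 2)))
    return float(np.mean(rms) / np.pi)


def lindemann_classify(value: float, threshold: float = LINDEMANN_THRESHOLD) -> str:
    """'ordered' below the threshold, 'disordered' at or above it."""
    if value < 0:
        raise DomainError("fluctuation statistic must be >= 0")
    return "ordered" if value < threshold else "disordered"


def transition_density(series: Sequence[OrderSeriesPoint], which: str = "positional",
                       threshold: float = LINDEMANN_THRESHOLD) -> float:
    """Concentration (mg/ml) where the chosen statistic crosses the threshold.

    The series must be sorted by concentration; the crossing is linearly
    interpolated between the bracketing pair.  Fluctuations grow toward low
    density, so the first bracket scanning from high to low concentration
    is used.
    """
    if which not in ("positional", "rotational"):
        raise DomainError("which must be 'positional' or 'rotational'")
    pts = sorted(series, key=lambda p: p.concentration)
    vals = np.array([
        p.sigma_r_over_a if which == "positional" else p.sigma_phi_over_pi
        for p in pts
    ])
    concs = np.array([p.concentration for p in pts])
    for k in range(len(pts) - 1, 0, -1):
        lo, hi = vals[k], vals[k - 1]
        if (lo - threshold) * (hi - threshold) <= 0 and lo != hi:
            frac = (threshold - hi) / (lo - hi)
            return float(concs[k - 1] + frac * (concs[k] - concs[k - 1]))
    side = "below" if vals.max() < threshold else "above"
    raise NoCrossingError(
        f"{which} statistic never crosses {threshold} (all {side})", side=side)
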