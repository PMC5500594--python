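"""Trajectory data model and extended-XYZ I/O.

A trajectory is an ordered list of frames of typed particles.  Coordinates
are in nm, right-handed, with z along the DNA long axis (periodic with
period ``z_period``, one helical pitch by default) and the lattice in the
x-y plane.  Per-particle typing (kind, molecule id, charge and optional
base-pair marker roles) lives in a YAML topology sidecar shared by all
frames; the frames themselves are extended-XYZ with a ``key=value`` comment
line carrying the box and time.

Positions (and dipoles) are serialized to 6 decimals, so read(write(t)) is
the identity for any trajectory whose coordinates are representable at that
precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import yaml

from .errors import ConsistencyError, DomainError, ParseError

logger = logging.getLogger("dnarray")

PARTICLE_KINDS = ("dna_site", "water", "na", "cl", "spd", "solvent_cg")

#: fixed charge per ion kind (elementary charges)
ION_CHARGES = {"na": 1.0, "cl": -1.0, "spd": 3.0}

PRECISION = 6  # decimals for serialized coordinates


@dataclasses.dataclass
class Particle:
    """A single typed particle (a convenience view; frames store arrays)."""

    id: int
    kind: str
    mol_id: int
    pos: np.ndarray
    charge: float = 0.0
    dipole: Optional[np.ndarray] = None
    role: Optional[str] = None  # e.g. 'c8'/'c6' base-pair markers
    bp: Optional[int] = None    # base-pair index within the molecule


@dataclasses.dataclass
class Topology:
    """Per-particle static attributes, columnar."""

    ids: np.ndarray
    kinds: np.ndarray          # array of str
    mol_ids: np.ndarray
    charges: np.ndarray
    roles: Optional[np.ndarray] = None   # str or '' where unset
    bps: Optional[np.ndarray] = None     # int, -1 where unset
    flags: Optional[dict] = None         # e.g. {'is_acceptor': bool array}

    def __len__(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        n = len(self.ids)
        for name in ("kinds", "mol_ids", "charges"):
            if len(getattr(self, name)) != n:
                raise ConsistencyError(f"topology column {name!r} has wrong length")
        if len(np.unique(self.ids)) != n:
            raise ConsistencyError("particle ids are not unique")
        for k in np.unique(self.kinds):
            if k not in PARTICLE_KINDS:
                raise DomainError(f"unknown particle kind {k!r}")
        for kind, q in ION_CHARGES.items():
            sel = self.kinds == kind
            if sel.any() and not np.allclose(self.charges[sel], q):
                raise ConsistencyError(f"{kind} particles must carry charge {q:+g}")
        dna = self.kinds == "dna_site"
        if dna.any() and (self.charges[dna] > 0).any():
            raise ConsistencyError("dna_site charge must be <= 0")


@dataclasses.dataclass
class Frame:
    """One time step: positions (N,3) nm and optional dipoles (N,3) e.nm."""

    time: float
    box: np.ndarray
    pos: np.ndarray
    dipole: Optional[np.ndarray] = None

    def validate(self) -> None:
        if not np.all(np.isfinite(self.pos)):
            raise ConsistencyError("non-finite position")
        if np.asarray(self.box).shape != (3,) or np.any(np.asarray(self.box) <= 0):
            raise ConsistencyError("box must be 3 positive lengths")


@dataclasses.dataclass
class Trajectory:
    """Ordered frames over a fixed topology; z-periodic with period z_period."""

    topology: Topology
    frames: list[Frame]
    z_period: float = 3.4
    metadata: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return len(self.topology)

    def validate(self) -> None:
        if self.z_period <= 0:
            raise DomainError("z_period must be positive")
        self.topology.validate()
        n = self.n_particles
        for i, fr in enumerate(self.frames):
            fr.validate()
            if fr.pos.shape != (n, 3):
                raise ConsistencyError(
                    f"frame {i} has {fr.pos.shape[0]} particles, topology has {n}"
                )
        water = self.topology.kinds == "water"
        if water.any():
            for i, fr in enumerate(self.frames):
                if fr.dipole is None:
                    raise ConsistencyError(f"frame {i}: water present but no dipoles")

    def particles(self, frame_index: int = 0) -> Iterator[Particle]:
        """Yield Particle views of one frame (slow path, for inspection)."""
        top, fr = self.topology, self.frames[frame_index]
        for j in range(len(top)):
            yield Particle(
                id=int(top.ids[j]),
                kind=str(top.kinds[j]),
                mol_id=int(top.mol_ids[j]),
                pos=fr.pos[j],
                charge=float(top.charges[j]),
                dipole=None if fr.dipole is None else fr.dipole[j],
                role=None if top.roles is None or top.roles[j] == "" else str(top.roles[j]),
                bp=None if top.bps is None or top.bps[j] < 0 else int(top.bps[j]),
            )

    def positions(self) -> np.ndarray:
        """(n_frames, N, 3) stacked positions."""
        return np.stack([fr.pos for fr in self.frames])

    def dipoles(self) -> np.ndarray:
        return np.stack([fr.dipole for fr in self.frames])


# ---------------------------------------------------------------------------
# extended-XYZ frames + YAML topology sidecar


def _parse_comment(comment: str, lineno: int) -> tuple[float, np.ndarray, bool]:
    """Parse the key=value comment line; returns (time, box, has_dipole)."""
    fields: dict[str, str] = {}
    # tokens are key=value; quoted values may contain spaces
    import shlex

    try:
        tokens = shlex.split(comment)
    except ValueError as exc:
        raise ParseError(f"unbalanced quoting in comment: {exc}", line=lineno)
    for tok in tokens:
        if "=" not in tok:
            raise ParseError(f"comment token {tok!r} is not key=value", line=lineno)
        key, val = tok.split("=", 1)
        fields[key] = val
    if "Lattice" not in fields:
        raise ParseError("comment line lacks Lattice=", line=lineno)
    try:
        lat = np.array(fields["Lattice"].split(), dtype=float)
    except ValueError:
        raise ParseError("Lattice values are not numeric", line=lineno)
    if lat.size != 9:
        raise ParseError("Lattice must contain 9 numbers", line=lineno)
    box = lat.reshape(3, 3).diagonal().copy()
    time = float(fields.get("Time", 0.0))
    has_dipole = "dipole" in fields.get("Properties", "")
    return time, box, has_dipole


def read_frames(path) -> list[tuple[float, np.ndarray, np.ndarray, Optional[np.ndarray], list[str]]]:
    """Low-level extended-XYZ parse; returns per-frame raw records."""
    out = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected particle count, got {lines[i]!r}", line=i + 1)
        if i + 1 >= len(lines):
            raise ParseError("truncated frame: missing comment line", line=i + 2)
        time, box, has_dipole = _parse_comment(lines[i + 1], i + 2)
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(f"truncated frame: expected {n} particle lines", line=i + 2 + len(body))
        species, rows = [], []
        ncol = 7 if has_dipole else 4
        for k, ln in enumerate(body):
            parts = ln.split()
            if len(parts) != ncol:
                raise ParseError(
                    f"expected {ncol} columns, got {len(parts)}", line=i + 3 + k
                )
            species.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        arr = np.asarray(rows)
        pos = arr[:, :3]
        dip = arr[:, 3:6] if has_dipole else None
        out.append((time, box, pos, dip, species))
        i += 2 + n
    return out


def read_trajectory(path, topology_path) -> Trajectory:
    """Read an extended-XYZ trajectory with its YAML topology sidecar.

    Raises ParseError on malformed frames (naming the line number) and
    ConsistencyError when frames disagree with the topology or each other.
    """
    top, z_period, metadata = read_topology(topology_path)
    records = read_frames(path)
    frames = []
    ref_species = list(top.kinds)
    for idx, (time, box, pos, dip, species) in enumerate(records):
        if len(species) != len(top):
            raise ConsistencyError(
                f"frame {idx} has {len(species)} particles, topology declares {len(top)}"
            )
        if species != ref_species:
            raise ConsistencyError(f"frame {idx} particle kinds differ from topology")
        frames.append(Frame(time=time, box=box, pos=pos, dipole=dip))
    traj = Trajectory(topology=top, frames=frames, z_period=z_period, metadata=metadata)
    traj.validate()
    return traj


def write_trajectory(traj: Trajectory, path, topology_path=None) -> None:
    """Write extended-XYZ frames; optionally the topology sidecar alongside."""
    path = Path(path)
    fmt = f"%.{PRECISION}f"
    with open(path, "w") as fh:
        for fr in traj.frames:
            has_dip = fr.dipole is not None
            props = "species:S:1:pos:R:3" + (":dipole:R:3" if has_dip else "")
            lat = "{0} 0 0 0 {1} 0 0 0 {2}".format(
                *(fmt % b for b in np.asarray(fr.box, dtype=float))
            )
            fh.write(f"{len(traj.topology)}\n")
            fh.write(f'Time={fr.time:.6f} Lattice="{lat}" Properties={props}\n')
            for j in range(len(traj.topology)):
                cols = [str(traj.topology.kinds[j])]
                cols += [fmt % x for x in fr.pos[j]]
                if has_dip:
                    cols += [fmt % x for x in fr.dipole[j]]
                fh.write(" ".join(cols) + "\n")
    if topology_path is not None:
        write_topology(traj.topology, topology_path, z_period=traj.z_period,
                       metadata=traj.metadata)


def read_topology(path) -> tuple[Topology, float, dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "particles" not in doc:
        raise ParseError(f"topology file {path} lacks a 'particles' section")
    cols = doc["particles"]
    top = Topology(
        ids=np.asarray(cols["id"], dtype=int),
        kinds=np.asarray(cols["kind"], dtype=object),
        mol_ids=np.asarray(cols["mol_id"], dtype=int),
        charges=np.asarray(cols["charge"], dtype=float),
        roles=np.asarray(cols["role"], dtype=object) if "role" in cols else None,
        bps=np.asarray(cols["bp"], dtype=int) if "bp" in cols else None,
        flags={k: np.asarray(v) for k, v in doc.get("flags", {}).items()} or None,
    )
    top.validate()
    return top, float(doc.get("z_period", 3.4)), doc.get("metadata", {}) or {}


def write_topology(top: Topology, path, z_period: float = 3.4, metadata=None) -> None:
    cols = {
        "id": [int(x) for x in top.ids],
        "kind": [str(x) for x in top.kinds],
        "mol_id": [int(x) for x in top.mol_ids],
        "charge": [float(x) for x in top.charges],
    }
    if top.roles is not None:
        cols["role"] = [str(x) for x in top.roles]
    if top.bps is not None:
        cols["bp"] = [int(x) for x in top.bps]
    doc = {"z_period": float(z_period), "metadata": metadata or {}, "particles": cols}
    if top.flags:
        doc["flags"] = {k: [bool(x) for x in v] for k, v in top.flags.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, default_flow_style=True, sort_keys=False)


def file_hash(path) -> str:
    """Short sha256 of a file, for structured log lines."""
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:12]


def log_stage(stage: str, seed=None, params=None, inputs: Sequence = ()) -> None:
    """One structured log line per CLI stage (input hashes, parameters, seed)."""
    hashes = {str(p): file_hash(p) for p in inputs}
    logger.info("stage=%s seed=%s params=%s inputs=%s", stage, seed, params, hashes)
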