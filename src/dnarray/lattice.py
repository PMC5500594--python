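"""Lattice geometry of columnar DNA arrays.

Dense parallel DNA helices pack on a hexagonal (hex) or centered-rectangular
(orto) two-dimensional lattice described by parameters a and b.  The hex
lattice is the special case b/a = sqrt(3); experimentally the orthorhombic
distortion reaches b/a = 1.43.  Sites are generated row by row,

    site(r, c) = (c*a + (r mod 2)*a/2,  r*b/2),

which for b/a = sqrt(3) is the ideal triangular lattice with nearest-neighbor
distance a.  The interaxial spacing d is the nearest-neighbor site distance:
d = a for hex, d = (a/2)*sqrt(1 + (b/a)^2) for orto.

The module also converts between interaxial spacing and DNA mass density
(mg/ml) using standard B-DNA constants, and evaluates the inverse Debye
screening length of the bathing electrolyte.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import constants as c
from .errors import DomainError, GeometryError

SQRT3 = math.sqrt(3.0)


@dataclasses.dataclass
class LatticeSpec:
    kind: str                 # 'hex' | 'orto'
    a: float                  # nm
    b_over_a: float
    n_rows: int
    n_cols: int
    sites: np.ndarray         # (n_rows*n_cols, 2) nm
    angle: float              # degrees, arctan(b/a)

    @property
    def b(self) -> float:
        return self.a * self.b_over_a

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def spacing(self) -> float:
        """Interaxial spacing d = nearest-neighbor site distance, nm."""
        if self.kind == "hex":
            return self.a
        return 0.5 * self.a * math.hypot(1.0, self.b_over_a)


@dataclasses.dataclass
class NeighborShell:
    pairs: list[tuple[int, int]]   # symmetric-unique (i < j)
    shell_distance: float          # nm
    coordination: int              # of the probed interior site


def build_lattice(kind: str, a: float, b_over_a: float, n_rows: int, n_cols: int) -> LatticeSpec:
    """Construct a hex or orto lattice of n_rows x n_cols sites."""
    if a <= 0:
        raise DomainError("lattice parameter a must be positive")
    if n_rows < 1 or n_cols < 1:
        raise DomainError("n_rows and n_cols must be >= 1")
    if kind == "hex":
        if abs(b_over_a - SQRT3) > 1e-9:
            raise DomainError("hex lattice requires b/a = sqrt(3)")
    elif kind == "orto":
        if not (1.0 < b_over_a < SQRT3):
            raise DomainError("orto lattice requires b/a in (1, sqrt(3))")
    else:
        raise DomainError(f"unknown lattice kind {kind!r}")
    b = a * b_over_a
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    x = cols * a + (rows % 2) * a / 2.0
    y = rows * b / 2.0
    sites = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    angle = math.degrees(math.atan(b_over_a))
    return LatticeSpec(kind=kind, a=a, b_over_a=b_over_a, n_rows=n_rows,
                       n_cols=n_cols, sites=sites, angle=angle)


def interior_site(lattice: LatticeSpec) -> int:
    """Index of an interior site (closest to the centroid, not on the rim)."""
    if lattice.n_rows < 3 or lattice.n_cols < 3:
        raise GeometryError("lattice has no interior site (need >= 3x3)")
    rows = np.arange(lattice.n_sites) // lattice.n_cols
    cols = np.arange(lattice.n_sites) % lattice.n_cols
    inner = (rows > 0) & (rows < lattice.n_rows - 1) & (cols > 0) & (cols < lattice.n_cols - 1)
    idx = np.flatnonzero(inner)
    centroid = lattice.sites.mean(axis=0)
    d2 = np.sum((lattice.sites[idx] - centroid) ** 2, axis=1)
    return int(idx[np.argmin(d2)])


def first_neighbor_shell(lattice: LatticeSpec, tol: float = 1e-6) -> NeighborShell:
    """First (nearest, equidistant-within-tol) neighbor shell of the lattice.

    Coordination is counted at an interior site; ``pairs`` lists every
    symmetric-unique pair of sites separated by the shell distance, across
    the whole finite array (shell semantics: ties included, not k-nearest).
    """
    if lattice.n_sites < 9:
        raise GeometryError("need at least 9 sites to resolve a first shell")
    center = interior_site(lattice)
    d = np.linalg.norm(lattice.sites - lattice.sites[center], axis=1)
    d[center] = np.inf
    dmin = d.min()
    coordination = int(np.sum(d <= dmin * (1.0 + tol)))
    # all pairs at the shell distance
    diff = lattice.sites[:, None, :] - lattice.sites[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(lattice.n_sites, k=1)
    sel = np.abs(dist[iu, ju] - dmin) <= dmin * tol
    pairs = list(zip(iu[sel].tolist(), ju[sel].tolist()))
    return NeighborShell(pairs=pairs, shell_distance=float(dmin), coordination=coordination)


def area_per_molecule(d: float, kind: str = "hex", b_over_a: float = SQRT3) -> float:
    """Cross-sectional area per molecule (nm^2) at interaxial spacing d.

    hex: (sqrt(3)/2) d^2.  orto: the primitive cell holds one molecule of
    area a*b/2 with d = (a/2)*sqrt(1+(b/a)^2), i.e. 2*(b/a)*d^2/(1+(b/a)^2).
    """
    if d <= 0:
        raise DomainError("spacing must be positive")
    if kind == "hex":
        return (SQRT3 / 2.0) * d * d
    return 2.0 * b_over_a * d * d / (1.0 + b_over_a ** 2)


def spacing_to_concentration(d: float, kind: str = "hex", b_over_a: float = SQRT3) -> float:
    """DNA concentration (mg/ml) at interaxial spacing d (nm).

    Uses the B-DNA linear mass density 660 g/mol per bp over a 0.34 nm rise
    (1941 g mol^-1 nm^-1); bare DNA mass, no counterions.
    """
    lin = c.DNA_LINEAR_MASS_G_MOL_NM / c.N_AVOGADRO      # g per nm of axis
    rho = lin / area_per_molecule(d, kind, b_over_a)     # g / nm^3
    return rho * 1e21 * 1e3                              # -> mg/ml (1 nm^3 = 1e-21 ml)


def concentration_to_spacing(conc: float, kind: str = "hex", b_over_a: float = SQRT3) -> float:
    """Inverse of spacing_to_concentration (c is proportional to 1/d^2)."""
    if conc <= 0:
        raise DomainError("concentration must be positive")
    d_ref = 1.0
    c_ref = spacing_to_concentration(d_ref, kind, b_over_a)
    return d_ref * math.sqrt(c_ref / conc)


def debye_kappa(ionic_strength: float, temperature: float = 300.0,
                relative_permittivity: float = 80.0) -> float:
    """Inverse Debye screening length, nm^-1.

    kappa = sqrt(2 N_A e^2 I*1e3 / (eps_r eps0 k_B T)); I in mol/l.
    """
    if ionic_strength < 0:
        raise DomainError("ionic strength must be >= 0")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    if relative_permittivity < 1:
        raise DomainError("relative permittivity must be >= 1")
    num = 2.0 * c.N_AVOGADRO * c.E_CHARGE ** 2 * ionic_strength * 1e3
    den = relative_permittivity * c.EPS0_SI * c.KB_SI * temperature
    return math.sqrt(num / den) * 1e-9  # m^-1 -> nm^-1
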