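"""Rounded-rhombus geometry shared by the membrane and the resolution regions.

The core shape is a parallelogram with unit edge directions u, v (at the
lattice angle) and half-lengths A, B; the actual boundary is its Minkowski
dilation by a rounding radius, which rounds the corners with radial caps.
Distances are Euclidean, so the outward normal is well defined everywhere
on the rounded boundary.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import GeometryError


@dataclasses.dataclass
class RoundedRhombus:
    center: np.ndarray          # (2,)
    u: np.ndarray               # unit edge direction
    v: np.ndarray               # unit edge direction
    half_u: float               # half-length along u (A)
    half_v: float               # half-length along v (B)
    rounding: float = 0.2       # corner rounding radius, nm

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.u = np.asarray(self.u, float) / np.linalg.norm(self.u)
        self.v = np.asarray(self.v, float) / np.linalg.norm(self.v)
        if self.half_u <= 0 or self.half_v <= 0 or self.rounding < 0:
            raise GeometryError("rhombus extents must be positive")
        cross = abs(self.u[0] * self.v[1] - self.u[1] * self.v[0])
        if cross < 1e-9:
            raise GeometryError("edge directions are collinear")
        self._sin = cross
        # slab normals and half-widths: parallelogram = two slabs
        self._n1 = np.array([-self.u[1], self.u[0]])
        self._n2 = np.array([-self.v[1], self.v[0]])
        self._h1 = self.half_v * self._sin
        self._h2 = self.half_u * self._sin
        a, b = self.half_u, self.half_v
        self._corners = np.array([
            self.center + a * self.u + b * self.v,
            self.center - a * self.u + b * self.v,
            self.center - a * self.u - b * self.v,
            self.center + a * self.u - b * self.v,
        ])

    @property
    def perimeter(self) -> float:
        """Perimeter of the rounded boundary."""
        return 4.0 * (self.half_u + self.half_v) + 2.0 * math.pi * self.rounding

    @property
    def area(self) -> float:
        """Area enclosed by the rounded boundary."""
        core = 4.0 * self.half_u * self.half_v * self._sin
        return core + 4.0 * (self.half_u + self.half_v) * self.rounding \
            + math.pi * self.rounding ** 2

    def core_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance to the solid core parallelogram (0 inside) and its gradient.

        The gradient is the outward unit vector from the nearest boundary
        point (zero for interior points).
        """
        p = np.atleast_2d(np.asarray(points, float))
        rel = p - self.center
        inside = (np.abs(rel @ self._n1) <= self._h1) & (np.abs(rel @ self._n2) <= self._h2)
        d = np.zeros(len(p))
        g = np.zeros_like(p)
        out = ~inside
        if out.any():
            q = p[out]
            best_d = np.full(len(q), np.inf)
            best_g = np.zeros_like(q)
            for k in range(4):
                a, b = self._corners[k], self._corners[(k + 1) % 4]
                ab = b - a
                tt = np.clip(((q - a) @ ab) / (ab @ ab), 0.0, 1.0)
                proj = a + tt[:, None] * ab
                dv = q - proj
                dd = np.linalg.norm(dv, axis=1)
                better = dd < best_d
                best_d[better] = dd[better]
                with np.errstate(invalid="ignore", divide="ignore"):
                    best_g[better] = dv[better] / np.where(dd[better] > 0, dd[better], 1.0)[:, None]
            d[out] = best_d
            g[out] = best_g
        return d, g

    def signed_boundary_coordinate(self, points: np.ndarray) -> np.ndarray:
        """s = core distance - rounding: <0 inside the rounded region, >0 outside."""
        d, _ = self.core_distance(points)
        return d - self.rounding

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_boundary_coordinate(points) <= 0.0

    def penetration(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Depth beyond the rounded boundary (0 inside) and the outward normal."""
        d, g = self.core_distance(points)
        return np.maximum(0.0, d - self.rounding), g


def fit_membrane(sites: np.ndarray, angle_deg: float, margin: float,
                 rounding: float = 0.2) -> RoundedRhombus:
    """Smallest rounded rhombus at the lattice angle containing all sites + margin.

    Edges run along x and along the lattice angle (the array direction), as
    the membrane is tilted at the same angle as the array.
    """
    sites = np.asarray(sites, float)
    u = np.array([1.0, 0.0])
    g = math.radians(angle_deg)
    v = np.array([math.cos(g), math.sin(g)])
    sin = abs(u[0] * v[1] - u[1] * v[0])
    n1 = np.array([-u[1], u[0]])
    n2 = np.array([-v[1], v[0]])
    center = 0.5 * (sites.min(axis=0) + sites.max(axis=0))
    rel = sites - center
    # margin is a clearance measured normal to each edge
    h1 = np.abs(rel @ n1).max() + margin
    h2 = np.abs(rel @ n2).max() + margin
    return RoundedRhombus(center=center, u=u, v=v,
                          half_u=max(h2 / sin, 1e-9), half_v=max(h1 / sin, 1e-9),
                          rounding=rounding)
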