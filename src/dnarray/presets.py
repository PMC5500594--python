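"""Default study conditions for the desk-scale analyses.

These constants define the toy-array study the analysis scripts and tests
run: a 16-rod (4x4) array, screening taken from the 1 M NaCl bathing
solution (kappa = 3.25 nm^-1), a Yukawa amplitude stiff enough that the
densest state is positionally ordered, and an azimuthal coupling that
decays with spacing so rotational order is lost within the studied
spacing window.  See docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

import math

from .lattice import LatticeSpec, build_lattice
from .simulate import PairPotential, RodSystem, SpinCoupling, default_system

#: interaxial spacings (nm) of the density sweep; each point is a separate run
SPACING_GRID = [1.8, 2.2, 2.6, 3.0, 3.4]

#: Langevin steps per sweep point and sampling stride
SWEEP_STEPS = 50000
SAMPLE_EVERY = 10

#: fraction of sampled frames discarded before fluctuation statistics
EQUILIBRATION_FRACTION = 0.2


def study_lattice(kind: str = "hex", a: float = 2.8,
                  n_rows: int = 4, n_cols: int = 4) -> LatticeSpec:
    b_over_a = math.sqrt(3.0) if kind == "hex" else 1.43
    return build_lattice(kind, a, b_over_a, n_rows, n_cols)


def study_pair_potential() -> PairPotential:
    # Yukawa amplitude chosen so the d = 1.8 nm state sits below the
    # positional Lindemann threshold while d >= 2.2 nm is molten
    return PairPotential(yukawa_amplitude=1.0e5, kappa=3.25)


def study_spin_coupling(kind: str = "hex") -> SpinCoupling:
    # three-fold (hex) / four-fold (orto) coupling: both signs of the
    # preferred neighbor rotation are equivalent minima, so the preferred
    # pattern is not geometrically frustrated on the lattice
    if kind == "hex":
        return SpinCoupling(amplitude=2000.0, decay=0.45,
                            preferred_delta_phi=2.0 * math.pi / 3.0,
                            multiplicity=3)
    return SpinCoupling(amplitude=2000.0, decay=0.45,
                        preferred_delta_phi=math.pi / 2.0, multiplicity=4)


def study_system(kind: str = "hex") -> RodSystem:
    lattice = study_lattice(kind)
    return default_system(
        lattice,
        pair_potential=study_pair_potential(),
        spin_coupling=study_spin_coupling(kind),
        mass=20.0,
        dt=0.008,
        wall_stiffness=2000.0,
    )
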