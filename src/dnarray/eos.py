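"""Osmotic pressure, exponential equation-of-state fit, and phase assembly.

The osmotic pressure of the confined array is the mean total outward-normal
force on the semipermeable membrane divided by the membrane area
(perimeter x L_z); uncertainty comes from 5-block averaging after a 10%
equilibration discard.  The EoS is fitted as a single exponential,
Pi = Pi0 exp(-d/lambda) against spacing or Pi = Pi0 exp(c/c0) against
concentration, by weighted least squares in log Pi.  The phase report
combines the Lindemann crossings of the positional and rotational
fluctuation series with the fitted EoS: the crossings are explicit proxies
("positional/rotational Lindemann bands"), not thermodynamic phase
boundaries.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError, FitError, NoCrossingError
from .lattice import concentration_to_spacing
from .order import OrderSeriesPoint, transition_density
from .simulate import WallForceTrace

EQUILIBRATION_FRACTION = 0.1
N_BLOCKS = 5


@dataclasses.dataclass
class ExponentialFit:
    prefactor: float              # Pi0
    scale: float                  # lambda (spacing, decay) or c0 (concentration, growth)
    vs: str                       # 'spacing' | 'concentration'
    covariance: np.ndarray        # 2x2, of (log Pi0, slope)
    residuals: np.ndarray         # log-space residuals
    domain: tuple[float, float]   # fitted abscissa range

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.vs == "spacing":
            return self.prefactor * np.exp(-x / self.scale)
        return self.prefactor * np.exp(x / self.scale)


@dataclasses.dataclass
class EoSTable:
    spacing: np.ndarray           # nm
    concentration: np.ndarray     # mg/ml
    pressure: np.ndarray          # pN/nm^2 (MPa)
    pressure_sd: np.ndarray
    fit: Optional[ExponentialFit] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "spacing": self.spacing,
            "concentration": self.concentration,
            "pressure": self.pressure,
            "pressure_sd": self.pressure_sd,
        })

    @classmethod
    def from_sweep(cls, points) -> "EoSTable":
        return cls(
            spacing=np.array([p.spacing for p in points]),
            concentration=np.array([p.concentration for p in points]),
            pressure=np.array([p.pressure for p in points]),
            pressure_sd=np.array([p.pressure_sd for p in points]),
        )


def osmotic_pressure(trace: WallForceTrace,
                     equilibration: float = EQUILIBRATION_FRACTION,
                     n_blocks: int = N_BLOCKS) -> tuple[float, float]:
    """(mean, s.d.) osmotic pressure in pN/nm^2 from a wall-force trace.

    The first ``equilibration`` fraction of samples is discarded; the s.d.
    is the standard error of the mean over ``n_blocks`` equal blocks.
    """
    forces = np.asarray(trace.forces, dtype=float)
    skip = int(np.floor(len(forces) * equilibration))
    prod = forces[skip:]
    if len(prod) < n_blocks:
        raise DegenerateInputError(
            f"trace has {len(prod)} production samples, need >= {n_blocks}")
    mean = float(prod.mean() / trace.membrane_area)
    usable = len(prod) - (len(prod) % n_blocks)
    blocks = prod[:usable].reshape(n_blocks, -1).mean(axis=1) / trace.membrane_area
    sd = float(blocks.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return mean, sd


def fit_exponential(table: EoSTable, vs: str = "spacing") -> ExponentialFit:
    """Weighted least squares of log(pressure) against spacing or concentration.

    Non-positive-pressure rows are excluded (with a warning); at least 3
    usable rows are required.  Weights are 1/var(log Pi) = (Pi/sd)^2 when
    s.d. values are available, unit otherwise.
    """
    if vs not in ("spacing", "concentration"):
        raise DomainError("vs must be 'spacing' or 'concentration'")
    x = table.spacing if vs == "spacing" else table.concentration
    p = np.asarray(table.pressure, dtype=float)
    sd = np.asarray(table.pressure_sd, dtype=float)
    good = p > 0
    if not good.all():
        import warnings

        warnings.warn(f"excluding {int((~good).sum())} non-positive pressure rows "
                      "from the exponential fit", stacklevel=2)
    x, p, sd = x[good], p[good], sd[good]
    if len(p) < 3:
        raise FitError(f"need >= 3 positive-pressure rows, have {len(p)}")
    y = np.log(p)
    if np.all(sd > 0):
        w = (p / sd) ** 2
    else:
        w = np.ones_like(p)
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    resid = y - X @ beta
    slope = beta[1]
    if vs == "spacing":
        if slope >= 0:
            import warnings

            warnings.warn("pressure does not decay with spacing; lambda is negative",
                          stacklevel=2)
        scale = -1.0 / slope
    else:
        scale = 1.0 / slope
    return ExponentialFit(prefactor=float(np.exp(beta[0])), scale=float(scale),
                          vs=vs, covariance=cov, residuals=resid,
                          domain=(float(x.min()), float(x.max())))


@dataclasses.dataclass
class PhaseCrossing:
    concentration: float          # mg/ml
    spacing: float                # nm
    pressure: Optional[float]     # pN/nm^2 from the fitted EoS, if available


@dataclasses.dataclass
class PhaseReport:
    positional: Optional[PhaseCrossing]   # ordered <-> positionally disordered
    rotational: Optional[PhaseCrossing]   # rotational-order loss (orto <-> hex proxy)
    threshold: float
    bands: pd.DataFrame                   # per input density: concentration, band


def assemble_phase_diagram(order_series: Sequence[OrderSeriesPoint],
                           eos_table: EoSTable, threshold: float = 0.1,
                           lattice_kind: str = "hex",
                           b_over_a: float = np.sqrt(3.0)) -> PhaseReport:
    """Combine Lindemann crossings with the EoS into a phase report.

    Missing crossings are reported as open boundaries (None), never raised.
    Each density is classified by its own statistics against the threshold
    (both ordered -> orto proxy; positionally ordered only -> hex proxy;
    otherwise disordered), so the banding is consistent with the series even
    when the two crossings occur in either order.
    """
    fit = eos_table.fit
    if fit is None or fit.vs != "concentration":
        try:
            fit = fit_exponential(eos_table, vs="concentration")
        except FitError:
            fit = None

    def crossing(which):
        try:
            conc = transition_density(order_series, which=which, threshold=threshold)
        except NoCrossingError:
            return None
        return PhaseCrossing(
            concentration=conc,
            spacing=concentration_to_spacing(conc, lattice_kind, b_over_a),
            pressure=float(fit.predict(conc)) if fit is not None else None,
        )

    pos_x = crossing("positional")
    rot_x = crossing("rotational")

    pts = sorted(order_series, key=lambda p: p.concentration)
    band = []
    for p in pts:
        pos_ok = p.sigma_r_over_a < threshold
        rot_ok = p.sigma_phi_over_pi < threshold
        if pos_ok and rot_ok:
            band.append("orto (positionally and rotationally ordered)")
        elif pos_ok:
            band.append("hex (positionally ordered, rotationally disordered)")
        elif rot_ok:
            band.append("rotationally ordered, positionally disordered")
        else:
            band.append("disordered (both Lindemann thresholds exceeded)")
    bands = pd.DataFrame({"concentration": [p.concentration for p in pts],
                          "band": band})
    return PhaseReport(positional=pos_x, rotational=rot_x, threshold=threshold,
                       bands=bands)
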