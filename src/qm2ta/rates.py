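"""Closed-form study metrics.

Exchange fluxes per cell under exponential growth: with dN/dt = mu N and
dM/dt = J N, integrating over [0, T] gives

    mu = ln(N_T / N_0) / T
    J  = mu (M_T - M_0) / (N_T - N_0)        (mu != 0)
    J  = (M_T - M_0) / (N_0 T)               (mu -> 0 limit)

Negative J is net consumption under the export-positive sign convention.
Tumor volumes use the modified ellipsoid formula L W^2 pi/6 and growth
inhibition the baseline-normalized ratio of treated to control volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

#: |mu| T below this uses the constant-population limit for J
MU_LIMIT = 1e-9


@dataclass
class GrowthAssay:
    """Paired cell counts and metabolite quantities over a time window.

    Counts in cells, metabolite quantities in any consistent amount unit,
    duration in hours; the returned flux is amount per cell per hour.
    """

    n0: float
    nt: float
    m0: float
    mt: float
    duration: float

    def __post_init__(self) -> None:
        if self.n0 <= 0 or self.nt <= 0:
            raise DomainError("cell counts must be positive")
        if self.duration <= 0:
            raise DomainError("assay duration must be positive")


def exchange_rate(assay: GrowthAssay) -> tuple[float, float]:
    """Per-cell net exchange flux and growth rate: returns (J, mu)."""
    mu = math.log(assay.nt / assay.n0) / assay.duration
    dm = assay.mt - assay.m0
    if abs(mu) * assay.duration < MU_LIMIT:
        j = dm / (assay.n0 * assay.duration)
    else:
        j = mu * dm / (assay.nt - assay.n0)
    return j, mu


def doubling_time(mu: float) -> float:
    """Population doubling time ln(2)/mu, in hours."""
    if mu <= 0:
        raise DomainError(f"growth rate must be positive, got {mu}")
    return math.log(2.0) / mu


@dataclass
class TumorMeasurement:
    """One caliper measurement; length >= width is enforced by swapping."""

    length: float
    width: float
    day: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise DomainError("tumor dimensions must be positive")
        if self.width > self.length:
            warnings.warn(
                f"width {self.width} exceeds length {self.length}; swapping"
            )
            self.length, self.width = self.width, self.length


def ellipsoid_volume(m: TumorMeasurement) -> float:
    """Modified ellipsoid tumor volume: L * W^2 * pi / 6 (mm^3)."""
    return m.length * m.width**2 * math.pi / 6.0


def tgi(v_t_t: float, v_t_0: float, v_c_t: float, v_c_0: float) -> float:
    """Tumor growth inhibition (%) from baseline-normalized volumes.

    TGI = (1 - (V_T,t / V_T,0) / (V_C,t / V_C,0)) x 100; negative when the
    treated group grows faster than control.
    """
    for v in (v_t_t, v_t_0, v_c_t, v_c_0):
        if v <= 0:
            raise DomainError("tumor volumes must be positive")
    return (1.0 - (v_t_t / v_t_0) / (v_c_t / v_c_0)) * 100.0


def enzyme_activity_proxy(product_levels, substrate_levels, control_ratio):
    """Relative enzyme activity from product/substrate metabolite ratios.

    Returns (product/substrate) / control_ratio, elementwise for array
    input. This is a proxy only: the exact ratio definitions for specific
    enzymes are not standardized here, and results should be read as
    relative trends ("proxy, underspecified").
    """
    product = np.asarray(product_levels, dtype=float)
    substrate = np.asarray(substrate_levels, dtype=float)
    if np.any(substrate <= 0) or np.any(product < 0):
        raise DomainError("levels must be positive (substrate strictly)")
    if np.any(np.asarray(control_ratio, dtype=float) <= 0):
        raise DomainError("control ratio must be positive")
    out = (product / substrate) / control_ratio
    return float(out) if out.ndim == 0 else out
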