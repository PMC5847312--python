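"""Conversion between metabolic enzyme cost and cell growth rate.

At balanced growth the metabolic-enzyme fraction of the proteome shrinks
linearly with growth rate, ``E_met / c_BM = f_prot * (a - b * mu)``.
Eliminating the biomass density ``c_BM`` (via ``mu = v_BM / c_BM``) turns the
minimal enzyme mass concentration ``E_met`` (mg/l) delivered by enzyme cost
minimization into a growth rate

    mu = a * f_prot * v_BM / (E_met + b * f_prot * v_BM)

which is strictly decreasing in ``E_met`` with supremum ``a / b`` at zero
cost.  The same algebra gives the cell doubling time as an affine function of
the metabolic-enzyme doubling time ``tau_met = ln(2) * E_met / v_BM``:

    T = tau_met / (a * f_prot) + ln(2) * b / a

All constants are organism- and dataset-specific; the defaults describe
exponentially growing E. coli on glucose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthParams",
    "GrowthResult",
    "growth_rate_from_cost",
    "cost_from_growth_rate",
    "doubling_time_from_cost",
    "MM_PER_S_TO_MMOL_PER_L_PER_H",
]

#: 1 mM/s expressed in mmol l^-1 h^-1 (the unit in which yields are computed).
MM_PER_S_TO_MMOL_PER_L_PER_H = 3600.0


@dataclass(frozen=True)
class GrowthParams:
    """Constants of the enzyme-cost -> growth-rate conversion.

    Parameters
    ----------
    a : dimensionless intercept of the metabolic-proteome fraction law.
    b : slope of that law, in hours.
    f_prot : protein fraction of cell dry mass.
    v_bm_mass : biomass production rate equivalent of one unit of biomass
        flux, in mg l^-1 h^-1.
    """

    a: float = 0.27
    b: float = 0.2
    f_prot: float = 0.5
    v_bm_mass: float = 7.45e7

    def __post_init__(self) -> None:
        for name in ("a", "b", "f_prot", "v_bm_mass"):
            if not getattr(self, name) > 0:
                raise ValueError(f"GrowthParams.{name} must be positive")

    @property
    def numerator(self) -> float:
        """a * f_prot * v_BM, in mg l^-1 h^-1."""
        return self.a * self.f_prot * self.v_bm_mass

    @property
    def offset_cost(self) -> float:
        """b * f_prot * v_BM, in mg l^-1 (the cost at which mu = a/2b)."""
        return self.b * self.f_prot * self.v_bm_mass

    @property
    def mu_max(self) -> float:
        """Supremum of the growth rate, a/b, reached at zero enzyme cost."""
        return self.a / self.b

    @property
    def doubling_slope(self) -> float:
        """Slope of T versus E_met: ln2 / (a * f_prot * v_BM), in h l mg^-1."""
        return math.log(2.0) / self.numerator

    @property
    def doubling_offset(self) -> float:
        """Intercept of the doubling-time law, ln2 * b / a, in hours."""
        return math.log(2.0) * self.b / self.a

    @property
    def tau_factor(self) -> float:
        """Multiplier converting tau_met into cell doubling time, 1/(a*f_prot)."""
        return 1.0 / (self.a * self.f_prot)


@dataclass(frozen=True)
class GrowthResult:
    """Growth quantities derived from one enzyme cost value.

    mu : growth rate (1/h); tau_met : metabolic-enzyme doubling time (h);
    doubling_time : cell doubling time (h), equal to ln2/mu;
    r_bm : enzyme-specific biomass rate v_BM / E_met (1/h).
    """

    mu: float
    tau_met: float
    doubling_time: float
    r_bm: float


def growth_rate_from_cost(e_met: float, params: GrowthParams | None = None) -> float:
    """Growth rate (1/h) achievable at total metabolic enzyme cost ``e_met`` (mg/l)."""
    params = params or GrowthParams()
    if e_met < 0:
        raise ValueError(f"enzyme cost must be non-negative, got {e_met}")
    return params.numerator / (e_met + params.offset_cost)


def cost_from_growth_rate(mu: float, params: GrowthParams | None = None) -> float:
    """Inverse of :func:`growth_rate_from_cost` (for mu in (0, a/b))."""
    params = params or GrowthParams()
    if not 0 < mu < params.mu_max:
        raise ValueError(f"mu must lie in (0, {params.mu_max}), got {mu}")
    return params.numerator / mu - params.offset_cost


def doubling_time_from_cost(e_met: float, params: GrowthParams | None = None) -> GrowthResult:
    """Doubling times and growth rate for a given enzyme cost (mg/l)."""
    params = params or GrowthParams()
    if e_met < 0:
        raise ValueError(f"enzyme cost must be non-negative, got {e_met}")
    mu = growth_rate_from_cost(e_met, params)
    tau_met = math.log(2.0) * e_met / params.v_bm_mass
    doubling_time = params.tau_factor * tau_met + params.doubling_offset
    r_bm = params.v_bm_mass / e_met if e_met > 0 else math.inf
    return GrowthResult(mu=mu, tau_met=tau_met, doubling_time=doubling_time, r_bm=r_bm)
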