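"""Enzyme Cost Minimization (ECM).

For a fixed flux mode ``v``, the enzyme level needed by reaction ``r``
under the common modular rate law factorizes as

    E_r = v_r / (kcat_fwd_r * eta_rev_r(x) * eta_sat_r(x))

where ``x = ln c`` are log metabolite concentrations (mM),

    theta_r   = ln Keq_r - sum_i n_{i,r} x_i          (driving force, RT units)
    eta_rev_r = 1 - exp(-theta_r)                     (thermodynamic efficiency)
    eta_sat_r = prod_S (c/K)^m
                / [prod_S (1 + c/K)^m + prod_P (1 + c/K)^m - 1]

with molecularities ``m = |n|`` over substrates S and products P that carry
a Michaelis constant.  The total cost ``E_met = sum_r w_r E_r`` (mg/l) is
convex in ``x``, so a single local solve finds the global optimum over the
metabolite polytope (box bounds plus ``theta_r >= eps`` on the support).

The solver runs scipy's SLSQP with analytic gradients; a linear max-min
driving force pre-solve (scipy.optimize.linprog) certifies feasibility of
the polytope and provides the starting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import linprog, minimize

from efcm.efm import EFM
from efcm.model import MetabolicModel, Reaction

__all__ = [
    "Condition",
    "EcmOptions",
    "EfficiencyFactors",
    "ECMSolution",
    "ThermodynamicallyInfeasible",
    "InfeasibleDirection",
    "driving_force",
    "efficiency_factors",
    "enzyme_demand",
    "total_enzyme_cost",
    "minimize_enzyme_cost",
    "capacity_utilization",
]

#: Numerical floor on driving forces (RT units) inside the polytope.
THETA_FLOOR = 1e-6


class ThermodynamicallyInfeasible(RuntimeError):
    """The metabolite polytope of a flux mode is empty."""

    def __init__(self, message: str, worst_reaction: str | None = None):
        super().__init__(message)
        self.worst_reaction = worst_reaction


class InfeasibleDirection(ValueError):
    """A reaction is asked to run against its thermodynamic driving force."""


@dataclass(frozen=True)
class Condition:
    """External metabolite concentrations plus kinetic-parameter overrides.

    ``param_overrides`` maps ``(reaction_id, parameter)`` to a value, where
    parameter is ``"kcat_fwd"``, ``"keq"``, ``"enzyme_mass"`` or
    ``"km:<metabolite>"``.
    """

    external_conc: Mapping[str, float] = field(default_factory=dict)
    param_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, conc in self.external_conc.items():
            if not conc > 0:
                raise ValueError(f"external concentration of {met} must be > 0, got {conc}")

    def conc(self, met_id: str, model: MetabolicModel) -> float:
        if met_id in self.external_conc:
            return float(self.external_conc[met_id])
        met = model.metabolite(met_id)
        if not met.is_external:
            raise KeyError(f"{met_id} is internal; its concentration is a variable")
        return float(met.fixed_conc)

    def kinetics_of(self, rxn: Reaction) -> tuple[float, float, dict[str, float], float]:
        """Effective (kcat_fwd, keq, km, enzyme_mass) after overrides."""
        ov = self.param_overrides
        kcat = float(ov.get((rxn.id, "kcat_fwd"), rxn.kinetics.kcat_fwd))
        keq = float(ov.get((rxn.id, "keq"), rxn.kinetics.keq))
        mass = float(ov.get((rxn.id, "enzyme_mass"), rxn.kinetics.enzyme_mass))
        km = dict(rxn.kinetics.km)
        for (rid, par), val in ov.items():
            if rid == rxn.id and par.startswith("km:"):
                km[par[3:]] = float(val)
        for key in (kcat, keq, mass):
            if not key > 0:
                raise ValueError(f"overridden parameter of {rxn.id} must stay positive")
        return kcat, keq, km, mass

    def fingerprint(self) -> str:
        import hashlib
        import json

        payload = {
            "conc": sorted(self.external_conc.items()),
            "over": sorted((r, p, v) for (r, p), v in self.param_overrides.items()),
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()


@dataclass(frozen=True)
class EfficiencyFactors:
    theta: float  # driving force, RT units
    eta_rev: float  # 1 - exp(-theta), in (0, 1)
    eta_sat: float  # saturation efficiency, in (0, 1]


@dataclass
class EcmOptions:
    theta_floor: float = THETA_FLOOR
    tol: float = 1e-8  # convergence tolerance on the scaled cost
    max_iter: int = 500
    simple_saturation: bool = False  # substrate-only eta_sat variant
    weight_fn: Callable[[Reaction], float] | None = None  # default: enzyme mass


@dataclass
class ECMSolution:
    """Optimal metabolite profile and enzyme demands for one flux mode."""

    x: dict[str, float]  # ln(c / 1 mM) for internal metabolites
    enzyme_demand: dict[str, float]  # mM per active reaction
    cost_terms: dict[str, float]  # w * E, mg/l
    e_met: float  # total enzyme cost, mg/l
    factors: dict[str, EfficiencyFactors]
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "x": self.x,
            "enzyme_demand_mM": self.enzyme_demand,
            "cost_terms_mg_per_l": self.cost_terms,
            "e_met_mg_per_l": self.e_met,
            "theta": {r: f.theta for r, f in self.factors.items()},
            "eta_rev": {r: f.eta_rev for r, f in self.factors.items()},
            "eta_sat": {r: f.eta_sat for r, f in self.factors.items()},
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


# ----------------------------------------------------------------------
# pointwise kinetics
# ----------------------------------------------------------------------

def _oriented(rxn: Reaction, keq: float, sign: int) -> tuple[dict[str, float], float]:
    """Stoichiometry and Keq in the direction of flux (sign = +-1)."""
    if sign >= 0:
        return {m: float(n) for m, n in rxn.stoich.items()}, keq
    return {m: -float(n) for m, n in rxn.stoich.items()}, 1.0 / keq


def _ln_conc(met_id: str, x: Mapping[str, float], model: MetabolicModel,
             condition: Condition) -> float:
    if met_id in x:
        return float(x[met_id])
    return math.log(condition.conc(met_id, model))


def driving_force(x: Mapping[str, float], reaction: Reaction, model: MetabolicModel,
                  condition: Condition, sign: int = +1) -> float:
    """theta = ln Keq - sum_i n_i * ln c_i, in the direction of flux."""
    _, keq, _, _ = condition.kinetics_of(reaction)
    stoich, keq = _oriented(reaction, keq, sign)
    return math.log(keq) - sum(
        n * _ln_conc(m, x, model, condition) for m, n in stoich.items()
    )


def _saturation(x: Mapping[str, float], stoich: Mapping[str, float], km: Mapping[str, float],
                model: MetabolicModel, condition: Condition,
                simple: bool = False) -> tuple[float, dict[str, float]]:
    """eta_sat and its partial derivatives d ln eta_sat / d ln c per reactant.

    Only reactants with a Michaelis constant participate; molecularities are
    the absolute stoichiometric coefficients.
    """
    ln_num = 0.0
    prod_sub = 1.0  # prod_S (1 + c/K)^m
    prod_prod = 1.0  # prod_P (1 + c/K)^m
    ratios: dict[str, tuple[float, float, bool]] = {}  # met -> (m, c/K, is_substrate)
    for met, n in stoich.items():
        if met not in km:
            continue
        m_i = abs(n)
        ratio = math.exp(_ln_conc(met, x, model, condition)) / km[met]
        if n < 0:
            ln_num += m_i * math.log(ratio)
            prod_sub *= (1.0 + ratio) ** m_i
            ratios[met] = (m_i, ratio, True)
        else:
            prod_prod *= (1.0 + ratio) ** m_i
            ratios[met] = (m_i, ratio, False)
    if simple:
        denom = prod_sub
        prod_prod = 1.0
    else:
        denom = prod_sub + prod_prod - 1.0
    eta = math.exp(ln_num) / denom
    grad: dict[str, float] = {}
    for met, (m_i, ratio, is_sub) in ratios.items():
        s = ratio / (1.0 + ratio)
        if is_sub:
            grad[met] = m_i - prod_sub * m_i * s / denom
        elif not simple:
            grad[met] = -prod_prod * m_i * s / denom
        else:
            grad[met] = 0.0
    return eta, grad


def efficiency_factors(x: Mapping[str, float], reaction: Reaction, model: MetabolicModel,
                       condition: Condition, sign: int = +1,
                       simple_saturation: bool = False) -> EfficiencyFactors:
    """Driving force and the two efficiency factors of one active reaction."""
    theta = driving_force(x, reaction, model, condition, sign=sign)
    if theta <= 0:
        raise InfeasibleDirection(
            f"reaction {reaction.id}: driving force {theta:.3g} <= 0 in flux direction"
        )
    _, keq, km, _ = condition.kinetics_of(reaction)
    stoich, _ = _oriented(reaction, keq, sign)
    eta_sat, _ = _saturation(x, stoich, km, model, condition, simple=simple_saturation)
    return EfficiencyFactors(theta=theta, eta_rev=1.0 - math.exp(-theta), eta_sat=eta_sat)


def enzyme_demand(flux: Mapping[str, float], x: Mapping[str, float], model: MetabolicModel,
                  condition: Condition, simple_saturation: bool = False) -> dict[str, float]:
    """E_r = v_r / (kcat_fwd * eta_rev * eta_sat) in mM; zero-flux reactions -> 0."""
    out: dict[str, float] = {}
    for rxn in model.reactions:
        v = float(flux.get(rxn.id, 0.0))
        if v == 0.0:
            out[rxn.id] = 0.0
            continue
        sign = 1 if v > 0 else -1
        fac = efficiency_factors(
            x, rxn, model, condition, sign=sign, simple_saturation=simple_saturation
        )
        kcat, _, _, _ = condition.kinetics_of(rxn)
        out[rxn.id] = abs(v) / (kcat * fac.eta_rev * fac.eta_sat)
    return out


def _weight(rxn: Reaction, condition: Condition,
            weight_fn: Callable[[Reaction], float] | None) -> float:
    if weight_fn is not None:
        return float(weight_fn(rxn))
    _, _, _, mass = condition.kinetics_of(rxn)
    return mass


def total_enzyme_cost(flux: Mapping[str, float], x: Mapping[str, float],
                      model: MetabolicModel, condition: Condition,
                      simple_saturation: bool = False,
                      weight_fn: Callable[[Reaction], float] | None = None) -> float:
    """E_met = sum_r w_r E_r in mg/l."""
    demand = enzyme_demand(flux, x, model, condition, simple_saturation=simple_saturation)
    return sum(
        _weight(rxn, condition, weight_fn) * demand[rxn.id]
        for rxn in model.reactions
        if demand[rxn.id] > 0
    )


# ----------------------------------------------------------------------
# the convex solve
# ----------------------------------------------------------------------

def _active_problem(efm: EFM, model: MetabolicModel, condition: Condition):
    """Assemble the oriented active reactions and the variable set."""
    active = []
    var_mets: list[str] = []
    seen = set()
    for rxn in model.reactions:
        v = float(efm.flux.get(rxn.id, 0.0))
        if v == 0.0:
            continue
        sign = 1 if v > 0 else -1
        kcat, keq, km, mass = condition.kinetics_of(rxn)
        stoich, keq_dir = _oriented(rxn, keq, sign)
        active.append((rxn, abs(v), sign, kcat, keq_dir, stoich, km, mass))
        for met in stoich:
            if not model.metabolite(met).is_external and met not in seen:
                seen.add(met)
                var_mets.append(met)
    return active, var_mets


def minimize_enzyme_cost(efm: EFM, model: MetabolicModel, condition: Condition,
                         opts: EcmOptions | None = None) -> ECMSolution:
    """Minimize total enzyme cost over the metabolite polytope of ``efm``.

    The objective is convex in log concentrations, so the converged point is
    the global minimum.  Raises :class:`ThermodynamicallyInfeasible` when the
    polytope is empty (reporting the reaction with the most negative
    achievable driving force).
    """
    opts = opts or EcmOptions()
    active, var_mets = _active_problem(efm, model, condition)
    if not active:
        raise ValueError(f"EFM {efm.id} has no active reactions")
    idx = {m: i for i, m in enumerate(var_mets)}
    n_var = len(var_mets)
    lb = np.array([math.log(model.metabolite(m).c_min) for m in var_mets])
    ub = np.array([math.log(model.metabolite(m).c_max) for m in var_mets])

    # linear driving-force data: theta_r(x) = theta0_r - A[r] @ x
    A = np.zeros((len(active), n_var))
    theta0 = np.zeros(len(active))
    for r, (rxn, v, sign, kcat, keq_dir, stoich, km, mass) in enumerate(active):
        t0 = math.log(keq_dir)
        for met, n in stoich.items():
            if met in idx:
                A[r, idx[met]] = n
            else:
                t0 -= n * math.log(condition.conc(met, model))
        theta0[r] = t0

    # feasibility pre-solve: maximize t s.t. theta0 - A x >= t, lb <= x <= ub
    c = np.zeros(n_var + 1)
    c[-1] = -1.0
    A_ub = np.hstack([A, np.ones((len(active), 1))])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=theta0,
        bounds=[(l, u) for l, u in zip(lb, ub)] + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise ThermodynamicallyInfeasible(f"EFM {efm.id}: feasibility pre-solve failed")
    t_max = res.x[-1]
    if t_max <= opts.theta_floor:
        thetas = theta0 - A @ res.x[:-1]
        worst = active[int(np.argmin(thetas))][0].id
        raise ThermodynamicallyInfeasible(
            f"EFM {efm.id}: empty metabolite polytope "
            f"(max-min driving force {t_max:.3g} RT; tightest reaction {worst})",
            worst_reaction=worst,
        )
    x0 = np.clip(res.x[:-1], lb, ub)

    def cost_and_grad(xv: np.ndarray) -> tuple[float, np.ndarray]:
        xmap = {m: xv[i] for m, i in idx.items()}
        total = 0.0
        grad = np.zeros(n_var)
        for r, (rxn, v, sign, kcat, keq_dir, stoich, km, mass) in enumerate(active):
            theta = theta0[r] - float(A[r] @ xv)
            # below the floor the barrier-free cost would be invalid; clamp
            theta = max(theta, opts.theta_floor * 1e-3)
            e_mth = math.exp(-theta)
            eta_rev = 1.0 - e_mth
            eta_sat, sat_grad = _saturation(
                xmap, stoich, km, model, condition, simple=opts.simple_saturation
            )
            w = mass if opts.weight_fn is None else float(opts.weight_fn(rxn))
            term = w * v / (kcat * eta_rev * eta_sat)
            total += term
            # d ln eta_rev / dx_i = (e^-theta / eta_rev) * (-A[r,i]) * (-1)
            coef_rev = e_mth / eta_rev
            for met, n in stoich.items():
                i = idx.get(met)
                if i is None:
                    continue
                dln = -coef_rev * A[r, i] + sat_grad.get(met, 0.0)
                grad[i] += -term * dln
        return total, grad

    scale = max(cost_and_grad(x0)[0], 1e-300)

    def f(xv):
        c0, g = cost_and_grad(xv)
        return c0 / scale, g / scale

    constraints = [
        {
            "type": "ineq",
            "fun": lambda xv: theta0 - A @ xv - opts.theta_floor,
            "jac": lambda xv: -A,
        }
    ]
    sol = minimize(
        f,
        x0,
        jac=True,
        method="SLSQP",
        bounds=list(zip(lb, ub)),
        constraints=constraints,
        options={"maxiter": opts.max_iter, "ftol": opts.tol * 1e-4},
    )
    if not sol.success:
        # SLSQP occasionally stalls on the constraint boundary; retry from a
        # perturbed interior point before giving up.
        x_retry = np.clip(0.5 * (x0 + sol.x), lb, ub)
        sol2 = minimize(
            f, x_retry, jac=True, method="SLSQP", bounds=list(zip(lb, ub)),
            constraints=constraints,
            options={"maxiter": opts.max_iter, "ftol": opts.tol * 1e-4},
        )
        if sol2.success or sol2.fun < sol.fun:
            sol = sol2

    x_opt = np.clip(sol.x, lb, ub)
    xmap = {m: float(x_opt[idx[m]]) for m in var_mets}
    demand: dict[str, float] = {}
    cost_terms: dict[str, float] = {}
    factors: dict[str, EfficiencyFactors] = {}
    e_met = 0.0
    for rxn, v, sign, kcat, keq_dir, stoich, km, mass in active:
        fac = efficiency_factors(
            xmap, rxn, model, condition, sign=sign,
            simple_saturation=opts.simple_saturation,
        )
        e = v / (kcat * fac.eta_rev * fac.eta_sat)
        w = mass if opts.weight_fn is None else float(opts.weight_fn(rxn))
        demand[rxn.id] = e
        cost_terms[rxn.id] = w * e
        factors[rxn.id] = fac
        e_met += w * e
    return ECMSolution(
        x=xmap,
        enzyme_demand=demand,
        cost_terms=cost_terms,
        e_met=e_met,
        factors=factors,
        converged=bool(sol.success),
        diagnostics={
            "solver": "SLSQP",
            "message": str(sol.message),
            "n_iter": int(sol.get("nit", -1)),
            "max_min_driving_force": float(t_max),
        },
    )


def capacity_utilization(solution: ECMSolution) -> dict[str, float]:
    """eta_rev * eta_sat per active reaction: apparent / maximal catalytic rate.

    Equals E_ideal / E_actual, where E_ideal = v / kcat is the demand of a
    fully efficient enzyme.
    """
    return {r: f.eta_rev * f.eta_sat for r, f in solution.factors.items()}
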