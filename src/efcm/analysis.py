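"""Rate/yield analyses built on EFM enumeration and enzyme cost minimization.

The nested screening procedure: every condition-feasible EFM gets an ECM
solve, its minimal cost is converted into a growth rate, and the resulting
(yield, growth rate) spectrum is examined for Pareto optimality, Monod
behaviour over substrate grids, parameter sensitivities (via the envelope
theorem), and knockout/epistasis effects — the latter two reusing the
precomputed spectrum without any new optimization runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from efcm.ecm import (
    Condition,
    EcmOptions,
    ECMSolution,
    ThermodynamicallyInfeasible,
    _oriented,
    _saturation,
    minimize_enzyme_cost,
)
from efcm.efm import EFM, EFMSet, knockout_filter
from efcm.growth import growth_rate_from_cost
from efcm.model import MetabolicModel

__all__ = [
    "RateYieldPoint",
    "MonodSurface",
    "EcmCache",
    "rate_yield_spectrum",
    "pareto_front",
    "monod_scan",
    "growth_sensitivities",
    "knockout_analysis",
    "epistasis",
]

#: Two growth rates within this absolute tolerance count as tied winners.
WINNER_TIE_TOL = 1e-10


@dataclass(frozen=True)
class RateYieldPoint:
    efm_id: int
    yield_g_per_cmol: float
    mu: float  # 1/h
    e_met: float  # mg/l
    exchanges: dict[str, float] = field(default_factory=dict)  # per C-mol glucose


class EcmCache(dict):
    """Memo of ECM solutions keyed by (model, EFM id, condition) content hashes."""

    def solve(self, efm: EFM, model: MetabolicModel, condition: Condition,
              opts: EcmOptions | None = None) -> ECMSolution:
        key = (model.fingerprint(), efm.id, condition.fingerprint())
        if key not in self:
            self[key] = minimize_enzyme_cost(efm, model, condition, opts)
        return self[key]


def _exchange_fluxes(efm: EFM, model: MetabolicModel) -> dict[str, float]:
    """Selected exchange fluxes scaled per C-mol of glucose uptake."""
    v_upt = efm.flux.get(model.glucose_uptake_reaction_id, 0.0)
    if v_upt <= 0 or not model.exchange_reactions:
        return {}
    from efcm.efm import _glucose_carbon

    carbon = _glucose_carbon(model)
    return {
        r: efm.flux.get(r, 0.0) / (carbon * v_upt) for r in model.exchange_reactions
    }


def rate_yield_spectrum(
    efms: EFMSet,
    model: MetabolicModel,
    condition: Condition,
    opts: EcmOptions | None = None,
    cache: EcmCache | None = None,
) -> tuple[list[RateYieldPoint], list[tuple[int, str]]]:
    """One (yield, growth rate) point per biomass EFM with a converged ECM.

    Returns ``(points, failures)`` where failures lists (efm_id, reason) for
    thermodynamically infeasible or non-converged modes.
    """
    cache = cache if cache is not None else EcmCache()
    points: list[RateYieldPoint] = []
    failures: list[tuple[int, str]] = []
    for efm in efms.biomass_producing(model):
        if efm.yield_g_per_cmol is None:
            failures.append((efm.id, "undefined yield (no carbon uptake)"))
            continue
        try:
            sol = cache.solve(efm, model, condition, opts)
        except ThermodynamicallyInfeasible as exc:
            failures.append((efm.id, str(exc)))
            continue
        if not sol.converged:
            failures.append((efm.id, f"solver did not converge: {sol.diagnostics}"))
            continue
        points.append(
            RateYieldPoint(
                efm_id=efm.id,
                yield_g_per_cmol=efm.yield_g_per_cmol,
                mu=growth_rate_from_cost(sol.e_met, model.growth_params),
                e_met=sol.e_met,
                exchanges=_exchange_fluxes(efm, model),
            )
        )
    return points, failures


def _dominates(p: RateYieldPoint, q: RateYieldPoint) -> bool:
    """p dominates q under (maximize mu, maximize yield)."""
    ge = p.mu >= q.mu and p.yield_g_per_cmol >= q.yield_g_per_cmol
    gt = p.mu > q.mu or p.yield_g_per_cmol > q.yield_g_per_cmol
    return ge and gt


def pareto_front(points: list[RateYieldPoint]) -> list[RateYieldPoint]:
    """Maximal non-dominated subset, ordered by descending yield."""
    if not points:
        return []
    ordered = sorted(points, key=lambda p: (-p.yield_g_per_cmol, -p.mu, p.efm_id))
    front: list[RateYieldPoint] = []
    best_mu = -math.inf
    for p in ordered:
        if p.mu > best_mu:
            front.append(p)
            best_mu = p.mu
        elif p.mu == best_mu and front and p.yield_g_per_cmol == front[-1].yield_g_per_cmol:
            front.append(p)  # exact tie in both objectives: keep both
    return front


@dataclass
class MonodSurface:
    glucose_grid: np.ndarray  # mM
    oxygen_grid: np.ndarray  # mM (may contain 0 for strict anaerobiosis)
    mu: np.ndarray  # (n_glc, n_o2); NaN where no EFM is feasible
    winner: np.ndarray  # EFM id per cell; -1 where no EFM is feasible
    winner_exchanges: list[list[dict[str, float]]]


def _feasible_under_oxygen(efm: EFM, model: MetabolicModel, o2: float) -> bool:
    sensitive = efm.uses_tag("oxygen_sensitive", model)
    dependent = efm.uses_tag("oxygen_dependent", model)
    if sensitive and dependent:
        return False
    return not dependent if o2 <= 0 else not sensitive


def monod_scan(
    model: MetabolicModel,
    efms: EFMSet,
    glucose_grid,
    oxygen_grid,
    glucose_id: str | None = None,
    oxygen_id: str | None = None,
    base_condition: Condition | None = None,
    opts: EcmOptions | None = None,
    cache: EcmCache | None = None,
) -> MonodSurface:
    """Best growth rate and winning EFM over a glucose x oxygen grid.

    Each grid cell is an independent condition; at zero oxygen the anaerobic
    feasibility rule applies.  Ties in the winning growth rate (within
    1e-10) are broken by higher yield, then lower EFM id.
    """
    glucose_id = glucose_id or model.glucose_metabolite_id
    oxygen_id = oxygen_id or model.oxygen_metabolite_id
    if glucose_id is None:
        raise ValueError("model declares no glucose metabolite id")
    base = base_condition or Condition()
    cache = cache if cache is not None else EcmCache()
    glc = np.asarray(list(glucose_grid), dtype=float)
    o2 = np.asarray(list(oxygen_grid), dtype=float)
    mu_grid = np.full((len(glc), len(o2)), np.nan)
    winner = np.full((len(glc), len(o2)), -1, dtype=int)
    winner_ex: list[list[dict[str, float]]] = [
        [{} for _ in range(len(o2))] for _ in range(len(glc))
    ]
    pool = list(efms.biomass_producing(model))
    for i, g in enumerate(glc):
        for j, o in enumerate(o2):
            ext = dict(base.external_conc)
            ext[glucose_id] = float(g)
            if oxygen_id is not None and o > 0:
                ext[oxygen_id] = float(o)
            cond = Condition(external_conc=ext, param_overrides=base.param_overrides)
            best: tuple[float, float, int] | None = None  # (mu, yield, id)
            for efm in pool:
                if not _feasible_under_oxygen(efm, model, float(o)):
                    continue
                try:
                    sol = cache.solve(efm, model, cond, opts)
                except ThermodynamicallyInfeasible:
                    continue
                if not sol.converged:
                    continue
                mu = growth_rate_from_cost(sol.e_met, model.growth_params)
                y = efm.yield_g_per_cmol or 0.0
                if best is None:
                    best = (mu, y, efm.id)
                elif mu > best[0] + WINNER_TIE_TOL:
                    best = (mu, y, efm.id)
                elif abs(mu - best[0]) <= WINNER_TIE_TOL and (
                    y > best[1] or (y == best[1] and efm.id < best[2])
                ):
                    best = (max(mu, best[0]), y, efm.id)
            if best is not None:
                mu_grid[i, j] = best[0]
                winner[i, j] = best[2]
                winner_ex[i][j] = _exchange_fluxes(efms[best[2]], model)
    return MonodSurface(glc, o2, mu_grid, winner, winner_ex)


# ----------------------------------------------------------------------
# envelope sensitivities
# ----------------------------------------------------------------------

def _cost_partials(efm: EFM, solution: ECMSolution, model: MetabolicModel,
                   condition: Condition) -> dict[tuple[str, str], float]:
    """dE_met / d ln p at fixed metabolite levels (envelope theorem).

    Covers kcat_fwd, keq and each K_M of every support reaction, plus
    sensitivities to external metabolite concentrations (key
    ``("", "conc:<met>")``).
    """
    out: dict[tuple[str, str], float] = {}
    ext_acc: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.id not in efm.support:
            continue
        v = efm.flux[rxn.id]
        sign = 1 if v > 0 else -1
        _, keq, km, _ = condition.kinetics_of(rxn)
        stoich, _keq_dir = _oriented(rxn, keq, sign)
        cost = solution.cost_terms[rxn.id]
        fac = solution.factors[rxn.id]
        # E_r ~ 1/kcat at fixed x
        out[(rxn.id, "kcat_fwd")] = -cost
        # eta_rev depends on theta = ln Keq_dir - n.x; d theta/d ln keq = sign
        dln_rev_dlnkeq = math.exp(-fac.theta) / fac.eta_rev * sign
        out[(rxn.id, "keq")] = -cost * dln_rev_dlnkeq
        _, sat_grad = _saturation({m: solution.x[m] for m in solution.x}, stoich, km,
                                  model, condition)
        for met, dln_dlnc in sat_grad.items():
            # ratio c/K: d ln eta_sat / d ln K = - d ln eta_sat / d ln c
            out[(rxn.id, f"km:{met}")] = cost * dln_dlnc
        # external concentrations act through theta and saturation
        for met, n in stoich.items():
            m_obj = model.metabolite(met)
            if not m_obj.is_external:
                continue
            dln_rev = math.exp(-fac.theta) / fac.eta_rev * (-n)
            dln = dln_rev + sat_grad.get(met, 0.0)
            ext_acc[met] = ext_acc.get(met, 0.0) - cost * dln
    for met, val in ext_acc.items():
        out[("", f"conc:{met}")] = val
    return out


def growth_sensitivities(efm: EFM, solution: ECMSolution, model: MetabolicModel,
                         condition: Condition) -> pd.DataFrame:
    """First derivatives d mu / d ln p for every kinetic parameter.

    At the ECM optimum the first-order effect of a parameter on the minimal
    cost equals its effect at fixed metabolite levels, so no re-optimization
    is needed.  Parameters of reactions outside the EFM support have exactly
    zero sensitivity.
    """
    gp = model.growth_params
    e_met = solution.e_met
    dmu_de = -gp.numerator / (e_met + gp.offset_cost) ** 2
    partials = _cost_partials(efm, solution, model, condition)
    rows = []
    for rxn in model.reactions:
        for par in ["kcat_fwd", "keq"] + [f"km:{m}" for m in sorted(rxn.kinetics.km)]:
            de = partials.get((rxn.id, par), 0.0)
            rows.append(
                {
                    "reaction": rxn.id,
                    "parameter": par,
                    "dEmet_dlnp": de,
                    "dmu_dlnp": dmu_de * de,
                }
            )
    for (rid, par), de in partials.items():
        if rid == "":
            rows.append(
                {"reaction": "", "parameter": par, "dEmet_dlnp": de,
                 "dmu_dlnp": dmu_de * de}
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# knockouts and epistasis
# ----------------------------------------------------------------------

def _best_mu(points: list[RateYieldPoint], surviving_ids: set[int]) -> float:
    mus = [p.mu for p in points if p.efm_id in surviving_ids]
    return max(mus) if mus else 0.0


def knockout_analysis(
    model: MetabolicModel,
    efms: EFMSet,
    knockouts: set[str],
    condition: Condition,
    spectrum: list[RateYieldPoint] | None = None,
    opts: EcmOptions | None = None,
    cache: EcmCache | None = None,
) -> dict[str, float]:
    """Growth advantage of the wild type over a knockout strain.

    EFMs using a knocked-out reaction are discarded; no new optimizations
    run when a precomputed ``spectrum`` is supplied.  A lethal knockout
    (no surviving EFM) reports ``advantage = inf``.
    """
    for r in knockouts:
        model.reaction(r)  # KeyError on unknown ids
    if spectrum is None:
        spectrum, _ = rate_yield_spectrum(efms, model, condition, opts, cache)
    wt_ids = {e.id for e in efms.biomass_producing(model)}
    ko_ids = {e.id for e in knockout_filter(efms, knockouts).biomass_producing(model)}
    mu_wt = _best_mu(spectrum, wt_ids)
    mu_ko = _best_mu(spectrum, ko_ids)
    advantage = math.inf if mu_ko == 0.0 else mu_wt / mu_ko - 1.0
    return {"mu_wt": mu_wt, "mu_ko": mu_ko, "advantage": advantage}


def epistasis(
    model: MetabolicModel,
    efms: EFMSet,
    rxn_a: str,
    rxn_b: str,
    condition: Condition,
    spectrum: list[RateYieldPoint] | None = None,
    opts: EcmOptions | None = None,
    cache: EcmCache | None = None,
) -> dict[str, float]:
    """Multiplicative epistasis between two reaction knockouts.

    eps = (mu_AB * mu_wt) / (mu_A * mu_B); all four growth rates are
    reported so alternative statistics can be recomputed.  Lethal knockouts
    (mu = 0) make the score NaN.
    """
    if spectrum is None:
        cache = cache if cache is not None else EcmCache()
        spectrum, _ = rate_yield_spectrum(efms, model, condition, opts, cache)
    mu_wt = _best_mu(spectrum, {e.id for e in efms.biomass_producing(model)})
    mus = {}
    for label, kos in [("a", {rxn_a}), ("b", {rxn_b}), ("ab", {rxn_a, rxn_b})]:
        ids = {e.id for e in knockout_filter(efms, kos).biomass_producing(model)}
        mus[label] = _best_mu(spectrum, ids)
    if mus["a"] == 0.0 or mus["b"] == 0.0:
        score = math.nan
    else:
        score = (mus["ab"] * mu_wt) / (mus["a"] * mus["b"])
    return {
        "epsilon": score,
        "mu_wt": mu_wt,
        "mu_a": mus["a"],
        "mu_b": mus["b"],
        "mu_ab": mus["ab"],
        "definition": "multiplicative",
    }
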