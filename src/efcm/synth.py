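"""Small, fully specified model bundles with known structure.

These generators emulate a curated kinetic-model bundle at toy scale:
linear chains (exactly one EFM), diamonds (two parallel routes, two EFMs),
a certified rate/yield trade-off branch model, and seeded random networks
for cross-checking the enumerator against an exhaustive oracle.

Feasibility is built in rather than filtered in afterwards: every
equilibrium constant is assigned so the driving force is positive at a
reference interior concentration profile (1 mM for internal metabolites),
which keeps fixtures stable across solver versions.  Kinetic constants are
sampled log-uniformly from ranges typical of central metabolism: kcat in
[1, 100] 1/s, K_M in [0.01, 1] mM, enzyme masses in [1e4, 1e5] Da.

The biomass-mass conversion ``v_bm_mass`` of each toy is chosen so yields
land in the single-digit-to-tens g/C-mol range characteristic of
heterotrophic growth; growth-law constants keep their E. coli defaults.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from efcm.growth import GrowthParams, MM_PER_S_TO_MMOL_PER_L_PER_H
from efcm.model import (
    BIOMASS_KCAT_DEFAULT,
    DEFAULT_C_MAX,
    DEFAULT_C_MIN,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKinetics,
    validate_model,
)

__all__ = [
    "make_chain_model",
    "make_diamond_model",
    "make_branch_tradeoff_model",
    "make_random_model",
    "sample_kinetics",
]

_KCAT_RANGE = (1.0, 100.0)
_KM_RANGE = (0.01, 1.0)
_MASS_RANGE = (1e4, 1e5)
#: Driving-force margin (RT units) guaranteed at the reference profile.
_FEASIBILITY_MARGIN = 1.0


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _reference_ln_conc(met: Metabolite) -> float:
    if met.is_external:
        return math.log(met.fixed_conc)
    return 0.0  # 1 mM reference for internal metabolites


def sample_kinetics(
    stoich_map: dict[str, dict[str, Fraction]],
    metabolites: dict[str, Metabolite],
    seed: int,
    margin: float = _FEASIBILITY_MARGIN,
) -> dict[str, ReactionKinetics]:
    """Sample kinetics for each reaction; Keq assigned for built-in feasibility.

    ``ln Keq = sum_i n_i ln c_ref_i + margin`` makes the driving force equal
    to ``margin`` (RT units) at the reference profile, so every flux mode
    oriented forward admits a feasible metabolite polytope.  The margin is
    verified with a max-min driving-force check when the bundle is solved.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for rxn_id in sorted(stoich_map):
        stoich = stoich_map[rxn_id]
        ln_keq = margin + sum(
            float(n) * _reference_ln_conc(metabolites[m]) for m, n in stoich.items()
        )
        km = {
            m: _log_uniform(rng, *_KM_RANGE)
            for m in sorted(stoich)
            if not metabolites[m].is_external
        }
        out[rxn_id] = ReactionKinetics(
            kcat_fwd=_log_uniform(rng, *_KCAT_RANGE),
            keq=math.exp(ln_keq),
            km=km,
            enzyme_mass=_log_uniform(rng, *_MASS_RANGE),
        )
    return out


def _internal(met_id: str, carbon: int = 1) -> Metabolite:
    return Metabolite(met_id, is_external=False, c_min=DEFAULT_C_MIN,
                      c_max=DEFAULT_C_MAX, carbon_count=carbon)


def _external(met_id: str, conc: float, carbon: int = 0) -> Metabolite:
    return Metabolite(met_id, is_external=True, fixed_conc=conc, carbon_count=carbon)


def _biomass_kinetics(km: dict[str, float]) -> ReactionKinetics:
    # very fast and thermodynamically downhill: never cost-limiting
    return ReactionKinetics(kcat_fwd=BIOMASS_KCAT_DEFAULT, keq=1e6, km=km,
                            enzyme_mass=1.0)


def _finish(model: MetabolicModel) -> MetabolicModel:
    issues = validate_model(model)
    if issues:  # pragma: no cover - generator bug guard
        raise AssertionError("generated bundle invalid: " + "; ".join(issues))
    return model


def _v_bm_mass_for_yield(target_yield: float, uptake_flux: float, carbon: int) -> float:
    """Pick v_bm_mass so a unit-biomass EFM with the given uptake hits a yield."""
    return target_yield * carbon * uptake_flux * MM_PER_S_TO_MMOL_PER_L_PER_H


def make_chain_model(n: int, seed: int = 0) -> MetabolicModel:
    """Linear chain glc_ext -> M1 -> ... -> Mn -> biomass; exactly one EFM.

    The single EFM has uptake flux 1 (at biomass convention 1 mM/s) and a
    yield of 10 g/C-mol by construction of ``v_bm_mass``.
    """
    if n < 2:
        raise ValueError("chain needs n >= 2 internal metabolites")
    mets = [_external("glc_ext", 100.0, carbon=6)]
    mets += [_internal(f"M{i+1}", carbon=6) for i in range(n)]
    mets.append(_external("biomass_ext", 1.0))
    met_map = {m.id: m for m in mets}

    stoichs: dict[str, dict[str, Fraction]] = {
        "upt": {"glc_ext": Fraction(-1), "M1": Fraction(1)}
    }
    for i in range(1, n):
        stoichs[f"r{i}"] = {f"M{i}": Fraction(-1), f"M{i+1}": Fraction(1)}
    kin = sample_kinetics(stoichs, met_map, seed)

    rxns = [Reaction("upt", stoichs["upt"], kinetics=kin["upt"])]
    for i in range(1, n):
        rxns.append(Reaction(f"r{i}", stoichs[f"r{i}"], kinetics=kin[f"r{i}"]))
    bm_stoich = {f"M{n}": Fraction(-1), "biomass_ext": Fraction(1)}
    rxns.append(Reaction("bm", bm_stoich, kinetics=_biomass_kinetics({f"M{n}": 1.0})))

    return _finish(
        MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id="bm",
            glucose_uptake_reaction_id="upt",
            growth_params=GrowthParams(
                v_bm_mass=_v_bm_mass_for_yield(10.0, 1.0, 6)
            ),
            glucose_metabolite_id="glc_ext",
            name=f"chain{n}",
        )
    )


def make_diamond_model(seed: int = 0) -> MetabolicModel:
    """glc -> A, two parallel conversions A -> B, B -> biomass: two EFMs."""
    mets = [_external("glc_ext", 100.0, carbon=6), _internal("A", 6), _internal("B", 6),
            _external("biomass_ext", 1.0)]
    met_map = {m.id: m for m in mets}
    stoichs = {
        "upt": {"glc_ext": Fraction(-1), "A": Fraction(1)},
        "p1": {"A": Fraction(-1), "B": Fraction(1)},
        "p2": {"A": Fraction(-1), "B": Fraction(1)},
    }
    kin = sample_kinetics(stoichs, met_map, seed)
    rxns = [
        Reaction("upt", stoichs["upt"], kinetics=kin["upt"]),
        Reaction("p1", stoichs["p1"], kinetics=kin["p1"]),
        Reaction("p2", stoichs["p2"], kinetics=kin["p2"]),
        Reaction("bm", {"B": Fraction(-1), "biomass_ext": Fraction(1)},
                 kinetics=_biomass_kinetics({"B": 1.0})),
    ]
    return _finish(
        MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id="bm",
            glucose_uptake_reaction_id="upt",
            growth_params=GrowthParams(v_bm_mass=_v_bm_mass_for_yield(10.0, 1.0, 6)),
            glucose_metabolite_id="glc_ext",
            name="diamond",
        )
    )


def make_branch_tradeoff_model(seed: int = 0) -> MetabolicModel:
    """Two routes from glucose to biomass with a certified rate/yield trade-off.

    Route H (``high_yield``): A -> P, slow sluggish enzyme (kcat 1/s, heavy,
    modest driving force) — one glucose per biomass, yield 20 g/C-mol.
    Route L (``low_yield``): 2 A -> P, fast and strongly driven (kcat
    100/s, light) — two glucoses per biomass, yield 10 g/C-mol but far
    cheaper enzyme.  Route L wins on growth rate, route H on yield, so the
    Pareto front contains both EFMs.
    """
    rng = np.random.default_rng(seed)
    mets = [_external("glc_ext", 100.0, carbon=6), _internal("A", 6), _internal("P", 6),
            _external("biomass_ext", 1.0)]
    rxns = [
        Reaction(
            "upt",
            {"glc_ext": Fraction(-1), "A": Fraction(1)},
            kinetics=ReactionKinetics(
                kcat_fwd=50.0, keq=100.0,
                km={"A": float(rng.uniform(0.1, 1.0))},
                enzyme_mass=3e4,
            ),
        ),
        Reaction(
            "high_yield",
            {"A": Fraction(-1), "P": Fraction(1)},
            kinetics=ReactionKinetics(
                kcat_fwd=1.0, keq=3.0, km={"A": 0.5, "P": 0.5}, enzyme_mass=5e4
            ),
        ),
        Reaction(
            "low_yield",
            {"A": Fraction(-2), "P": Fraction(1)},
            kinetics=ReactionKinetics(
                kcat_fwd=100.0, keq=1e4, km={"A": 0.5, "P": 0.5}, enzyme_mass=2e4
            ),
        ),
        Reaction("bm", {"P": Fraction(-1), "biomass_ext": Fraction(1)},
                 kinetics=_biomass_kinetics({"P": 1.0})),
    ]
    return _finish(
        MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id="bm",
            glucose_uptake_reaction_id="upt",
            # route H consumes 1 glucose per biomass -> 20 g/C-mol
            growth_params=GrowthParams(v_bm_mass=_v_bm_mass_for_yield(20.0, 1.0, 6)),
            glucose_metabolite_id="glc_ext",
            name="branch_tradeoff",
        )
    )


def make_random_model(n_reactions: int, seed: int = 0,
                      reversible_fraction: float = 0.3) -> MetabolicModel:
    """Seeded random network: a backbone chain plus random shortcut reactions.

    Shortcuts connect earlier to later chain metabolites (possibly skipping
    several, possibly with stoichiometry 2:1), some marked reversible, so
    the enumerator's splitting/merging logic is exercised.  Guaranteed
    feasible by Keq construction.  Intended for <= 12 reactions where the
    exhaustive support-subset oracle is affordable.
    """
    if n_reactions < 3:
        raise ValueError("need at least uptake, one conversion, and biomass")
    rng = np.random.default_rng(seed)
    n_chain = max(2, n_reactions - 2 - int(rng.integers(0, max(1, n_reactions - 4 + 1))))
    n_extra = n_reactions - 2 - (n_chain - 1)

    mets = [_external("glc_ext", 100.0, carbon=6)]
    mets += [_internal(f"M{i+1}", carbon=6) for i in range(n_chain)]
    mets.append(_external("biomass_ext", 1.0))
    met_map = {m.id: m for m in mets}

    stoichs: dict[str, dict[str, Fraction]] = {
        "upt": {"glc_ext": Fraction(-1), "M1": Fraction(1)}
    }
    reversibles: set[str] = set()
    for i in range(1, n_chain):
        stoichs[f"r{i}"] = {f"M{i}": Fraction(-1), f"M{i+1}": Fraction(1)}
    for k in range(max(0, n_extra)):
        i = int(rng.integers(1, n_chain))
        j = int(rng.integers(i + 1, n_chain + 1))
        coeff = Fraction(int(rng.integers(1, 3)))
        rid = f"s{k}"
        stoichs[rid] = {f"M{i}": -coeff, f"M{j}": Fraction(1)}
        if rng.random() < reversible_fraction:
            reversibles.add(rid)
    kin = sample_kinetics(stoichs, met_map, seed + 1)

    rxns = [
        Reaction(rid, stoichs[rid], reversible=rid in reversibles, kinetics=kin[rid])
        for rid in stoichs
    ]
    rxns.append(
        Reaction("bm", {f"M{n_chain}": Fraction(-1), "biomass_ext": Fraction(1)},
                 kinetics=_biomass_kinetics({f"M{n_chain}": 1.0}))
    )
    return _finish(
        MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id="bm",
            glucose_uptake_reaction_id="upt",
            growth_params=GrowthParams(v_bm_mass=_v_bm_mass_for_yield(10.0, 1.0, 6)),
            glucose_metabolite_id="glc_ext",
            name=f"random{n_reactions}_{seed}",
        )
    )
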