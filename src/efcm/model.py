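"""Kinetic metabolic model data structures.

A :class:`MetabolicModel` couples a stoichiometric network with the kinetic
constants needed for enzyme cost minimization: per reaction a forward
turnover number ``kcat_fwd`` (1/s), an equilibrium constant ``Keq``
(dimensionless, mM concentration convention), Michaelis constants ``K_M``
(mM) for its reactants, and the enzyme's molecular mass ``w`` (Da, i.e.
mg/mmol).  Metabolites are either *internal* (steady-state balanced, with
concentration bounds) or *external* (held at a fixed concentration that a
:class:`~efcm.ecm.Condition` may override).

All concentrations are in mM throughout the package, and equilibrium
constants follow the mM convention.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

__all__ = [
    "DEFAULT_C_MIN",
    "DEFAULT_C_MAX",
    "BIOMASS_KCAT_DEFAULT",
    "TAG_VOCABULARY",
    "Metabolite",
    "ReactionKinetics",
    "Reaction",
    "MetabolicModel",
    "FormulaError",
    "parse_reaction_formula",
    "render_reaction_formula",
    "validate_model",
]

#: Default concentration bounds (mM) applied when a bundle omits them.
DEFAULT_C_MIN = 1e-3
DEFAULT_C_MAX = 10.0

#: Default turnover for the biomass reaction, chosen large enough that the
#: biomass step is never cost-limiting.
BIOMASS_KCAT_DEFAULT = 1e6

#: Declared vocabulary for reaction tags used by condition filtering.
TAG_VOCABULARY = frozenset({"oxygen_sensitive", "oxygen_dependent"})


@dataclass
class Metabolite:
    id: str
    is_external: bool = False
    fixed_conc: float | None = None  # mM, required iff external
    c_min: float | None = None  # mM, required iff internal
    c_max: float | None = None
    carbon_count: int = 0

    def issues(self) -> list[str]:
        out = []
        if self.is_external:
            if self.fixed_conc is None or not self.fixed_conc > 0:
                out.append(f"metabolite {self.id}: external requires fixed_conc > 0")
        else:
            if self.c_min is None or self.c_max is None:
                out.append(f"metabolite {self.id}: internal requires c_min and c_max")
            elif not (0 < self.c_min <= self.c_max):
                out.append(
                    f"metabolite {self.id}: need 0 < c_min <= c_max, "
                    f"got [{self.c_min}, {self.c_max}]"
                )
        if self.carbon_count < 0 or self.carbon_count != int(self.carbon_count):
            out.append(f"metabolite {self.id}: carbon_count must be an integer >= 0")
        return out


@dataclass
class ReactionKinetics:
    kcat_fwd: float  # 1/s
    keq: float  # dimensionless, mM convention
    km: dict[str, float] = field(default_factory=dict)  # reactant id -> mM
    enzyme_mass: float = 1.0  # Da = mg/mmol

    def issues(self, rxn_id: str = "?") -> list[str]:
        out = []
        if not self.kcat_fwd > 0:
            out.append(f"reaction {rxn_id}: kcat_fwd must be > 0, got {self.kcat_fwd}")
        if not self.keq > 0:
            out.append(f"reaction {rxn_id}: keq must be > 0, got {self.keq}")
        if not self.enzyme_mass > 0:
            out.append(f"reaction {rxn_id}: enzyme_mass must be > 0, got {self.enzyme_mass}")
        for met, km in self.km.items():
            if not km > 0:
                out.append(f"reaction {rxn_id}: K_M({met}) must be > 0, got {km}")
        return out


@dataclass
class Reaction:
    id: str
    stoich: dict[str, Fraction]  # metabolite -> signed coefficient
    reversible: bool = False
    kinetics: ReactionKinetics | None = None
    tags: frozenset[str] = frozenset()

    @property
    def substrates(self) -> list[str]:
        return [m for m, n in self.stoich.items() if n < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, n in self.stoich.items() if n > 0]


class FormulaError(ValueError):
    """Raised when a reaction formula cannot be parsed."""


_ARROWS = ("<=>", "->")
_TOKEN_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_\-\.]*$")


def _parse_coeff(token: str) -> Fraction:
    try:
        return Fraction(token)
    except (ValueError, ZeroDivisionError) as exc:
        raise FormulaError(f"bad coefficient token {token!r}") from exc


def _parse_side(side: str, sign: int, stoich: dict[str, Fraction]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        parts = term.split()
        if not parts:
            raise FormulaError(f"empty term in formula side {side!r}")
        if len(parts) == 1:
            coeff, name = Fraction(1), parts[0]
        elif len(parts) == 2:
            coeff, name = _parse_coeff(parts[0]), parts[1]
        else:
            raise FormulaError(f"malformed term {' '.join(parts)!r}")
        if coeff <= 0:
            raise FormulaError(f"coefficient must be positive in term {term.strip()!r}")
        if not _TOKEN_RE.match(name):
            raise FormulaError(f"bad metabolite token {name!r}")
        stoich[name] = stoich.get(name, Fraction(0)) + sign * coeff
    # a metabolite appearing on both sides with equal coefficients cancels
    for name in [m for m, n in stoich.items() if n == 0]:
        del stoich[name]


def parse_reaction_formula(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A + B -> C"`` / ``"A <=> B"`` into a signed stoichiometry map.

    Substrates get negative, products positive coefficients; ``<=>`` marks
    the reaction reversible.  Coefficients may be integers, decimals, or
    fractions like ``3/2``.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise FormulaError(f"formula {text!r} contains neither '<=>' nor '->'")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, Fraction] = {}
    _parse_side(lhs, -1, stoich)
    _parse_side(rhs, +1, stoich)
    if not any(n < 0 for n in stoich.values()) or not any(n > 0 for n in stoich.values()):
        raise FormulaError(f"formula {text!r} needs substrates and products")
    return stoich, arrow == "<=>"


def _fmt_coeff(c: Fraction) -> str:
    return "" if c == 1 else f"{c} "


def render_reaction_formula(stoich: Mapping[str, Fraction], reversible: bool) -> str:
    """Canonical inverse of :func:`parse_reaction_formula` (alphabetical terms)."""
    subs = sorted(m for m, n in stoich.items() if n < 0)
    prods = sorted(m for m, n in stoich.items() if n > 0)
    lhs = " + ".join(f"{_fmt_coeff(-Fraction(stoich[m]))}{m}" for m in subs)
    rhs = " + ".join(f"{_fmt_coeff(Fraction(stoich[m]))}{m}" for m in prods)
    arrow = "<=>" if reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    glucose_uptake_reaction_id: str
    biomass_flux_convention: float = 1.0  # mM/s
    growth_params: "GrowthParams | None" = None
    glucose_metabolite_id: str | None = None
    oxygen_metabolite_id: str | None = None
    exchange_reactions: list[str] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        if self.growth_params is None:
            from efcm.growth import GrowthParams

            self.growth_params = GrowthParams()

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index()[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    @property
    def external_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.is_external]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def v_bm_mass(self) -> float:
        return self.growth_params.v_bm_mass

    def internal_stoichiometric_matrix(self) -> tuple[list[str], list[list[Fraction]]]:
        """Rows = internal metabolites, columns = reactions, exact Fractions."""
        mets = [m.id for m in self.internal_metabolites]
        idx = {m: i for i, m in enumerate(mets)}
        mat = [[Fraction(0)] * len(self.reactions) for _ in mets]
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoich.items():
                if met in idx:
                    mat[idx[met]][j] = Fraction(coeff)
        return mets, mat

    def fingerprint(self) -> str:
        """Content hash of the model, stable across sessions."""
        payload = {
            "metabolites": [
                [m.id, m.is_external, m.fixed_conc, m.c_min, m.c_max, m.carbon_count]
                for m in self.metabolites
            ],
            "reactions": [
                [
                    r.id,
                    sorted((k, str(v)) for k, v in r.stoich.items()),
                    r.reversible,
                    sorted(r.tags),
                    [r.kinetics.kcat_fwd, r.kinetics.keq, r.kinetics.enzyme_mass],
                    sorted(r.kinetics.km.items()),
                ]
                for r in self.reactions
            ],
            "biomass": self.biomass_reaction_id,
            "uptake": self.glucose_uptake_reaction_id,
            "convention": self.biomass_flux_convention,
            "growth": [
                self.growth_params.a,
                self.growth_params.b,
                self.growth_params.f_prot,
                self.growth_params.v_bm_mass,
            ],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _nullspace_dimension(model: MetabolicModel) -> int:
    import sympy

    _, mat = model.internal_stoichiometric_matrix()
    if not mat:
        return len(model.reactions)
    M = sympy.Matrix([[sympy.Rational(x) for x in row] for row in mat])
    return len(model.reactions) - M.rank()


def validate_model(model: MetabolicModel, extra_tags: Iterable[str] = ()) -> list[str]:
    """Return a list of human-readable issues; empty iff the model is valid."""
    issues: list[str] = []
    vocab = TAG_VOCABULARY | set(extra_tags)

    seen_mets: dict[str, int] = {}
    for i, met in enumerate(model.metabolites):
        if met.id in seen_mets:
            issues.append(
                f"duplicate metabolite id {met.id} (entries {seen_mets[met.id]} and {i})"
            )
        seen_mets[met.id] = i
        issues.extend(met.issues())

    seen_rxns: dict[str, int] = {}
    internal = {m.id for m in model.metabolites if not m.is_external}
    for i, rxn in enumerate(model.reactions):
        if rxn.id in seen_rxns:
            issues.append(
                f"duplicate reaction id {rxn.id} (entries {seen_rxns[rxn.id]} and {i})"
            )
        seen_rxns[rxn.id] = i
        if not rxn.stoich:
            issues.append(f"reaction {rxn.id}: empty stoichiometry")
        for met in rxn.stoich:
            if met not in seen_mets:
                issues.append(f"reaction {rxn.id}: unknown metabolite id {met}")
        bad_tags = rxn.tags - vocab
        if bad_tags:
            issues.append(f"reaction {rxn.id}: unknown tags {sorted(bad_tags)}")
        if rxn.kinetics is None:
            issues.append(f"reaction {rxn.id}: missing kinetics")
            continue
        issues.extend(rxn.kinetics.issues(rxn.id))
        for met in rxn.stoich:
            if met in internal and met not in rxn.kinetics.km:
                issues.append(f"reaction {rxn.id}: missing K_M for metabolite {met}")

    if model.biomass_reaction_id not in seen_rxns:
        issues.append(f"biomass_reaction_id {model.biomass_reaction_id} not in reactions")
    if model.glucose_uptake_reaction_id not in seen_rxns:
        issues.append(
            f"glucose_uptake_reaction_id {model.glucose_uptake_reaction_id} not in reactions"
        )
    if not model.biomass_flux_convention > 0:
        issues.append("biomass_flux_convention must be > 0")

    if not issues and _nullspace_dimension(model) < 1:
        issues.append("internal stoichiometric matrix has trivial nullspace (no flux modes)")
    return issues
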