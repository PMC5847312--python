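"""Elementary flux mode (EFM) enumeration and bookkeeping.

An EFM is a minimal steady-state flux mode: a flux vector ``v`` with
``S_int v = 0``, non-negative on irreversible reactions, whose support
contains no smaller support that also carries a steady-state flux.  EFMs
are enumerated with the nullspace/double-description scheme over exact
rational arithmetic: reversible reactions are split into forward/backward
halves, the flux cone ``{u >= 0 : S u = 0}`` is built one metabolite
balance at a time while pruning non-support-minimal rays, futile
forward/backward two-cycles are dropped, and the surviving rays are merged
back to net fluxes.  Floating point appears only in the final flux values.

Biomass-producing EFMs are normalized so the biomass reaction carries the
model's flux convention (1 mM/s by default); non-producing EFMs are kept
for diagnostics but excluded from rate/yield analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import reduce

from efcm.growth import MM_PER_S_TO_MMOL_PER_L_PER_H
from efcm.model import MetabolicModel

__all__ = [
    "EFM",
    "EFMSet",
    "EfmOverflowError",
    "NotBiomassProducing",
    "enumerate_efms",
    "normalize_efm",
    "efm_yield",
    "condition_classes",
    "filter_efms_by_condition",
    "knockout_filter",
]

#: Entries below this magnitude (after rational -> float conversion and
#: biomass normalization) are treated as structural zeros.
ZERO_FLUX_TOL = 1e-12


class EfmOverflowError(RuntimeError):
    """Intermediate ray count exceeded the configured cap."""


class NotBiomassProducing(ValueError):
    """Raised when normalizing an EFM whose biomass flux is zero."""


@dataclass(frozen=True)
class EFM:
    """One elementary flux mode, in net-flux orientation."""

    id: int
    flux: dict[str, float]  # reaction id -> flux (mM/s); zeros omitted
    support: frozenset[str]
    yield_g_per_cmol: float | None = None

    def uses(self, reaction_id: str) -> bool:
        return reaction_id in self.support

    def uses_tag(self, tag: str, model: MetabolicModel) -> bool:
        return any(tag in model.reaction(r).tags for r in self.support)


@dataclass
class EFMSet:
    efms: list[EFM]
    model_fingerprint: str = ""

    def __len__(self) -> int:
        return len(self.efms)

    def __iter__(self):
        return iter(self.efms)

    def __getitem__(self, efm_id: int) -> EFM:
        for e in self.efms:
            if e.id == efm_id:
                return e
        raise KeyError(efm_id)

    def biomass_producing(self, model: MetabolicModel) -> "EFMSet":
        bm = model.biomass_reaction_id
        return EFMSet(
            [e for e in self.efms if e.flux.get(bm, 0.0) > 0], self.model_fingerprint
        )


# ----------------------------------------------------------------------
# double description over exact rationals
# ----------------------------------------------------------------------

def _primitive(vec: tuple[Fraction, ...]) -> tuple[int, ...]:
    """Scale a rational ray to a primitive integer vector (gcd 1)."""
    denoms = [f.denominator for f in vec]
    lcm = reduce(lambda a, b: a * b // math.gcd(a, b), denoms, 1)
    ints = [int(f * lcm) for f in vec]
    g = reduce(math.gcd, (abs(x) for x in ints if x), 1)
    return tuple(x // g for x in ints)


def _extreme_rays(columns: list[tuple[Fraction, ...]], max_rays: int) -> list[tuple[int, ...]]:
    """Extreme rays of {u >= 0 : sum_k u_k * columns[k] = 0}.

    ``columns[k]`` is the internal-metabolite balance vector of split
    reaction k.  Returns primitive integer rays.
    """
    n = len(columns)
    m = len(columns[0]) if columns else 0
    # each ray: (coeffs tuple, residual tuple)
    rays: list[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]] = []
    for k in range(n):
        coeffs = tuple(Fraction(1) if j == k else Fraction(0) for j in range(n))
        rays.append((coeffs, tuple(columns[k])))

    for i in range(m):
        zero, pos, neg = [], [], []
        for ray in rays:
            r_i = ray[1][i]
            (zero if r_i == 0 else pos if r_i > 0 else neg).append(ray)
        combos = []
        for cp, rp in pos:
            a = rp[i]
            for cq, rq in neg:
                b = -rq[i]
                coeffs = tuple(b * x + a * y for x, y in zip(cp, cq))
                resid = tuple(b * x + a * y for x, y in zip(rp, rq))
                combos.append((coeffs, resid))
        candidates = zero + combos
        if len(candidates) > max_rays:
            raise EfmOverflowError(
                f"{len(candidates)} intermediate rays exceed cap {max_rays} "
                f"at balance {i + 1}/{m}"
            )
        # support-minimality pruning + dedupe on primitive form
        supports = [frozenset(j for j, c in enumerate(c0) if c != 0) for c0, _ in candidates]
        keep: list[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]] = []
        seen: set[tuple[int, ...]] = set()
        for k, (cand, supp) in enumerate(zip(candidates, supports)):
            if any(l != k and supports[l] < supp for l in range(len(candidates))):
                continue
            prim = _primitive(cand[0])
            if prim in seen:
                continue
            seen.add(prim)
            keep.append(cand)
        rays = keep
    return [_primitive(c) for c, _ in rays]


def enumerate_efms(model: MetabolicModel, max_rays: int = 200_000) -> EFMSet:
    """Enumerate all elementary flux modes of ``model``.

    Biomass-producing EFMs are normalized to the model's biomass flux
    convention and carry their yield; other EFMs are kept unscaled (primitive
    integer fluxes).  Raises :class:`EfmOverflowError` if the intermediate
    ray count exceeds ``max_rays`` — never truncates silently.
    """
    _, s_int = model.internal_stoichiometric_matrix()
    n = len(model.reactions)
    # split reversible reactions
    split: list[tuple[int, int]] = []  # (reaction index, sign)
    columns: list[tuple[Fraction, ...]] = []
    for j, rxn in enumerate(model.reactions):
        col = tuple(row[j] for row in s_int)
        split.append((j, +1))
        columns.append(col)
        if rxn.reversible:
            split.append((j, -1))
            columns.append(tuple(-x for x in col))

    rays = _extreme_rays(columns, max_rays)

    # merge split halves to net fluxes; drop futile two-cycles
    net_rays: list[tuple[int, ...]] = []
    for u in rays:
        supp_rxns = {split[k][0] for k, x in enumerate(u) if x}
        active = [k for k, x in enumerate(u) if x]
        if len(active) == 2 and len(supp_rxns) == 1:
            continue  # forward/backward two-cycle
        v = [0] * n
        for k, x in enumerate(u):
            j, sign = split[k]
            v[j] += sign * x
        net_rays.append(tuple(v))

    # canonical orientation / dedupe of mirrored reversible modes
    bm_idx = model.reaction_ids.index(model.biomass_reaction_id)
    reversible = [r.reversible for r in model.reactions]
    canon: dict[tuple[int, ...], tuple[int, ...]] = {}
    for v in net_rays:
        neg = tuple(-x for x in v)
        if neg in canon:
            continue
        # flipping is legal only when the support is fully reversible
        flippable = all(reversible[j] for j, x in enumerate(v) if x)
        if flippable:
            if v[bm_idx] < 0:
                v = neg
            elif v[bm_idx] == 0 and next((x for x in v if x), 0) < 0:
                v = neg
        canon[v] = v
    ordered = sorted(
        canon,
        key=lambda v: (0 if v[bm_idx] > 0 else 1, tuple(1 if x else 0 for x in v), v),
    )

    rxn_ids = model.reaction_ids
    efms: list[EFM] = []
    for i, v in enumerate(ordered):
        flux = {rxn_ids[j]: float(x) for j, x in enumerate(v) if x}
        efm = EFM(id=i, flux=flux, support=frozenset(flux))
        if flux.get(model.biomass_reaction_id, 0.0) > 0:
            efm = normalize_efm(efm, model)
            efm = EFM(
                id=i,
                flux=efm.flux,
                support=efm.support,
                yield_g_per_cmol=efm_yield(efm, model),
            )
        efms.append(efm)
    return EFMSet(efms, model.fingerprint())


def normalize_efm(efm: EFM, model: MetabolicModel) -> EFM:
    """Rescale so the biomass flux equals the model convention (idempotent)."""
    v_bm = efm.flux.get(model.biomass_reaction_id, 0.0)
    if v_bm == 0.0:
        raise NotBiomassProducing(f"EFM {efm.id} carries no biomass flux")
    scale = model.biomass_flux_convention / v_bm
    flux = {r: v * scale for r, v in efm.flux.items() if abs(v * scale) > ZERO_FLUX_TOL}
    return EFM(
        id=efm.id,
        flux=flux,
        support=frozenset(flux),
        yield_g_per_cmol=efm.yield_g_per_cmol,
    )


def _glucose_carbon(model: MetabolicModel) -> int:
    if model.glucose_metabolite_id is not None:
        return model.metabolite(model.glucose_metabolite_id).carbon_count
    upt = model.reaction(model.glucose_uptake_reaction_id)
    for met in upt.substrates:
        m = model.metabolite(met)
        if m.is_external and m.carbon_count > 0:
            return m.carbon_count
    raise ValueError("cannot identify the carbon source of the uptake reaction")


def efm_yield(efm: EFM, model: MetabolicModel) -> float | None:
    """Biomass yield in g per C-mol of carbon substrate, or None if undefined.

    yield = v_bm_mass * (v_biomass / convention)
            / (carbon_count * uptake flux in mmol l^-1 h^-1)
    """
    v_upt = efm.flux.get(model.glucose_uptake_reaction_id, 0.0)
    if v_upt <= 0:
        return None
    v_bm = efm.flux.get(model.biomass_reaction_id, 0.0)
    carbon = _glucose_carbon(model)
    uptake_mmol_per_l_h = v_upt * MM_PER_S_TO_MMOL_PER_L_PER_H
    return (
        model.v_bm_mass
        * (v_bm / model.biomass_flux_convention)
        / (carbon * uptake_mmol_per_l_h)
    )


# ----------------------------------------------------------------------
# condition and knockout filtering
# ----------------------------------------------------------------------

def condition_classes(efms: EFMSet, model: MetabolicModel) -> dict[str, list[int]]:
    """Classify EFM ids by oxygen-rule feasibility.

    ``discarded``: uses an oxygen-sensitive and an oxygen-dependent reaction
    simultaneously (infeasible everywhere).  ``aerobic``: no
    oxygen-sensitive usage.  ``anaerobic``: no oxygen-dependent usage.
    ``both``: intersection of the two.
    """
    out: dict[str, list[int]] = {"aerobic": [], "anaerobic": [], "both": [], "discarded": []}
    for e in efms:
        sensitive = e.uses_tag("oxygen_sensitive", model)
        dependent = e.uses_tag("oxygen_dependent", model)
        if sensitive and dependent:
            out["discarded"].append(e.id)
            continue
        if not sensitive:
            out["aerobic"].append(e.id)
        if not dependent:
            out["anaerobic"].append(e.id)
        if not sensitive and not dependent:
            out["both"].append(e.id)
    return out


def filter_efms_by_condition(efms: EFMSet, model: MetabolicModel, mode: str) -> EFMSet:
    """Keep EFMs feasible under ``mode`` in {'aerobic', 'anaerobic', 'both'}."""
    classes = condition_classes(efms, model)
    if mode not in classes or mode == "discarded":
        raise ValueError(f"unknown condition mode {mode!r}; use aerobic/anaerobic/both")
    wanted = set(classes[mode])
    return EFMSet([e for e in efms if e.id in wanted], efms.model_fingerprint)


def knockout_filter(efms: EFMSet, reactions: set[str]) -> EFMSet:
    """Drop every EFM whose support intersects the knocked-out reactions."""
    reactions = set(reactions)
    return EFMSet(
        [e for e in efms if not (e.support & reactions)], efms.model_fingerprint
    )
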