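"""Reading and writing model bundles.

A bundle is a directory with four files:

* ``compounds.tsv`` — id, name, is_external, fixed_conc_mM, c_min_mM,
  c_max_mM, carbon_count
* ``reactions.tsv`` — id, formula, kcat_fwd_per_s, keq, enzyme_mass_da, tags
* ``km.tsv`` — reaction_id, compound_id, km_mM
* ``config.json`` — biomass/uptake reaction ids, growth-conversion
  constants, optional glucose/oxygen metabolite ids and exchange reactions.

Numbers round-trip bit-identically (written with ``repr``).  An optional
SBML file may seed the stoichiometry (via cobra); kinetics always come from
the TSV tables.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from efcm.growth import GrowthParams
from efcm.model import (
    DEFAULT_C_MAX,
    DEFAULT_C_MIN,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKinetics,
    parse_reaction_formula,
    render_reaction_formula,
    validate_model,
)

__all__ = ["load_model", "write_model", "ModelValidationError", "stoichiometry_from_sbml"]


class ModelValidationError(ValueError):
    """Raised by :func:`load_model` when the bundle violates the model contract."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("invalid model bundle:\n" + "\n".join(f"- {s}" for s in issues))


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_model(path: str | Path) -> MetabolicModel:
    """Load and fully validate a model bundle directory."""
    path = Path(path)
    compounds = pd.read_csv(path / "compounds.tsv", sep="\t", float_precision="round_trip")
    reactions = pd.read_csv(path / "reactions.tsv", sep="\t", float_precision="round_trip")
    km = pd.read_csv(path / "km.tsv", sep="\t", float_precision="round_trip")
    config = json.loads((path / "config.json").read_text())

    default_c_min = float(config.get("default_c_min_mM", DEFAULT_C_MIN))
    default_c_max = float(config.get("default_c_max_mM", DEFAULT_C_MAX))

    mets = []
    for row in compounds.itertuples(index=False):
        external = bool(row.is_external)
        c_min = _opt(getattr(row, "c_min_mM", None))
        c_max = _opt(getattr(row, "c_max_mM", None))
        if not external:
            c_min = default_c_min if c_min is None else c_min
            c_max = default_c_max if c_max is None else c_max
        mets.append(
            Metabolite(
                id=str(row.id),
                is_external=external,
                fixed_conc=_opt(getattr(row, "fixed_conc_mM", None)),
                c_min=c_min if not external else None,
                c_max=c_max if not external else None,
                carbon_count=int(row.carbon_count),
            )
        )

    km_map: dict[str, dict[str, float]] = {}
    for row in km.itertuples(index=False):
        km_map.setdefault(str(row.reaction_id), {})[str(row.compound_id)] = float(row.km_mM)

    rxns = []
    for row in reactions.itertuples(index=False):
        stoich, reversible = parse_reaction_formula(str(row.formula))
        tags = getattr(row, "tags", "")
        tags = frozenset() if (not isinstance(tags, str) or not tags) else frozenset(
            t for t in tags.split(";") if t
        )
        rxns.append(
            Reaction(
                id=str(row.id),
                stoich=stoich,
                reversible=reversible,
                kinetics=ReactionKinetics(
                    kcat_fwd=float(row.kcat_fwd_per_s),
                    keq=float(row.keq),
                    km=km_map.get(str(row.id), {}),
                    enzyme_mass=float(row.enzyme_mass_da),
                ),
                tags=tags,
            )
        )

    gp = config.get("growth_params", {})
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=str(config["biomass_reaction_id"]),
        glucose_uptake_reaction_id=str(config["glucose_uptake_reaction_id"]),
        biomass_flux_convention=float(config.get("biomass_flux_convention_mM_per_s", 1.0)),
        growth_params=GrowthParams(
            a=float(gp.get("a", 0.27)),
            b=float(gp.get("b", 0.2)),
            f_prot=float(gp.get("f_prot", 0.5)),
            v_bm_mass=float(config.get("v_bm_mass_mg_per_l_per_h", 7.45e7)),
        ),
        glucose_metabolite_id=config.get("glucose_metabolite_id"),
        oxygen_metabolite_id=config.get("oxygen_metabolite_id"),
        exchange_reactions=list(config.get("exchange_reactions", [])),
        name=str(config.get("name", path.name)),
    )
    issues = validate_model(model, extra_tags=config.get("extra_tags", ()))
    if issues:
        raise ModelValidationError(issues)
    return model


def write_model(model: MetabolicModel, path: str | Path) -> Path:
    """Write a model as a bundle directory (inverse of :func:`load_model`)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    comp_rows = []
    for m in model.metabolites:
        comp_rows.append(
            {
                "id": m.id,
                "name": m.id,
                "is_external": int(m.is_external),
                "fixed_conc_mM": "" if m.fixed_conc is None else repr(m.fixed_conc),
                "c_min_mM": "" if m.c_min is None else repr(m.c_min),
                "c_max_mM": "" if m.c_max is None else repr(m.c_max),
                "carbon_count": m.carbon_count,
            }
        )
    pd.DataFrame(comp_rows).to_csv(path / "compounds.tsv", sep="\t", index=False)

    rxn_rows, km_rows = [], []
    for r in model.reactions:
        rxn_rows.append(
            {
                "id": r.id,
                "formula": render_reaction_formula(r.stoich, r.reversible),
                "kcat_fwd_per_s": repr(r.kinetics.kcat_fwd),
                "keq": repr(r.kinetics.keq),
                "enzyme_mass_da": repr(r.kinetics.enzyme_mass),
                "tags": ";".join(sorted(r.tags)),
            }
        )
        for met, km in sorted(r.kinetics.km.items()):
            km_rows.append({"reaction_id": r.id, "compound_id": met, "km_mM": repr(km)})
    pd.DataFrame(rxn_rows).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(km_rows, columns=["reaction_id", "compound_id", "km_mM"]).to_csv(
        path / "km.tsv", sep="\t", index=False
    )

    gp = model.growth_params
    config = {
        "name": model.name,
        "biomass_reaction_id": model.biomass_reaction_id,
        "glucose_uptake_reaction_id": model.glucose_uptake_reaction_id,
        "biomass_flux_convention_mM_per_s": model.biomass_flux_convention,
        "v_bm_mass_mg_per_l_per_h": gp.v_bm_mass,
        "growth_params": {"a": gp.a, "b": gp.b, "f_prot": gp.f_prot},
        "glucose_metabolite_id": model.glucose_metabolite_id,
        "oxygen_metabolite_id": model.oxygen_metabolite_id,
        "exchange_reactions": model.exchange_reactions,
    }
    (path / "config.json").write_text(json.dumps(config, indent=1) + "\n")
    return path


def stoichiometry_from_sbml(sbml_path: str | Path) -> list[Reaction]:
    """Read reaction stoichiometries (only) from an SBML file via cobra.

    Kinetic constants are not taken from SBML; attach them from TSV tables
    afterwards.
    """
    from fractions import Fraction

    import cobra.io

    cm = cobra.io.read_sbml_model(str(sbml_path))
    out = []
    for rxn in cm.reactions:
        stoich = {met.id: Fraction(coeff).limit_denominator(10**6)
                  for met, coeff in rxn.metabolites.items()}
        out.append(Reaction(id=rxn.id, stoich=stoich, reversible=rxn.reversibility))
    return out
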