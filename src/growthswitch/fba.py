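"""Theoretical maximum glycerol yield by flux balance analysis.

Linear programming over steady-state fluxes (S v = 0, bounds respected)
maximizing the glycerol exchange flux, with the production scenario's
constraints: glucose exchange fixed at -1 mmol/gDW/h, non-growth-associated
maintenance (NGAM) pinned to 6.75 mmol/gDW/h, growth-associated maintenance
zero, oxygen uptake unconstrained. The mass yield converts the molar flux
ratio with MW(glycerol) = 92.09 and MW(glucose) = 180.16 g/mol.

The module is a thin surface over cobrapy (GLPK backend). A bundled toy
network (7 metabolites, 9 reactions) covers unit testing; a genome-scale
model such as iAF1260 can be supplied as SBML or COBRA JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "MetabolicModel", "FBAResult", "toy_glycerol_model", "load_model",
    "write_model_json", "apply_paper_constraints", "maximize_product_yield",
]

MW_GLYCEROL = 92.09   # g/mol
MW_GLUCOSE = 180.16   # g/mol

#: ATP gained per triose fully oxidized in the toy network; chosen so the
#: default NGAM of 6.75 diverts exactly half a triose from glycerol
ATP_PER_TRIOSE = 13.5


class ConfigurationError(ValueError):
    """A designated reaction id is absent from the model."""


@dataclass
class MetabolicModel:
    """A stoichiometric model plus its designated reaction ids."""
    model: cobra.Model
    glucose_exchange: str = "EX_glc_e"
    product_exchange: str = "EX_glyc_e"
    oxygen_exchange: str = "EX_o2_e"
    maintenance: str = "ATPM"

    def __post_init__(self):
        for rid in (self.glucose_exchange, self.product_exchange,
                    self.oxygen_exchange, self.maintenance):
            if rid not in self.model.reactions:
                raise ConfigurationError(
                    f"designated reaction {rid!r} not in model"
                )
        for rxn in self.model.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"inverted bounds on {rxn.id}")

    @property
    def n_metabolites(self) -> int:
        return len(self.model.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.model.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        return create_stoichiometric_matrix(self.model)

    def copy(self) -> "MetabolicModel":
        return replace(self, model=self.model.copy())


@dataclass
class FBAResult:
    objective_flux: float            # mmol/gDW/h
    fluxes: dict                     # reaction id -> flux
    mass_yield: float                # g product per g substrate
    status: str


def toy_glycerol_model() -> MetabolicModel:
    """Bundled 7-metabolite, 9-reaction glucose-to-glycerol toy network.

    glc_e -> glc_c -> 2 triose; each triose either becomes glycerol or is
    oxidized for ATP; ATP leaves through the maintenance drain.
    """
    m = cobra.Model("toy_glycerol")
    mets = {mid: cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])
            for mid in
            ("glc_e", "glc_c", "tri_c", "gly_c", "gly_e", "o2_e", "atp_c")}

    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        return r

    m.add_reactions([
        rxn("EX_glc_e", {"glc_e": -1}, -10.0, 0.0),
        rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0),
        rxn("SPLIT", {"glc_c": -1, "tri_c": 2}, 0.0, 1000.0),
        rxn("TRI2GLY", {"tri_c": -1, "gly_c": 1}, 0.0, 1000.0),
        rxn("GLYCt", {"gly_c": -1, "gly_e": 1}, 0.0, 1000.0),
        rxn("EX_glyc_e", {"gly_e": -1}, 0.0, 1000.0),
        rxn("OXID", {"tri_c": -1, "o2_e": -3, "atp_c": ATP_PER_TRIOSE},
            0.0, 1000.0),
        rxn("EX_o2_e", {"o2_e": -1}, -1000.0, 0.0),
        rxn("ATPM", {"atp_c": -1}, 0.0, 1000.0),
    ])
    return MetabolicModel(model=m)


def load_model(path, fmt: str | None = None, **designated) -> MetabolicModel:
    """Load an SBML (Level 3 FBC) or COBRA-style JSON model from ``path``.

    ``designated`` overrides the default exchange/maintenance reaction ids
    (e.g. ``glucose_exchange="EX_glc__D_e"`` for iAF1260-family models).
    """
    path = str(path)
    if fmt is None:
        fmt = "json" if path.endswith(".json") else "sbml"
    if fmt == "json":
        model = cobra.io.load_json_model(path)
    elif fmt == "sbml":
        model = cobra.io.read_sbml_model(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return MetabolicModel(model=model, **designated)


def write_model_json(mm: MetabolicModel, path) -> None:
    cobra.io.save_json_model(mm.model, str(path))


def apply_paper_constraints(
    mm: MetabolicModel,
    glucose_uptake: float = -1.0,
    ngam: float = 6.75,
    fix_biomass_zero: bool = False,
    biomass_id: str | None = None,
) -> MetabolicModel:
    """Production-scenario constraints, returned as a new model.

    Glucose exchange fixed at ``glucose_uptake`` (mmol/gDW/h, negative =
    uptake), maintenance pinned to ``ngam``, oxygen exchange opened.
    Growth-associated maintenance is zero by construction in the toy model;
    for genome-scale models the biomass flux is left free by default
    (``fix_biomass_zero=True`` additionally pins it to 0). Idempotent.
    """
    out = mm.copy()
    model = out.model
    model.reactions.get_by_id(out.glucose_exchange).bounds = (
        glucose_uptake, glucose_uptake
    )
    model.reactions.get_by_id(out.maintenance).bounds = (ngam, ngam)
    model.reactions.get_by_id(out.oxygen_exchange).bounds = (-1000.0, 1000.0)
    if fix_biomass_zero:
        if biomass_id is None:
            candidates = [r.id for r in model.reactions
                          if "biomass" in r.id.lower()]
            if not candidates:
                raise ConfigurationError("no biomass reaction found to fix")
            biomass_id = candidates[0]
        model.reactions.get_by_id(biomass_id).bounds = (0.0, 0.0)
    return out


def maximize_product_yield(
    mm: MetabolicModel,
    product_exchange: str | None = None,
    mw_product: float = MW_GLYCEROL,
    mw_substrate: float = MW_GLUCOSE,
) -> FBAResult:
    """Maximize the product exchange flux subject to S v = 0 and bounds."""
    product_exchange = product_exchange or mm.product_exchange
    model = mm.model
    if product_exchange not in model.reactions:
        raise ConfigurationError(
            f"product exchange {product_exchange!r} not in model"
        )
    model.objective = model.reactions.get_by_id(product_exchange)
    model.objective_direction = "max"
    sol = model.optimize()
    if sol.status == "infeasible":
        fixed = [r.id for r in model.reactions
                 if r.lower_bound == r.upper_bound and r.lower_bound != 0]
        raise RuntimeError(
            f"FBA infeasible; binding fixed-flux constraints: {fixed}"
        )
    if sol.status == "unbounded":
        raise RuntimeError("FBA unbounded: product flux has no finite optimum")
    v_product = float(sol.objective_value)
    v_substrate = float(sol.fluxes[mm.glucose_exchange])
    if math.isclose(v_substrate, 0.0, abs_tol=1e-12):
        raise RuntimeError("zero substrate uptake; mass yield undefined")
    mass_yield = (v_product * mw_product) / (abs(v_substrate) * mw_substrate)
    return FBAResult(
        objective_flux=v_product,
        fluxes=sol.fluxes.to_dict(),
        mass_yield=mass_yield,
        status=sol.status,
    )
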