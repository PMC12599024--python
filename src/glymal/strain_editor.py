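"""Model refinement for the M4-lineage glycerol / L-malate strains.

The published in-silico strains start from the E. coli core network and

* gain glycerol assimilation: glycerol exchange (EX_glyc_e), facilitated
  transport (GLYCt), glycerol kinase (GLYK) and the NADP-dependent
  glycerol-3-phosphate dehydrogenase (G3PD2), with BIGG-standard
  stoichiometries;
* gain NAD-dependent acetaldehyde dehydrogenase to acetate (ALDD2x) — with
  the Pta-AckA route deleted it is the only remaining acetate source, and the
  published flux panels carry it;
* lose glucose uptake (EX_glc__D_e removed, no glucose in the medium) and the
  knocked-out steps acetate kinase (ACKr), phosphotransacetylase (PTAr) and
  succinate dehydrogenase (SUCDi);
* lose PEP carboxylase (PPC) and instead carry a reversible PEP carboxykinase
  (PPCK), so anaplerotic carboxylation runs through Pck
  (PEP + CO2 + ADP -> OAA + ATP), the route the published flux tables report
  under ATP-producing reactions;
* export L-malate: the core malate/H+ symporter (MALt2_2) is uptake-only and
  is opened to run in both directions, since the engineered strains secrete
  L-malate.

All three M4-lineage strains share this structural edit set; they differ only
through their measured exchange-rate constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .stoich_model import Metabolite, Reaction, StoichModel

__all__ = ["StrainEditSet", "apply_edits", "builtin_m4_edits"]


@dataclass(frozen=True)
class StrainEditSet:
    """A declarative set of structural model edits.

    ``bound_changes`` maps reaction id -> (lb, ub) and covers reversibility
    edits (e.g. opening a transporter) without touching the stoichiometry.
    ``knockout_by_bounds`` applies removals as [0, 0] bounds instead of
    deleting the reactions — a sensitivity-check option.
    """

    label: str
    additions: Sequence[Reaction] = ()
    new_metabolites: Sequence[Metabolite] = ()
    removals: Sequence[str] = ()
    bound_changes: Mapping[str, tuple[float, float]] = field(default_factory=dict)


def apply_edits(
    model: StoichModel, edits: StrainEditSet, knockout_by_bounds: bool = False
) -> StoichModel:
    """Return a new model with the edits applied; the input is untouched.

    Unknown removal ids, colliding addition ids, and additions referencing
    metabolites that are neither in the model nor in ``new_metabolites``
    all raise ``ValueError`` naming the offender.
    """
    for rid in edits.removals:
        if rid not in model.reactions:
            raise ValueError(f"cannot remove unknown reaction {rid!r}")
    for rxn in edits.additions:
        if rxn.id in model.reactions:
            raise ValueError(f"addition {rxn.id!r} collides with an existing reaction")
    for rid in edits.bound_changes:
        if rid not in model.reactions and rid not in {r.id for r in edits.additions}:
            raise ValueError(f"bound change targets unknown reaction {rid!r}")

    mets = dict(model.metabolites)
    for met in edits.new_metabolites:
        mets.setdefault(met.id, met)
    known = set(mets)
    for rxn in edits.additions:
        missing = [m for m in rxn.stoichiometry if m not in known]
        if missing:
            raise ValueError(
                f"addition {rxn.id!r} references unresolved metabolite(s) {missing}"
            )

    removed = set(edits.removals)
    rxns: dict[str, Reaction] = {}
    for rid, rxn in model.reactions.items():
        if rid in removed:
            if knockout_by_bounds:
                rxns[rid] = replace(rxn, lower_bound=0.0, upper_bound=0.0)
            continue
        rxns[rid] = rxn
    for rxn in edits.additions:
        rxns[rxn.id] = rxn
    for rid, (lb, ub) in edits.bound_changes.items():
        rxns[rid] = replace(rxns[rid], lower_bound=lb, upper_bound=ub)

    out = StoichModel(mets.values(), rxns.values(), model_id=model.id, notes=model.notes)
    return out


def builtin_m4_edits() -> StrainEditSet:
    """The canonical M4-lineage edit set used by every scenario.

    Glycerol uptake is left open (lb = -1000) pending scenario constraints.
    """
    glyc_e = Metabolite("glyc_e", "Glycerol", "e", {"C": 3, "H": 8, "O": 3}, 0)
    glyc_c = Metabolite("glyc_c", "Glycerol", "c", {"C": 3, "H": 8, "O": 3}, 0)
    glyc3p_c = Metabolite(
        "glyc3p_c", "Glycerol 3-phosphate", "c", {"C": 3, "H": 7, "O": 6, "P": 1}, -2
    )
    additions = (
        Reaction("EX_glyc_e", {"glyc_e": -1.0}, "Glycerol exchange", -1000.0, 1000.0),
        Reaction(
            "GLYCt", {"glyc_e": -1.0, "glyc_c": 1.0},
            "Glycerol transport via facilitated diffusion", -1000.0, 1000.0,
        ),
        Reaction(
            "GLYK",
            {"glyc_c": -1.0, "atp_c": -1.0, "glyc3p_c": 1.0, "adp_c": 1.0, "h_c": 1.0},
            "Glycerol kinase", 0.0, 1000.0,
        ),
        Reaction(
            "G3PD2",
            {"glyc3p_c": -1.0, "nadp_c": -1.0, "dhap_c": 1.0, "nadph_c": 1.0, "h_c": 1.0},
            "Glycerol-3-phosphate dehydrogenase (NADP)", -1000.0, 1000.0,
        ),
        Reaction(
            "ALDD2x",
            {"acald_c": -1.0, "h2o_c": -1.0, "nad_c": -1.0,
             "ac_c": 1.0, "h_c": 2.0, "nadh_c": 1.0},
            "Aldehyde dehydrogenase (acetaldehyde, NAD)", 0.0, 1000.0,
        ),
    )
    return StrainEditSet(
        label="M4-lineage",
        additions=additions,
        new_metabolites=(glyc_e, glyc_c, glyc3p_c),
        removals=("EX_glc__D_e", "ACKr", "PTAr", "SUCDi", "PPC"),
        bound_changes={
            # Pck runs anaplerotically: allow PEP + CO2 + ADP -> OAA + ATP
            "PPCK": (-1000.0, 1000.0),
            # engineered strains export L-malate; core transporter is uptake-only
            "MALt2_2": (-1000.0, 1000.0),
        },
    )
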