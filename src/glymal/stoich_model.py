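"""Data model for constraint-based metabolic networks.

A :class:`StoichModel` is the in-memory form of a BIGG-style model: metabolites
with elemental formulas, reactions with signed stoichiometries and flux bounds,
and a linear objective.  Exchange reactions (single-metabolite pseudo-reactions
moving mass across the system boundary) follow the standard sign convention:
negative flux = uptake, positive flux = secretion.

Readers are provided for the BIGG JSON dialect (read/write) and for SBML
Level 3 with the flux-bounds (FBC) extension (read).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichModel",
    "FluxState",
    "ModelParseError",
    "parse_formula",
    "read_bigg_json",
    "write_bigg_json",
    "read_sbml_fbc",
    "load_ecoli_core",
    "element_balance",
]

# Element symbols accepted in formulas.  Covers the biological subset plus the
# generic "R"/"X" placeholders, which are rejected explicitly below.
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba W Hg Pb".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelParseError(ValueError):
    """Raised when a model document violates the format contract."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C3H8O3`` into ``{element: count}``.

    Multi-letter elements are supported and a missing count means 1.
    Unknown symbols (including the generic ``X``/``R`` placeholders) raise
    :class:`ModelParseError`.
    """
    if formula is None or formula == "":
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ModelParseError(f"malformed formula {formula!r}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        if el not in _ELEMENTS:
            raise ModelParseError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
    if pos != len(formula):
        raise ModelParseError(f"malformed formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Inverse of :func:`parse_formula` (Hill-ish element order: C, H, rest)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order if counts[e])


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self):
        for el, n in self.formula.items():
            if el not in _ELEMENTS:
                raise ModelParseError(f"unknown element {el!r} in {self.id}")
            if n < 0:
                raise ModelParseError(f"negative atom count for {el} in {self.id}")

    def carbon(self) -> int:
        return int(self.formula.get("C", 0))


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    objective_coefficient: float = 0.0

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelParseError(f"reaction {self.id} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelParseError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def reversed_sign(self) -> bool:
        return self.lower_bound < 0


class StoichModel:
    """A stoichiometric model: metabolites x reactions, bounds, objective."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        model_id: str = "",
        notes: Mapping[str, str] | None = None,
    ):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelParseError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelParseError(f"duplicate reaction id {rxn.id!r}")
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelParseError(
                        f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                    )
            self.reactions[rxn.id] = rxn
        self.notes = dict(notes or {})

    # -- basic introspection ------------------------------------------------
    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StoichModel {self.id or '?'}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )

    def copy(self) -> "StoichModel":
        return StoichModel(
            self.metabolites.values(), self.reactions.values(), self.id, self.notes
        )

    def exchange_ids(self) -> list[str]:
        """Reactions with exactly one stoichiometric entry."""
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def objective_reaction_ids(self) -> set[str]:
        return {r.id for r in self.reactions.values() if r.objective_coefficient != 0}

    def with_bounds(self, rxn_id: str, lb: float, ub: float) -> "StoichModel":
        """Pure bound update; returns a new model."""
        if rxn_id not in self.reactions:
            raise KeyError(f"unknown reaction {rxn_id!r}")
        out = self.copy()
        out.reactions[rxn_id] = replace(
            self.reactions[rxn_id], lower_bound=lb, upper_bound=ub
        )
        return out

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) with its row/column id orders."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coef
        return S, met_ids, rxn_ids


@dataclass
class FluxState:
    """Result of an LP solve over a :class:`StoichModel`."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"
    total_absolute_flux: float = math.nan

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# BIGG JSON dialect
# ---------------------------------------------------------------------------

def read_bigg_json(path: str | Path) -> StoichModel:
    """Read a BIGG-dialect JSON model file.

    Boundary metabolites (older ``_b`` dialect) are dropped; exchanges are
    kept as one-sided reactions.  Duplicate or unresolved ids raise
    :class:`ModelParseError` naming the offending id.
    """
    with open(path) as fh:
        doc = json.load(fh)
    return _model_from_bigg_dict(doc)


def _model_from_bigg_dict(doc: Mapping) -> StoichModel:
    mets = []
    boundary: set[str] = set()
    for m in doc.get("metabolites", []):
        mid = m["id"]
        if mid.endswith("_b"):
            boundary.add(mid)
            continue
        formula = m.get("formula") or ""
        mets.append(
            Metabolite(
                id=mid,
                name=m.get("name", ""),
                compartment=m.get("compartment", mid.rsplit("_", 1)[-1]),
                formula=parse_formula(formula) if isinstance(formula, str) else formula,
                charge=int(m.get("charge", 0) or 0),
            )
        )
    rxns = []
    for r in doc.get("reactions", []):
        stoich = {
            mid: float(c)
            for mid, c in r.get("metabolites", {}).items()
            if mid not in boundary
        }
        rxns.append(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
        )
    notes = doc.get("notes", {}) or {}
    return StoichModel(mets, rxns, model_id=doc.get("id", ""), notes=notes)


def write_bigg_json(model: StoichModel, path: str | Path) -> None:
    """Write a model in the BIGG JSON dialect (read_bigg_json round-trips)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": format_formula(m.formula),
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "objective_coefficient": r.objective_coefficient,
            }
            for r in model.reactions.values()
        ],
        "genes": [],
        "compartments": {
            c: c for c in sorted({m.compartment for m in model.metabolites.values()})
        },
        "notes": model.notes,
        "version": "1",
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_ecoli_core() -> StoichModel:
    """Load the bundled E. coli core model (BIGG id ``e_coli_core``).

    ~72 metabolites / 95 reactions; provenance is recorded in the fixture's
    ``notes`` block.
    """
    ref = resources.files("glymal.data").joinpath("e_coli_core.json")
    with resources.as_file(ref) as p:
        return read_bigg_json(p)


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC (read only)
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version{v}/core"
_FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version{v}"


def read_sbml_fbc(path: str | Path) -> StoichModel:
    """Read an SBML Level 3 document carrying the FBC flux-bounds extension.

    Produces a model semantically identical to the equivalent BIGG JSON.
    Documents whose reactions carry no flux bounds raise
    :class:`ModelParseError` instructing the caller to supply bounds.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    nsmap = {k: v for k, v in root.nsmap.items()}
    fbc_ns = next((v for v in nsmap.values() if "/fbc/" in str(v)), None)
    sbml_ns = root.tag.split("}")[0].strip("{")

    def q(tag, ns=sbml_ns):
        return f"{{{ns}}}{tag}"

    model_el = root.find(q("model"))
    if model_el is None:
        raise ModelParseError(f"{path}: no <model> element")

    # flux-bound parameters
    params: dict[str, float] = {}
    for p in model_el.iterfind(f"{q('listOfParameters')}/{q('parameter')}"):
        params[p.get("id")] = float(p.get("value"))

    mets = []
    for sp in model_el.iterfind(f"{q('listOfSpecies')}/{q('species')}"):
        sid = _desbml(sp.get("id"))
        if sp.get("boundaryCondition") == "true" or sid.endswith("_b"):
            continue
        formula = sp.get(q("chemicalFormula", fbc_ns)) if fbc_ns else None
        charge = sp.get(q("charge", fbc_ns)) if fbc_ns else None
        mets.append(
            Metabolite(
                id=sid,
                name=sp.get("name", ""),
                compartment=sp.get("compartment", ""),
                formula=parse_formula(formula or ""),
                charge=int(float(charge)) if charge is not None else 0,
            )
        )
    met_ids = {m.id for m in mets}

    # FBC objective
    obj_coefs: dict[str, float] = {}
    if fbc_ns is not None:
        list_obj = model_el.find(q("listOfObjectives", fbc_ns))
        if list_obj is not None:
            active = list_obj.get(q("activeObjective", fbc_ns))
            for obj in list_obj.iterfind(q("objective", fbc_ns)):
                if active and obj.get(q("id", fbc_ns)) not in (active, None):
                    continue
                for fo in obj.iter(q("fluxObjective", fbc_ns)):
                    rid = _desbml(fo.get(q("reaction", fbc_ns)))
                    obj_coefs[rid] = float(fo.get(q("coefficient", fbc_ns), 1.0))

    rxns = []
    saw_bounds = False
    for rx in model_el.iterfind(f"{q('listOfReactions')}/{q('reaction')}"):
        rid = _desbml(rx.get("id"))
        stoich: dict[str, float] = {}
        for ref in rx.iterfind(f"{q('listOfReactants')}/{q('speciesReference')}"):
            sid = _desbml(ref.get("species"))
            if sid in met_ids:
                stoich[sid] = stoich.get(sid, 0.0) - float(ref.get("stoichiometry", 1))
        for ref in rx.iterfind(f"{q('listOfProducts')}/{q('speciesReference')}"):
            sid = _desbml(ref.get("species"))
            if sid in met_ids:
                stoich[sid] = stoich.get(sid, 0.0) + float(ref.get("stoichiometry", 1))
        lb_ref = rx.get(q("lowerFluxBound", fbc_ns)) if fbc_ns else None
        ub_ref = rx.get(q("upperFluxBound", fbc_ns)) if fbc_ns else None
        if lb_ref is None or ub_ref is None:
            raise ModelParseError(
                f"reaction {rid}: no FBC flux bounds; supply bounds via the FBC "
                "extension (lowerFluxBound/upperFluxBound) to read this document"
            )
        saw_bounds = True
        if not stoich:
            continue  # pure boundary reaction against dropped _b species
        rxns.append(
            Reaction(
                id=rid,
                name=rx.get("name", ""),
                stoichiometry=stoich,
                lower_bound=params.get(lb_ref, float(lb_ref) if _isnum(lb_ref) else -1000.0),
                upper_bound=params.get(ub_ref, float(ub_ref) if _isnum(ub_ref) else 1000.0),
                objective_coefficient=obj_coefs.get(rid, 0.0),
            )
        )
    if rxns and not saw_bounds:  # pragma: no cover - defensive
        raise ModelParseError(f"{path}: document carries no flux bounds")
    return StoichModel(mets, rxns, model_id=model_el.get("id", ""))


def _desbml(sid: str | None) -> str:
    """Strip the conventional SBML id prefixes (M_, R_, G_)."""
    if sid is None:
        return ""
    for pref in ("M_", "R_", "G_"):
        if sid.startswith(pref):
            return sid[len(pref):]
    return sid


def _isnum(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Elemental accounting
# ---------------------------------------------------------------------------

def element_balance(model: StoichModel, reaction_id: str) -> dict[str, float]:
    """Net atoms per element for one reaction: sum of coefficient x count.

    An all-zero map means the reaction is elementally balanced.  Exchange
    reactions net to the single metabolite's formula by construction.  A
    participating metabolite without a formula raises ``ValueError`` naming it.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    rxn = model.reactions[reaction_id]
    net: dict[str, float] = {}
    for mid, coef in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        if not met.formula:
            raise ValueError(
                f"metabolite {mid!r} in reaction {reaction_id!r} carries no formula"
            )
        for el, n in met.formula.items():
            net[el] = net.get(el, 0.0) + coef * n
    return {el: v for el, v in net.items() if abs(v) > 1e-9} or {}
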