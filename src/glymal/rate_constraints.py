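"""From fermentation measurements to normalized flux constraints.

The pipeline is: time-course -> interval specific rates (mmol/gCDW/h) ->
normalization to a glycerol uptake of -20 mmol/gCDW/h -> carbon closure with a
compensating CO2 flux -> a fully constrained scenario model for pFBA/FVA.

Carbon bookkeeping counts 3 C per glycerol, 4 per L-malate and succinate,
2 per acetate, and the biomass carbon coefficient taken from the model's own
biomass stoichiometry, so closure is self-consistent with the network the
fluxes are fed into.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ferm_quant import MOLECULAR_WEIGHTS
from .stoich_model import StoichModel

__all__ = [
    "TimeCourse",
    "SpecificRates",
    "ScenarioConstraints",
    "CarbonBalance",
    "SPECIES_CARBON",
    "specific_rates",
    "normalize_to_glycerol",
    "biomass_carbon",
    "carbon_closure",
    "build_scenario",
    "builtin_table1_scenarios",
    "EXCHANGE_IDS",
]

SPECIES_CARBON = {"glycerol": 3, "malate": 4, "succinate": 4, "acetate": 2}

#: exchange / biomass reaction ids the scenarios constrain
EXCHANGE_IDS = {
    "glycerol": "EX_glyc_e",
    "malate": "EX_mal__L_e",
    "acetate": "EX_ac_e",
    "succinate": "EX_succ_e",
    "co2": "EX_co2_e",
    "o2": "EX_o2_e",
    "biomass": "BIOMASS_Ecoli_core_w_GAM",
}


@dataclass(frozen=True)
class TimeCourse:
    """Batch fermentation measurements on a shared time grid.

    times in h (strictly increasing), biomass in g CDW/L, concentrations in
    g/L per species.  pH and dissolved-oxygen channels are optional cosmetic
    extras and never consumed by the estimators.
    """

    times: Sequence[float]
    biomass: Sequence[float]
    concentrations: Mapping[str, Sequence[float]]
    ph: Sequence[float] | None = None
    do_percent: Sequence[float] | None = None

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing, length >= 2")
        if len(self.biomass) != len(t):
            raise ValueError("biomass series length differs from times")
        for sp, series in self.concentrations.items():
            if len(series) != len(t):
                raise ValueError(f"series {sp!r} length differs from times")
            if np.any(np.asarray(series, float) < -1e-12):
                raise ValueError(f"negative concentration in series {sp!r}")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": list(self.times), "biomass_gCDW_L": list(self.biomass)}
        for sp, series in self.concentrations.items():
            data[f"{sp}_g_L"] = list(series)
        if self.ph is not None:
            data["pH"] = list(self.ph)
        if self.do_percent is not None:
            data["DO_pct"] = list(self.do_percent)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourse":
        conc = {
            c[: -len("_g_L")]: df[c].tolist()
            for c in df.columns
            if c.endswith("_g_L")
        }
        return cls(
            times=df["time_h"].tolist(),
            biomass=df["biomass_gCDW_L"].tolist(),
            concentrations=conc,
            ph=df["pH"].tolist() if "pH" in df else None,
            do_percent=df["DO_pct"].tolist() if "DO_pct" in df else None,
        )


@dataclass(frozen=True)
class SpecificRates:
    """Exchange rates in mmol/gCDW/h (uptake negative) and growth rate 1/h."""

    rates: Mapping[str, float]
    growth_rate: float
    interval: tuple[float, float]

    def __post_init__(self):
        for sp, q in self.rates.items():
            if not math.isfinite(q):
                raise ValueError(f"non-finite rate for {sp!r}")
        if not math.isfinite(self.growth_rate):
            raise ValueError("non-finite growth rate")


@dataclass(frozen=True)
class ScenarioConstraints:
    """A strain/grade/scale label plus fixed exchange fluxes (normalized)."""

    label: str
    glycerol_grade: str  # "pure" | "crude"
    scale: str  # "flask" | "bioreactor"
    fixed_fluxes: Mapping[str, float]  # species/"biomass" -> mmol/gCDW/h

    def __post_init__(self):
        for k, v in self.fixed_fluxes.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite flux for {k!r}")


@dataclass(frozen=True)
class CarbonBalance:
    c_in: float  # mmol C/gCDW/h entering (glycerol + consumed products)
    c_out: float  # mmol C/gCDW/h leaving (products + biomass), pre-compensation
    closure: float  # c_out / c_in before CO2 compensation
    co2_compensation: float  # mmol/gCDW/h; > 0 CO2 produced, < 0 net uptake


def specific_rates(
    tc: TimeCourse,
    interval: tuple[float, float],
    molecular_weights: Mapping[str, float] | None = None,
    biomass_mean: str = "arithmetic",
) -> SpecificRates:
    """Interval specific rates q_i = 1000 dC_i / (MW_i dt Xbar).

    Xbar is the arithmetic mean of the endpoint biomass (log-mean available
    via ``biomass_mean="log"``); growth rate is dX / (dt Xbar).
    """
    mw = dict(MOLECULAR_WEIGHTS if molecular_weights is None else molecular_weights)
    t = np.asarray(tc.times, float)
    t1, t2 = interval
    idx = {}
    for name, tv in (("start", t1), ("end", t2)):
        hits = np.nonzero(np.isclose(t, tv))[0]
        if len(hits) == 0:
            raise ValueError(f"interval {name} {tv} h is not a sampled time")
        idx[name] = int(hits[0])
    i1, i2 = idx["start"], idx["end"]
    if i2 <= i1:
        raise ValueError("interval must run forward in time")
    x1, x2 = float(tc.biomass[i1]), float(tc.biomass[i2])
    if x1 <= 0 or x2 <= 0:
        raise ValueError("biomass must be positive on the interval")
    if biomass_mean == "arithmetic":
        xbar = 0.5 * (x1 + x2)
    elif biomass_mean == "log":
        xbar = (x2 - x1) / math.log(x2 / x1) if x2 != x1 else x1
    else:
        raise ValueError(f"unknown biomass_mean {biomass_mean!r}")
    dt = float(t2 - t1)
    rates = {}
    for sp, series in tc.concentrations.items():
        if sp not in mw:
            raise KeyError(f"no molecular weight for species {sp!r}")
        dC = float(series[i2]) - float(series[i1])
        rates[sp] = 1000.0 * dC / (mw[sp] * dt * xbar)
    mu = (x2 - x1) / (dt * xbar)
    return SpecificRates(rates=rates, growth_rate=mu, interval=(t1, t2))


def normalize_to_glycerol(rates: SpecificRates, target: float = -20.0) -> SpecificRates:
    """Scale all rates (incl. growth) so the glycerol flux equals ``target``.

    Ratios between rates are preserved exactly; the glycerol entry becomes
    ``target`` with no rounding residue.
    """
    q_gly = rates.rates.get("glycerol")
    if q_gly is None:
        raise KeyError("rates carry no 'glycerol' entry")
    if q_gly == 0:
        raise ValueError("cannot normalize: glycerol rate is zero")
    scale = abs(target) / abs(q_gly)
    new = {sp: q * scale for sp, q in rates.rates.items()}
    new["glycerol"] = float(target)
    return replace(rates, rates=new, growth_rate=rates.growth_rate * scale)


def biomass_carbon(model: StoichModel, biomass_id: str | None = None) -> float:
    """mmol C per gCDW implied by the model's biomass stoichiometry.

    Net carbon drained per unit biomass flux: carbon consumed minus carbon
    returned (e.g. the core biomass reaction releases some 2-oxoglutarate and
    CoA).  Exactly one biomass reaction must exist unless ``biomass_id`` says
    which.
    """
    if biomass_id is None:
        cands = [r for r in model.reactions if r.upper().startswith("BIOMASS")]
        if len(cands) != 1:
            raise ValueError(
                f"expected exactly one biomass reaction, found {cands or 'none'}"
            )
        biomass_id = cands[0]
    elif biomass_id not in model.reactions:
        raise KeyError(f"unknown biomass reaction {biomass_id!r}")
    rxn = model.reactions[biomass_id]
    net = 0.0
    for mid, coef in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        net -= coef * met.carbon()  # consumed (coef<0) counts positive
    return net


def carbon_closure(
    fluxes: Mapping[str, float],
    biomass_c: float,
    species_carbon: Mapping[str, int] = SPECIES_CARBON,
) -> CarbonBalance:
    """Carbon in/out, closure ratio and the compensating CO2 flux.

    ``fluxes`` holds the normalized exchange rates plus ``biomass`` (growth,
    1/h).  Negative product fluxes (consumption) count on the inflow side.
    Adding the compensation to the outflow restores balance to 1.0 exactly.
    """
    required = set(species_carbon) | {"biomass"}
    missing = sorted(required - set(fluxes))
    if missing:
        raise KeyError(f"missing species in flux map: {missing}")
    q_gly = fluxes["glycerol"]
    if q_gly >= 0:
        raise ValueError("glycerol flux must be negative (uptake)")
    c_in = species_carbon["glycerol"] * abs(q_gly)
    c_out = biomass_c * fluxes["biomass"]
    for sp, natoms in species_carbon.items():
        if sp == "glycerol":
            continue
        q = fluxes[sp]
        if q >= 0:
            c_out += natoms * q
        else:
            c_in += natoms * abs(q)
    closure = c_out / c_in
    return CarbonBalance(
        c_in=c_in, c_out=c_out, closure=closure, co2_compensation=c_in - c_out
    )


def build_scenario(
    model: StoichModel,
    scenario: ScenarioConstraints,
    fix_o2: float | None = None,
    biomass_c: float | None = None,
) -> StoichModel:
    """Fix the scenario's exchange and biomass fluxes on a copy of the model.

    The CO2 exchange is pinned to the carbon-closure compensation computed
    from the model's own biomass carbon, so the carbon books close exactly
    through the stoichiometry.  O2 is left free for uptake by default — the
    reported O2 exchange is a model prediction, since dissolved oxygen was a
    controlled setpoint rather than a measured rate — or fixed via ``fix_o2``.
    """
    out = model.copy()
    bc = biomass_carbon(model) if biomass_c is None else biomass_c
    balance = carbon_closure(scenario.fixed_fluxes, bc)
    targets = dict(scenario.fixed_fluxes)
    targets["co2"] = balance.co2_compensation
    for key, value in targets.items():
        rid = EXCHANGE_IDS.get(key, key)
        if rid not in out.reactions:
            raise KeyError(f"scenario references unresolvable reaction {rid!r}")
        out = out.with_bounds(rid, value, value)
    o2_id = EXCHANGE_IDS["o2"]
    if fix_o2 is None:
        out = out.with_bounds(o2_id, -1000.0, 1000.0)
    else:
        out = out.with_bounds(o2_id, fix_o2, fix_o2)
    return out


#: Published scenario constraint columns: five strain/grade/scale conditions,
#: all normalized to a glycerol uptake of -20 mmol/gCDW/h.
_TABLE1 = (
    ("M4-iclR", "pure", "flask",
     {"glycerol": -20.0, "malate": -0.11, "biomass": 0.48,
      "acetate": 1.49, "succinate": 3.10}),
    ("M4-iclR/pck", "pure", "flask",
     {"glycerol": -20.0, "malate": 5.45, "biomass": 0.26,
      "acetate": 6.38, "succinate": 2.14}),
    ("M4-iclR/pck-glpK", "pure", "flask",
     {"glycerol": -20.0, "malate": 5.78, "biomass": 0.25,
      "acetate": 3.26, "succinate": 1.39}),
    ("M4-iclR/pck-glpK", "crude", "flask",
     {"glycerol": -20.0, "malate": 10.10, "biomass": 0.16,
      "acetate": 1.76, "succinate": 0.01}),
    ("M4-iclR/pck-glpK", "crude", "bioreactor",
     {"glycerol": -20.0, "malate": 12.79, "biomass": 0.15,
      "acetate": 2.29, "succinate": 0.21}),
)


def builtin_table1_scenarios() -> list[ScenarioConstraints]:
    """The five published measurement scenarios (normalized fluxes)."""
    return [
        ScenarioConstraints(label, grade, scale, dict(fluxes))
        for label, grade, scale, fluxes in _TABLE1
    ]
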