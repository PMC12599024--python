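"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* :func:`gen_fermentation` — batch glycerol fermentation time-courses with
  logistic biomass, yield-coupled glycerol consumption and Luedeking-Piret
  product formation, plus additive Gaussian observation noise.  The presets
  emulate the published flask and bioreactor runs (about 12.5 g/L glycerol
  consumed within 24-72 h, L-malate accumulating to roughly 9-11 g/L).
* :func:`gen_doe_responses` — factorial-screening response vectors from a
  planted linear model in the coded factors plus Gaussian noise.
* :func:`toy_network` — small hand-built stoichiometric models with known
  analytic optima, used as LP fixtures.

Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .doe_screen import FactorialDesign
from .ferm_quant import MOLECULAR_WEIGHTS
from .rate_constraints import TimeCourse
from .stoich_model import Metabolite, Reaction, StoichModel

__all__ = [
    "FermentationParams",
    "PRESETS",
    "gen_fermentation",
    "gen_doe_responses",
    "toy_network",
]

# carbon mass fraction of each species, from the molecular formulas
_C_MASS_FRAC = {
    "glycerol": 3 * 12.011 / MOLECULAR_WEIGHTS["glycerol"],
    "malate": 4 * 12.011 / MOLECULAR_WEIGHTS["malate"],
    "succinate": 4 * 12.011 / MOLECULAR_WEIGHTS["succinate"],
    "acetate": 2 * 12.011 / MOLECULAR_WEIGHTS["acetate"],
}
_BIOMASS_C_FRAC = 0.48  # g C per g CDW, standard cell composition


@dataclass(frozen=True)
class FermentationParams:
    """Curve parameters for one batch fermentation.

    Biomass follows the logistic X(t) = K X0 e^(mu t) / (K + X0 (e^(mu t)-1)).
    Products follow Luedeking-Piret kinetics dP_i/dt = Y_i (alpha dX/dt +
    beta X): a growth-associated and a non-growth-associated term, scaled by
    the product yield Y_i (g product per g glycerol routed to products).
    Glycerol supplies growth (1/Y_xs dX/dt) plus the product stream
    (alpha dX/dt + beta X) and is floored at zero.
    """

    initial_glycerol: float = 12.5  # g/L
    initial_biomass: float = 0.363  # g CDW/L (OD570 1.1 inoculum)
    carrying_capacity: float = 1.1  # g CDW/L
    growth_rate: float = 0.25  # 1/h
    biomass_yield: float = 0.30  # g CDW per g glycerol routed to growth
    yields: Mapping[str, float] = field(
        default_factory=lambda: {"malate": 0.80, "succinate": 0.02, "acetate": 0.10}
    )
    alpha: float = 1.0  # growth-associated product split (g/g CDW)
    beta: float = 0.28  # non-growth-associated split (g/g CDW/h)
    noise_sd: float = 0.0  # g/L additive Gaussian observation noise
    times: Sequence[float] = (0.0, 6.0, 24.0, 48.0, 72.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(y < 0 for y in self.yields.values()):
            raise ValueError("yields must be >= 0")
        prod_c = sum(
            y * _C_MASS_FRAC[sp] for sp, y in self.yields.items()
        )
        if prod_c > _C_MASS_FRAC["glycerol"] + 1e-12:
            raise ValueError(
                f"infeasible yields: product carbon {prod_c:.3f} g C per g "
                f"glycerol exceeds the glycerol carbon content "
                f"{_C_MASS_FRAC['glycerol']:.3f}"
            )
        if self.biomass_yield * _BIOMASS_C_FRAC > _C_MASS_FRAC["glycerol"] + 1e-12:
            raise ValueError("infeasible biomass yield on a carbon basis")


#: Named presets for the published culture conditions.  The flask preset
#: starts at the OD570 0.1 inoculum; the bioreactor presets at OD570 1.1.
PRESETS: dict[str, FermentationParams] = {
    "flask_pure": FermentationParams(
        initial_glycerol=12.5, initial_biomass=0.033, carrying_capacity=0.9,
        growth_rate=0.30, yields={"malate": 0.72, "succinate": 0.11, "acetate": 0.12},
        beta=0.30, noise_sd=0.25,
    ),
    "bioreactor_pure": FermentationParams(
        initial_glycerol=12.5, initial_biomass=0.363, carrying_capacity=1.1,
        growth_rate=0.25, yields={"malate": 0.75, "succinate": 0.10, "acetate": 0.12},
        noise_sd=0.25,
    ),
    "bioreactor_crude": FermentationParams(
        initial_glycerol=12.5, initial_biomass=0.363, carrying_capacity=1.1,
        growth_rate=0.25, yields={"malate": 0.80, "succinate": 0.02, "acetate": 0.10},
        noise_sd=0.25,
    ),
}


def _logistic_biomass(p: FermentationParams, t: np.ndarray) -> np.ndarray:
    x0, k, mu = p.initial_biomass, p.carrying_capacity, p.growth_rate
    e = np.exp(mu * t)
    return k * x0 * e / (k + x0 * (e - 1.0))


def _integral_biomass(p: FermentationParams, t: np.ndarray) -> np.ndarray:
    """Closed form of the logistic integral int_0^t X ds."""
    x0, k, mu = p.initial_biomass, p.carrying_capacity, p.growth_rate
    return (k / mu) * np.log((k + x0 * (np.exp(mu * t) - 1.0)) / k)


def gen_fermentation(params: FermentationParams) -> TimeCourse:
    """Generate one noisy batch time-course from closed-form kinetics.

    With ``noise_sd = 0`` the curves are exact, so interval specific rates
    recomputed from the series reproduce the planted kinetics to numerical
    precision.  Glycerol is floored at zero and all activity stops once it is
    exhausted (concentrations are held at their exhaustion values).
    """
    t = np.asarray(params.times, float)
    X = _logistic_biomass(params, t)
    dX = X - X[0]
    intX = _integral_biomass(params, t)
    product_stream = params.alpha * dX + params.beta * intX  # g/L glycerol to products
    growth_stream = dX / params.biomass_yield
    consumed = growth_stream + product_stream

    # exhaustion: clip the consumption trajectory at the initial pool
    consumed = np.minimum(consumed, params.initial_glycerol)
    scale = np.where(
        (growth_stream + product_stream) > 0,
        consumed / np.maximum(growth_stream + product_stream, 1e-30),
        1.0,
    )
    product_stream = product_stream * scale
    glycerol = params.initial_glycerol - consumed
    conc = {"glycerol": glycerol}
    for sp, y in params.yields.items():
        conc[sp] = y * product_stream

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        for sp in conc:
            conc[sp] = np.maximum(
                conc[sp] + rng.normal(0.0, params.noise_sd, size=len(t)), 0.0
            )
    ph = 7.0 - 1.2 * (conc["malate"] / max(conc["malate"].max(), 1e-9))
    return TimeCourse(
        times=t.tolist(),
        biomass=X.tolist(),
        concentrations={sp: v.tolist() for sp, v in conc.items()},
        ph=ph.tolist(),
    )


def gen_doe_responses(
    design: FactorialDesign,
    coefficients: Mapping[str, float],
    sigma: float,
    seed: int,
    intercept: float = 0.5,
) -> np.ndarray:
    """Responses y = intercept + sum coeff x coded-contrast + N(0, sigma).

    ``coefficients`` are keyed by design term names (e.g. ``"biomass"``,
    ``"biomass:glycerol"``); unknown keys raise.  Center runs carry only the
    intercept plus noise, so center replicates estimate pure error.
    """
    terms = design.term_names()
    unknown = sorted(set(coefficients) - set(terms))
    if unknown:
        raise KeyError(f"unknown design term(s) {unknown}; valid: {terms}")
    names = [f.name for f in design.factors]
    col = {n: j for j, n in enumerate(names)}
    y = np.full(len(design.runs), float(intercept))
    for term, coef in coefficients.items():
        contrast = np.prod(
            [design.runs[:, col[n]] for n in term.split(":")], axis=0
        )
        y = y + coef * contrast
    rng = np.random.default_rng(seed)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(y))
    return y


def _toy(mets, rxns) -> StoichModel:
    return StoichModel(
        [Metabolite(m, compartment="c", formula={"C": 1}) for m in mets],
        [Reaction(rid, stoich, lower_bound=lb, upper_bound=ub,
                  objective_coefficient=obj)
         for rid, stoich, lb, ub, obj in rxns],
        model_id="toy",
    )


def toy_network(name: str) -> StoichModel:
    """Hand-built LP fixtures with documented analytic optima.

    ``chain``: EX_A (uptake <= 10) -> A -> B -> EX_B, maximize EX_B; optimum 10.
    ``diamond``: A -> B directly or via X in two steps; pFBA routes all flux
    through the one-step branch.
    ``futile_cycle``: chain plus a closed two-reaction loop; FBA optimum is
    unchanged by the loop and pFBA zeroes it.
    ``branched``: one substrate split to two sinks with different bounds.
    """
    if name == "chain":
        return _toy(
            ["A", "B"],
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, 0.0),
                ("A2B", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, 0.0),
                ("EX_B", {"B": -1.0}, 0.0, 1000.0, 1.0),
            ],
        )
    if name == "diamond":
        return _toy(
            ["A", "X", "B"],
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, 0.0),
                ("A2B", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, 0.0),
                ("A2X", {"A": -1.0, "X": 1.0}, 0.0, 1000.0, 0.0),
                ("X2B", {"X": -1.0, "B": 1.0}, 0.0, 1000.0, 0.0),
                ("EX_B", {"B": -1.0}, 0.0, 1000.0, 1.0),
            ],
        )
    if name == "futile_cycle":
        return _toy(
            ["A", "B", "C"],
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, 0.0),
                ("A2B", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, 0.0),
                ("B2C", {"B": -1.0, "C": 1.0}, 0.0, 1000.0, 0.0),
                ("C2B", {"C": -1.0, "B": 1.0}, 0.0, 1000.0, 0.0),
                ("EX_B", {"B": -1.0}, 0.0, 1000.0, 1.0),
            ],
        )
    if name == "branched":
        return _toy(
            ["A", "B", "C"],
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, 0.0),
                ("A2B", {"A": -1.0, "B": 1.0}, 0.0, 4.0, 0.0),
                ("A2C", {"A": -1.0, "C": 1.0}, 0.0, 1000.0, 0.0),
                ("EX_B", {"B": -1.0}, 0.0, 1000.0, 1.0),
                ("EX_C", {"C": -1.0}, 0.0, 1000.0, 0.5),
            ],
        )
    raise ValueError(
        f"unknown toy network {name!r}; options: chain, diamond, futile_cycle, branched"
    )
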