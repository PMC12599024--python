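"""Two-level full-factorial screening with center points.

The screening design used for the L-malate molar-yield optimization: a 2^k
factorial in coded levels {-1, +1} plus replicated center points (level 0).
Main and interaction effects come from the factorial contrasts,

    effect(term) = mean(y | contrast = +1) - mean(y | contrast = -1),

pure error s^2 from the center replicates (df = n_center - 1),
Var(effect) = 4 s^2 / N with N the number of factorial runs, and a term is
declared significant when |effect / SE| exceeds the two-sided 95% Student-t
critical value at the pure-error df — the vertical reference line of a
standardized-effects Pareto chart.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Factor",
    "FactorialDesign",
    "EffectEstimate",
    "DEFAULT_FACTORS",
    "build_design",
    "estimate_effects",
    "pareto_table",
]


@dataclass(frozen=True)
class Factor:
    name: str
    low: float
    center: float
    high: float

    def __post_init__(self):
        if not self.low < self.center < self.high:
            raise ValueError(
                f"factor {self.name!r}: need low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )


#: The screening factors of the study: inoculum biomass (OD570), dissolved
#: oxygen (% air saturation) and initial glycerol (g/L).
DEFAULT_FACTORS = (
    Factor("biomass", 0.10, 0.60, 1.10),
    Factor("DO", 20.0, 60.0, 100.0),
    Factor("glycerol", 9.0, 12.0, 15.0),
)


@dataclass(frozen=True)
class FactorialDesign:
    factors: tuple[Factor, ...]
    runs: np.ndarray  # (2^k + n_center, k) coded levels in {-1, 0, +1}
    n_center: int

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_factorial(self) -> int:
        return 2 ** self.k

    def factorial_rows(self) -> np.ndarray:
        return self.runs[np.all(self.runs != 0, axis=1)]

    def center_mask(self) -> np.ndarray:
        return np.all(self.runs == 0, axis=1)

    def actual_levels(self) -> pd.DataFrame:
        cols = {}
        for j, f in enumerate(self.factors):
            coded = self.runs[:, j]
            cols[f.name] = np.where(
                coded < 0, f.low, np.where(coded > 0, f.high, f.center)
            )
        return pd.DataFrame(cols)

    def term_names(self) -> list[str]:
        names = [f.name for f in self.factors]
        terms = []
        for order in range(1, self.k + 1):
            for combo in itertools.combinations(range(self.k), order):
                terms.append(":".join(names[j] for j in combo))
        return terms


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    effect: float  # response units: mean at +1 minus mean at -1
    standardized_effect: float  # effect / SE; nan when unavailable
    significant: bool
    rank: int  # Pareto position, 1 = largest |standardized effect|


def build_design(
    factors: Sequence[Factor] = DEFAULT_FACTORS,
    n_center: int = 3,
    seed: int | None = None,
) -> FactorialDesign:
    """Full 2^k coded matrix plus center replicates.

    ``seed`` randomizes the run order (the estimates are order-invariant;
    randomization matters only for physical execution).
    """
    factors = tuple(
        f if isinstance(f, Factor) else Factor(*f) for f in factors
    )
    k = len(factors)
    if k == 0:
        raise ValueError("need at least one factor")
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    centers = np.zeros((n_center, k))
    runs = np.vstack([corners, centers])
    if seed is not None:
        rng = np.random.default_rng(seed)
        runs = runs[rng.permutation(len(runs))]
    return FactorialDesign(factors=factors, runs=runs, n_center=n_center)


def estimate_effects(
    design: FactorialDesign, responses: Sequence[float]
) -> list[EffectEstimate]:
    """Main and interaction effects with center-point pure-error tests.

    With fewer than two center replicates the effects are still returned but
    standardization is unavailable (NaN, nothing significant).  The
    third-order (and higher) interactions are estimated and reported, not
    pooled into error.
    """
    y = np.asarray(responses, float)
    if len(y) != len(design.runs):
        raise ValueError(
            f"got {len(y)} responses for {len(design.runs)} runs"
        )
    fact_mask = np.all(design.runs != 0, axis=1)
    X = design.runs[fact_mask]
    yf = y[fact_mask]
    yc = y[design.center_mask()]
    N = len(yf)

    have_error = len(yc) >= 2
    if have_error:
        s2 = float(np.var(yc, ddof=1))
        df = len(yc) - 1
        se = math.sqrt(4.0 * s2 / N)
        tcrit = float(stats.t.ppf(0.975, df))
    else:
        se = float("nan")
        tcrit = float("inf")

    estimates = []
    names = [f.name for f in design.factors]
    for order in range(1, design.k + 1):
        for combo in itertools.combinations(range(design.k), order):
            contrast = np.prod(X[:, list(combo)], axis=1)
            effect = float(yf[contrast > 0].mean() - yf[contrast < 0].mean())
            if have_error and se > 0:
                std = effect / se
            elif have_error and se == 0:
                std = math.copysign(math.inf, effect) if effect else 0.0
            else:
                std = float("nan")
            sig = have_error and abs(std) > tcrit
            estimates.append(
                EffectEstimate(
                    term=":".join(names[j] for j in combo),
                    effect=effect,
                    standardized_effect=std,
                    significant=bool(sig),
                    rank=0,
                )
            )
    return _rank(estimates)


def _rank(estimates: list[EffectEstimate]) -> list[EffectEstimate]:
    def key(e: EffectEstimate):
        mag = abs(e.standardized_effect)
        if math.isnan(mag):
            mag = abs(e.effect)
        return (-mag, e.term)  # ties broken stably by term name

    ordered = sorted(estimates, key=key)
    return [
        EffectEstimate(e.term, e.effect, e.standardized_effect, e.significant, i + 1)
        for i, e in enumerate(ordered)
    ]


def curvature(design: FactorialDesign, responses: Sequence[float]) -> float:
    """Center mean minus factorial mean (reported, not formally tested)."""
    y = np.asarray(responses, float)
    fact = np.all(design.runs != 0, axis=1)
    return float(y[~fact].mean() - y[fact].mean())


def pareto_table(
    effects: Sequence[EffectEstimate], df: int | None = None
) -> pd.DataFrame:
    """Effects ordered by |standardized effect| with the 95% threshold.

    The ``sign`` column keeps the direction (the chart colours negative vs
    positive bars); rows are sorted by Pareto rank.
    """
    rows = sorted(effects, key=lambda e: e.rank)
    tcrit = float(stats.t.ppf(0.975, df)) if df else float("nan")
    return pd.DataFrame(
        {
            "rank": [e.rank for e in rows],
            "term": [e.term for e in rows],
            "effect": [e.effect for e in rows],
            "standardized_effect": [e.standardized_effect for e in rows],
            "abs_standardized": [abs(e.standardized_effect) for e in rows],
            "sign": [
                "-" if e.effect < 0 else "+" if e.effect > 0 else "0" for e in rows
            ],
            "significant_95": [e.significant for e in rows],
            "critical_t": [tcrit] * len(rows),
        }
    )
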