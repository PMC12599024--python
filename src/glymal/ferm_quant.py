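"""Deterministic quantitation arithmetic for the fermentation study.

Unit conversions (optical density -> cell dry weight, photon flux ->
irradiance, mass -> molar concentration), consumption tables, H2 yields and
productivities, and headspace H2 quantification from pressure/volume/fraction
measurements under the ideal-gas law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ConversionConstants",
    "CONSTANTS",
    "MOLECULAR_WEIGHTS",
    "ConsumptionRow",
    "od_to_cdw",
    "photon_to_irradiance",
    "mass_to_molar",
    "consumption_table",
    "h2_yield_and_productivity",
    "headspace_h2",
]

MOLECULAR_WEIGHTS: dict[str, float] = {
    "glycerol": 92.09,
    "malate": 134.09,
    "succinate": 118.09,
    "acetate": 60.05,
}


@dataclass(frozen=True)
class ConversionConstants:
    """Physical constants and calibrations used throughout.

    ``od_to_cdw``: g CDW/L per OD570 unit for E. coli.
    ``photon_to_irradiance``: W m-2 per umol photons m-2 s-1 for a
    full-spectrum LED in the PAR range; the calibration is only valid in
    [0.20, 0.23].
    ``temperature``: default gas temperature, 303.15 K (30 C incubation).
    """

    od_to_cdw: float = 0.33
    photon_to_irradiance: float = 0.22
    photon_factor_range: tuple[float, float] = (0.20, 0.23)
    molecular_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(MOLECULAR_WEIGHTS)
    )
    gas_constant: float = 8.314  # J/(mol K)
    atmospheric_pressure: float = 101.325  # kPa
    temperature: float = 303.15  # K

    def __post_init__(self):
        if self.od_to_cdw <= 0 or self.gas_constant <= 0 or self.temperature <= 0:
            raise ValueError("conversion constants must be positive")
        lo, hi = self.photon_factor_range
        if not lo <= self.photon_to_irradiance <= hi:
            raise ValueError(
                f"photon factor {self.photon_to_irradiance} outside [{lo}, {hi}]"
            )


CONSTANTS = ConversionConstants()


def od_to_cdw(od: float, constants: ConversionConstants = CONSTANTS) -> float:
    """OD570 -> g CDW/L (1 OD570 = 0.33 g CDW/L for E. coli)."""
    if od < 0:
        raise ValueError(f"optical density must be non-negative, got {od}")
    return od * constants.od_to_cdw


def photon_to_irradiance(
    ppfd: float, factor: float | None = None,
    constants: ConversionConstants = CONSTANTS,
) -> float:
    """Photon flux (umol photons m-2 s-1) -> irradiance (W m-2)."""
    f = constants.photon_to_irradiance if factor is None else factor
    lo, hi = constants.photon_factor_range
    if not lo <= f <= hi:
        raise ValueError(f"photon conversion factor {f} outside the calibrated "
                         f"range [{lo}, {hi}]")
    return ppfd * f


def mass_to_molar(
    conc_g_per_l: float, species: str,
    constants: ConversionConstants = CONSTANTS,
) -> float:
    """g/L -> mM for a species in the molecular-weight table."""
    mw = constants.molecular_weights.get(species)
    if mw is None:
        raise KeyError(
            f"unknown species {species!r}; known: {sorted(constants.molecular_weights)}"
        )
    return conc_g_per_l / mw * 1000.0


@dataclass(frozen=True)
class ConsumptionRow:
    species: str
    initial_mm: float
    final_mm: float
    consumed_mm: float
    consumed_pct: float
    overshoot: bool = False  # final > initial (negative consumption), flagged


def consumption_table(
    initial: Mapping[str, float], final: Mapping[str, float]
) -> list[ConsumptionRow]:
    """Per-species consumed mM and %, plus a ``total`` row.

    ``final > initial`` is allowed (net production) but flagged via
    ``overshoot``.  The total row's % is total consumed / total initial.
    """
    if set(initial) != set(final):
        raise ValueError(
            f"species sets differ: {sorted(set(initial) ^ set(final))}"
        )
    rows = []
    for sp in initial:
        c = initial[sp] - final[sp]
        pct = 100.0 * c / initial[sp] if initial[sp] else 0.0
        rows.append(ConsumptionRow(sp, initial[sp], final[sp], c, pct, overshoot=c < 0))
    tot_i = sum(initial.values())
    tot_f = sum(final.values())
    tot_c = tot_i - tot_f
    rows.append(
        ConsumptionRow(
            "total", tot_i, tot_f, tot_c,
            100.0 * tot_c / tot_i if tot_i else 0.0,
            overshoot=tot_c < 0,
        )
    )
    return rows


def h2_yield_and_productivity(
    h2_mmol_per_l: float,
    consumed_mmol_per_l: float,
    time_h: float,
    cdw_g_per_l: float,
) -> tuple[float, float, float]:
    """(mol H2 / mol substrate consumed, mmol/L/h, mmol/gCDW/h).

    The substrate denominator is the total C2-C4 carbon-source consumption
    (L-malate, succinate, acetate and glycerol).
    """
    if consumed_mmol_per_l <= 0 or time_h <= 0 or cdw_g_per_l <= 0:
        raise ValueError("consumed, time and cdw must all be positive")
    return (
        h2_mmol_per_l / consumed_mmol_per_l,
        h2_mmol_per_l / time_h,
        h2_mmol_per_l / (time_h * cdw_g_per_l),
    )


def headspace_h2(
    pressure_kpa: float,
    headspace_volume_ml: float,
    h2_fraction: float,
    temperature_k: float | None = None,
    constants: ConversionConstants = CONSTANTS,
) -> tuple[float, float]:
    """Headspace overpressure -> (gas volume at P', mmol H2).

    The measured absolute pressure P in the sealed vial of headspace volume V
    is converted isothermally to the volume V' = P V / P' the gas would occupy
    at atmospheric pressure P', and the H2 amount follows from the ideal-gas
    law n = P' V' f / (R T).  Water-vapour correction is omitted.
    """
    if pressure_kpa <= 0 or headspace_volume_ml <= 0:
        raise ValueError("pressure and headspace volume must be positive")
    if not 0.0 <= h2_fraction <= 1.0:
        raise ValueError(f"H2 fraction {h2_fraction} outside [0, 1]")
    T = constants.temperature if temperature_k is None else temperature_k
    v_prime_ml = pressure_kpa * headspace_volume_ml / constants.atmospheric_pressure
    # kPa * mL = 1e-6 kJ = 1e-3 J; n [mol] = P'V'/(RT); report mmol
    n_mmol = (
        constants.atmospheric_pressure * v_prime_ml * h2_fraction
        / (constants.gas_constant * T)
    )
    return v_prime_ml, n_mmol
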