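"""The aquatic-risk score: measure of effect x measure of mobility and persistence.

* Measure of effect = maximum application rate (umol AI/ha) divided by the
  threshold expressed in umol/ML; the megalitres of water per hectare needed
  to dilute the applied dose down to the threshold.
* Proportion transported in runoff is predicted from K_OC by the linear model
  percent = -10.076 log10(K_OC) + 39.123, divided by 100 and clamped to
  [floor, 1] (default floor 0; the line goes negative above log K_OC 3.883).
* Measure of mobility and persistence = soil DT50 x water DT50 x proportion
  transported (days^2 x proportion).
* Aquatic risk = effect x mobility-and-persistence; the reference table
  prints risk / 100, and both scales are always carried.

The score is a unitless ranking quantity: it orders active ingredients by the
likelihood of reaching a waterway and causing harm, and is not a predicted
environmental concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .etv_derivation import EtvRecord
from .registry import PAIRecord, PAITable, ai_mass_rate, mass_to_molar_rate

RUNOFF_SLOPE = -10.076     # percent transported per log10(K_OC) unit
RUNOFF_INTERCEPT = 39.123  # percent transported at K_OC = 1 L/kg


# ---------------------------------------------------------------------------
# domain types

@dataclass
class SprayRegime:
    """How much of the field is treated; scales the effective rate per ha."""

    mode: Literal["broadcast", "band", "spot"] = "broadcast"
    treated_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("broadcast", "band", "spot"):
            raise ValidationError(f"unknown spray mode {self.mode!r}")
        if not 0 < self.treated_fraction <= 1:
            raise ValidationError(
                f"treated_fraction must be in (0, 1], got {self.treated_fraction}")
        if self.mode == "broadcast" and self.treated_fraction != 1.0:
            raise ValidationError("broadcast spraying treats the whole field")


BROADCAST = SprayRegime()


@dataclass
class RiskResult:
    """Risk components for one formulation."""

    pai_name: str
    effect: float                   # ML/ha
    mobility_persistence: float     # days^2 x proportion
    aquatic_risk: float = field(init=False)
    aquatic_risk_reported: float = field(init=False)

    def __post_init__(self) -> None:
        if self.effect < 0 or self.mobility_persistence < 0:
            raise ValidationError("risk components must be >= 0")
        self.aquatic_risk = self.effect * self.mobility_persistence
        self.aquatic_risk_reported = self.aquatic_risk / 100.0


@dataclass
class TankMix:
    """Several formulations applied together in one spray application."""

    components: list[tuple[str, RiskResult]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("a tank mix needs at least one component")


# ---------------------------------------------------------------------------
# the three equations

def proportion_transported(koc: float, floor: float = 0.0) -> float:
    """Proportion of applied PAI lost to runoff, predicted from K_OC.

    Strictly decreasing in K_OC until the line hits the floor
    (log10 K_OC ~ 3.883 for floor 0).
    """
    if not koc > 0:
        raise ValidationError(f"koc must be > 0, got {koc}")
    if not 0 <= floor <= 1:
        raise ValidationError(f"floor must be in [0, 1], got {floor}")
    percent = RUNOFF_SLOPE * math.log10(koc) + RUNOFF_INTERCEPT
    return min(max(percent / 100.0, floor), 1.0)


def measure_of_effect(app_rate_umol_ha: float, etv_umol_L: float) -> float:
    """Application rate over the threshold in umol/ML (= umol/L x 1e6)."""
    if app_rate_umol_ha < 0:
        raise ValidationError(f"application rate must be >= 0, got {app_rate_umol_ha}")
    if not etv_umol_L > 0:
        raise ValidationError(f"threshold must be > 0, got {etv_umol_L}")
    return app_rate_umol_ha / (etv_umol_L * 1e6)


def measure_of_mobility_persistence(dt50_soil: float, dt50_water: float,
                                    proportion: float) -> float:
    """Soil half-life x water half-life x proportion transported."""
    if dt50_soil < 0 or dt50_water < 0:
        raise ValidationError("half-lives must be >= 0")
    if not 0 <= proportion <= 1:
        raise ValidationError(f"proportion must be in [0, 1], got {proportion}")
    return dt50_soil * dt50_water * proportion


def aquatic_risk(effect: float, mobility_persistence: float) -> tuple[float, float]:
    """(risk, reported) where reported = risk / 100 (the printed scale)."""
    if effect < 0 or mobility_persistence < 0:
        raise ValidationError("risk components must be >= 0")
    risk = effect * mobility_persistence
    return risk, risk / 100.0


def apply_regime(app_rate_umol_ha: float, regime: SprayRegime) -> float:
    """Scale the per-hectare rate by the treated fraction of the field."""
    return app_rate_umol_ha * regime.treated_fraction


# ---------------------------------------------------------------------------
# table-level pipeline

def risk_for_record(record: PAIRecord, rate, etv: EtvRecord,
                    which: str = "max",
                    regime: SprayRegime = BROADCAST,
                    floor: float = 0.0) -> RiskResult:
    """Full per-formulation pipeline from label rate and properties to risk."""
    mass = ai_mass_rate(rate, which)
    umol = apply_regime(mass_to_molar_rate(mass, record.molar_mass), regime)
    effect = measure_of_effect(umol, etv.limit)
    if record.mobility_given is not None:
        mobility = record.mobility_given
    else:
        mobility = measure_of_mobility_persistence(
            record.dt50_soil, record.dt50_water,
            proportion_transported(record.koc, floor))
    return RiskResult(pai_name=rate.formulation, effect=effect,
                      mobility_persistence=mobility)


def risk_results(table: PAITable, which: str = "max",
                 regime: SprayRegime = BROADCAST,
                 floor: float = 0.0) -> list[RiskResult]:
    """One :class:`RiskResult` per formulation (rate entry) in the table."""
    return [risk_for_record(table.record(rate.pai_name), rate,
                            table.etv(rate.pai_name), which, regime, floor)
            for rate in table.rates]


def compute_risk_table(table: PAITable, which: str = "max",
                       regime: SprayRegime = BROADCAST,
                       floor: float = 0.0) -> pd.DataFrame:
    """Risk table as a DataFrame, one row per formulation, ranked by risk."""
    rows = []
    for rate in table.rates:
        record = table.record(rate.pai_name)
        etv = table.etv(rate.pai_name)
        res = risk_for_record(record, rate, etv, which, regime, floor)
        mass = ai_mass_rate(rate, which) * regime.treated_fraction
        rows.append({
            "name": rate.formulation,
            "pesticide_class": record.pesticide_class,
            "app_rate_kg_ai_ha": mass,
            "app_rate_umol_ha": mass_to_molar_rate(mass, record.molar_mass),
            "etv_umol_L": etv.limit,
            "effect": res.effect,
            "mobility_persistence": res.mobility_persistence,
            "aquatic_risk": res.aquatic_risk,
            "aquatic_risk_reported": res.aquatic_risk_reported,
        })
    df = pd.DataFrame(rows)
    df["rank_by_risk"] = rankdata(-df["aquatic_risk"], method="average")
    return df


def tank_mix_risk(mix: TankMix) -> float:
    """Sum of component aquatic risks — an indicative (not definitive) total,
    since joint toxicity of the mixture is not modelled."""
    return float(sum(res.aquatic_risk for _, res in mix.components))


# ---------------------------------------------------------------------------
# ranking and comparison

_RANK_KEYS = {"effect": lambda r: r.effect,
              "mobility": lambda r: r.mobility_persistence,
              "risk": lambda r: r.aquatic_risk}


def rank_pais(results: Sequence[RiskResult],
              key: Literal["effect", "mobility", "risk"] = "risk") -> dict[str, float]:
    """Descending ranks (1 = largest) with ties sharing the average rank."""
    if not results:
        raise ValidationError("cannot rank an empty result set")
    try:
        getter = _RANK_KEYS[key]
    except KeyError:
        raise ValidationError(f"key must be one of {sorted(_RANK_KEYS)}") from None
    values = np.asarray([getter(r) for r in results], dtype=float)
    ranks = rankdata(-values, method="average")
    return {r.pai_name: float(rank) for r, rank in zip(results, ranks)}


def compare_pais(a: RiskResult, b: RiskResult) -> str:
    """Dominance on the (effect, mobility) plane; risk breaks trade-offs.

    ``a_dominates`` means a is at or below b on both axes (one strictly), i.e.
    a poses the lower risk outright; otherwise the product decides.
    """
    a_le = a.effect <= b.effect and a.mobility_persistence <= b.mobility_persistence
    b_le = b.effect <= a.effect and b.mobility_persistence <= a.mobility_persistence
    if a_le and not b_le:
        return "a_dominates"
    if b_le and not a_le:
        return "b_dominates"
    return "tradeoff_use_risk"


def preferred(a: RiskResult, b: RiskResult) -> str:
    """Name of the lower-risk component under :func:`compare_pais` semantics."""
    verdict = compare_pais(a, b)
    if verdict == "a_dominates":
        return a.pai_name
    if verdict == "b_dominates":
        return b.pai_name
    return a.pai_name if a.aquatic_risk <= b.aquatic_risk else b.pai_name


# ---------------------------------------------------------------------------
# display helpers

def round_sig(x: float, sig_figs: int) -> float:
    """Round to significant figures (round-half-even, as numpy does)."""
    if sig_figs < 1:
        raise ValidationError(f"sig_figs must be >= 1, got {sig_figs}")
    if x == 0 or not np.isfinite(x):
        return float(x)
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - sig_figs + 1)
    return float(np.round(x / factor) * factor)


def fold_variation(values: Iterable[float], sig_figs: int = 2) -> float:
    """max/min of a positive set, rounded to significant figures."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("fold_variation needs at least one value")
    if np.any(vals <= 0):
        raise ValidationError("all values must be > 0")
    return round_sig(float(vals.max() / vals.min()), sig_figs)
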