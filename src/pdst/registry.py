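"""Data model for pesticide active ingredients (PAIs) and their CSV I/O.

A :class:`PAITable` bundles three tables that together drive the risk engine:

* physicochemical properties per PAI (molar mass, K_OC, log K_OW, pK_a,
  soil and water DT50),
* label application rates per product formulation (a PAI may appear under
  more than one formulation, e.g. liquid and slow-release imidacloprid),
* one ecotoxicity threshold (DGV or ETV, in umol/L) per PAI.

The bundled reference dataset reconstructs the published 47-PAI / 48-
formulation sugar-cane table: thresholds are taken verbatim from the published
threshold table, while application rates and water half-lives are
back-computed so that the risk engine reproduces the published measure-of-
effect and measure-of-mobility-and-persistence columns.  They are
reconstructions consistent with the published measures, not label-verbatim
values.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    IntegrityError,
    NameLookupError,
    SchemaError,
    ValidationError,
)
from .etv_derivation import EtvRecord

PESTICIDE_CLASSES = frozenset({"herbicide", "insecticide", "fungicide", "nematicide"})
RATE_UNITS = frozenset({"kg_per_ha", "L_per_ha"})

_PROPERTIES_COLUMNS = [
    "name", "pesticide_class", "chemical_class", "molar_mass_g_mol",
    "koc_exp_L_kg", "koc_model_L_kg", "log_kow", "pka",
    "dt50_soil_days", "dt50_water_days",
]
_RATES_COLUMNS = [
    "name", "product_name", "rate_units", "product_rate_min",
    "product_rate_max", "ai_fraction", "product_density_kg_L",
    "slow_release_interval_years",
]
_ETV_COLUMNS = [
    "name", "limit_umol_L", "limit_type", "method", "percentile", "reliability",
]


@dataclass
class PAIRecord:
    """One active ingredient with its identity and fate properties.

    ``koc_experimental`` and ``koc_modelled`` are both retained; the resolved
    :attr:`koc` prefers the experimental value when available.
    ``mobility_given`` optionally pins the mobility-and-persistence measure to
    a published value for strongly sorbed compounds whose runoff proportion
    clamps to the floor (the reference table prints "approximately 0.01" for
    log K_OC > 4 PAIs).
    """

    name: str
    pesticide_class: str
    chemical_class: str
    molar_mass: float          # g/mol
    koc_experimental: float | None  # L/kg
    koc_modelled: float | None      # L/kg
    log_kow: float
    pka: float | None
    dt50_soil: float           # days
    dt50_water: float          # days
    mobility_given: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("PAI name must be non-empty")
        if self.pesticide_class not in PESTICIDE_CLASSES:
            raise ValidationError(
                f"{self.name}: pesticide_class {self.pesticide_class!r} not one of "
                f"{sorted(PESTICIDE_CLASSES)}")
        for label, value in (("molar_mass", self.molar_mass),
                             ("dt50_soil", self.dt50_soil),
                             ("dt50_water", self.dt50_water)):
            if not (value is not None and np.isfinite(value) and value > 0):
                raise ValidationError(f"{self.name}: {label} must be > 0, got {value!r}")
        if self.koc_experimental is None and self.koc_modelled is None:
            raise ValidationError(f"{self.name}: at least one K_OC value is required")
        for label, value in (("koc_experimental", self.koc_experimental),
                             ("koc_modelled", self.koc_modelled),
                             ("mobility_given", self.mobility_given)):
            if value is not None and not value > 0:
                raise ValidationError(f"{self.name}: {label} must be > 0, got {value!r}")

    @property
    def koc(self) -> float:
        """Resolved K_OC (L/kg); experimental preferred over modelled."""
        if self.koc_experimental is not None:
            return self.koc_experimental
        return self.koc_modelled

    @property
    def koc_source(self) -> Literal["experimental", "modelled"]:
        return "experimental" if self.koc_experimental is not None else "modelled"


@dataclass
class ApplicationRate:
    """A label application-rate range for one product formulation."""

    pai_name: str
    product_name: str
    rate_units: str            # kg_per_ha | L_per_ha
    product_rate_min: float    # kg or L product per ha
    product_rate_max: float
    ai_fraction: float         # (0, 1]
    product_density: float | None = None   # kg/L, required for L_per_ha
    slow_release_interval: float | None = None   # years

    def __post_init__(self) -> None:
        if self.rate_units not in RATE_UNITS:
            raise ValidationError(
                f"{self.pai_name}: rate_units {self.rate_units!r} not one of "
                f"{sorted(RATE_UNITS)}")
        if not 0 < self.ai_fraction <= 1:
            raise ValidationError(
                f"{self.pai_name}: ai_fraction must be in (0, 1], got {self.ai_fraction}")
        if self.product_rate_min < 0 or self.product_rate_max <= 0:
            raise ValidationError(f"{self.pai_name}: product rates must be positive")
        if self.product_rate_min > self.product_rate_max:
            raise ValidationError(
                f"{self.pai_name}: product_rate_min {self.product_rate_min} exceeds "
                f"product_rate_max {self.product_rate_max}")
        if self.product_density is not None and not self.product_density > 0:
            raise ValidationError(f"{self.pai_name}: product_density must be > 0")
        if self.slow_release_interval is not None and self.slow_release_interval < 1:
            raise ValidationError(
                f"{self.pai_name}: slow_release_interval must be >= 1 year")

    @property
    def formulation(self) -> str:
        return self.product_name or self.pai_name


@dataclass
class PAITable:
    """Validated container tying properties, rates and thresholds together."""

    records: list[PAIRecord]
    rates: list[ApplicationRate]
    etvs: list[EtvRecord]
    _by_name: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise IntegrityError(f"duplicate PAI names: {sorted(dupes)}")
        self._by_name = {r.name: r for r in self.records}
        if not self.rates:
            raise IntegrityError("no application rates: every PAI needs at least one")
        for rate in self.rates:
            if rate.pai_name not in self._by_name:
                raise IntegrityError(
                    f"application rate references unknown PAI {rate.pai_name!r}")
        forms = [r.formulation for r in self.rates]
        dupes = {f for f in forms if forms.count(f) > 1}
        if dupes:
            raise IntegrityError(f"duplicate formulations: {sorted(dupes)}")
        etv_names = [e.pai_name for e in self.etvs]
        dupes = {n for n in etv_names if etv_names.count(n) > 1}
        if dupes:
            raise IntegrityError(f"more than one threshold for: {sorted(dupes)}")
        for etv in self.etvs:
            if etv.pai_name not in self._by_name:
                raise IntegrityError(
                    f"threshold references unknown PAI {etv.pai_name!r}")
        self._etv_by_name = {e.pai_name: e for e in self.etvs}

    def record(self, name: str) -> PAIRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise NameLookupError(name, self.suggest(name)) from None

    def etv(self, name: str) -> EtvRecord:
        try:
            return self._etv_by_name[name]
        except KeyError:
            raise NameLookupError(name, self.suggest(name)) from None

    def rates_for(self, name: str) -> list[ApplicationRate]:
        found = [r for r in self.rates if r.pai_name == name]
        if not found:
            raise NameLookupError(name, self.suggest(name))
        return found

    def suggest(self, name: str, n: int = 3) -> tuple[str, ...]:
        import difflib
        pool = list(self._by_name) + [r.formulation for r in self.rates]
        return tuple(difflib.get_close_matches(name, pool, n=n, cutoff=0.6))

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]


# ---------------------------------------------------------------------------
# unit conversions

def ai_mass_rate(rate: ApplicationRate,
                 which: Literal["min", "max", "mean"] = "max") -> float:
    """Active-ingredient mass application rate in kg AI/ha (annualised).

    Product rate x AI fraction (x density for volumetric labels); slow-release
    formulations are divided by their release interval in years to give an
    annual-equivalent rate.
    """
    if which == "min":
        product = rate.product_rate_min
    elif which == "max":
        product = rate.product_rate_max
    elif which == "mean":
        product = 0.5 * (rate.product_rate_min + rate.product_rate_max)
    else:
        raise ValidationError(f"which must be min|max|mean, got {which!r}")
    mass = product * rate.ai_fraction
    if rate.rate_units == "L_per_ha":
        if rate.product_density is None:
            raise ConfigurationError(
                f"{rate.pai_name}: volumetric rate needs product_density_kg_L")
        mass *= rate.product_density
    if rate.slow_release_interval is not None:
        mass /= rate.slow_release_interval
    return mass


def mass_to_molar_rate(mass_rate: float, molar_mass: float) -> float:
    """Convert kg AI/ha to umol AI/ha (kg -> ug -> umol via g/mol)."""
    if not molar_mass > 0:
        raise ValidationError(f"molar_mass must be > 0, got {molar_mass}")
    if mass_rate < 0:
        raise ValidationError(f"mass_rate must be >= 0, got {mass_rate}")
    return mass_rate * 1e9 / molar_mass


# ---------------------------------------------------------------------------
# CSV I/O

def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_pai_table(properties_path, rates_path, etv_path) -> PAITable:
    """Read and validate the three CSV tables into a :class:`PAITable`.

    Rows failing invariant checks are reported with their 1-based CSV row
    number; referential problems raise :class:`IntegrityError`.
    """
    try:
        props = pd.read_csv(properties_path)
        rates = pd.read_csv(rates_path)
        etvs = pd.read_csv(etv_path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"could not parse input CSV: {exc}") from exc
    _require_columns(props, _PROPERTIES_COLUMNS, properties_path)
    _require_columns(rates, _RATES_COLUMNS, rates_path)
    _require_columns(etvs, _ETV_COLUMNS, etv_path)

    problems: list[str] = []

    records = []
    for i, row in props.iterrows():
        try:
            records.append(PAIRecord(
                name=str(row["name"]),
                pesticide_class=str(row["pesticide_class"]),
                chemical_class=str(row["chemical_class"]),
                molar_mass=float(row["molar_mass_g_mol"]),
                koc_experimental=_opt(row["koc_exp_L_kg"]),
                koc_modelled=_opt(row["koc_model_L_kg"]),
                log_kow=float(row["log_kow"]),
                pka=_opt(row["pka"]),
                dt50_soil=float(row["dt50_soil_days"]),
                dt50_water=float(row["dt50_water_days"]),
                mobility_given=_opt(row.get("mobility_given")),
            ))
        except (ValidationError, ValueError) as exc:
            problems.append(f"{properties_path} row {i + 2}: {exc}")

    rate_records = []
    for i, row in rates.iterrows():
        try:
            rate_records.append(ApplicationRate(
                pai_name=str(row["name"]),
                product_name="" if pd.isna(row["product_name"]) else str(row["product_name"]),
                rate_units=str(row["rate_units"]),
                product_rate_min=float(row["product_rate_min"]),
                product_rate_max=float(row["product_rate_max"]),
                ai_fraction=float(row["ai_fraction"]),
                product_density=_opt(row["product_density_kg_L"]),
                slow_release_interval=_opt(row["slow_release_interval_years"]),
            ))
        except (ValidationError, ValueError) as exc:
            problems.append(f"{rates_path} row {i + 2}: {exc}")

    etv_records = []
    for i, row in etvs.iterrows():
        try:
            pct = row["percentile"]
            pct = None if (pd.isna(pct) or str(pct).upper() == "NA") else int(float(pct))
            etv_records.append(EtvRecord(
                pai_name=str(row["name"]),
                limit=float(row["limit_umol_L"]),
                limit_type=str(row["limit_type"]),
                method=str(row["method"]),
                percentile_used=pct,
                reliability=str(row["reliability"]),
            ))
        except (ValidationError, ValueError) as exc:
            problems.append(f"{etv_path} row {i + 2}: {exc}")

    if problems:
        raise ValidationError("input rows failed validation:\n  " + "\n  ".join(problems))
    return PAITable(records=records, rates=rate_records, etvs=etv_records)


def write_pai_table(table: PAITable, properties_path, rates_path, etv_path) -> None:
    """Write the three CSVs back out at full floating-point precision."""
    def fmt(v):
        return "" if v is None else repr(float(v))

    props = pd.DataFrame([{
        "name": r.name, "pesticide_class": r.pesticide_class,
        "chemical_class": r.chemical_class, "molar_mass_g_mol": fmt(r.molar_mass),
        "koc_exp_L_kg": fmt(r.koc_experimental), "koc_model_L_kg": fmt(r.koc_modelled),
        "log_kow": fmt(r.log_kow), "pka": fmt(r.pka),
        "dt50_soil_days": fmt(r.dt50_soil), "dt50_water_days": fmt(r.dt50_water),
        "mobility_given": fmt(r.mobility_given),
    } for r in table.records])
    rates = pd.DataFrame([{
        "name": r.pai_name, "product_name": r.product_name,
        "rate_units": r.rate_units, "product_rate_min": fmt(r.product_rate_min),
        "product_rate_max": fmt(r.product_rate_max), "ai_fraction": fmt(r.ai_fraction),
        "product_density_kg_L": fmt(r.product_density),
        "slow_release_interval_years": fmt(r.slow_release_interval),
    } for r in table.rates])
    etvs = pd.DataFrame([{
        "name": e.pai_name, "limit_umol_L": fmt(e.limit), "limit_type": e.limit_type,
        "method": e.method,
        "percentile": "NA" if e.percentile_used is None else e.percentile_used,
        "reliability": e.reliability,
    } for e in table.etvs])
    props.to_csv(properties_path, index=False)
    rates.to_csv(rates_path, index=False)
    etvs.to_csv(etv_path, index=False)


# ---------------------------------------------------------------------------
# bundled reference dataset

def _data_path(fname: str):
    return importlib.resources.files("pdst.data").joinpath(fname)


def load_reference_table() -> PAITable:
    """The bundled 47-PAI / 48-formulation reference dataset."""
    return load_pai_table(_data_path("pai_properties.csv"),
                          _data_path("application_rates.csv"),
                          _data_path("etv.csv"))


def load_reference_risk() -> pd.DataFrame:
    """Published per-formulation measures and risk (rounded as printed).

    Columns: formulation, name, mobility, effect, risk_reported (string as
    printed, empty when the published table prints "< 1"), risk_lt_one flag.
    """
    with importlib.resources.as_file(_data_path("reference_risk.csv")) as p:
        return pd.read_csv(p, dtype={"risk_reported": str})


# ---------------------------------------------------------------------------
# synthetic fixture generation

_SYNTH_CLASSES = ("herbicide", "insecticide", "fungicide", "nematicide")
_SYNTH_CLASS_P = (32 / 47, 9 / 47, 5 / 47, 1 / 47)


def generate_fixture_table(seed: int, n_pai: int) -> PAITable:
    """Deterministic synthetic :class:`PAITable` with documented ranges.

    Properties are drawn log-uniformly over ranges spanning the bundled
    dataset: K_OC 1-1e6 L/kg, DT50 0.1-1e4 d, thresholds 1e-7-10 umol/L,
    molar mass uniform 150-500 g/mol, AI mass rates log-uniform
    0.005-5 kg/ha.  Class frequencies mirror the bundled dataset.
    """
    if n_pai < 1:
        raise ValidationError("n_pai must be >= 1")
    rng = np.random.default_rng(seed)

    def logu(lo, hi, size=None):
        return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size)

    records, rates, etvs = [], [], []
    for i in range(n_pai):
        name = f"synthcide-{i:03d}"
        koc = logu(1.0, 1e6)
        exp_available = rng.random() < 0.66
        records.append(PAIRecord(
            name=name,
            pesticide_class=rng.choice(_SYNTH_CLASSES, p=_SYNTH_CLASS_P),
            chemical_class="synthetic",
            molar_mass=rng.uniform(150.0, 500.0),
            koc_experimental=koc if exp_available else None,
            koc_modelled=koc * 10 ** rng.normal(0.0, 0.3),
            log_kow=rng.uniform(-4.0, 7.0),
            pka=rng.uniform(1.0, 7.0) if rng.random() < 0.4 else None,
            dt50_soil=logu(0.1, 1e4),
            dt50_water=logu(0.1, 1e4),
        ))
        max_rate = logu(0.005, 5.0)
        ai_fraction = rng.uniform(0.1, 1.0)
        slow = 4.0 if rng.random() < 0.02 else None
        rates.append(ApplicationRate(
            pai_name=name, product_name=name, rate_units="kg_per_ha",
            product_rate_min=max_rate * rng.uniform(0.2, 1.0),
            product_rate_max=max_rate, ai_fraction=ai_fraction,
            product_density=None, slow_release_interval=slow,
        ))
        etvs.append(EtvRecord(
            pai_name=name, limit=logu(1e-7, 10.0), limit_type="ETV",
            method="SSD", percentile_used=95, reliability="moderate",
        ))
    return PAITable(records=records, rates=rates, etvs=etvs)
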