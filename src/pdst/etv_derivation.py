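"""Derivation of ecotoxicity threshold values (ETVs) from species toxicity data.

The preferred route fits a species sensitivity distribution (SSD) to one
chronic toxicity value per species and reads off a protective concentration
(PCp, the (100-p)th percentile): PC95 by default, PC99 for potential
biomagnifiers (log K_OW >= 4).  When fewer than five species spanning four
taxonomic groups are available, the assessment-factor (AF) method is used
instead: the single lowest value divided by a factor keyed to the endpoint
class of that value.  AF-derived thresholds carry no percentile and an
"unknown" reliability.

Distribution policy approximates the Burrlioz derivation software: a
two-parameter log-logistic for small datasets (n < 8 species) and the
three-parameter Burr III for larger ones, both fitted by maximum likelihood
(Nelder-Mead with multiple starts for Burr III), with a log-logistic fallback
when the Burr III optimiser fails.

Parameterisations:

* log-logistic(alpha, beta):  F(x) = 1 / (1 + (x/alpha)^-beta)
  (log x follows a logistic with location ln alpha and scale 1/beta)
* Burr III(b, c, k):          F(x) = (1 + (x/b)^-c)^-k
  (reduces to the log-logistic at k = 1)
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .errors import InsufficientDataError, ValidationError

ENDPOINT_CLASSES = ("chronic", "chronic_estimated", "converted_acute")
RELIABILITY_LEVELS = ("very_low", "low", "moderate", "high", "very_high", "unknown")
PROTECTION_LEVELS = (80, 90, 95, 99)

# minimum-data rule for the SSD route
MIN_SPECIES = 5
MIN_GROUPS = 4


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ToxicityRecord:
    """One screened toxicity result for one species."""

    pai_name: str
    species: str
    taxonomic_group: str
    phylum: str
    endpoint_class: str        # chronic | chronic_estimated | converted_acute
    value: float               # umol/L
    quality_accepted: bool = True

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("species must be non-empty")
        if self.endpoint_class not in ENDPOINT_CLASSES:
            raise ValidationError(
                f"endpoint_class {self.endpoint_class!r} not one of {ENDPOINT_CLASSES}")
        if not self.value > 0:
            raise ValidationError(f"toxicity value must be > 0, got {self.value}")


@dataclass
class SSDFit:
    """A fitted sensitivity distribution and its protective concentrations."""

    distribution: Literal["log_logistic", "burr_iii"]
    parameters: tuple[float, ...]
    n_species: int
    protective_concentrations: dict[int, float] = field(default_factory=dict)
    convergence_flag: bool = True

    def __post_init__(self) -> None:
        if any(not p > 0 for p in self.parameters):
            raise ValidationError(f"all SSD parameters must be > 0: {self.parameters}")


@dataclass
class EtvRecord:
    """A threshold (umol/L) with its derivation provenance."""

    pai_name: str
    limit: float               # umol/L
    limit_type: str            # DGV | ETV
    method: str                # SSD | AF
    percentile_used: int | None   # 95, 99 or None
    reliability: str

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise ValidationError(f"{self.pai_name}: limit must be > 0, got {self.limit}")
        if self.limit_type not in ("DGV", "ETV"):
            raise ValidationError(f"limit_type must be DGV or ETV, got {self.limit_type!r}")
        if self.method not in ("SSD", "AF"):
            raise ValidationError(f"method must be SSD or AF, got {self.method!r}")
        if self.method == "AF" and self.percentile_used is not None:
            raise ValidationError("AF-derived thresholds carry no percentile")
        if self.method == "AF" and self.reliability != "unknown":
            raise ValidationError("AF-derived thresholds have unknown reliability")
        if self.percentile_used not in (None, 95, 99):
            raise ValidationError(f"percentile_used must be 95, 99 or None")
        if self.reliability not in RELIABILITY_LEVELS:
            raise ValidationError(f"unknown reliability {self.reliability!r}")


@dataclass
class AFConfig:
    """Assessment factors keyed by the endpoint class of the lowest value."""

    factors: dict[str, float] = field(default_factory=lambda: {
        "chronic": 10.0, "chronic_estimated": 20.0, "converted_acute": 100.0})

    def __post_init__(self) -> None:
        for k, v in self.factors.items():
            if v < 1:
                raise ValidationError(f"assessment factor for {k} must be >= 1, got {v}")

    def factor_for(self, endpoint_class: str) -> float:
        try:
            return self.factors[endpoint_class]
        except KeyError:
            raise ValidationError(
                f"no assessment factor configured for {endpoint_class!r}") from None


@dataclass
class DerivationConfig:
    """Tunables of the derivation pipeline (shipped defaults are editable)."""

    auto_burr_min_n: int = 8
    species_aggregation: Literal["geometric_mean", "minimum"] = "geometric_mean"
    af: AFConfig = field(default_factory=AFConfig)
    sensitive_groups: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "herbicide": ("phototroph",),
        "insecticide": ("arthropod",),
        "nematicide": ("arthropod", "nematode"),
        "fungicide": ("fungus",),
    })
    # reliability rubric: component scores summed then mapped to a class
    rubric_size_tiers: tuple[tuple[int, int, int], ...] = (
        (15, 5, 3), (8, 4, 2), (5, 4, 1))   # (min species, min groups) -> score
    rubric_endpoint_scores: dict[str, int] = field(default_factory=lambda: {
        "all_chronic": 2, "mixed": 1, "all_converted_acute": 0})
    rubric_fit_scores: dict[str, int] = field(default_factory=lambda: {
        "good": 2, "acceptable": 1, "poor": 0})
    rubric_class_cuts: tuple[tuple[int, str], ...] = (
        (7, "very_high"), (5, "high"), (3, "moderate"), (1, "low"), (0, "very_low"))


def load_derivation_config(path=None) -> DerivationConfig:
    """Load a :class:`DerivationConfig` from YAML (bundled default if no path)."""
    if path is None:
        path = importlib.resources.files("pdst.data").joinpath("derivation_config.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = DerivationConfig()
    if "auto_burr_min_n" in raw:
        cfg.auto_burr_min_n = int(raw["auto_burr_min_n"])
    if "species_aggregation" in raw:
        cfg.species_aggregation = raw["species_aggregation"]
    if "assessment_factors" in raw:
        cfg.af = AFConfig({k: float(v) for k, v in raw["assessment_factors"].items()})
    if "sensitive_groups" in raw:
        cfg.sensitive_groups = {k: tuple(v) for k, v in raw["sensitive_groups"].items()}
    if "reliability_rubric" in raw:
        rub = raw["reliability_rubric"]
        cfg.rubric_size_tiers = tuple(tuple(t) for t in rub["size_tiers"])
        cfg.rubric_endpoint_scores = dict(rub["endpoint_scores"])
        cfg.rubric_fit_scores = dict(rub["fit_scores"])
        cfg.rubric_class_cuts = tuple((int(c), s) for c, s in rub["class_cuts"])
    return cfg


# ---------------------------------------------------------------------------
# pipeline stages

def convert_concentration(value_mg_L: float, molar_mass: float) -> float:
    """mg/L -> umol/L given the molar mass in g/mol."""
    if not molar_mass > 0:
        raise ValidationError(f"molar_mass must be > 0, got {molar_mass}")
    if value_mg_L < 0:
        raise ValidationError(f"concentration must be >= 0, got {value_mg_L}")
    return value_mg_L * 1000.0 / molar_mass


def species_values(records: Iterable[ToxicityRecord],
                   aggregation: str = "geometric_mean") -> dict[str, float]:
    """Aggregate accepted records to a single value per species.

    The default aggregate is the geometric mean of each species' accepted
    values; ``aggregation="minimum"`` takes the species minimum instead.
    """
    per_species: dict[str, list[float]] = {}
    for rec in records:
        if rec.quality_accepted:
            per_species.setdefault(rec.species, []).append(rec.value)
    if not per_species:
        raise InsufficientDataError("no quality-accepted toxicity records")
    if aggregation == "geometric_mean":
        return {sp: float(np.exp(np.mean(np.log(v)))) for sp, v in per_species.items()}
    if aggregation == "minimum":
        return {sp: float(min(v)) for sp, v in per_species.items()}
    raise ValidationError(f"unknown aggregation {aggregation!r}")


def check_minimum_data(values: Mapping[str, float],
                       groups: Mapping[str, str]) -> bool:
    """True iff >= 5 species spanning >= 4 distinct taxonomic groups."""
    missing = [sp for sp in values if sp not in groups]
    if missing:
        raise ValidationError(f"no taxonomic group for species {missing}")
    n_species = len(values)
    n_groups = len({groups[sp] for sp in values})
    return n_species >= MIN_SPECIES and n_groups >= MIN_GROUPS


def select_sensitive_subset(values: Mapping[str, float],
                            groups: Mapping[str, str],
                            sensitive_group_labels: Iterable[str],
                            bimodal: bool) -> dict[str, float]:
    """For bimodal data keep only the most sensitive group of organisms.

    Bimodality is declared by the caller from the mode of action (e.g.
    phototrophs for herbicides, arthropods for insecticides); unimodal data
    pass through unchanged.
    """
    if not bimodal:
        return dict(values)
    labels = set(sensitive_group_labels)
    subset = {sp: v for sp, v in values.items() if groups.get(sp) in labels}
    if not subset:
        raise InsufficientDataError(
            f"bimodal selection for groups {sorted(labels)} removed every species")
    return subset


def bimodality_gap_statistic(values: Iterable[float]) -> float:
    """Advisory diagnostic: largest adjacent gap in sorted log10 values,
    as a multiple of the mean gap.  Large values (>~3) hint at bimodality;
    the pipeline never acts on this automatically."""
    logs = np.sort(np.log10(np.asarray(list(values), dtype=float)))
    if logs.size < 3:
        return 0.0
    gaps = np.diff(logs)
    mean = gaps.mean()
    return float(gaps.max() / mean) if mean > 0 else 0.0


# ---------------------------------------------------------------------------
# SSD fitting

def _loglogistic_mle(logs: np.ndarray) -> tuple[float, float]:
    """MLE of the log-logistic via a logistic fit on log-transformed values."""
    loc, scale = stats.logistic.fit(logs)
    return float(np.exp(loc)), float(1.0 / scale)


def _burr_nll(theta: np.ndarray, x: np.ndarray) -> float:
    b, c, k = np.exp(theta)
    with np.errstate(all="ignore"):
        nll = -np.sum(stats.burr.logpdf(x, c, k, loc=0.0, scale=b))
    return nll if np.isfinite(nll) else 1e12


def fit_ssd(values: Iterable[float],
            distribution: Literal["auto", "log_logistic", "burr_iii"] = "auto",
            auto_burr_min_n: int = 8) -> SSDFit:
    """Fit an SSD by maximum likelihood and populate PC80/90/95/99.

    ``auto`` selects the log-logistic below ``auto_burr_min_n`` species and
    Burr III at or above it.  A failed Burr III optimisation falls back to the
    log-logistic with ``convergence_flag=False``.
    """
    x = np.asarray(list(values), dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValidationError("all toxicity values must be finite and > 0")
    n = x.size
    if np.unique(x).size < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct toxicity values to fit an SSD, got {np.unique(x).size}")
    logs = np.log(x)

    if distribution == "auto":
        distribution = "log_logistic" if n < auto_burr_min_n else "burr_iii"

    converged = True
    if distribution == "log_logistic":
        alpha, beta = _loglogistic_mle(logs)
        params: tuple[float, ...] = (alpha, beta)
    elif distribution == "burr_iii":
        alpha, beta = _loglogistic_mle(logs)
        # multi-start Nelder-Mead on (ln b, ln c, ln k); the log-logistic fit
        # (k = 1) is an exact sub-model and anchors the first start
        starts = [(math.log(alpha), math.log(beta), 0.0)]
        for dk in (-1.0, 1.0):
            starts.append((math.log(alpha) - dk / beta, math.log(beta), dk))
        best = None
        for s in starts:
            res = optimize.minimize(_burr_nll, np.asarray(s), args=(x,),
                                    method="Nelder-Mead",
                                    options={"maxiter": 2000, "xatol": 1e-8,
                                             "fatol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        ll_nll = _burr_nll(np.asarray(starts[0]), x)
        if best is None or not np.all(np.isfinite(best.x)) or best.fun > ll_nll + 1e-6:
            distribution, params, converged = "log_logistic", (alpha, beta), False
        else:
            params = tuple(float(v) for v in np.exp(best.x))
            if not best.success:
                converged = False
    else:
        raise ValidationError(f"unknown distribution {distribution!r}")

    fit = SSDFit(distribution=distribution, parameters=params, n_species=n,
                 convergence_flag=converged)
    fit.protective_concentrations = {
        p: protective_concentration(fit, p) for p in PROTECTION_LEVELS}
    return fit


def protective_concentration(fit: SSDFit, p: int) -> float:
    """PCp: the (100-p)/100 quantile of the fitted distribution (umol/L)."""
    if p not in PROTECTION_LEVELS:
        raise ValidationError(f"p must be one of {PROTECTION_LEVELS}, got {p}")
    q = (100 - p) / 100.0
    if fit.distribution == "log_logistic":
        alpha, beta = fit.parameters
        return float(alpha * (q / (1 - q)) ** (1 / beta))
    b, c, k = fit.parameters
    # x = b (q^{-1/k} - 1)^{-1/c}, evaluated in log space so that extreme
    # shape parameters (flat likelihood ridges at small n) stay finite:
    # with a = -ln(q)/k,  ln(q^{-1/k} - 1) = a + log1p(-exp(-a))
    a = -math.log(q) / k
    log_term = a + math.log(-math.expm1(-a))
    return float(math.exp(math.log(b) - log_term / c))


# ---------------------------------------------------------------------------
# assessment-factor route, percentile policy, reliability

def assessment_factor_etv(values: Iterable[float],
                          config: AFConfig,
                          endpoint_class: str = "converted_acute",
                          pai_name: str = "") -> EtvRecord:
    """Lowest toxicity value divided by the configured assessment factor."""
    vals = list(values)
    if not vals:
        raise InsufficientDataError("assessment-factor method needs >= 1 value")
    if any(v <= 0 for v in vals):
        raise ValidationError("all toxicity values must be > 0")
    factor = config.factor_for(endpoint_class)
    return EtvRecord(pai_name=pai_name, limit=min(vals) / factor,
                     limit_type="ETV", method="AF",
                     percentile_used=None, reliability="unknown")


def select_percentile(log_kow: float, ssd_derived: bool) -> int | None:
    """PC99 for potential biomagnifiers (log K_OW >= 4), PC95 otherwise;
    AF-derived thresholds cannot be adjusted and carry no percentile."""
    if not ssd_derived:
        return None
    return 99 if log_kow >= 4.0 else 95


def classify_reliability(n_species: int, n_groups: int,
                         endpoint_mix: str, fit_quality: str,
                         config: DerivationConfig | None = None) -> str:
    """Deterministic monotone rubric: data volume + endpoint type + SSD fit.

    More species/groups, all-chronic data and a better fit never lower the
    class.  The component scores and class cuts ship in the default config
    and are editable.
    """
    cfg = config or DerivationConfig()
    if n_species < 0 or n_groups < 0:
        raise ValidationError("counts must be >= 0")
    size_score = 0
    for min_sp, min_gr, score in cfg.rubric_size_tiers:
        if n_species >= min_sp and n_groups >= min_gr:
            size_score = max(size_score, score)
    try:
        total = (size_score + cfg.rubric_endpoint_scores[endpoint_mix]
                 + cfg.rubric_fit_scores[fit_quality])
    except KeyError as exc:
        raise ValidationError(f"unknown rubric key {exc}") from None
    for cut, label in cfg.rubric_class_cuts:
        if total >= cut:
            return label
    return cfg.rubric_class_cuts[-1][1]


def _endpoint_mix(records: Sequence[ToxicityRecord]) -> str:
    classes = {r.endpoint_class for r in records if r.quality_accepted}
    if classes <= {"converted_acute"}:
        return "all_converted_acute"
    if classes <= {"chronic"}:
        return "all_chronic"
    return "mixed"


def _fit_quality(fit: SSDFit, values: Sequence[float]) -> str:
    """Grade the SSD fit from a one-sample KS test on log-transformed values."""
    logs = np.log(np.asarray(values, dtype=float))
    if fit.distribution == "log_logistic":
        alpha, beta = fit.parameters
        cdf = stats.logistic(loc=math.log(alpha), scale=1 / beta).cdf
    else:
        b, c, k = fit.parameters
        cdf = stats.burr(c, k, loc=0.0, scale=b).cdf
        logs = np.asarray(values, dtype=float)  # burr cdf is on the raw scale
    p = stats.kstest(logs, cdf).pvalue
    if not fit.convergence_flag:
        return "poor"
    return "good" if p >= 0.5 else "acceptable" if p >= 0.05 else "poor"


def derive_etv(records: Sequence[ToxicityRecord],
               groups: Mapping[str, str] | None = None,
               *,
               log_kow: float,
               bimodal: bool = False,
               sensitive_group_labels: Iterable[str] = (),
               limit_type: str = "ETV",
               config: DerivationConfig | None = None) -> EtvRecord:
    """End-to-end threshold derivation for one active ingredient.

    Pipeline: per-species aggregation -> (optional) sensitive-subset selection
    for bimodal data -> minimum-data check -> SSD fit and PCp at the selected
    percentile, else the assessment-factor fallback.
    """
    if not records:
        raise InsufficientDataError("no toxicity records supplied")
    cfg = config or DerivationConfig()
    pai_name = records[0].pai_name
    if groups is None:
        groups = {r.species: r.taxonomic_group for r in records}
    values = species_values(records, cfg.species_aggregation)
    values = select_sensitive_subset(values, groups, sensitive_group_labels, bimodal)

    if not check_minimum_data(values, groups):
        accepted = [r for r in records if r.quality_accepted]
        lowest = min(accepted, key=lambda r: r.value)
        return assessment_factor_etv(values.values(), cfg.af,
                                     endpoint_class=lowest.endpoint_class,
                                     pai_name=pai_name)

    vals = list(values.values())
    fit = fit_ssd(vals, "auto", cfg.auto_burr_min_n)
    percentile = select_percentile(log_kow, ssd_derived=True)
    limit = protective_concentration(fit, percentile)
    reliability = classify_reliability(
        n_species=len(values),
        n_groups=len({groups[sp] for sp in values}),
        endpoint_mix=_endpoint_mix(records),
        fit_quality=_fit_quality(fit, vals),
        config=cfg)
    return EtvRecord(pai_name=pai_name, limit=limit, limit_type=limit_type,
                     method="SSD", percentile_used=percentile,
                     reliability=reliability)


# ---------------------------------------------------------------------------
# synthetic toxicity data

_GROUP_CYCLE = ("fish", "arthropod", "phototroph", "mollusc", "amphibian", "annelid")
_PHYLUM = {"fish": "chordata", "arthropod": "arthropoda", "phototroph": "chlorophyta",
           "mollusc": "mollusca", "amphibian": "chordata", "annelid": "annelida"}


def generate_toxicity_dataset(seed: int, n_species: int,
                              pai_name: str = "synthcide",
                              mu_log10: float = -1.0,
                              sigma_log10: float = 0.5,
                              n_per_species: int = 1,
                              endpoint_class: str = "chronic") -> list[ToxicityRecord]:
    """Synthetic species sensitivities: log10 values ~ Normal(mu, sigma).

    With these defaults the true 5th percentile (the PC95 a perfect
    derivation would recover) is 10**(mu - 1.6449 sigma).
    """
    if n_species < 1:
        raise ValidationError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_species):
        group = _GROUP_CYCLE[i % len(_GROUP_CYCLE)]
        true_log = rng.normal(mu_log10, sigma_log10)
        for j in range(n_per_species):
            obs = true_log + (rng.normal(0.0, 0.1) if n_per_species > 1 else 0.0)
            records.append(ToxicityRecord(
                pai_name=pai_name, species=f"species-{i:03d}",
                taxonomic_group=group, phylum=_PHYLUM[group],
                endpoint_class=endpoint_class, value=float(10.0 ** obs)))
    return records
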