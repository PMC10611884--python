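"""Supporting statistics behind the mobility model and rate choice.

The runoff proportion model is a linear regression of experimental percent
PAI loss on log10 K_OC from rainfall-simulation field trials on two soil
types (a poorly drained hydrosol and a well-drained sandy soil).  This module
reproduces that machinery on user-supplied or synthetic trial tables: the
Spearman rank correlation between loss and K_OC, the OLS line itself, the
experimental-vs-modelled K_OC fold difference screen, and the sensitivity of
measure-of-effect rankings to the choice of label rate bound.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .errors import InsufficientDataError, ValidationError
from .registry import PAITable
from .risk_engine import RUNOFF_INTERCEPT, RUNOFF_SLOPE, rank_pais, risk_results

SOIL_TYPES = ("hydrosol", "sandy")

# exact permutation p-values are used up to this sample size (9! = 362,880)
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class RunoffTrial:
    """One field-trial observation: percent of applied PAI lost in runoff."""

    pai_name: str
    soil_type: str
    percent_loss: float
    koc: float

    def __post_init__(self) -> None:
        if self.soil_type not in SOIL_TYPES:
            raise ValidationError(f"soil_type must be one of {SOIL_TYPES}")
        if self.percent_loss < 0:
            raise ValidationError("percent_loss must be >= 0")
        if not self.koc > 0:
            raise ValidationError("koc must be > 0")


@dataclass
class RegressionResult:
    slope: float        # percent loss per log10(K_OC) unit
    intercept: float    # percent loss at K_OC = 1
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValidationError(f"|rho| > 1: {self.rho}")


# ---------------------------------------------------------------------------
# Spearman rank correlation with exact small-n permutation p-values

def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x: Sequence[float], y: Sequence[float],
             method: str = "auto") -> CorrelationResult:
    """Spearman rho (average ranks) with a two-sided p-value.

    ``exact`` enumerates all n! permutations (feasible for n <= 9 and the
    default below that size); ``approx`` uses the t-distribution
    approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValidationError("spearman needs n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("spearman is undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_rho(rx, ry)

    if method == "auto":
        method = "exact" if n <= EXACT_PERMUTATION_MAX_N else "approx"
    if method == "exact":
        hits = total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= target:
                hits += 1
        p = hits / total
    elif method == "approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        raise ValidationError(f"method must be auto|exact|approx, got {method!r}")
    return CorrelationResult(rho=rho, p_value=min(max(p, 0.0), 1.0), n=n)


# ---------------------------------------------------------------------------
# the runoff-loss regression (the source of the mobility line)

def fit_loss_regression(trials: Iterable[RunoffTrial], soil_type: str,
                        drop: Iterable[str] = ()) -> RegressionResult:
    """OLS of percent loss on log10(K_OC) for one soil type.

    ``drop`` removes named PAIs before fitting — outlier exclusion (e.g. a
    charged compound on sandy soil) is an explicit caller decision, never
    automatic.
    """
    if soil_type not in SOIL_TYPES:
        raise ValidationError(f"soil_type must be one of {SOIL_TYPES}")
    dropped = set(drop)
    pts = [(math.log10(t.koc), t.percent_loss) for t in trials
           if t.soil_type == soil_type and t.pai_name not in dropped]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 {soil_type} trials, got {len(pts)}")
    xs, ys = map(np.asarray, zip(*pts))
    res = stats.linregress(xs, ys)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=min(float(res.rvalue) ** 2, 1.0), n=len(pts))


def koc_fold_difference(koc_a: float, koc_b: float) -> float:
    """Symmetric fold difference max/min between two K_OC values (>= 1)."""
    if not (koc_a > 0 and koc_b > 0):
        raise ValidationError("both K_OC values must be > 0")
    return max(koc_a, koc_b) / min(koc_a, koc_b)


# ---------------------------------------------------------------------------
# application-rate sensitivity of the effect ranking

RATE_BOUNDS = ("max", "min", "mean")


def rate_sensitivity(table: PAITable) -> dict[tuple[str, str], CorrelationResult]:
    """Pairwise Spearman correlation of effect rankings across rate bounds.

    Returns the full symmetric 3x3 matrix over {max, min, mean} keyed by
    bound pairs; diagonal entries are exactly 1.
    """
    rankings = {}
    for bound in RATE_BOUNDS:
        results = risk_results(table, which=bound)
        ranks = rank_pais(results, key="effect")
        rankings[bound] = [ranks[r.pai_name] for r in results]
    out: dict[tuple[str, str], CorrelationResult] = {}
    for a in RATE_BOUNDS:
        for b in RATE_BOUNDS:
            if a == b:
                out[(a, b)] = CorrelationResult(1.0, 0.0, len(rankings[a]))
            elif (b, a) in out:
                out[(a, b)] = out[(b, a)]
            elif len(rankings[a]) < 3:
                # tiny tables: rho is still defined, no meaningful p-value
                rho = _rank_rho(rankdata(rankings[a]), rankdata(rankings[b]))
                out[(a, b)] = CorrelationResult(rho, 1.0, len(rankings[a]))
            else:
                out[(a, b)] = spearman(rankings[a], rankings[b], method="approx")
    return out


# ---------------------------------------------------------------------------
# synthetic trials and reporting

def generate_runoff_trials(seed: int, n: int, soil_type: str = "hydrosol",
                           slope: float = RUNOFF_SLOPE,
                           intercept: float = RUNOFF_INTERCEPT,
                           sigma: float = 0.0) -> list[RunoffTrial]:
    """Synthetic trials on (or noisily around) a percent-loss line.

    K_OC is drawn log-uniformly over 10-10^3.5 L/kg (the un-clamped range of
    the line); Gaussian noise of standard deviation ``sigma`` percent is
    added to the line, with losses truncated at zero.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        logk = rng.uniform(1.0, 3.5)
        loss = slope * logk + intercept + (rng.normal(0.0, sigma) if sigma else 0.0)
        trials.append(RunoffTrial(pai_name=f"trial-{i:03d}", soil_type=soil_type,
                                  percent_loss=max(loss, 0.0), koc=10.0 ** logk))
    return trials


def load_runoff_trials(path) -> list[RunoffTrial]:
    """Read runoff_trials.csv (pai_name, soil_type, percent_loss, koc_L_kg)."""
    import pandas as pd

    from .errors import SchemaError
    df = pd.read_csv(path)
    required = ["pai_name", "soil_type", "percent_loss", "koc_L_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [RunoffTrial(pai_name=str(r.pai_name), soil_type=str(r.soil_type),
                        percent_loss=float(r.percent_loss), koc=float(r.koc_L_kg))
            for r in df.itertuples()]


def calibration_report(trials: Sequence[RunoffTrial],
                       drop: Iterable[str] = ()) -> dict:
    """Per-soil regression and rank-correlation blocks as a JSON-able dict."""
    report: dict = {}
    for soil in SOIL_TYPES:
        sub = [t for t in trials if t.soil_type == soil and t.pai_name not in set(drop)]
        if len(sub) < 3:
            report[soil] = {"n": len(sub), "note": "insufficient trials"}
            continue
        reg = fit_loss_regression(trials, soil, drop=drop)
        corr = spearman([t.koc for t in sub], [t.percent_loss for t in sub])
        report[soil] = {
            "n": reg.n,
            "regression": {"slope": reg.slope, "intercept": reg.intercept,
                           "r_squared": reg.r_squared},
            "spearman": {"rho": corr.rho, "p_value": corr.p_value},
        }
    return report
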