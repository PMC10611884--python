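"""Threshold derivation: SSD fitting, assessment factors, percentile policy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pdst
from pdst.errors import InsufficientDataError, ValidationError
from pdst.etv_derivation import SSDFit


def tox(species, value, group="fish", accepted=True, endpoint="chronic"):
    return pdst.ToxicityRecord(pai_name="x", species=species,
                               taxonomic_group=group, phylum="p",
                               endpoint_class=endpoint, value=value,
                               quality_accepted=accepted)


# ---------------------------------------------------------------------------
# per-species aggregation and data-sufficiency rules

class TestSpeciesValues:
    def test_singleton(self):
        assert pdst.species_values([tox("A", 1.0)]) == {"A": 1.0}

    def test_geometric_mean(self):
        vals = pdst.species_values([tox("A", 1.0), tox("A", 100.0)])
        assert vals["A"] == pytest.approx(10.0)

    def test_matches_brute_force_over_species(self):
        rng = np.random.default_rng(0)
        records, expected = [], {}
        for sp in ("A", "B", "C"):
            v = rng.lognormal(0, 1, size=2)
            records += [tox(sp, v[0]), tox(sp, v[1])]
            expected[sp] = math.sqrt(v[0] * v[1])
        got = pdst.species_values(records)
        assert got == pytest.approx(expected)

    def test_rejected_records_ignored(self):
        vals = pdst.species_values([tox("A", 1.0), tox("A", 1e6, accepted=False)])
        assert vals["A"] == pytest.approx(1.0)

    def test_no_accepted_records_errors(self):
        with pytest.raises(InsufficientDataError):
            pdst.species_values([tox("A", 1.0, accepted=False)])

    def test_minimum_aggregation_option(self):
        vals = pdst.species_values([tox("A", 1.0), tox("A", 100.0)],
                                   aggregation="minimum")
        assert vals["A"] == 1.0


class TestMinimumData:
    @pytest.mark.parametrize("n_species, n_groups, expected", [
        (5, 4, True), (5, 3, False), (4, 4, False), (10, 4, True), (5, 5, True),
    ])
    def test_rule(self, n_species, n_groups, expected):
        values = {f"s{i}": 1.0 + i for i in range(n_species)}
        groups = {f"s{i}": f"g{i % n_groups}" for i in range(n_species)}
        assert pdst.check_minimum_data(values, groups) is expected


class TestSensitiveSubset:
    def test_unimodal_identity(self):
        values = {"a": 1.0, "b": 2.0}
        got = pdst.select_sensitive_subset(values, {"a": "fish", "b": "fish"},
                                           {"phototroph"}, bimodal=False)
        assert got == values

    def test_bimodal_keeps_sensitive_group(self):
        values = {f"p{i}": 0.1 * (i + 1) for i in range(6)}
        values.update({f"f{i}": 100.0 + i for i in range(4)})
        groups = {k: ("phototroph" if k.startswith("p") else "fish") for k in values}
        got = pdst.select_sensitive_subset(values, groups, {"phototroph"}, True)
        assert sorted(got) == [f"p{i}" for i in range(6)]

    def test_bimodal_empty_subset_errors(self):
        with pytest.raises(InsufficientDataError):
            pdst.select_sensitive_subset({"a": 1.0}, {"a": "fish"},
                                         {"arthropod"}, True)


# ---------------------------------------------------------------------------
# SSD fitting

def loglogistic_quantile_lattice(alpha, beta, n):
    """Plug-in quantiles of a log-logistic: an 'exact' sample of size n."""
    q = (np.arange(1, n + 1) - 0.5) / n
    return alpha * (q / (1 - q)) ** (1 / beta)


class TestFitSSD:
    def test_loglogistic_lattice_recovers_parameters(self):
        values = loglogistic_quantile_lattice(1.0, 2.0, 1000)
        fit = pdst.fit_ssd(values, "log_logistic")
        alpha, beta = fit.parameters
        assert alpha == pytest.approx(1.0, rel=0.01)
        assert beta == pytest.approx(2.0, rel=0.01)
        # closed-form 5th percentile: alpha * (0.05/0.95)^(1/beta)
        assert fit.protective_concentrations[95] == pytest.approx(0.2294, rel=0.01)

    def test_auto_policy_small_n_uses_loglogistic(self):
        fit = pdst.fit_ssd([0.5, 1.0, 2.0, 4.0, 8.0], "auto")
        assert fit.distribution == "log_logistic"
        assert fit.n_species == 5

    def test_auto_policy_large_n_uses_burr(self):
        values = loglogistic_quantile_lattice(1.0, 1.5, 30)
        fit = pdst.fit_ssd(values, "auto")
        assert fit.distribution == "burr_iii"
        assert len(fit.parameters) == 3

    def test_burr_nests_loglogistic_at_matching_likelihood(self):
        # Burr III contains the log-logistic (k=1); on log-logistic lattice data
        # its PC95 must agree closely with the closed-form quantile
        values = loglogistic_quantile_lattice(2.0, 3.0, 200)
        fit = pdst.fit_ssd(values, "burr_iii")
        expected = 2.0 * (0.05 / 0.95) ** (1 / 3.0)
        assert fit.protective_concentrations[95] == pytest.approx(expected, rel=0.02)

    def test_empirical_quantile_oracle_lognormal(self):
        rng = np.random.default_rng(42)
        sample = 10.0 ** rng.normal(-1.0, 0.5, size=10_000)
        fit = pdst.fit_ssd(sample, "auto")
        empirical = np.quantile(sample, 0.05)
        assert fit.protective_concentrations[95] == pytest.approx(empirical, rel=0.10)

    def test_degenerate_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            pdst.fit_ssd([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            pdst.fit_ssd([1.0, -2.0, 3.0])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 40),
           sigma=st.floats(0.2, 1.0))
    def test_quantile_coherence(self, seed, n, sigma):
        rng = np.random.default_rng(seed)
        values = 10.0 ** rng.normal(0.0, sigma, size=n)
        if np.unique(values).size < 2:
            return
        fit = pdst.fit_ssd(values, "auto")
        pc = fit.protective_concentrations
        assert pc[99] <= pc[95] <= pc[90] <= pc[80]

    def test_scale_equivariance_of_ssd_route(self):
        rng = np.random.default_rng(3)
        values = 10.0 ** rng.normal(0.0, 0.4, size=12)
        f1 = pdst.fit_ssd(values, "auto")
        f2 = pdst.fit_ssd(values * 50.0, "auto")
        assert f2.protective_concentrations[95] == pytest.approx(
            50.0 * f1.protective_concentrations[95], rel=1e-3)


class TestProtectiveConcentration:
    def test_loglogistic_closed_form(self):
        fit = SSDFit("log_logistic", (1.0, 1.0), 10)
        assert pdst.protective_concentration(fit, 95) == pytest.approx(0.05 / 0.95)

    def test_burr_matches_bisection_oracle(self):
        # Burr III(b=1, c=2, k=1): solve F(x) = 0.10 by bisection
        b, c, k = 1.0, 2.0, 1.0
        lo, hi = 1e-9, 1e9
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if (1 + (mid / b) ** -c) ** -k < 0.10:
                lo = mid
            else:
                hi = mid
        fit = SSDFit("burr_iii", (b, c, k), 10)
        got = pdst.protective_concentration(fit, 90)
        assert got == pytest.approx(lo, rel=1e-6)
        assert got == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_monotone_in_protection_level(self):
        fit = SSDFit("burr_iii", (2.0, 1.5, 0.7), 10)
        pcs = [pdst.protective_concentration(fit, p) for p in (99, 95, 90, 80)]
        assert pcs == sorted(pcs)

    def test_unsupported_level_rejected(self):
        fit = SSDFit("log_logistic", (1.0, 1.0), 10)
        with pytest.raises(ValidationError):
            pdst.protective_concentration(fit, 50)


# ---------------------------------------------------------------------------
# assessment-factor route and policies

class TestAssessmentFactor:
    def test_lowest_over_factor(self):
        cfg = pdst.AFConfig({"chronic": 1000.0})
        etv = pdst.assessment_factor_etv([2.0, 5.0], cfg, "chronic")
        assert etv.limit == pytest.approx(0.002)
        assert etv.method == "AF"
        assert etv.percentile_used is None
        assert etv.reliability == "unknown"

    def test_identity_factor(self):
        cfg = pdst.AFConfig({"chronic": 1.0})
        assert pdst.assessment_factor_etv([3.7], cfg, "chronic").limit == 3.7

    def test_sparse_published_case(self):
        # single lowest value 0.0067 over a factor of 1000 reproduces the
        # published sparse-data insecticide threshold 0.0000067
        cfg = pdst.AFConfig({"converted_acute": 1000.0})
        etv = pdst.assessment_factor_etv([0.0067], cfg, "converted_acute",
                                         pai_name="cadusafos")
        assert etv.limit == pytest.approx(6.7e-6)

    def test_empty_errors(self):
        with pytest.raises(InsufficientDataError):
            pdst.assessment_factor_etv([], pdst.AFConfig())

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(0.01, 100.0),
           vals=st.lists(st.floats(0.001, 1e4), min_size=1, max_size=8))
    def test_scale_equivariance(self, c, vals):
        cfg = pdst.AFConfig({"chronic": 10.0})
        base = pdst.assessment_factor_etv(vals, cfg, "chronic")
        scaled = pdst.assessment_factor_etv([v * c for v in vals], cfg, "chronic")
        assert scaled.limit == pytest.approx(c * base.limit, rel=1e-9)


class TestSelectPercentile:
    @pytest.mark.parametrize("log_kow, ssd, expected", [
        (4.7, True, 99), (3.9, True, 95), (6.0, False, None),
        (4.0, True, 99),   # boundary included: "4 or greater"
        (3.999999, True, 95),
    ])
    def test_policy(self, log_kow, ssd, expected):
        assert pdst.select_percentile(log_kow, ssd) == expected


class TestReliabilityRubric:
    def test_sparse_converted_acute_is_low(self):
        assert pdst.classify_reliability(5, 4, "all_converted_acute", "poor") == "low"

    def test_rich_chronic_is_very_high(self):
        assert pdst.classify_reliability(30, 7, "all_chronic", "good") == "very_high"

    def test_deterministic(self):
        a = pdst.classify_reliability(9, 4, "mixed", "acceptable")
        assert a == pdst.classify_reliability(9, 4, "mixed", "acceptable")

    def test_monotone_in_every_argument(self):
        order = ["very_low", "low", "moderate", "high", "very_high"]
        mixes = ["all_converted_acute", "mixed", "all_chronic"]
        fits = ["poor", "acceptable", "good"]
        for n in (4, 5, 8, 15, 30):
            for g in (3, 4, 5, 7):
                for mi in range(2):
                    for fi in range(2):
                        lo = pdst.classify_reliability(n, g, mixes[mi], fits[fi])
                        hi = pdst.classify_reliability(n + 5, g + 1,
                                                       mixes[mi + 1], fits[fi + 1])
                        assert order.index(lo) <= order.index(hi)


# ---------------------------------------------------------------------------
# end-to-end derivation

class TestDeriveEtv:
    def test_sufficient_data_takes_ssd_route(self):
        records = [tox(f"s{i}", 1.0 + i, group=f"g{i % 4}") for i in range(5)]
        etv = pdst.derive_etv(records, log_kow=2.0)
        assert etv.method == "SSD"
        assert etv.percentile_used == 95

    def test_sparse_data_takes_af_route(self):
        records = [tox(f"s{i}", 1.0 + i, group=f"g{i}") for i in range(3)]
        etv = pdst.derive_etv(records, log_kow=2.0)
        assert etv.method == "AF"
        assert etv.reliability == "unknown"
        # chronic lowest value: default factor 10 on the minimum 1.0
        assert etv.limit == pytest.approx(0.1)

    def test_biomagnifier_uses_pc99_below_pc95(self):
        records = pdst.generate_toxicity_dataset(seed=11, n_species=20)
        etv99 = pdst.derive_etv(records, log_kow=5.0)
        etv95 = pdst.derive_etv(records, log_kow=2.0)
        assert etv99.percentile_used == 99 and etv95.percentile_used == 95
        assert etv99.limit < etv95.limit

    def test_bimodal_selection_uses_sensitive_group_only(self):
        sensitive = [tox(f"p{i}", 0.01 * (1 + i), group="phototroph")
                     for i in range(6)]
        tolerant = [tox(f"f{i}", 100.0 * (1 + i), group=g)
                    for i, g in enumerate(["fish", "arthropod", "mollusc",
                                           "amphibian", "annelid"])]
        records = sensitive + tolerant
        both = pdst.derive_etv(records, log_kow=2.0)
        groups = {r.species: r.taxonomic_group for r in records}
        only = pdst.species_values(sensitive)
        # fewer than 4 groups among phototrophs alone -> AF on the subset
        bimodal = pdst.derive_etv(records, groups, log_kow=2.0, bimodal=True,
                                  sensitive_group_labels=("phototroph",))
        assert both.method == "SSD"
        assert bimodal.method == "AF"
        # AF on the sensitive subset: lowest phototroph value / chronic factor
        assert bimodal.limit == pytest.approx(min(only.values()) / 10.0)


class TestConvertConcentration:
    @pytest.mark.parametrize("mg, mm, expected", [
        (1.0, 1000.0, 1.0), (0.0, 100.0, 0.0), (0.233, 233.0, 1.0),
    ])
    def test_values(self, mg, mm, expected):
        assert pdst.convert_concentration(mg, mm) == pytest.approx(expected)

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValidationError):
            pdst.convert_concentration(1.0, -1.0)


class TestSyntheticToxicity:
    def test_deterministic_and_distinct_species(self):
        a = pdst.generate_toxicity_dataset(seed=5, n_species=12)
        b = pdst.generate_toxicity_dataset(seed=5, n_species=12)
        assert a == b
        assert len({r.species for r in a}) == 12

    def test_groups_span_minimum_rule(self):
        records = pdst.generate_toxicity_dataset(seed=5, n_species=8)
        values = pdst.species_values(records)
        groups = {r.species: r.taxonomic_group for r in records}
        assert pdst.check_minimum_data(values, groups)


def test_default_config_round_trips_from_yaml():
    cfg = pdst.load_derivation_config()
    assert cfg.auto_burr_min_n == 8
    assert cfg.af.factor_for("chronic") == 10.0
    assert cfg.sensitive_groups["herbicide"] == ("phototroph",)
    assert pdst.classify_reliability(30, 7, "all_chronic", "good", cfg) == "very_high"
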