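import numpy as np
import pandas as pd
import pytest

from pafsim.errors import DomainError
from pafsim.exposure_model import ExposureDistribution, discretize, mean_rr
from pafsim.risk_model import RelativeRiskSpec, fit_loglinear
from pafsim.simulation_engine import (
    Scenario,
    apply_latency,
    calibrate_baseline,
    format_percent,
    paf_from_counts,
    run_scenario,
    sensitivity_run,
)


@pytest.fixture
def one_stratum_exposure():
    return [ExposureDistribution("male", 0, 120, mean=62.4, sd=55.0, family="gamma")]


class TestCalibrateBaseline:
    def test_exact_division(self):
        assert calibrate_baseline(11.7, 1.17) == pytest.approx(10.0)

    def test_unit_rr_is_identity(self):
        assert calibrate_baseline(25.0, 1.0) == 25.0

    def test_round_trip_reproduces_observed(self, red_meat_rf, gamma_unit_exposure):
        mrr = mean_rr(discretize(gamma_unit_exposure, 20.0), red_meat_rf)
        r0 = calibrate_baseline(42.0, mrr)
        assert r0 * mrr == pytest.approx(42.0, rel=1e-12)

    def test_nonpositive_mean_rr_rejected(self):
        with pytest.raises(DomainError):
            calibrate_baseline(10.0, 0.0)


class TestPafFromCounts:
    @pytest.mark.parametrize(
        "ref, inter, frac, percent",
        [
            (2480, 2149, 0.1335, 13),  # red meat, men
            (2878, 2581, 0.1032, 10),  # red meat, women
            (2878, 2490, 0.1348, 13),  # processed meat, women
            (2480, 2118, 0.1460, 15),  # processed meat, men
            (2480, 1992, 0.1968, 20),  # red meat men, upper sensitivity bound
        ],
    )
    def test_published_count_arithmetic(self, ref, inter, frac, percent):
        paf = paf_from_counts(ref, inter)
        assert paf == pytest.approx(frac, abs=5e-5)
        assert format_percent(paf) == percent

    def test_no_effect_gives_zero(self):
        assert paf_from_counts(1234, 1234) == 0.0

    def test_zero_reference_undefined(self):
        with pytest.raises(DomainError):
            paf_from_counts(0, 0)

    def test_intervention_exceeding_reference_rejected(self):
        with pytest.raises(DomainError):
            paf_from_counts(100, 101)


class TestRunScenario:
    def test_identity_scenario_changes_nothing(
        self, one_stratum_exposure, red_meat_rf, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        res = run_scenario(
            one_stratum_exposure, red_meat_rf, rates, pop,
            Scenario(exposure_transform="identity"),
        )
        row = res.by_sex.loc["male"]
        assert row["paf"] == 0.0
        assert row["avoided_cases"] == 0.0
        assert row["reference_asr"] == pytest.approx(row["intervention_asr"])

    def test_single_stratum_matches_closed_form(
        self, one_stratum_exposure, red_meat_rf, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        res = run_scenario(
            one_stratum_exposure, red_meat_rf, rates, pop, Scenario()
        )
        mrr = mean_rr(discretize(one_stratum_exposure[0], 20.0), red_meat_rf)
        assert res.by_sex.loc["male", "paf"] == pytest.approx(
            1 - 1 / mrr, rel=1e-12
        )

    def test_reference_reproduces_observed_incidence(
        self, one_stratum_exposure, red_meat_rf, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        res = run_scenario(
            one_stratum_exposure, red_meat_rf, rates, pop, Scenario()
        )
        expected = 30.0 * 1_000_000 / 100_000
        assert res.by_sex.loc["male", "reference_cases"] == pytest.approx(expected)

    def test_null_rr_gives_zero_paf(
        self, one_stratum_exposure, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        rf = fit_loglinear(RelativeRiskSpec("null", 1.0, 1.0, 1.0, 100.0))
        res = run_scenario(one_stratum_exposure, rf, rates, pop, Scenario())
        assert res.by_sex.loc["male", "paf"] == 0.0

    def test_zero_exposure_population_gives_zero_paf(
        self, red_meat_rf, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        exposures = [
            ExposureDistribution("male", 0, 120, 0.0, 0.0, family="point_mass")
        ]
        res = run_scenario(exposures, red_meat_rf, rates, pop, Scenario())
        assert res.by_sex.loc["male", "paf"] == pytest.approx(0.0, abs=1e-15)

    def test_avoided_cases_conserved_over_strata(
        self, red_meat_rf, small_demography
    ):
        rates, pop = small_demography
        exposures = [
            ExposureDistribution(sex, 0, 120, 55.0, 50.0, family="gamma")
            for sex in ("male", "female")
        ]
        res = run_scenario(exposures, red_meat_rf, rates, pop, Scenario())
        for sex in ("male", "female"):
            stratum_sum = res.strata.loc[
                res.strata["sex"] == sex, "avoided_cases"
            ].sum()
            assert res.by_sex.loc[sex, "avoided_cases"] == pytest.approx(stratum_sum)

    def test_paf_monotone_in_rr_and_mean_dose(self, single_stratum_tables):
        rates, pop = single_stratum_tables

        def paf(rr, mean):
            rf = fit_loglinear(RelativeRiskSpec("x", rr, rr, rr, 100.0))
            exp = [ExposureDistribution("male", 0, 120, mean, mean * 0.9, "gamma")]
            return run_scenario(exp, rf, rates, pop, Scenario()).by_sex.loc[
                "male", "paf"
            ]

        assert paf(1.05, 55.0) < paf(1.17, 55.0) < paf(1.31, 55.0)
        assert paf(1.17, 40.0) < paf(1.17, 55.0) < paf(1.17, 70.0)

    def test_partial_reduction_between_identity_and_zero(
        self, one_stratum_exposure, red_meat_rf, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        pafs = [
            run_scenario(
                one_stratum_exposure, red_meat_rf, rates, pop,
                Scenario(exposure_transform=t),
            ).by_sex.loc["male", "paf"]
            for t in ("identity", 0.5, "zero")
        ]
        assert pafs[0] == 0.0
        assert 0.0 < pafs[1] < pafs[2]


class TestSensitivity:
    def test_bounds_bracket_central(
        self, one_stratum_exposure, red_meat_spec, single_stratum_tables
    ):
        rates, pop = single_stratum_tables
        res = sensitivity_run(
            one_stratum_exposure, red_meat_spec, rates, pop, Scenario()
        )
        row = res["central"].by_sex.loc["male"]
        assert row["paf_lower"] < row["paf"] < row["paf_upper"]
        # lower intervention count pairs with the upper PAF bound
        assert row["intervention_cases_lower"] < row["intervention_cases"]
        assert row["intervention_cases_upper"] > row["intervention_cases"]

    def test_degenerate_ci_collapses(self, one_stratum_exposure, single_stratum_tables):
        rates, pop = single_stratum_tables
        spec = RelativeRiskSpec("x", 1.17, 1.17, 1.17, 100.0)
        res = sensitivity_run(
            one_stratum_exposure, spec, rates, pop, Scenario()
        )
        row = res["central"].by_sex.loc["male"]
        assert row["paf_lower"] == row["paf"] == row["paf_upper"]

    def test_wider_rr_interval_widens_paf_interval(
        self, one_stratum_exposure, single_stratum_tables
    ):
        rates, pop = single_stratum_tables

        def width(lo, up):
            spec = RelativeRiskSpec("x", 1.17, lo, up, 100.0)
            row = sensitivity_run(
                one_stratum_exposure, spec, rates, pop, Scenario()
            )["central"].by_sex.loc["male"]
            return row["paf_upper"] - row["paf_lower"]

        assert width(1.05, 1.31) > width(1.10, 1.25)


class TestLatency:
    @pytest.fixture
    def stream(self):
        return pd.DataFrame(
            {
                "year": range(2010, 2020),
                "reference": np.linspace(100, 109, 10),
                "intervention": np.linspace(80, 89, 10),
            }
        )

    def test_zero_latency_is_identity(self, stream):
        out = apply_latency(stream, 0)
        pd.testing.assert_frame_equal(out, stream)

    def test_positive_latency_delays_effect(self, stream):
        out = apply_latency(stream, 5)
        assert (out["intervention"][:5] == out["reference"][:5]).all()
        assert (out["intervention"][5:] == stream["intervention"][5:]).all()

    def test_latency_beyond_stream(self, stream):
        out = apply_latency(stream, 50)
        assert (out["intervention"] == out["reference"]).all()

    def test_negative_latency_rejected(self, stream):
        with pytest.raises(DomainError):
            apply_latency(stream, -1)

    def test_scenario_rejects_negative_latency(self):
        with pytest.raises(DomainError):
            Scenario(latency_years=-2)
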