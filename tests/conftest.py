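import pandas as pd
import pytest

from pafsim.demography import PopulationTable, StratifiedRateTable
from pafsim.exposure_model import ExposureDistribution
from pafsim.risk_model import RelativeRiskSpec, fit_loglinear


@pytest.fixture
def red_meat_spec():
    """Meta-analytic red-meat RR per 100 g/day with its 95% CI."""
    return RelativeRiskSpec("red_meat", 1.17, 1.05, 1.31, reference_dose=100.0)


@pytest.fixture
def processed_meat_spec():
    return RelativeRiskSpec("processed_meat", 1.35, 1.27, 1.45, reference_dose=100.0)


@pytest.fixture
def red_meat_rf(red_meat_spec):
    return fit_loglinear(red_meat_spec, "central")


@pytest.fixture
def gamma_unit_exposure():
    """Gamma with k=1 (exponential), mean=sd=50 g/day: closed-form CDF/MGF."""
    return ExposureDistribution("male", 15, 44, mean=50.0, sd=50.0, family="gamma")


def _single_stratum_tables(rate=30.0, count=1_000_000.0, sex="male"):
    rates = StratifiedRateTable(
        pd.DataFrame(
            [{"sex": sex, "age_low": 0, "age_high": "+", "rate_per_100k": rate}]
        )
    )
    pop = PopulationTable(
        pd.DataFrame([{"sex": sex, "age_low": 0, "age_high": "+", "count": count}])
    )
    return rates, pop


@pytest.fixture
def single_stratum_tables():
    return _single_stratum_tables()


@pytest.fixture
def small_demography():
    """Two sexes x four age groups with hand-checkable numbers."""
    rows_r, rows_p = [], []
    for sex in ("male", "female"):
        for i, (lo, hi) in enumerate([(0, 29), (30, 59), (60, 79), (80, "+")]):
            rows_r.append(
                {"sex": sex, "age_low": lo, "age_high": hi,
                 "rate_per_100k": 2.0 + 10.0 * i}
            )
            rows_p.append(
                {"sex": sex, "age_low": lo, "age_high": hi,
                 "count": 1_000_000.0 / (i + 1)}
            )
    return (
        StratifiedRateTable(pd.DataFrame(rows_r)),
        PopulationTable(pd.DataFrame(rows_p)),
    )
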