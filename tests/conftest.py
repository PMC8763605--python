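import pandas as pd
import pytest

from copecba.config import UnitCostConfig
from copecba.costing import UtilizationRecord


@pytest.fixture(scope="session")
def config() -> UnitCostConfig:
    return UnitCostConfig.default()


@pytest.fixture()
def five_records() -> list[UtilizationRecord]:
    """Mixed fixture whose total is hand-costed in the tests."""
    return [
        UtilizationRecord("d1", "cope", "baseline", "meals", 3),
        UtilizationRecord("d1", "cope", "month12", "inpatient", 1, "I50.9"),
        UtilizationRecord("d2", "cope", "month12", "mileage", 100),
        UtilizationRecord("d3", "usual_care", "baseline", "adult_day", 5),
        UtilizationRecord("d4", "usual_care", "month12", "visiting_nurse", 4),
    ]


@pytest.fixture()
def three_dyad_cost_lines() -> pd.DataFrame:
    """Hand-built cost lines for delta checks (absent periods count as 0)."""
    rows = [
        # dyad A (cope): meals 100 -> 100, inpatient 0 -> 250
        ("A", "cope", "baseline", "meals", 100.0),
        ("A", "cope", "month12", "meals", 100.0),
        ("A", "cope", "month12", "inpatient", 250.0),
        # dyad B (cope): nursing home 500 -> 200
        ("B", "cope", "baseline", "nursing_home", 500.0),
        ("B", "cope", "month12", "nursing_home", 200.0),
        # dyad C (usual): meals only at baseline
        ("C", "usual_care", "baseline", "meals", 40.0),
    ]
    return pd.DataFrame(
        rows, columns=["dyad_id", "arm", "period", "report_category", "cost_usd2019"]
    )
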