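from pathlib import Path

import pandas as pd
import pytest

import expoalloc as ea

DATA_DIR = Path(__file__).parent / "data"


def make_scenario(var, cost, alpha=1.0, beta=1.0, R=500.0) -> ea.Scenario:
    return ea.Scenario(
        var2=ea.VarianceComponents2(*var),
        cost2=ea.CostModel2(*cost, alpha=alpha, beta=beta),
        budget=ea.Budget(R),
    )


@pytest.fixture(scope="session")
def reference_grid_optima() -> pd.DataFrame:
    """Reference optima and 2-d.p. variances for the 225-scenario grid."""
    return pd.read_csv(DATA_DIR / "reference_grid_optima.csv")


@pytest.fixture(scope="session")
def grid_table_500() -> pd.DataFrame:
    return ea.run_grid(ea.build_grid(500))


@pytest.fixture(scope="session")
def grid_table_1000() -> pd.DataFrame:
    return ea.run_grid(ea.build_grid(1000))
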