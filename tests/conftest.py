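from pathlib import Path

import pandas as pd
import pytest

from sportmed import simulate

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_cohort() -> pd.DataFrame:
    """Seed-locked 420-child cohort shipped as CSV (7 countries x 4 schools)."""
    return pd.read_csv(DATA_DIR / "fixture_cohort.csv")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One realization of the full-size default cohort, no missingness."""
    return simulate.generate_cohort(simulate.default_energy_truth(missing_rate=0.0))


@pytest.fixture(scope="session")
def recovery_cohort() -> pd.DataFrame:
    """One realization of the documented calibration truth (n = 3010)."""
    return simulate.generate_cohort(simulate.recovery_truth(seed=3))
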