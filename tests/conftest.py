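import numpy as np
import pytest

from dlnmkit.pipeline import AnalysisConfig, DailySeries, run_factor_analysis
from dlnmkit.synthetic import BaselineSpec, TrueSurface, simulate_dataset

# Reference simulation used across tests: a temperature-like factor with a
# known quadratic x exponential-decay surface (risk minimum at 27) on a
# daily-count scale informative enough for surface recovery (2 cases/day,
# the scale of a mid-size-city daily surveillance series).
RECOVERY_SURFACE = TrueSurface(x_ref=27.0, gamma=0.1, scale=5.5, tau=3.0)
RECOVERY_BASELINE = BaselineSpec(mean_daily_count=2.0)


@pytest.fixture(scope="session")
def recovery_data():
    df, truth = simulate_dataset(
        n_days=4000,
        factors=["mean_temperature"],
        surfaces={"mean_temperature": RECOVERY_SURFACE},
        baseline=RECOVERY_BASELINE,
        seed=1,
    )
    return DailySeries(df), truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    series, _ = recovery_data
    cfg = AnalysisConfig(factors=("mean_temperature",))
    return run_factor_analysis(series, "mean_temperature", cfg)


@pytest.fixture(scope="session")
def null_data():
    """Sparse series with no exposure effect (study-scale 0.21 cases/day)."""
    df, truth = simulate_dataset(
        n_days=3000, factors=["mean_temperature"], surfaces={}, seed=7
    )
    return DailySeries(df), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
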