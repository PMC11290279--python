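import numpy as np
import pandas as pd
import pytest

from platformsim import build_design, make_scenario, simulate_trial


@pytest.fixture(scope="session")
def design_one():
    return build_design("one")


@pytest.fixture(scope="session")
def null_dataset(design_one):
    """One simulated trial under the global null with no heterogeneity."""
    rng = np.random.default_rng(20240730)
    return simulate_trial(design_one, make_scenario("S0", 1, 0.0), rng)


@pytest.fixture(scope="session")
def hetero_dataset(design_one):
    """One trial with a random cohort effect, heteroscedasticity and a trend."""
    rng = np.random.default_rng(99)
    return simulate_trial(design_one, make_scenario("SA.b", 4, -0.5), rng)


def make_manual_dataset(cell_values: dict) -> pd.DataFrame:
    """Build a dataset from explicit per (arm, stage) outcome lists."""
    rows = []
    for (arm, stage), values in cell_values.items():
        for v in values:
            rows.append((len(rows) + 1, stage, arm if arm != "0" else "A", arm, float(v)))
    return pd.DataFrame(
        rows, columns=["subject_id", "stage", "cohort", "arm", "y"]
    )


@pytest.fixture(scope="session")
def manual_dataset_factory():
    return make_manual_dataset
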