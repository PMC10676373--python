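import numpy as np
import pandas as pd
import pytest

from bloodtrace import CountMatrix, SimConfig, simulate_diagnostic_cohort, simulate_survival


@pytest.fixture(scope="session")
def small_cohort():
    """Diagnostic cohort with planted DE genes and survival outcomes."""
    cfg = SimConfig(n_genes=400, n_samples_per_group=40, frac_de=0.05, seed=101)
    counts, ann, truth = simulate_diagnostic_cohort(cfg)
    ann = simulate_survival(ann, truth, cfg)
    return counts, ann, truth, cfg


@pytest.fixture()
def toy_counts():
    """Hand-sized count matrix with easily enumerable CPMs."""
    df = pd.DataFrame(
        {
            "s1": [0, 10, 100, 5, 885],
            "s2": [0, 20, 50, 0, 930],
            "s3": [0, 0, 80, 10, 910],
        },
        index=[f"g{i}" for i in range(5)],
    )
    return CountMatrix(df)


@pytest.fixture()
def two_group_design():
    n = 6
    return pd.DataFrame(
        {"intercept": np.ones(n), "group": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]},
        index=[f"s{i}" for i in range(n)],
    )
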