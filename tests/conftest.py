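import pandas as pd
import pytest

from driverscape import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort reused by several tests: 20 TSG, 20 OG, 60 passengers,
    80 samples."""
    spec = syn.CohortSpec(n_samples=80, n_tsg=20, n_og=20, n_passenger=60,
                          seed=42)
    return spec, syn.generate_cohort(spec)


@pytest.fixture()
def toy_expression():
    genes = ["G1", "G2"]
    samples = [f"S{i}" for i in range(6)]
    return pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
                        index=genes, columns=samples)
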