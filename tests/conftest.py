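import numpy as np
import pandas as pd
import pytest

from epistate3c import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """A minutes-scale cohort: 3 AD + 2 control donors, 30 cells/sample."""
    return sd.SimConfig(seed=11, n_ad_donors=3, n_control_donors=2, cells_per_sample=30)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    meta, truth = sd.simulate_cohort(small_config)
    return meta, truth


@pytest.fixture(scope="session")
def small_methylome(small_config, small_cohort):
    meta, truth = small_cohort
    return sd.simulate_methylome(meta, truth, small_config)


@pytest.fixture(scope="session")
def small_contacts(small_config, small_cohort):
    meta, truth = small_cohort
    return sd.simulate_contacts(meta, truth, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_cohort_meta(
    n_donors_ad=6, n_donors_ct=6, regions=("VC", "PFC", "TC"), seed=0
) -> pd.DataFrame:
    """Minimal donor-level metadata grid for association tests."""
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_donors_ad + n_donors_ct):
        donor = f"D{i:02d}"
        disease = "AD" if i < n_donors_ad else "Control"
        age = int(r.integers(60, 90))
        sex = "Female" if i % 2 == 0 else "Male"
        for region in regions:
            rows.append(
                {
                    "sample": f"{donor}|{region}",
                    "donor": donor,
                    "disease": disease,
                    "region": region,
                    "age": age,
                    "sex": sex,
                }
            )
    return pd.DataFrame(rows).set_index("sample")
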