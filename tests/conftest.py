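import numpy as np
import pandas as pd
import pytest

from twinmotion.data import TwinDataset
from twinmotion.simulate import GeneratingConfig, preset, simulate_families


def small_ae_config(
    n_mzf=40, n_mzm=0, n_dzf=40, n_dzm=0, n_dzos=0, n_sib=0, n_single=0,
    h2=0.4, var=1.0, mu=0.0, beta_sex=0.0, seed=0,
):
    """Univariate AE generating config on the hm_log column."""
    return GeneratingConfig(
        traits=("hm_log",),
        n_pairs={"MZF": n_mzf, "MZM": n_mzm, "DZF": n_dzf, "DZM": n_dzm,
                 "DZOS": n_dzos, "SIB": n_sib},
        n_singletons=n_single,
        paths={
            "A": np.array([[np.sqrt(h2 * var)]]),
            "E": np.array([[np.sqrt((1 - h2) * var)]]),
        },
        means={"hm_log": mu},
        betas={"hm_log": {"sex": beta_sex}},
        seed=seed,
    )


@pytest.fixture(scope="session")
def hm_cohort():
    """One G-HM cohort reused across read-only tests."""
    return simulate_families(preset("G-HM"), seed=11)


@pytest.fixture(scope="session")
def biv_cohort():
    """One maternal-Inattention bivariate cohort."""
    return simulate_families(preset("G-BIV-MI"), seed=11)


@pytest.fixture()
def tiny_table():
    """Hand-written 3-family table: one MZ pair, one DZ pair with a missing
    value, one singleton."""
    return pd.DataFrame(
        {
            "family_id": ["f1", "f1", "f2", "f2", "f3"],
            "individual_id": ["f1.1", "f1.2", "f2.1", "f2.2", "f3.1"],
            "zygosity": ["MZF", "MZF", "DZM", "DZM", "MZM"],
            "sex": ["F", "F", "M", "M", "M"],
            "birth_order": [1, 2, 1, 2, 1],
            "age_scan": [22.0, 22.0, 25.0, 25.0, 20.0],
            "hm_log": [-2.5, -2.7, -2.4, np.nan, -2.9],
        }
    )


@pytest.fixture()
def tiny_dataset(tiny_table):
    return TwinDataset(tiny_table)
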