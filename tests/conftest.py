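import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cstelo.config import SimConfig
from cstelo import simulate as sim

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_individuals=120, seed=2024)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.make_cohort(small_config)


@pytest.fixture(scope="session")
def small_reads(small_cohort):
    return sim.emit_reads(small_cohort)


@pytest.fixture(scope="session")
def small_truth_table(small_cohort):
    """Noise-free person x arm table restricted to the 39 analysis arms."""
    from cstelo.arms import ANALYSIS_ARMS

    tab = sim.truth_arm_table(small_cohort)
    return tab[tab["arm"].isin(ANALYSIS_ARMS)].reset_index(drop=True)


@pytest.fixture()
def toy_calls() -> pd.DataFrame:
    """Hand-built call table exercising every QC rule."""
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * 5 + ["s2"] * 3,
            "arm": ["7q", "7q", "3p", "13p", "5q", "7q", "3p", "3p"],
            "allele_index": [0, 1, 0, 0, 0, 0, 0, 1],
            "tl_p75": [4000.0, 6000.0, 99.0, 5000.0, 100.0, 3200.0, 101.0, 2000.0],
            "tvr_len": [1200.0, 800.0, 500.0, 300.0, 0.0, 900.0, -1.0, 250.0],
            "n_supporting_reads": [5, 4, 6, 3, 8, 4, 5, 7],
            "mapping_ambiguous": [False, False, False, True, False, False, False, False],
        }
    )


def crossed_dataset(seed, n_ind=30, n_arm=8, s_ind=2.0, s_arm=3.0, s_e=1.5,
                    beta_age=0.3, miss=0.1):
    """Small crossed-design dataset with known variance components."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s_ind), n_ind)
    b = rng.normal(0, np.sqrt(s_arm), n_arm)
    rows = []
    for i in range(n_ind):
        age = rng.normal(45, 12)
        for a in range(n_arm):
            if rng.random() < miss:
                continue
            y = 10 + beta_age * age + u[i] + b[a] + rng.normal(0, np.sqrt(s_e))
            rows.append((f"s{i:03d}", f"arm{a:02d}", age, y))
    return pd.DataFrame(rows, columns=["sample_id", "arm", "age", "cstl_bp"])
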