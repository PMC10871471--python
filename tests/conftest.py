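import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from glucest.phantom import PhantomConfig, make_phantom
from glucest.pipeline import default_calibration
from glucest.simulate import PoolSystem, default_cest_scheme, default_wassr_scheme

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

UNIFORM_REGIONS = ("WM", "GM", "CG", "JLC", "ParaG", "FP", "MFG", "PreG", "PostG")


@pytest.fixture(scope="session")
def pools():
    return PoolSystem()


@pytest.fixture(scope="session")
def cest_scheme():
    return default_cest_scheme()


@pytest.fixture(scope="session")
def wassr_scheme():
    return default_wassr_scheme()


@pytest.fixture(scope="session")
def calibration(pools):
    return default_calibration(pools)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """48x32 noise-free phantom with smooth B0 and kappa fields."""
    return make_phantom(PhantomConfig(shape=(48, 32), noise_sigma=0.0), seed=314)


@pytest.fixture(scope="session")
def trivial_phantom():
    """Unperturbed phantom: B0 = 0, kappa = 1, no noise."""
    return make_phantom(
        PhantomConfig(
            shape=(48, 32), noise_sigma=0.0, b0_amplitude_ppm=0.0,
            kappa_range=(1.0, 1.0),
        ),
        seed=315,
    )


@pytest.fixture(scope="session")
def uniform_kappa_phantom():
    """Uniform glutamate, kappa gradient 0.8-1.2, homogeneous B0, no noise."""
    return make_phantom(
        PhantomConfig(
            shape=(48, 32),
            region_glu_mM={r: 10.0 for r in UNIFORM_REGIONS},
            noise_sigma=0.0,
            b0_amplitude_ppm=0.0,
        ),
        seed=316,
    )


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)


def synthetic_cohort(seed=0, effect=0.0, n_ns=10, n_s=9):
    """Per-subject regional table fixture for the statistics stage."""
    rng = np.random.default_rng(seed)
    rows = []
    regions = (
        "WholeBrain", "GM", "WM", "CG", "JLC", "ParaG", "FP", "MFG", "PreG", "PostG"
    )
    for group, n in (("non-smoker", n_ns), ("smoker", n_s)):
        for i in range(n):
            age = rng.uniform(20, 70)
            gm_frac = rng.uniform(0.55, 0.75)
            for region in regions:
                val = 9.0 + rng.normal(0, 0.5) + (effect if group == "smoker" else 0.0)
                rows.append(
                    dict(
                        subject_id=f"{group[:2]}{i}", group=group, age=age, sex="F",
                        region=region, mean_percent=val,
                        gm_fraction=gm_frac, wm_fraction=1 - gm_frac,
                    )
                )
    return pd.DataFrame(rows)
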