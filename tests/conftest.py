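import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neurokde as nk
from neurokde.simulate import SimCohortConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_tiny_config(p: int = 6, n_per_stratum: int = 100, seed: int = 0,
                     n_factors: int = 2, noise_frac: float = 0.06,
                     slope_frac: float = -0.003, **overrides) -> SimCohortConfig:
    """A reduced-dimension simulator config with simple known parameters."""
    rng = np.random.default_rng(123)
    intercepts = rng.uniform(2000.0, 10000.0, p)
    fields = dict(
        n_per_stratum=n_per_stratum,
        roi_names=[f"ROI{i + 1}" for i in range(p)],
        intercepts=intercepts,
        age_slopes=slope_frac * intercepts,
        noise_sd=noise_frac * intercepts,
        sex_effects=0.08 * intercepts,
        race_effects={
            "White": np.zeros(p),
            "Black": 0.02 * intercepts,
            "Asian": -0.015 * intercepts,
        },
        loadings=(rng.normal(0, 0.04, (p, n_factors)) * intercepts[:, None]
                  if n_factors else None),
        seed=seed,
    )
    fields.update(overrides)
    return SimCohortConfig(**fields)


@pytest.fixture(scope="session")
def small_config():
    """Full-width (145-ROI) default config at a small per-stratum size."""
    return nk.default_config(n_per_stratum=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return nk.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_models(small_cohort):
    """Six stratum KDEs fitted at a fixed bandwidth (grid search elsewhere)."""
    return nk.fit_all_strata(small_cohort, bandwidth=0.7)
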