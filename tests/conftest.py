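import numpy as np
import pandas as pd
import pytest

import mortlink as ml

DEMO_SEED = 20220401


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Small (~5,000 person) end-to-end pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("demo")
    manifest = ml.make_demo_fixture(out, seed=DEMO_SEED)
    return out, manifest


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Default-scale (21,000 person) run through the weighting stage."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = ml.default_config(seed=7, n_per_cohort=1000)
    manifest = ml.run_pipeline(cfg, out, stages=("generate", "link", "weight"))
    return out, cfg, manifest


@pytest.fixture(scope="session")
def clean_linked_world():
    """Noise-free population with unique name keys, a numident-like register and
    its census — the setting where linkage must be perfect."""
    spec = ml.PopulationSpec(
        cohort_range=(1900, 1920),
        cohort_sizes=500,
        seed=11,
        unique_names=True,
        n_first_names=20000,
    )
    pop = ml.generate_population(spec)
    pop = ml.simulate_mortality(pop, ml.GompertzParams(), seed=11)
    census = ml.build_census_file(pop)
    rspec = ml.RegisterSpec(kind="numident-like", window=(1988, 2005), p_in=1.0, p_out=0.0)
    register, truth = ml.build_death_register(pop, rspec, ml.NoiseSpec(), seed=11)
    return {"pop": pop, "census": census, "register": register, "truth": truth, "window": (1988, 2005)}


def simulate_truncated(
    seed: int,
    n_obs: int,
    a: float = 3.34e-5,
    b: float = 0.1,
    hr_per_unit: float = 0.96,
    cohorts: tuple[int, int] = (1906, 1920),
    window: tuple[int, int] = (1975, 2005),
    min_age: float = 65.0,
    max_age: float = 100.0,
    return_full: bool = False,
):
    """Continuous-age doubly-truncated draws for estimation tests.

    Education is uniform on 0..17; observation requires min_age <= T < the
    cohort's window-implied right bound.  Returns a TruncatedSample of the
    first ``n_obs`` observed records (and optionally the full untruncated
    arrays for attenuation comparisons).
    """
    from mortlink.gompertz import GompertzParams, sample_death_ages
    from mortlink.mortality import TruncatedSample, truncation_window

    rng = np.random.default_rng(seed)
    beta = np.log(hr_per_unit)
    n_sim = int(n_obs / 0.5) + 2000  # generous headroom for the observation rate
    edu = rng.integers(0, 18, size=n_sim).astype(float)
    byear = rng.integers(cohorts[0], cohorts[1] + 1, size=n_sim)
    ages = sample_death_ages(GompertzParams(a=a, b=b), beta * edu, rng, size=n_sim)
    x_l, x_r = truncation_window(byear, window, min_age=min_age, max_age=max_age)
    keep = np.flatnonzero((ages >= x_l) & (ages < x_r))[:n_obs]
    sample = TruncatedSample(
        x=ages[keep], x_l=x_l[keep], x_r=x_r[keep],
        Z=edu[keep], covariate_names=("education_years",), cohort=byear[keep],
    )
    if return_full:
        full = pd.DataFrame({"death_age": ages, "education_years": edu, "byear": byear})
        trunc = full.iloc[keep]
        return sample, full, trunc
    return sample
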