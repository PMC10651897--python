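import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mortlink as ml
from mortlink.errors import ConfigError
from mortlink.gompertz import GompertzParams, cum_hazard, sample_death_ages, survival
from mortlink.synthetic import (
    ABROAD,
    NoiseSpec,
    PopulationSpec,
    RegisterSpec,
    build_census_file,
    build_death_register,
    build_reference_totals,
    completed_age_at_death,
    completed_age_on_day,
    generate_population,
    simulate_mortality,
)


def small_spec(**kw):
    defaults = dict(cohort_range=(1900, 1905), cohort_sizes=300, seed=5)
    defaults.update(kw)
    return PopulationSpec(**defaults)


class TestGeneratePopulation:
    def test_count_is_sum_of_cohort_sizes(self):
        spec = PopulationSpec(cohort_range=(1900, 1920), cohort_sizes=1000, seed=0)
        pop = generate_population(spec)
        assert len(pop) == 21_000

    def test_same_seed_same_tables(self):
        spec = small_spec(seed=42)
        pd.testing.assert_frame_equal(generate_population(spec), generate_population(PopulationSpec(**{**spec.__dict__})))

    def test_histid_unique(self):
        pop = generate_population(small_spec())
        assert pop["histid"].is_unique

    def test_race_shares_within_three_binomial_sd(self):
        n = 100_000
        spec = PopulationSpec(cohort_range=(1900, 1900), cohort_sizes=n, seed=9)
        pop = generate_population(spec)
        for race, p in (("White", 0.899), ("Black", 0.096), ("Other", 0.005)):
            share = (pop["race"] == race).mean()
            assert abs(share - p) <= 3 * np.sqrt(p * (1 - p) / n)

    @pytest.mark.parametrize(
        "kw, fieldname",
        [
            (dict(race_dist={"White": 0.5, "Black": 0.4}), "race_dist"),
            (dict(cohort_sizes=0), "cohort_sizes"),
            (dict(n_first_names=0), "n_first_names"),
            (dict(sex_dist={"M": -0.5, "F": 1.5}), "sex_dist"),
            (dict(cohort_range=(1920, 1900)), "cohort_range"),
        ],
    )
    def test_invalid_spec_names_field(self, kw, fieldname):
        with pytest.raises(ConfigError, match=fieldname):
            small_spec(**kw)


class TestSimulateMortality:
    def test_cumulative_hazard_zero_at_zero(self):
        params = GompertzParams()
        for eta in (-1.0, 0.0, 2.0):
            assert cum_hazard(0.0, params, eta) == 0.0

    def test_death_strictly_after_birth(self):
        pop = simulate_mortality(generate_population(small_spec()), GompertzParams(), seed=5)
        assert (pop["true_death_age"] > 0).all()

    def test_survival_at_70_matches_closed_form(self):
        n = 200_000
        params = GompertzParams()
        rng = np.random.default_rng(123)
        ages = sample_death_ages(params, 0.0, rng, size=n)
        s_true = np.exp(-(params.a / params.b) * np.expm1(params.b * 70))
        s_hat = (ages > 70).mean()
        assert abs(s_hat - s_true) <= 3 * np.sqrt(s_true * (1 - s_true) / n)

    def test_proportional_hazards_squares_survival(self):
        # doubling e^{bz} doubles H(x), so S_high(x) = S_low(x)^2 pointwise
        n = 100_000
        params = GompertzParams()
        rng = np.random.default_rng(7)
        low = sample_death_ages(params, 0.0, rng, size=n)
        high = sample_death_ages(params, np.log(2.0), rng, size=n)
        for x in (60.0, 70.0, 80.0):
            s_lo = (low > x).mean()
            s_hi = (high > x).mean()
            sd = np.sqrt(s_hi * (1 - s_hi) / n + (2 * s_lo) ** 2 * s_lo * (1 - s_lo) / n)
            assert abs(s_hi - s_lo**2) <= 3 * sd + 1e-12

    def test_ks_against_closed_form_cdf(self):
        n = 100_000
        params = GompertzParams()
        rng = np.random.default_rng(77)
        ages = sample_death_ages(params, 0.0, rng, size=n)
        stat = stats.kstest(ages, lambda x: -np.expm1(-(params.a / params.b) * np.expm1(params.b * x))).statistic
        assert stat < 1.628 / np.sqrt(n)  # 1% critical value


class TestCensusFile:
    def _tiny_pop(self, bmonth, death_age):
        return pd.DataFrame(
            {
                "histid": ["H1"],
                "first_key": ["F"],
                "last_key": ["L"],
                "father_last_key": ["L"],
                "death_last_key": ["L"],
                "middle_initial": ["A"],
                "sex": ["M"],
                "race": ["White"],
                "birth_state": ["S01"],
                "education_years": [8],
                "marital_status": ["married"],
                "byear": [1905],
                "bmonth": [bmonth],
                "immigrated_pre_census": [False],
                "true_eta": [0.0],
                "true_death_age": [float(death_age)],
                "true_dyear": [0],
                "true_dmonth": [1],
            }
        )

    def test_pre_census_death_excluded(self):
        # born April 1905, dead ~March 1940 (age 34.9) -> not enumerated
        pop = self._tiny_pop(bmonth=4, death_age=34.9)
        assert len(build_census_file(pop)) == 0

    def test_april_birthday_not_yet_reached(self):
        assert completed_age_on_day(1905, 4, 1940, 4, 1) == 34
        assert completed_age_on_day(1905, 3, 1940, 4, 1) == 35
        pop = self._tiny_pop(bmonth=4, death_age=40.0)
        assert build_census_file(pop)["census_age"].iloc[0] == 34

    def test_conservation(self):
        pop = simulate_mortality(generate_population(small_spec(seed=2)), GompertzParams(), seed=2)
        census = build_census_file(pop)
        census_time = 1940 + 3 / 12
        from mortlink.synthetic import birth_time

        pre_census_deaths = (birth_time(pop["byear"], pop["bmonth"]) + pop["true_death_age"] <= census_time).sum()
        assert len(census) + pre_census_deaths == len(pop)

    def test_no_death_columns(self):
        pop = simulate_mortality(generate_population(small_spec()), GompertzParams(), seed=5)
        census = build_census_file(pop)
        assert not any(c.startswith("true_") for c in census.columns)


@pytest.fixture(scope="module")
def register_pop():
    spec = PopulationSpec(cohort_range=(1900, 1910), cohort_sizes=5000, seed=13)
    return simulate_mortality(generate_population(spec), GompertzParams(), seed=13)


@pytest.fixture(scope="module")
def totals_pop():
    spec = PopulationSpec(cohort_range=(1900, 1905), cohort_sizes=2000, seed=31)
    return simulate_mortality(generate_population(spec), GompertzParams(), seed=31)


class TestDeathRegister:
    @pytest.fixture()
    def pop(self, register_pop):
        return register_pop

    def test_full_in_window_coverage(self, pop):
        spec = RegisterSpec(kind="dmf-like", window=(1975, 2005), p_in=1.0, p_out=0.0)
        reg, truth = build_death_register(pop, spec, seed=1)
        expected = pop[pop["true_dyear"].between(1975, 2005)]
        assert len(reg) == len(expected)
        assert set(truth["histid"]) == set(expected["histid"])

    def test_truth_map_injective(self, pop):
        spec = RegisterSpec(kind="numident-like", window=(1988, 2005), p_in=0.9, p_out=0.1)
        _, truth = build_death_register(pop, spec, seed=2)
        assert truth["histid"].is_unique and truth["rec_id"].is_unique

    def test_zero_noise_keys_match_population(self, pop):
        spec = RegisterSpec(kind="numident-like", window=(1988, 2005), p_in=1.0, p_out=0.0)
        reg, truth = build_death_register(pop, spec, NoiseSpec(), seed=3)
        merged = truth.merge(reg, on="rec_id").merge(pop, on="histid", suffixes=("_reg", ""))
        assert (merged["first_key_reg"] == merged["first_key"]).all()
        assert (merged["last_key_reg"] == merged["death_last_key"]).all()
        assert (merged["byear_reg"] == merged["byear"]).all()

    def test_inclusion_rate_within_three_binomial_sd(self):
        spec = PopulationSpec(cohort_range=(1900, 1909), cohort_sizes=5000, seed=21)
        pop = simulate_mortality(generate_population(spec), GompertzParams(), seed=21)
        p_in = 0.96
        rspec = RegisterSpec(kind="dmf-like", window=(1960, 2010), p_in=p_in, p_out=0.0)
        reg, _ = build_death_register(pop, rspec, seed=21)
        n_window = int(pop["true_dyear"].between(1960, 2010).sum())
        assert n_window >= 45_000
        share = len(reg) / n_window
        assert abs(share - p_in) <= 3 * np.sqrt(p_in * (1 - p_in) / n_window)

    def test_register_kind_fields(self, pop):
        num = RegisterSpec(kind="numident-like", window=(1988, 2005), p_in=1.0, p_out=0.0)
        dmf = RegisterSpec(kind="dmf-like", window=(1975, 2005), p_in=1.0, p_out=0.0)
        reg_n, _ = build_death_register(pop, num, seed=4)
        reg_d, _ = build_death_register(pop, dmf, seed=4)
        assert {"sex", "bpl", "father_last_key"} <= set(reg_n.columns)
        assert {"sex", "bpl", "father_last_key"}.isdisjoint(reg_d.columns)

    def test_age_misstatement_shifts_death_age(self, pop):
        spec = RegisterSpec(kind="dmf-like", window=(1975, 2005), p_in=1.0, p_out=0.0)
        noise = NoiseSpec(age_misstatement_dist={-2: 0.5, 2: 0.5})
        reg, truth = build_death_register(pop, spec, noise, seed=5)
        merged = truth.merge(reg, on="rec_id").merge(pop, on="histid", suffixes=("_reg", ""))
        assert set((merged["byear_reg"] - merged["byear"]).unique()) == {-2, 2}


class TestReferenceTotals:
    @pytest.fixture()
    def pop(self, totals_pop):
        return totals_pop

    def test_conservation(self, pop):
        totals = build_reference_totals(pop, years=(1970, 2000))
        n_true = int(pop["true_dyear"].between(1970, 2000).sum())
        assert totals["n_deaths"].sum() == n_true

    def test_suppression_collapses_cells_total_unchanged(self, pop):
        base = build_reference_totals(pop, years=(1970, 2000))
        supp = build_reference_totals(pop, years=(1970, 2000), suppress_bstate_before=1985)
        assert supp["n_deaths"].sum() == base["n_deaths"].sum()
        assert (supp.loc[supp["dyear"] < 1985, "bstate"] == "").all()
        assert len(supp) < len(base)

    def test_entrant_inflation_leaves_native_cells(self, pop):
        base = build_reference_totals(pop, years=(1970, 2000))
        inflated = build_reference_totals(pop, years=(1970, 2000), foreign_entrant_inflation=0.10)
        for df in (base, inflated):
            df.sort_values(list(df.columns), inplace=True, ignore_index=True)
        native = base["bstate"] != ABROAD
        pd.testing.assert_frame_equal(base[native], inflated[native])
        assert inflated.loc[~native, "n_deaths"].sum() >= base.loc[~native, "n_deaths"].sum()


def test_completed_age_at_death_month_arithmetic():
    assert completed_age_at_death(1905, 6, 1975, 6) == 70
    assert completed_age_at_death(1905, 6, 1975, 5) == 69
    assert completed_age_at_death(1905, 6, 1975, 7) == 70
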