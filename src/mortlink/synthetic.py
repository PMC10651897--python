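"""Synthetic census-day population, mortality simulation, death registers and
reference death tallies.

Everything downstream (linkage, weighting, estimation) is exercised against the
tables produced here.  Names are opaque pool keys — linkage behaviour depends
only on key equality and collision structure, so realistic strings add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigError
from .gompertz import GompertzParams, sample_death_ages

#: 48 contiguous states + DC (native codes) and one foreign-birth category.
NATIVE_STATES: tuple[str, ...] = tuple(f"S{i:02d}" for i in range(1, 49)) + ("DC",)
ABROAD = "ABROAD"
STATE_LEVELS: tuple[str, ...] = NATIVE_STATES + (ABROAD,)

MARITAL_LEVELS = ("married", "never_married", "widowed", "divorced")
RACE_LEVELS = ("White", "Black", "Other")
SEX_LEVELS = ("M", "F")

_INITIALS = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

#: Census-day convention used throughout (year, month, day).
CENSUS_DAY = (1940, 4, 1)


def _default_education_dist() -> dict[int, float]:
    # Rough early-20th-century schooling shape: mass at grade 8 and 12,
    # thin college tail, support 0..21.
    raw = np.array(
        [1, 1, 2, 3, 4, 5, 6, 8, 22, 6, 6, 5, 18, 2, 2, 2, 4, 1, 0.6, 0.4, 0.3, 0.2],
        dtype=float,
    )
    p = raw / raw.sum()
    return {k: float(v) for k, v in enumerate(p)}


def _default_birth_state_dist() -> dict[str, float]:
    p_native = 0.95 / len(NATIVE_STATES)
    dist = {s: p_native for s in NATIVE_STATES}
    dist[ABROAD] = 0.05
    return dist


def _check_dist(name: str, dist: Mapping, tol: float = 1e-9) -> None:
    if not dist:
        raise ConfigError(f"{name}: distribution is empty")
    probs = np.array(list(dist.values()), dtype=float)
    if (probs < 0).any():
        raise ConfigError(f"{name}: negative probability")
    if abs(probs.sum() - 1.0) > tol:
        raise ConfigError(f"{name}: probabilities sum to {probs.sum():.12f}, not 1")


@dataclass
class PopulationSpec:
    """Configuration for a census-day population draw.

    ``cohort_sizes`` is either a single per-cohort count or a mapping
    ``birth year -> count`` covering ``cohort_range`` (inclusive).  Foreign-born
    persons are generated already restricted to pre-census-day immigrants: a
    person born abroad who never moved to the contiguous U.S. before census day
    would be unobservable in every downstream table, so they are never drawn.
    """

    cohort_range: tuple[int, int] = (1900, 1920)
    cohort_sizes: int | Mapping[int, int] = 1000
    sex_dist: Mapping[str, float] = field(default_factory=lambda: {"M": 0.5, "F": 0.5})
    race_dist: Mapping[str, float] = field(default_factory=lambda: {"White": 0.899, "Black": 0.096, "Other": 0.005})
    birth_state_dist: Mapping[str, float] = field(default_factory=_default_birth_state_dist)
    education_dist: Mapping[int, float] = field(default_factory=_default_education_dist)
    marital_dist: Mapping[str, float] = field(
        default_factory=lambda: {"married": 0.55, "never_married": 0.35, "widowed": 0.06, "divorced": 0.04}
    )
    n_first_names: int = 5000
    n_last_names: int = 5000
    #: draw first-name keys without replacement, guaranteeing unique match keys
    unique_names: bool = False
    #: probability a never-married woman takes a new surname before death
    p_marry_after_census: float = 0.0
    #: probability an ever-married woman changes surname again before death
    p_remarry_after_census: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cohort_range
        if lo > hi:
            raise ConfigError(f"cohort_range: start {lo} exceeds end {hi}")
        sizes = self.sizes_by_cohort()
        for year, n in sizes.items():
            if n <= 0:
                raise ConfigError(f"cohort_sizes: size for cohort {year} must be > 0, got {n}")
        for name in ("sex_dist", "race_dist", "birth_state_dist", "education_dist", "marital_dist"):
            _check_dist(name, getattr(self, name))
        if self.n_first_names <= 0 or self.n_last_names <= 0:
            raise ConfigError("n_first_names/n_last_names: name pools must be non-empty")
        total = sum(sizes.values())
        if self.unique_names and self.n_first_names < total:
            raise ConfigError(
                f"n_first_names: unique_names requires a pool >= population size ({self.n_first_names} < {total})"
            )
        for name in ("p_marry_after_census", "p_remarry_after_census"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")

    def sizes_by_cohort(self) -> dict[int, int]:
        lo, hi = self.cohort_range
        years = range(lo, hi + 1)
        if isinstance(self.cohort_sizes, Mapping):
            missing = [y for y in years if y not in self.cohort_sizes]
            if missing:
                raise ConfigError(f"cohort_sizes: missing cohorts {missing}")
            return {y: int(self.cohort_sizes[y]) for y in years}
        return {y: int(self.cohort_sizes) for y in years}


@dataclass
class CovariateEffect:
    """Log hazard ratios per covariate.

    ``betas`` maps a column name either to a per-unit coefficient (numeric
    column) or to a ``level -> coefficient`` mapping (categorical column);
    unmapped levels contribute 0.
    """

    betas: Mapping[str, float | Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, b in self.betas.items():
            vals = list(b.values()) if isinstance(b, Mapping) else [b]
            if not all(np.isfinite(v) for v in vals):
                raise ConfigError(f"CovariateEffect: non-finite beta for {col!r}")

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.zeros(len(df))
        for col, b in self.betas.items():
            if isinstance(b, Mapping):
                eta += df[col].map(b).fillna(0.0).to_numpy(dtype=float)
            else:
                eta += float(b) * df[col].to_numpy(dtype=float)
        return eta


@dataclass
class RegisterSpec:
    """A death register's coverage window, sampling rates and emitted fields."""

    kind: str  # "numident-like" | "dmf-like"
    window: tuple[int, int]
    p_in: float = 0.95
    p_out: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("numident-like", "dmf-like"):
            raise ConfigError(f"kind: must be 'numident-like' or 'dmf-like', got {self.kind!r}")
        if self.window[0] > self.window[1]:
            raise ConfigError(f"window: start {self.window[0]} exceeds end {self.window[1]}")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ConfigError(f"p_in/p_out: need 0 <= p_out < p_in <= 1, got ({self.p_in}, {self.p_out})")


@dataclass
class NoiseSpec:
    """Perturbations applied when emitting register (and census) name keys."""

    name_typo_rate: float = 0.0
    nickname_swap_rate: float = 0.0
    age_misstatement_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    duplicate_key_rate: float = 0.0
    middle_initial_missing_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("name_typo_rate", "nickname_swap_rate", "duplicate_key_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        for src, v in self.middle_initial_missing_rates.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"middle_initial_missing_rates[{src!r}]: must be in [0, 1], got {v}")
        _check_dist("age_misstatement_dist", self.age_misstatement_dist)
        if any(int(d) not in (-2, -1, 0, 1, 2) for d in self.age_misstatement_dist):
            raise ConfigError("age_misstatement_dist: support must be within {-2..+2}")


# ---------------------------------------------------------------------------
# date helpers (month granularity; birth placed mid-month)

def birth_time(byear, bmonth):
    """Continuous birth time, mid-month convention."""
    return np.asarray(byear, dtype=float) + (np.asarray(bmonth, dtype=float) - 0.5) / 12.0


def death_date_from_age(byear, bmonth, exact_age):
    """(dyear, dmonth) of the calendar month containing birth_time + exact_age."""
    t = birth_time(byear, bmonth) + np.asarray(exact_age, dtype=float)
    dyear = np.floor(t).astype(int)
    dmonth = np.minimum(12, (np.floor((t - dyear) * 12).astype(int) + 1))
    return dyear, dmonth


def completed_age_at_death(byear, bmonth, dyear, dmonth):
    """Age in completed years at a month-dated death.

    Day of month is unknown, so a death in the birthday month counts the
    birthday as reached (mid-month convention on both dates).
    """
    return np.asarray(dyear) - np.asarray(byear) - (np.asarray(dmonth) < np.asarray(bmonth)).astype(int)


def completed_age_on_day(byear, bmonth, year, month, day=1):
    """Age in completed years on an exact calendar day (e.g. census day).

    With day-of-birth unknown, birthdays falling in the reference month are
    treated as not yet reached when the reference day is the 1st.
    """
    not_yet = (np.asarray(bmonth) > month) | ((np.asarray(bmonth) == month) & (day <= 28))
    return year - np.asarray(byear) - not_yet.astype(int)


# ---------------------------------------------------------------------------
# operations

def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a population of PersonRecord rows per ``spec`` (no death dates yet).

    Surname mechanics: every person has a family (father's) surname.  Men and
    never-married women carry it as their census surname.  Ever-married women
    carry a husband's surname in the census.  ``death_last_key`` is the surname
    that will appear on a death register, reflecting marriages after census
    day; it is generation truth, dropped from the census table.
    """
    sizes = spec.sizes_by_cohort()
    n = sum(sizes.values())
    rng = substream(spec.seed, "population")

    byear = np.repeat(list(sizes.keys()), list(sizes.values()))
    bmonth = rng.integers(1, 13, size=n)

    def draw(dist: Mapping) -> np.ndarray:
        levels = list(dist.keys())
        p = np.array(list(dist.values()), dtype=float)
        return rng.choice(levels, p=p / p.sum(), size=n)

    sex = draw(spec.sex_dist)
    race = draw(spec.race_dist)
    birth_state = draw(spec.birth_state_dist)
    education = draw(spec.education_dist).astype(int)
    marital = draw(spec.marital_dist)

    first_pool = np.array([f"F{i:06d}" for i in range(spec.n_first_names)])
    last_pool = np.array([f"L{i:06d}" for i in range(spec.n_last_names)])
    if spec.unique_names:
        first = first_pool[rng.permutation(spec.n_first_names)[:n]]
    else:
        first = first_pool[rng.integers(0, spec.n_first_names, size=n)]
    father_last = last_pool[rng.integers(0, spec.n_last_names, size=n)]

    last = father_last.copy()
    death_last = father_last.copy()
    women = sex == "F"
    ever_married = women & np.isin(marital, ["married", "widowed", "divorced"])
    husband = last_pool[rng.integers(0, spec.n_last_names, size=n)]
    last[ever_married] = husband[ever_married]
    death_last[ever_married] = husband[ever_married]

    # surname changes after census day (these break linkage by construction)
    new_name = last_pool[rng.integers(0, spec.n_last_names, size=n)]
    u = rng.random(n)
    never_marries_later = women & (marital == "never_married") & (u < spec.p_marry_after_census)
    remarries_later = ever_married & (u < spec.p_remarry_after_census)
    death_last[never_marries_later | remarries_later] = new_name[never_marries_later | remarries_later]

    middle_initial = rng.choice(_INITIALS, size=n)

    pop = pd.DataFrame(
        {
            "histid": [f"H{i:07d}" for i in range(n)],
            "first_key": first,
            "last_key": last,
            "father_last_key": father_last,
            "death_last_key": death_last,
            "middle_initial": middle_initial,
            "sex": sex,
            "race": race,
            "birth_state": birth_state,
            "education_years": education,
            "marital_status": marital,
            "byear": byear.astype(int),
            "bmonth": bmonth.astype(int),
        }
    )
    pop["immigrated_pre_census"] = pop["birth_state"] == ABROAD
    return pop


def simulate_mortality(
    pop: pd.DataFrame,
    params: GompertzParams,
    effect: CovariateEffect | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a true death date to every person via the Gompertz PH law.

    Death ages are drawn by inverse-CDF sampling from the hazard
    ``a e^{bx} e^{beta Z}``; the continuous age is kept in
    ``true_death_age`` and the month-dated calendar death in
    ``true_dyear``/``true_dmonth``.
    """
    rng = substream(seed, "mortality")
    effect = effect or CovariateEffect()
    eta = effect.linear_predictor(pop)
    ages = sample_death_ages(params, eta, rng, size=len(pop))
    out = pop.copy()
    out["true_eta"] = eta
    out["true_death_age"] = ages
    dyear, dmonth = death_date_from_age(out["byear"].to_numpy(), out["bmonth"].to_numpy(), ages)
    out["true_dyear"] = dyear
    out["true_dmonth"] = dmonth
    return out


def build_census_file(
    pop: pd.DataFrame,
    census_day: tuple[int, int, int] = CENSUS_DAY,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Census table: persons alive on census day, integer age, no death fields."""
    cy, cm, cd = census_day
    census_time = cy + (cm - 1) / 12.0 + (cd - 1) / 365.25
    alive = birth_time(pop["byear"], pop["bmonth"]) + pop["true_death_age"].to_numpy() > census_time
    census = pop.loc[alive].copy()
    census["census_age"] = completed_age_on_day(
        census["byear"].to_numpy(), census["bmonth"].to_numpy(), cy, cm, cd
    )
    if noise is not None:
        miss = noise.middle_initial_missing_rates.get("census", 0.0)
        if miss > 0:
            rng = substream(seed, "census-noise")
            census.loc[rng.random(len(census)) < miss, "middle_initial"] = ""
    drop = ["father_last_key", "death_last_key", "true_eta", "true_death_age", "true_dyear", "true_dmonth"]
    return census.drop(columns=[c for c in drop if c in census]).reset_index(drop=True)


def build_death_register(
    pop: pd.DataFrame,
    spec: RegisterSpec,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a death register and its evaluation truth map.

    Decedents enter independently with probability ``p_in`` when the death
    year falls in the coverage window, else ``p_out``.  Register rows carry no
    histid; the returned ``(register, truth_map)`` pair keeps the mapping
    separate so linkage has to earn it.
    """
    rng = substream(seed, f"register-{spec.kind}")
    noise = noise or NoiseSpec()

    dyear = pop["true_dyear"].to_numpy()
    in_window = (dyear >= spec.window[0]) & (dyear <= spec.window[1])
    p = np.where(in_window, spec.p_in, spec.p_out)
    take = rng.random(len(pop)) < p
    reg = pop.loc[take].copy().reset_index(drop=True)
    m = len(reg)

    prefix = "N" if spec.kind == "numident-like" else "D"
    rec_id = np.array([f"{prefix}{i:07d}" for i in range(m)])

    byear = reg["byear"].to_numpy().copy()
    bmonth = reg["bmonth"].to_numpy()
    first = reg["first_key"].to_numpy().copy()
    last = reg["death_last_key"].to_numpy().copy()
    father_last = reg["father_last_key"].to_numpy().copy()
    initial = reg["middle_initial"].to_numpy(dtype=object).copy()
    bpl = reg["birth_state"].to_numpy().copy()

    # birth-year misstatement (propagates into register death ages)
    deltas = np.array(sorted(noise.age_misstatement_dist), dtype=int)
    probs = np.array([noise.age_misstatement_dist[int(d)] for d in deltas], dtype=float)
    if len(deltas) > 1 or deltas[0] != 0:
        byear = byear + rng.choice(deltas, p=probs / probs.sum(), size=m)

    # typo = resample to a fresh, never-used key
    for arr, tag in ((first, "first"), (last, "last")):
        hit = np.flatnonzero(rng.random(m) < noise.name_typo_rate)
        arr[hit] = [f"X{tag[0].upper()}{seed}_{i}" for i in hit]

    # nickname swap: emit the aliased form of the canonical key
    hit = rng.random(m) < noise.nickname_swap_rate
    first[hit] = np.char.add("NICK:", first[hit].astype(str))

    # full-key collision: copy another register row's match keys
    hit = np.flatnonzero(rng.random(m) < noise.duplicate_key_rate)
    if len(hit) and m > 1:
        src = rng.integers(0, m, size=len(hit))
        src = np.where(src == hit, (src + 1) % m, src)
        for arr in (first, last, father_last, bpl):
            arr[hit] = arr[src]
        byear[hit] = byear[src]

    miss = noise.middle_initial_missing_rates.get(spec.kind, 0.0)
    if miss > 0:
        initial[rng.random(m) < miss] = ""

    out = pd.DataFrame(
        {
            "rec_id": rec_id,
            "first_key": first,
            "last_key": last,
            "middle_initial": initial,
            "byear": byear,
            "bmonth": bmonth,
            "dyear": reg["true_dyear"].to_numpy(),
            "dmonth": reg["true_dmonth"].to_numpy(),
        }
    )
    out["death_age"] = completed_age_at_death(out["byear"], out["bmonth"], out["dyear"], out["dmonth"])
    if spec.kind == "numident-like":
        out["sex"] = reg["sex"].to_numpy()
        out["bpl"] = bpl
        out["father_last_key"] = father_last

    truth = pd.DataFrame({"histid": reg["histid"].to_numpy(), "rec_id": rec_id})
    return out, truth


REFERENCE_DIMS = ("dyear", "death_age", "sex", "race", "bstate")


def build_reference_totals(
    pop: pd.DataFrame,
    dims: tuple[str, ...] = REFERENCE_DIMS,
    years: tuple[int, int] | None = None,
    suppress_bstate_before: int | None = None,
    foreign_entrant_inflation: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete tabulation of true deaths by the requested cells.

    ``suppress_bstate_before`` blanks the birth state for death years before
    the cutoff (mimicking reference data without birthplace in early years).
    ``foreign_entrant_inflation`` multiplies foreign-born cell counts by
    ``1 + rate`` (rounded), mimicking reference tallies that include decedents
    who entered the country after census day.
    """
    bad = set(dims) - set(REFERENCE_DIMS)
    if bad:
        raise ConfigError(f"dims: unknown dimensions {sorted(bad)}")
    deaths = pd.DataFrame(
        {
            "dyear": pop["true_dyear"].to_numpy(),
            "death_age": completed_age_at_death(
                pop["byear"], pop["bmonth"], pop["true_dyear"], pop["true_dmonth"]
            ),
            "sex": pop["sex"].to_numpy(),
            "race": pop["race"].to_numpy(),
            "bstate": pop["birth_state"].to_numpy(),
        }
    )
    if years is not None:
        deaths = deaths[(deaths["dyear"] >= years[0]) & (deaths["dyear"] <= years[1])]
    if suppress_bstate_before is not None and "bstate" in dims:
        deaths.loc[deaths["dyear"] < suppress_bstate_before, "bstate"] = ""
    totals = deaths.groupby(list(dims), as_index=False).size().rename(columns={"size": "n_deaths"})
    if foreign_entrant_inflation and "bstate" in dims:
        foreign = totals["bstate"] == ABROAD
        totals.loc[foreign, "n_deaths"] = np.rint(
            totals.loc[foreign, "n_deaths"] * (1.0 + foreign_entrant_inflation)
        ).astype(int)
    return totals
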