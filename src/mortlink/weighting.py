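"""Post-stratification weights: ratio weights per death-year/age/sex/race/birth-state
cell, fallback rules for records outside the weightable universe, and calibration
by iterative raking with trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InfeasibleMarginError, SchemaError
from .synthetic import ABROAD

CELL_DIMS = ("dyear", "death_age", "sex", "race", "bstate")

#: weight_rule codes, in application order
RULE_CELL = "cell"              # direct ratio weight
RULE_PRECUTOFF = "precutoff"    # pre-birthplace-cutoff years borrow the cutoff year's weight
RULE_FOREIGN = "foreign_mean"   # foreign-born take the native mean of their (y,a,s,r) cell
RULE_STRATUM = "stratum_mean"   # residual records take the native mean of their (y,a,s,r) cell
RULE_ONE = "one"                # last resort


@dataclass(frozen=True)
class WeightingUniverse:
    """Records weighted directly: native-born, died in ``age_range`` (inclusive),
    death year inside the register's high-coverage window."""

    window: tuple[int, int]
    age_range: tuple[int, int] = (65, 100)
    foreign_codes: tuple[str, ...] = (ABROAD,)

    def mask(self, df: pd.DataFrame) -> pd.Series:
        native = ~df["bstate"].isin(self.foreign_codes)
        in_age = df["death_age"].between(*self.age_range)
        in_window = df["dyear"].between(*self.window)
        return native & in_age & in_window


@dataclass
class MarginSpec:
    """One raking dimension: target totals per level and a relative tolerance."""

    dimension: str
    targets: Mapping[Any, float]
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.targets.values()):
            raise ConfigError(f"MarginSpec[{self.dimension}]: negative target")


@dataclass
class WeightDiagnostics:
    coverage_ratio: float
    share_above_ceiling: float
    rounds: int
    rake_iterations: int
    max_margin_rel_error: dict = field(default_factory=dict)
    converged: bool = True
    n_by_rule: dict = field(default_factory=dict)


def compute_cell_weights(
    linked: pd.DataFrame,
    totals: pd.DataFrame,
    dims: Sequence[str] = CELL_DIMS,
    universe: WeightingUniverse | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ratio weights: target deaths over sample deaths per cell.

    Returns the linked table with ``weight``/``weight_rule`` columns (NaN /
    empty where no direct weight applies — fallback rules handle those) and
    the cell table with target count, sample count and the ratio.
    """
    dims = list(dims)
    missing = [c for c in dims if c not in linked.columns]
    if missing:
        raise SchemaError(f"linked table is missing weighting dimensions: {missing}")

    out = linked.copy()
    in_univ = universe.mask(out) if universe is not None else pd.Series(True, index=out.index)

    sample = (
        out.loc[in_univ].groupby(dims, as_index=False).size().rename(columns={"size": "n_sample"})
    )
    cells = totals.merge(sample, on=dims, how="outer")
    cells["n_target"] = cells["n_deaths"].fillna(0).astype(int)
    cells["n_sample"] = cells["n_sample"].fillna(0).astype(int)
    cells = cells.drop(columns=["n_deaths"])
    cells["w"] = np.where(cells["n_sample"] > 0, cells["n_target"] / cells["n_sample"].replace(0, 1), np.nan)
    cells.loc[cells["n_sample"] == 0, "w"] = np.nan

    merged = out.merge(cells[dims + ["w"]], on=dims, how="left")
    out["weight"] = np.where(in_univ.to_numpy(), merged["w"].to_numpy(), np.nan)
    # a populated sample cell absent from the totals has target 0 -> weight 0;
    # treat as unweightable and leave to fallback
    out.loc[out["weight"] <= 0, "weight"] = np.nan
    out["weight_rule"] = np.where(out["weight"].notna(), RULE_CELL, "")
    return out, cells


def assign_fallback_weights(
    linked: pd.DataFrame,
    cells: pd.DataFrame,
    universe: WeightingUniverse,
    cutoff_year: int | None = None,
    include_sex_in_precutoff: bool = False,
) -> pd.DataFrame:
    """Complete the weights for records the cell ratios could not cover.

    Applied in order: (i) deaths before ``cutoff_year`` (no birthplace in the
    reference data) borrow the cutoff year's weight for their age/race/birth-state
    stratum (sex excluded by default, switchable); (ii) foreign-born records take
    the mean weight of directly-weighted native records sharing death year, age,
    race and sex; (iii) remaining records take the same native stratum mean;
    (iv) whatever is left gets weight 1.  Every record ends strictly positive.
    """
    out = linked.copy()
    unweighted = out["weight"].isna()

    # (i) pre-cutoff years
    if cutoff_year is not None:
        strata = ["death_age", "race", "bstate"] + (["sex"] if include_sex_in_precutoff else [])
        ref = cells[(cells["dyear"] == cutoff_year) & cells["w"].notna()]
        lut = ref.groupby(strata)["w"].mean()
        pre = unweighted & (out["dyear"] < cutoff_year) & (out["dyear"] >= universe.window[0])
        pre &= out["death_age"].between(*universe.age_range) & ~out["bstate"].isin(universe.foreign_codes)
        if pre.any():
            key = pd.MultiIndex.from_frame(out.loc[pre, strata])
            vals = pd.Series(lut.reindex(key).to_numpy(), index=out.index[pre])
            got = vals.notna()
            out.loc[vals.index[got], "weight"] = vals[got]
            out.loc[vals.index[got], "weight_rule"] = RULE_PRECUTOFF
            unweighted = out["weight"].isna()

    # native stratum means used by rules (ii) and (iii)
    native_direct = out[(out["weight_rule"] == RULE_CELL)]
    lut2 = native_direct.groupby(["dyear", "death_age", "sex", "race"])["weight"].mean()

    def _apply(mask: pd.Series, rule: str) -> None:
        nonlocal unweighted
        if not mask.any():
            return
        key = pd.MultiIndex.from_frame(out.loc[mask, ["dyear", "death_age", "sex", "race"]])
        vals = pd.Series(lut2.reindex(key).to_numpy(), index=out.index[mask])
        got = vals.notna()
        out.loc[vals.index[got], "weight"] = vals[got]
        out.loc[vals.index[got], "weight_rule"] = rule
        unweighted = out["weight"].isna()

    # (ii) foreign-born
    _apply(unweighted & out["bstate"].isin(universe.foreign_codes), RULE_FOREIGN)
    # (iii) residual strata
    _apply(unweighted, RULE_STRATUM)
    # (iv) weight one
    out.loc[out["weight"].isna(), "weight_rule"] = RULE_ONE
    out.loc[out["weight"].isna(), "weight"] = 1.0
    return out


def margin_rel_errors(df: pd.DataFrame, margins: Sequence[MarginSpec], weight_col: str = "weight") -> dict[str, float]:
    """Max relative error of weighted marginal totals vs targets, per margin
    (levels present in the sample only)."""
    errs = {}
    for m in margins:
        got = df.groupby(m.dimension)[weight_col].sum()
        rel = 0.0
        for level, current in got.items():
            target = m.targets.get(level)
            if target is None or target <= 0:
                raise InfeasibleMarginError(
                    f"margin {m.dimension!r}: level {level!r} present in sample has no positive target"
                )
            rel = max(rel, abs(current - target) / target)
        errs[m.dimension] = rel
    return errs


def rake(
    df: pd.DataFrame,
    margins: Sequence[MarginSpec],
    weight_col: str = "weight",
    max_iter: int = 100,
) -> tuple[pd.Series, bool, int]:
    """Iterative proportional fitting of the weights to the margin targets.

    Cycles through the margins, scaling each record's weight by target/current
    for its level, until every margin's max relative error is within its
    tolerance or ``max_iter`` cycles elapse.  Returns (weights, converged,
    iterations).
    """
    w = df[weight_col].astype(float).copy()
    work = df[[m.dimension for m in margins]].copy()
    # validate feasibility up front
    margin_rel_errors(work.assign(**{weight_col: w}), margins, weight_col)

    it = 0
    converged = all(
        e <= m.tolerance for m, e in zip(margins, margin_rel_errors(work.assign(**{weight_col: w}), margins, weight_col).values())
    )
    while not converged and it < max_iter:
        it += 1
        for m in margins:
            current = w.groupby(work[m.dimension]).transform("sum")
            target = work[m.dimension].map(m.targets).astype(float)
            w = w * target / current
        errs = margin_rel_errors(work.assign(**{weight_col: w}), margins, weight_col)
        converged = all(errs[m.dimension] <= m.tolerance for m in margins)
    return w, converged, it


def trim(weights: pd.Series, floor: float = 1.0, ceiling: float | None = None) -> pd.Series:
    """Clamp weights into [floor, ceiling]; ceiling defaults to 5x the mean of
    the incoming (unadjusted) weights."""
    if ceiling is None:
        ceiling = 5.0 * float(np.mean(weights))
    if ceiling <= floor:
        raise ConfigError(f"trim: ceiling {ceiling} must exceed floor {floor}")
    return weights.clip(lower=floor, upper=ceiling)


def rake_trim_iterate(
    df: pd.DataFrame,
    margins: Sequence[MarginSpec],
    floor: float = 1.0,
    ceiling: float | None = None,
    max_rounds: int = 50,
    max_iter: int = 100,
    weight_col: str = "weight",
) -> tuple[pd.Series, WeightDiagnostics]:
    """Alternate raking and trimming until the weights are simultaneously inside
    [floor, ceiling] and calibrated (every margin within tolerance *after* the
    trim), or ``max_rounds`` is reached (reported, not raised).

    Weights pinned at the floor make a literally clamp-free round unattainable
    even at the fixed point, so the stopping rule checks the margins post-trim
    instead.  The trim ceiling is anchored once to the *unadjusted* incoming
    weights and held fixed across rounds.
    """
    unadjusted = df[weight_col].astype(float)
    if ceiling is None:
        ceiling = 5.0 * float(unadjusted.mean())
    share_above = float((unadjusted > ceiling).mean())

    w = unadjusted.copy()
    work = df.copy()
    total_iter = 0
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        work[weight_col] = w
        w, rake_ok, it = rake(work, margins, weight_col=weight_col, max_iter=max_iter)
        total_iter += it
        w = trim(w, floor=floor, ceiling=ceiling)
        work[weight_col] = w
        errs = margin_rel_errors(work, margins, weight_col)
        in_tol = all(errs[m.dimension] <= m.tolerance for m in margins)
        if in_tol and rake_ok:
            converged = True
            break

    work[weight_col] = w
    errs = margin_rel_errors(work, margins, weight_col)
    grand_target = sum(margins[0].targets.values()) if margins else float("nan")
    diag = WeightDiagnostics(
        coverage_ratio=float(w.sum() / grand_target) if margins else float("nan"),
        share_above_ceiling=share_above,
        rounds=rounds,
        rake_iterations=total_iter,
        max_margin_rel_error=errs,
        converged=converged,
    )
    return w, diag


def margins_from_totals(
    totals: pd.DataFrame,
    dims: Sequence[str] = ("dyear", "death_age", "race", "sex", "bstate"),
    tolerance: float = 1e-6,
) -> list[MarginSpec]:
    """Marginal target totals per dimension from a reference cell table."""
    return [
        MarginSpec(
            dimension=d,
            targets=totals.groupby(d)["n_deaths"].sum().to_dict(),
            tolerance=tolerance,
        )
        for d in dims
        if d in totals.columns
    ]
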