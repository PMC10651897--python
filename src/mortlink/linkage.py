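"""Conservative deterministic census-to-register linkage and its evaluation.

Matching requires exact agreement on standardized first and last name keys
(plus birth state for numident-like registers) and an age-in-1940 discrepancy
of at most ``max_band`` years.  Any record with more than one same-key
candidate inside the band is discarded outright — false matches are costlier
than missed ones, so ambiguity always loses.  Middle initials are never used
for matching; they are reserved for the post-hoc agreement diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, UnsupportedRegisterError

_NICK_PREFIX = "NICK:"

EVER_MARRIED = ("married", "widowed", "divorced")


def resolve_nickname_table(table: Mapping[str, str]) -> dict[str, str]:
    """Collapse alias chains so every alias maps directly to its class canonical."""
    resolved = {}
    for key in table:
        seen = {key}
        target = table[key]
        while target in table and target not in seen:
            seen.add(target)
            target = table[target]
        resolved[key] = target
    return resolved


def standardize_name(raw_key: str, table: Mapping[str, str] | None = None) -> str:
    """Canonical form of a name key; deterministic and idempotent.

    With no explicit equivalence table, the built-in convention strips the
    ``NICK:`` alias prefix used by the synthetic generator.
    """
    key = str(raw_key)
    if table is not None:
        return table.get(key, key)
    while key.startswith(_NICK_PREFIX):
        key = key[len(_NICK_PREFIX):]
    return key


def _standardize_series(s: pd.Series, table: Mapping[str, str] | None) -> pd.Series:
    if table is not None:
        return s.map(lambda k: table.get(str(k), str(k)))
    out = s.astype(str)
    mask = out.str.startswith(_NICK_PREFIX)
    while mask.any():
        out = out.where(~mask, out.str.slice(len(_NICK_PREFIX)))
        mask = out.str.startswith(_NICK_PREFIX)
    return out


@dataclass
class MatchResult:
    """Outcome of one linkage pass.

    ``pairs`` is one row per accepted link: (histid, rec_id, band) where band
    is the absolute age discrepancy used.  ``exclusions`` holds records thrown
    out by the conservative rule, reason-coded.  One-to-one by construction.
    """

    pairs: pd.DataFrame
    exclusions: pd.DataFrame
    n_census: int
    n_register: int
    counts: dict = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_census if self.n_census else float("nan")


_EMPTY_PAIRS = {"histid": pd.Series(dtype=str), "rec_id": pd.Series(dtype=str), "band": pd.Series(dtype=int)}


def abe_conservative_match(
    census: pd.DataFrame,
    register: pd.DataFrame,
    use_birth_state: bool = False,
    max_band: int = 2,
    census_year: int = 1940,
    census_month: int = 4,
    nickname_table: Mapping[str, str] | None = None,
    register_surname_col: str = "last_key",
) -> MatchResult:
    """Conservative exact-key match with +/- ``max_band`` years of age flexibility.

    A census row links to a register row iff they agree exactly on the
    standardized keys, their implied 1940 ages differ by at most the band, and
    neither side has any second candidate within ``max_band``.  This strict
    reading excludes a record even when its two candidates sit at different
    distances — closer is not safer enough.
    """
    if nickname_table is not None:
        nickname_table = resolve_nickname_table(nickname_table)

    need_c = ["histid", "first_key", "last_key", "census_age"] + (["birth_state"] if use_birth_state else [])
    need_r = ["rec_id", "first_key", register_surname_col, "byear", "bmonth"] + (
        ["bpl"] if use_birth_state else []
    )
    for cols, df, side in ((need_c, census, "census"), (need_r, register, "register")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{side} table is missing required columns: {missing}")

    c = pd.DataFrame(
        {
            "histid": census["histid"],
            "first_std": _standardize_series(census["first_key"], nickname_table),
            "last_std": _standardize_series(census["last_key"], nickname_table),
            "census_age": census["census_age"].astype(int),
        }
    )
    r = pd.DataFrame(
        {
            "rec_id": register["rec_id"],
            "first_std": _standardize_series(register["first_key"], nickname_table),
            "last_std": _standardize_series(register[register_surname_col], nickname_table),
        }
    )
    # register-implied age on census day, from its (possibly misstated) birth date
    r["implied_age"] = (
        census_year - register["byear"].astype(int) - (register["bmonth"].astype(int) >= census_month).astype(int)
    ).to_numpy()
    keys = ["first_std", "last_std"]
    if use_birth_state:
        c["bstate"] = census["birth_state"].to_numpy()
        r["bstate"] = register["bpl"].to_numpy()
        keys.append("bstate")

    cand = c.merge(r, on=keys, how="inner")
    cand["band"] = (cand["census_age"] - cand["implied_age"]).abs()
    cand = cand[cand["band"] <= max_band]

    amb_c = cand["histid"].value_counts()
    amb_c = set(amb_c.index[amb_c > 1])
    amb_r = cand["rec_id"].value_counts()
    amb_r = set(amb_r.index[amb_r > 1])

    ok = cand[~cand["histid"].isin(amb_c) & ~cand["rec_id"].isin(amb_r)]
    pairs = ok[["histid", "rec_id", "band"]].sort_values("histid").reset_index(drop=True)

    excl = pd.concat(
        [
            pd.DataFrame({"side": "census", "id": sorted(amb_c), "reason": "ambiguous-census"}),
            pd.DataFrame({"side": "register", "id": sorted(amb_r), "reason": "ambiguous-register"}),
        ],
        ignore_index=True,
    )
    counts = {
        "census_ambiguous": len(amb_c),
        "register_ambiguous": len(amb_r),
        "census_no_candidate": int(len(census) - cand["histid"].nunique()),
        "register_no_candidate": int(len(register) - cand["rec_id"].nunique()),
        "census_candidate_lost": int(cand["histid"].nunique() - len(amb_c) - len(pairs)),
    }
    if pairs.empty:
        pairs = pd.DataFrame(_EMPTY_PAIRS)
    return MatchResult(pairs=pairs, exclusions=excl, n_census=len(census), n_register=len(register), counts=counts)


def match_women(
    census: pd.DataFrame,
    numident_register: pd.DataFrame,
    use_birth_state: bool = True,
    max_band: int = 2,
    nickname_table: Mapping[str, str] | None = None,
    widowed_use_father: bool = False,
    **kwargs,
) -> MatchResult:
    """Link census women to a numident-like register.

    Ever-married women (per census marital status) are matched on their own
    surname on both sides.  Never-married women are matched using the census
    surname against the register's *father's* surname, a proxy for the maiden
    name; this cannot recover women who married (and changed name) after
    census day.  ``widowed_use_father`` flips widowed/divorced women onto the
    father-surname route instead; default treats them as ever-married.
    """
    if "father_last_key" not in numident_register.columns:
        raise UnsupportedRegisterError(
            "women can only be linked against a numident-like register carrying father_last_key"
        )
    if "marital_status" not in census.columns:
        raise SchemaError("census table is missing required columns: ['marital_status']")

    women = census[census["sex"] == "F"]
    father_route = women["marital_status"] == "never_married"
    if widowed_use_father:
        father_route |= women["marital_status"].isin(["widowed", "divorced"])
    own = women[~father_route]
    maiden = women[father_route]

    res_own = abe_conservative_match(
        own, numident_register, use_birth_state=use_birth_state, max_band=max_band,
        nickname_table=nickname_table, register_surname_col="last_key", **kwargs,
    )
    res_maiden = abe_conservative_match(
        maiden, numident_register, use_birth_state=use_birth_state, max_band=max_band,
        nickname_table=nickname_table, register_surname_col="father_last_key", **kwargs,
    )
    pairs = pd.concat([res_own.pairs, res_maiden.pairs], ignore_index=True)
    # a register row claimed by both routes is ambiguous after all
    dup = pairs["rec_id"].value_counts()
    dup = set(dup.index[dup > 1])
    cross = pd.DataFrame({"side": "register", "id": sorted(dup), "reason": "ambiguous-register"})
    pairs = pairs[~pairs["rec_id"].isin(dup)].sort_values("histid").reset_index(drop=True)
    exclusions = pd.concat([res_own.exclusions, res_maiden.exclusions, cross], ignore_index=True)
    counts = {k: res_own.counts.get(k, 0) + res_maiden.counts.get(k, 0) for k in res_own.counts}
    counts["register_ambiguous"] += len(dup)
    if pairs.empty:
        pairs = pd.DataFrame(_EMPTY_PAIRS)
    return MatchResult(
        pairs=pairs, exclusions=exclusions, n_census=len(women),
        n_register=len(numident_register), counts=counts,
    )


# ---------------------------------------------------------------------------
# evaluation

EDUCATION_BANDS = (
    (0, 11, "<High School"),
    (12, 15, "High School or some college"),
    (16, 16, "Bachelor's"),
    (17, 99, "Advanced"),
)

DEFAULT_STRATA = ("education_band", "race", "marital_status")


def education_band(years: pd.Series) -> pd.Series:
    out = pd.Series("", index=years.index, dtype=object)
    for lo, hi, label in EDUCATION_BANDS:
        out[(years >= lo) & (years <= hi)] = label
    return out


@dataclass
class LinkageReport:
    summary: dict
    representativeness: pd.DataFrame
    middle_initial_agreement: float


def representativeness_table(
    census: pd.DataFrame,
    matched_histids,
    strata: tuple[str, ...] = DEFAULT_STRATA,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Stratum shares among matched records vs the full census, with differences.

    ``weights`` (indexed like matched histids) adds a weighted-share column;
    the difference column compares the weighted share (unweighted if absent)
    to the census share.
    """
    cen = census.copy()
    if "education_band" in strata and "education_band" not in cen.columns:
        cen["education_band"] = education_band(cen["education_years"])
    matched = cen[cen["histid"].isin(set(matched_histids))]
    w = None
    if weights is not None:
        w = matched["histid"].map(weights).fillna(1.0)

    rows = []
    for var in strata:
        census_share = cen[var].value_counts(normalize=True)
        match_share = matched[var].value_counts(normalize=True)
        wt_share = None
        if w is not None:
            wt_share = matched.assign(_w=w.to_numpy()).groupby(var)["_w"].sum() / float(w.sum())
        for level in census_share.index:
            pct_unw = 100 * float(match_share.get(level, 0.0))
            pct_w = 100 * float(wt_share.get(level, 0.0)) if wt_share is not None else np.nan
            pct_cen = 100 * float(census_share[level])
            ref = pct_w if wt_share is not None else pct_unw
            rows.append(
                {
                    "stratum": var,
                    "level": level,
                    "count_matched": int((matched[var] == level).sum()),
                    "pct_unweighted": pct_unw,
                    "pct_weighted": pct_w,
                    "pct_census": pct_cen,
                    "difference": ref - pct_cen,
                }
            )
    return pd.DataFrame(rows)


def middle_initial_diagnostic(pairs: pd.DataFrame, census: pd.DataFrame, register: pd.DataFrame) -> float:
    """Share of matched pairs agreeing on middle initial, among pairs where both
    sides report one.  Disagreement upper-bounds the false-match rate."""
    merged = (
        pairs.merge(census[["histid", "middle_initial"]], on="histid")
        .merge(register[["rec_id", "middle_initial"]], on="rec_id", suffixes=("_census", "_register"))
    )
    both = merged[(merged["middle_initial_census"] != "") & (merged["middle_initial_register"] != "")]
    both = both.dropna(subset=["middle_initial_census", "middle_initial_register"])
    if both.empty:
        return float("nan")
    return float((both["middle_initial_census"] == both["middle_initial_register"]).mean())


def evaluate_linkage(
    result: MatchResult,
    truth_map: pd.DataFrame,
    census: pd.DataFrame,
    register: pd.DataFrame | None = None,
    strata: tuple[str, ...] = DEFAULT_STRATA,
    weights: pd.Series | None = None,
) -> LinkageReport:
    """Precision/recall against the generator truth map, plus representativeness
    and the middle-initial agreement diagnostic.

    Recall is computed on the census-intersect-register universe: truth pairs
    whose person appears in the census table and whose register row exists.
    """
    if truth_map["histid"].duplicated().any() or truth_map["rec_id"].duplicated().any():
        raise IntegrityError("truth map is not injective (duplicate histid or rec_id)")

    pairs = result.pairs
    correct = pairs.merge(truth_map, on=["histid", "rec_id"])
    n_correct = len(correct)
    precision = n_correct / len(pairs) if len(pairs) else float("nan")

    universe = truth_map[truth_map["histid"].isin(set(census["histid"]))]
    if register is not None:
        universe = universe[universe["rec_id"].isin(set(register["rec_id"]))]
    recall = n_correct / len(universe) if len(universe) else float("nan")

    agreement = float("nan")
    if register is not None and "middle_initial" in register.columns and len(pairs):
        agreement = middle_initial_diagnostic(pairs, census, register)

    rep = representativeness_table(census, pairs["histid"], strata=strata, weights=weights)
    summary = {
        "n_census": result.n_census,
        "n_register": result.n_register,
        "n_matched": result.n_matched,
        "match_rate": result.match_rate,
        "precision": precision,
        "recall": recall,
        "n_truth_universe": len(universe),
        **{f"excl_{k}": v for k, v in result.counts.items()},
    }
    return LinkageReport(summary=summary, representativeness=rep, middle_initial_agreement=agreement)
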