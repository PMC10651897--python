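import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mortlink as ml
from mortlink.errors import SchemaError, UnsupportedRegisterError
from mortlink.linkage import (
    abe_conservative_match,
    evaluate_linkage,
    match_women,
    middle_initial_diagnostic,
    representativeness_table,
    resolve_nickname_table,
    standardize_name,
)


class TestStandardizeName:
    @given(st.text(alphabet=st.characters(codec="ascii"), max_size=20))
    def test_idempotent(self, key):
        once = standardize_name(key)
        assert standardize_name(once) == once

    def test_nickname_alias_collapses(self):
        assert standardize_name("NICK:F00001") == "F00001"
        assert standardize_name("NICK:NICK:F00001") == "F00001"

    def test_equivalence_table(self):
        table = resolve_nickname_table({"BILL": "WILLIAM", "WILL": "BILL"})
        assert standardize_name("WILL", table) == "WILLIAM"
        assert standardize_name("BILL", table) == standardize_name("WILL", table)
        assert standardize_name("ROBERT", table) != standardize_name("WILL", table)

    @given(st.dictionaries(st.text(max_size=8), st.text(max_size=8), max_size=10))
    def test_resolved_table_is_idempotent(self, table):
        resolved = resolve_nickname_table(table)
        for key in resolved:
            assert standardize_name(standardize_name(key, resolved), resolved) == standardize_name(key, resolved)


def _census_row(histid, first, last, age, bstate="S01", **kw):
    row = {
        "histid": histid, "first_key": first, "last_key": last, "census_age": age,
        "birth_state": bstate, "sex": kw.get("sex", "M"),
        "marital_status": kw.get("marital_status", "married"),
        "middle_initial": kw.get("middle_initial", "A"),
        "education_years": kw.get("education_years", 8), "race": kw.get("race", "White"),
    }
    return row


def _register_row(rec_id, first, last, byear, bmonth=1, bpl="S01", **kw):
    return {
        "rec_id": rec_id, "first_key": first, "last_key": last,
        "father_last_key": kw.get("father_last_key", last),
        "byear": byear, "bmonth": bmonth, "bpl": bpl,
        "middle_initial": kw.get("middle_initial", "A"),
        "sex": kw.get("sex", "M"), "dyear": kw.get("dyear", 1990), "dmonth": 6,
    }


class TestConservativeMatch:
    def test_single_pair_band_zero(self):
        census = pd.DataFrame([_census_row("H1", "F1", "L1", 35)])
        register = pd.DataFrame([_register_row("R1", "F1", "L1", byear=1905, bmonth=1)])
        res = abe_conservative_match(census, register)
        assert res.pairs.to_dict("records") == [{"histid": "H1", "rec_id": "R1", "band": 0}]

    def test_two_candidates_one_year_apart_excluded(self):
        census = pd.DataFrame([_census_row("H1", "F1", "L1", 35)])
        register = pd.DataFrame(
            [
                _register_row("R1", "F1", "L1", byear=1905),
                _register_row("R2", "F1", "L1", byear=1906),
            ]
        )
        res = abe_conservative_match(census, register)
        assert res.n_matched == 0
        assert ("census", "H1", "ambiguous-census") in res.exclusions.itertuples(index=False, name=None)

    def test_strict_rule_excludes_even_with_exact_candidate(self):
        # one candidate at band 0 and one at band 2: conservative rule drops both
        census = pd.DataFrame([_census_row("H1", "F1", "L1", 35)])
        register = pd.DataFrame(
            [
                _register_row("R1", "F1", "L1", byear=1905),
                _register_row("R2", "F1", "L1", byear=1907),
            ]
        )
        assert abe_conservative_match(census, register, max_band=2).n_matched == 0
        # at band 0 the far candidate is invisible and the match goes through
        assert abe_conservative_match(census, register, max_band=0).n_matched == 1

    def test_age_band_limits(self):
        census = pd.DataFrame([_census_row("H1", "F1", "L1", 35)])
        for offset, expected_band in ((1, 1), (2, 2)):
            register = pd.DataFrame([_register_row("R1", "F1", "L1", byear=1905 + offset)])
            res = abe_conservative_match(census, register)
            assert res.pairs["band"].iloc[0] == expected_band
        register = pd.DataFrame([_register_row("R1", "F1", "L1", byear=1902)])
        assert abe_conservative_match(census, register).n_matched == 0

    def test_birth_state_separates_candidates(self):
        census = pd.DataFrame(
            [_census_row("H1", "F1", "L1", 35, bstate="S01"), _census_row("H2", "F1", "L1", 35, bstate="S02")]
        )
        register = pd.DataFrame(
            [_register_row("R1", "F1", "L1", 1905, bpl="S01"), _register_row("R2", "F1", "L1", 1905, bpl="S02")]
        )
        assert abe_conservative_match(census, register, use_birth_state=False).n_matched == 0
        res = abe_conservative_match(census, register, use_birth_state=True)
        assert res.n_matched == 2
        assert dict(zip(res.pairs["histid"], res.pairs["rec_id"])) == {"H1": "R1", "H2": "R2"}

    def test_missing_columns_schema_error(self):
        with pytest.raises(SchemaError, match="census_age"):
            abe_conservative_match(pd.DataFrame({"histid": []}), pd.DataFrame({"rec_id": []}))

    def test_one_to_one_and_band_monotonicity(self, clean_linked_world):
        w = clean_linked_world
        census_men = w["census"][w["census"]["sex"] == "M"]
        register = w["register"][w["register"]["sex"] == "M"]
        previous = -1
        for band in (0, 1, 2):
            res = abe_conservative_match(census_men, register, use_birth_state=True, max_band=band)
            assert not res.pairs["histid"].duplicated().any()
            assert not res.pairs["rec_id"].duplicated().any()
            assert res.n_matched >= previous
            previous = res.n_matched

    def test_noise_free_unique_keys_perfect(self, clean_linked_world):
        w = clean_linked_world
        census_men = w["census"][w["census"]["sex"] == "M"]
        register = w["register"][w["register"]["sex"] == "M"]
        res = abe_conservative_match(census_men, register, use_birth_state=True)
        report = evaluate_linkage(res, w["truth"], census_men, register)
        assert report.summary["precision"] == 1.0
        assert report.summary["recall"] == 1.0


class TestMatchWomen:
    def test_never_married_matched_via_father_surname(self):
        census = pd.DataFrame(
            [_census_row("H1", "F1", "LFATHER", 35, sex="F", marital_status="never_married")]
        )
        register = pd.DataFrame(
            [_register_row("R1", "F1", "LHUSBAND", 1905, father_last_key="LFATHER", sex="F")]
        )
        res = match_women(census, register)
        assert res.pairs["rec_id"].tolist() == ["R1"]

    def test_post_census_remarriage_unmatched(self):
        # ever-married woman whose register surname changed after census day
        census = pd.DataFrame([_census_row("H1", "F1", "LHUSB1", 35, sex="F", marital_status="married")])
        register = pd.DataFrame(
            [_register_row("R1", "F1", "LHUSB2", 1905, father_last_key="LFATHER", sex="F")]
        )
        assert match_women(census, register).n_matched == 0

    def test_dmf_like_register_unsupported(self):
        census = pd.DataFrame([_census_row("H1", "F1", "L1", 35, sex="F")])
        register = pd.DataFrame([_register_row("R1", "F1", "L1", 1905)]).drop(columns=["father_last_key"])
        with pytest.raises(UnsupportedRegisterError):
            match_women(census, register)

    def test_women_recall_below_men_precision_one(self):
        spec = ml.PopulationSpec(
            cohort_range=(1900, 1920), cohort_sizes=500, seed=19,
            unique_names=True, n_first_names=20000,
            p_marry_after_census=0.3, p_remarry_after_census=0.3,
        )
        pop = ml.simulate_mortality(ml.generate_population(spec), ml.GompertzParams(), seed=19)
        census = ml.build_census_file(pop)
        rspec = ml.RegisterSpec(kind="numident-like", window=(1988, 2005), p_in=1.0, p_out=0.0)
        register, truth = ml.build_death_register(pop, rspec, seed=19)
        men = census[census["sex"] == "M"]
        res_m = abe_conservative_match(men, register[register["sex"] == "M"], use_birth_state=True)
        res_w = match_women(census, register[register["sex"] == "F"])
        rep_m = evaluate_linkage(res_m, truth, men, register[register["sex"] == "M"])
        rep_w = evaluate_linkage(res_w, truth, census[census["sex"] == "F"], register[register["sex"] == "F"])
        assert rep_m.summary["precision"] == 1.0
        assert rep_w.summary["precision"] == 1.0
        assert rep_w.summary["recall"] < rep_m.summary["recall"]


class TestEvaluateLinkage:
    def test_perfect_match_full_agreement(self, clean_linked_world):
        w = clean_linked_world
        census_men = w["census"][w["census"]["sex"] == "M"]
        register = w["register"][w["register"]["sex"] == "M"]
        res = abe_conservative_match(census_men, register, use_birth_state=True)
        report = evaluate_linkage(res, w["truth"], census_men, register)
        assert report.middle_initial_agreement == 1.0

    def test_injected_false_matches_bound_disagreement(self, clean_linked_world):
        w = clean_linked_world
        census_men = w["census"][w["census"]["sex"] == "M"]
        register = w["register"][w["register"]["sex"] == "M"]
        res = abe_conservative_match(census_men, register, use_birth_state=True)
        pairs = res.pairs.copy()
        rng = np.random.default_rng(3)
        false_rate = 0.10
        k = int(round(false_rate * len(pairs)))
        idx = rng.choice(len(pairs), size=k, replace=False)
        # rewire a 10% subset cyclically so each becomes a false match
        pairs.loc[pairs.index[idx], "rec_id"] = np.roll(pairs["rec_id"].to_numpy()[idx], 1)
        agreement = middle_initial_diagnostic(pairs, census_men, register)
        disagreement = 1.0 - agreement
        expected = false_rate * 25 / 26
        mc_sd = np.sqrt(expected * (1 - expected) / len(pairs))
        assert disagreement >= false_rate - 3 * mc_sd
        assert abs(disagreement - expected) <= 3 * mc_sd

    def test_representativeness_unbiased_under_uniform_matching(self, clean_linked_world):
        w = clean_linked_world
        census = w["census"]
        rng = np.random.default_rng(8)
        matched = census["histid"].sample(frac=0.4, random_state=11)
        table = representativeness_table(census, matched)
        n = len(matched)
        for row in table.itertuples():
            p = row.pct_census / 100
            sd = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(row.difference) <= 3 * sd + 1e-9

    def test_truth_map_integrity_checked(self, clean_linked_world):
        w = clean_linked_world
        census_men = w["census"][w["census"]["sex"] == "M"]
        register = w["register"][w["register"]["sex"] == "M"]
        res = abe_conservative_match(census_men, register, use_birth_state=True)
        bad_truth = pd.concat([w["truth"], w["truth"].iloc[:1]], ignore_index=True)
        with pytest.raises(ml.errors.IntegrityError):
            evaluate_linkage(res, bad_truth, census_men, register)
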