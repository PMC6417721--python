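import numpy as np
import pandas as pd
import pytest

from sma_phewas.claims_model import Claim, Member, claims_frame, members_frame
from sma_phewas.cohort import (apply_final_diagnosis_rule, apply_min_coverage,
                               apply_pregnancy_exclusion, build_cohort,
                               identify_sma_candidates, select_controls,
                               stratify_cases)


def _claims(*rows):
    return claims_frame([Claim(*r) for r in rows])


class TestCandidates:
    def test_two_distinct_dates_qualify(self, vocab):
        c = _claims(("A", "2010-01-05", "335.10"), ("A", "2010-03-01", "335.0"))
        out = identify_sma_candidates(c, vocab.sma)
        assert out["member_id"].tolist() == ["A"]
        assert out["first_sma_date"].iloc[0] == pd.Timestamp("2010-01-05")

    def test_same_day_codes_are_one_visit(self, vocab):
        c = _claims(("A", "2010-01-05", "335.10"), ("A", "2010-01-05", "335.11"))
        out = identify_sma_candidates(c, vocab.sma)
        assert out.empty and out.attrs["single_visit"] == ["A"]

    def test_single_code_not_a_candidate(self, vocab):
        out = identify_sma_candidates(_claims(("A", "2010-01-05", "335.10")), vocab.sma)
        assert out.empty and out.attrs["single_visit"] == ["A"]


class TestFinalDiagnosisRule:
    def _run(self, vocab, *rows):
        claims = _claims(*rows)
        cands = identify_sma_candidates(claims, vocab.sma)
        return apply_final_diagnosis_rule(cands, claims, vocab.neuromuscular, vocab.sma)

    def test_later_md_excludes(self, vocab):
        out = self._run(vocab, ("A", "2010-01-10", "335.10"),
                        ("A", "2010-01-20", "335.10"), ("A", "2010-02-19", "359.0"))
        assert out.empty and out.attrs["excluded_final_dx"] == ["A"]

    def test_md_before_sma_keeps(self, vocab):
        out = self._run(vocab, ("A", "2010-01-10", "359.0"),
                        ("A", "2010-01-20", "335.10"), ("A", "2010-02-19", "335.10"))
        assert out["member_id"].tolist() == ["A"]

    def test_same_date_tie_counts_as_sma_final(self, vocab):
        out = self._run(vocab, ("A", "2010-01-10", "335.10"),
                        ("A", "2010-02-19", "335.10"), ("A", "2010-02-19", "359.0"))
        assert out["member_id"].tolist() == ["A"]


class TestPregnancyExclusion:
    def test_one_code_excludes_entirely(self, vocab):
        claims = _claims(("A", "2010-01-05", "335.10"), ("A", "2010-02-05", "335.10"),
                         ("A", "2010-01-05", "V22.0"))
        cands = identify_sma_candidates(claims, vocab.sma)
        out = apply_pregnancy_exclusion(cands, claims, vocab.pregnancy)
        assert out.empty and out.attrs["excluded_pregnancy"] == ["A"]

    def test_rule_is_code_based_regardless_of_gender(self, vocab):
        # a (data-error) male with a pregnancy code is still excluded
        claims = _claims(("M", "2010-01-05", "335.10"), ("M", "2010-02-05", "335.10"),
                         ("M", "2010-03-01", "V23.9"))
        cands = identify_sma_candidates(claims, vocab.sma)
        assert apply_pregnancy_exclusion(cands, claims, vocab.pregnancy).empty


class TestStratification:
    @pytest.mark.parametrize("age_years, group", [
        # integer ages via year arithmetic hit the interval edges exactly
        (0, "A"), (1, "A"), (2, "B"), (20, "B"), (21, "C"), (65, "C"), (66, None),
    ])
    def test_boundaries_year_mode(self, age_years, group):
        members = members_frame([Member("A", "female", 1980, "1980-06-01",
                                        "2060-01-01")])
        cases = pd.DataFrame({"member_id": ["A"],
                              "first_sma_date": [pd.Timestamp(f"{1980 + age_years}-06-01")]})
        out = stratify_cases(cases, members)
        if group is None:
            assert pd.isna(out["group"].iloc[0])
        else:
            assert out["group"].iloc[0] == group

    def test_fractional_age_day_mode(self):
        members = members_frame([Member("A", "female", 1980, "1980-01-01",
                                        "2060-01-01", birth_date="1980-01-01")])
        cases = pd.DataFrame({"member_id": ["A"],
                              "first_sma_date": [pd.Timestamp("1980-01-01")
                                                 + pd.Timedelta(days=548)]})  # ≈1.5y
        assert stratify_cases(cases, members)["group"].iloc[0] == "A"


class TestControls:
    def test_any_sma_code_bars_control(self, vocab, twelve):
        members, claims, _ = twelve
        cases = pd.DataFrame({"member_id": ["M01", "M02"]})
        controls = select_controls(members, claims, vocab.sma, cases)
        # M03/M04/M05 carry SMA codes (even just one) and never qualify
        assert not set("M03 M04 M05".split()) & set(controls["member_id"])

    def test_age_range_is_inclusive_of_case_extremes(self, vocab, twelve):
        members, claims, _ = twelve
        controls = select_controls(members, claims, vocab.sma,
                                   pd.DataFrame({"member_id": ["M01", "M02"]}))
        lo, hi = controls.attrs["age_range"]
        assert (controls["age_at_enrollment"].between(lo, hi)).all()
        assert set(controls["member_id"]) == set(f"M{i:02d}" for i in range(6, 13))

    def test_control_pools_of_groups_may_overlap(self, vocab):
        # group ranges: A cases enrolled at [0.1y, 1.0y]; B at [0.5y, 19y];
        # X enrolled at ~0.7y sits inside both
        members = members_frame([
            Member("A1", "male", 2009, "2009-02-06", "2013-01-01", birth_date="2009-01-01"),
            Member("A2", "male", 2008, "2009-01-01", "2013-01-01", birth_date="2008-01-01"),
            Member("B1", "male", 2008, "2009-01-01", "2013-01-01", birth_date="2008-07-02"),
            Member("B2", "male", 1990, "2009-01-01", "2013-01-01", birth_date="1990-01-01"),
            Member("X", "female", 2008, "2009-05-15", "2013-01-01", birth_date="2008-09-01"),
        ])
        claims = _claims(*[(m, d, "335.10") for m in ("A1", "A2", "B1", "B2")
                           for d in ("2010-01-01", "2010-02-01")])
        in_a = select_controls(members, claims, vocab.sma,
                               pd.DataFrame({"member_id": ["A1", "A2"]}))
        in_b = select_controls(members, claims, vocab.sma,
                               pd.DataFrame({"member_id": ["B1", "B2"]}))
        assert "X" in in_a["member_id"].tolist()
        assert "X" in in_b["member_id"].tolist()

    def test_no_cases_is_an_error(self, vocab, twelve):
        members, claims, _ = twelve
        with pytest.raises(ValueError):
            select_controls(members, claims, vocab.sma,
                            pd.DataFrame({"member_id": []}))


class TestCoverageGate:
    def _assign(self, *ids):
        return pd.DataFrame({"member_id": list(ids), "role": "case",
                             "group": "A", "first_sma_date": pd.NaT,
                             "exclusion_reason": pd.NA})

    def test_exactly_six_months_kept(self):
        days = round(6 * 30.4375)  # 183 days ≈ exactly 6.0 months
        win = pd.DataFrame({"member_id": ["A"], "kind": "entire",
                            "start": [pd.Timestamp("2010-01-01")],
                            "end": [pd.Timestamp("2010-01-01") + pd.Timedelta(days=days - 1)],
                            "inflection_date": pd.NaT})
        out = apply_min_coverage(self._assign("A"), win)
        assert out["role"].iloc[0] == "case"

    def test_short_pre_window_dropped(self):
        # inflection 90 days after enrollment start: ~2.96 months of window
        win = pd.DataFrame({"member_id": ["A"], "kind": "pre_degeneration",
                            "start": [pd.Timestamp("2010-01-01")],
                            "end": [pd.Timestamp("2010-03-31")],
                            "inflection_date": [pd.Timestamp("2010-04-01")]})
        out = apply_min_coverage(self._assign("A"), win)
        assert out["role"].iloc[0] == "excluded"
        assert out["exclusion_reason"].iloc[0] == "insufficient_coverage"

    def test_member_without_window_treated_as_zero_coverage(self):
        win = pd.DataFrame({"member_id": [], "kind": [], "start": pd.Series([], dtype="datetime64[ns]"),
                            "end": pd.Series([], dtype="datetime64[ns]"), "inflection_date": []})
        out = apply_min_coverage(self._assign("A"), win)
        assert out["role"].iloc[0] == "excluded"


class TestBuildCohort:
    def test_twelve_member_fixture_recovered_exactly(self, vocab, twelve):
        members, claims, expected = twelve
        out = build_cohort(members, claims, sma=vocab.sma,
                           neuromuscular=vocab.neuromuscular,
                           pregnancy=vocab.pregnancy, group="A")
        merged = out.merge(expected, on="member_id", suffixes=("", "_want"))
        assert (merged["role"] == merged["role_want"]).all()
        assert (merged["exclusion_reason"].fillna("")
                == merged["exclusion_reason_want"].fillna("")).all()

    def test_partition_every_member_has_one_role(self, vocab, planted_sim):
        out = build_cohort(planted_sim.members, planted_sim.claims, sma=vocab.sma,
                           neuromuscular=vocab.neuromuscular,
                           pregnancy=vocab.pregnancy, group="A")
        assert len(out) == len(planted_sim.members)
        assert out["member_id"].is_unique
        assert set(out["role"]) <= {"case", "control", "excluded", "ineligible"}
        excl = out[out["role"] == "excluded"]
        assert excl["exclusion_reason"].notna().all()

    def test_locality_removing_non_sma_member(self, vocab, twelve):
        """Dropping a member without SMA codes never changes case assignments."""
        members, claims, _ = twelve
        full = build_cohort(members, claims, sma=vocab.sma,
                            neuromuscular=vocab.neuromuscular,
                            pregnancy=vocab.pregnancy, group="A")
        reduced = build_cohort(members[members["member_id"] != "M07"],
                               claims[claims["member_id"] != "M07"],
                               sma=vocab.sma, neuromuscular=vocab.neuromuscular,
                               pregnancy=vocab.pregnancy, group="A")
        want = full[full["role"] == "case"].reset_index(drop=True)
        got = reduced[reduced["role"] == "case"].reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)

    def test_contaminants_all_rejected_on_synthetic_truth(self, vocab, planted_sim):
        out = build_cohort(planted_sim.members, planted_sim.claims, sma=vocab.sma,
                           neuromuscular=vocab.neuromuscular,
                           pregnancy=vocab.pregnancy, group="A").set_index("member_id")
        truth = planted_sim.truth.members.set_index("member_id")
        cases = set(out.index[out["role"] == "case"])
        assert cases == set(truth.index[truth["role"] == "case"])
        for role, reason in [("contaminant_pregnancy", "pregnancy_codes"),
                             ("contaminant_wrong_final_dx", "final_dx_not_sma"),
                             ("contaminant_single_code", "single_visit")]:
            ids = truth.index[truth["role"] == role]
            assert (out.loc[ids, "role"] == "excluded").all()
            assert (out.loc[ids, "exclusion_reason"] == reason).all()
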