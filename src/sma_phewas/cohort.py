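"""Case selection, group stratification, control selection, coverage gating.

The selection algorithm, in order:

1. **Candidates** — members with SMA codes on ≥2 *distinct service dates*
   ("different visits"; claims carry no visit identifier, so date
   granularity is all the schema offers).  The earliest such date is the
   first SMA diagnosis.
2. **Final-diagnosis rule** — among each candidate's claims carrying any
   neuromuscular-set code, the latest service date must include an SMA
   code; a later non-SMA neuromuscular code (muscular dystrophy, myoneural
   disorder, …) means a likely misdiagnosis and excludes the candidate.  A
   same-date tie counts as SMA-final: SMA claims routinely co-occur with
   degeneration codes on one encounter, and the rule exists to catch
   *later* competing diagnoses.
3. **Pregnancy exclusion** — candidates with any pregnancy-billing code are
   dropped entirely (prenatal SMA testing generates SMA codes for billing).
4. **Stratification** — surviving cases split by age at first SMA
   diagnosis: Group A [0, 2), Group B [2, 21), Group C [21, 65]; older
   cases are excluded as out of range.
5. **Controls** — all members with *zero* SMA codes whose age at enrollment
   lies within the [min, max] range of the group's cases' enrollment ages.
   Control pools of different groups may overlap.
6. **Coverage gate** — every cohort member needs ≥6 months of enrollment
   intersected with the analysis window (months = days / 30.4375).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .claims_model import DAYS_PER_MONTH, age_at
from .vocab import CodeSet

__all__ = ["GROUP_BOUNDS", "identify_sma_candidates", "apply_final_diagnosis_rule",
           "apply_pregnancy_exclusion", "stratify_cases", "select_controls",
           "apply_min_coverage", "build_cohort"]

#: Age-at-first-SMA-diagnosis intervals (years); A/B upper bounds exclusive,
#: C inclusive at 65.
GROUP_BOUNDS = {"A": (0.0, 2.0), "B": (2.0, 21.0), "C": (21.0, 65.0)}


def identify_sma_candidates(claims: pd.DataFrame, sma: CodeSet) -> pd.DataFrame:
    """Members with SMA-set codes on ≥2 distinct service dates.

    Returns columns ``member_id, first_sma_date, n_sma_dates`` (candidates
    only), plus the single-date members in ``attrs["single_visit"]`` — they
    carry SMA codes, so they are barred from the control pool but are not
    cases either.
    """
    sma_claims = claims[sma.match(claims["icd9"])]
    per_member = (sma_claims.drop_duplicates(["member_id", "service_date"])
                  .groupby("member_id")["service_date"]
                  .agg(first_sma_date="min", n_sma_dates="count")
                  .reset_index())
    out = per_member[per_member["n_sma_dates"] >= 2].reset_index(drop=True)
    out.attrs["single_visit"] = per_member.loc[
        per_member["n_sma_dates"] < 2, "member_id"].tolist()
    return out


def apply_final_diagnosis_rule(candidates: pd.DataFrame, claims: pd.DataFrame,
                               neuromuscular: CodeSet, sma: CodeSet) -> pd.DataFrame:
    """Keep candidates whose latest neuromuscular-coded date carries SMA."""
    cand_ids = set(candidates["member_id"])
    nm = claims[claims["member_id"].isin(cand_ids)
                & neuromuscular.match(claims["icd9"])].copy()
    if nm.empty and cand_ids:
        raise AssertionError("candidates have SMA codes, so neuromuscular claims "
                             "must exist; is the SMA set outside the neuromuscular set?")
    last_nm = nm.groupby("member_id")["service_date"].max()
    nm["is_sma"] = sma.match(nm["icd9"])
    sma_on_last = (nm[nm["is_sma"]]
                   .merge(last_nm.rename("last_date"), on="member_id")
                   .query("service_date == last_date")["member_id"].unique())
    keep = candidates["member_id"].isin(set(sma_on_last))
    out = candidates[keep].reset_index(drop=True)
    out.attrs["excluded_final_dx"] = candidates.loc[~keep, "member_id"].tolist()
    return out


def apply_pregnancy_exclusion(candidates: pd.DataFrame, claims: pd.DataFrame,
                              pregnancy: CodeSet) -> pd.DataFrame:
    """Drop candidates with any pregnancy-billing claim (code-based rule)."""
    flagged = set(claims.loc[pregnancy.match(claims["icd9"]), "member_id"])
    keep = ~candidates["member_id"].isin(flagged)
    out = candidates[keep].reset_index(drop=True)
    out.attrs["excluded_pregnancy"] = candidates.loc[~keep, "member_id"].tolist()
    return out


def stratify_cases(cases: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Assign Group A/B/C by age at first SMA diagnosis; >65 → excluded."""
    m = members.set_index("member_id")
    sub = m.loc[cases["member_id"]].reset_index()
    ages = age_at(sub, cases["first_sma_date"].to_numpy())
    if (ages < 0).any():
        raise ValueError("negative age at first SMA diagnosis: data error")
    out = cases.copy()
    out["age_at_first_sma"] = ages.to_numpy()
    group = pd.Series(pd.NA, index=out.index, dtype=object)
    for label, (lo, hi) in GROUP_BOUNDS.items():
        if label == "C":
            mask = (out["age_at_first_sma"] >= lo) & (out["age_at_first_sma"] <= hi)
        else:
            mask = (out["age_at_first_sma"] >= lo) & (out["age_at_first_sma"] < hi)
        group[mask] = label
    out["group"] = group
    return out


def select_controls(members: pd.DataFrame, claims: pd.DataFrame, sma: CodeSet,
                    group_cases: pd.DataFrame) -> pd.DataFrame:
    """All members with zero SMA codes whose enrollment age falls in the
    group's case enrollment-age range (inclusive).  Returns ``member_id``
    and ``age_at_enrollment``; empty with a warning attr if no cases."""
    if group_cases.empty:
        raise ValueError("control selection needs at least one case in the group")
    any_sma = set(claims.loc[sma.match(claims["icd9"]), "member_id"])
    pool = members[~members["member_id"].isin(any_sma)].reset_index(drop=True)
    pool_age = age_at(pool, pool["enroll_start"])

    case_members = members.set_index("member_id").loc[
        group_cases["member_id"]].reset_index()
    case_age = age_at(case_members, case_members["enroll_start"])
    lo, hi = float(case_age.min()), float(case_age.max())

    keep = (pool_age >= lo) & (pool_age <= hi)
    out = pd.DataFrame({"member_id": pool.loc[keep, "member_id"].to_numpy(),
                        "age_at_enrollment": pool_age[keep].to_numpy()})
    out.attrs["age_range"] = (lo, hi)
    return out


def apply_min_coverage(assignments: pd.DataFrame, windows: pd.DataFrame,
                       min_months: float = 6.0) -> pd.DataFrame:
    """Gate cohort members on enrolled months within the analysis window.

    Members whose window covers < ``min_months`` (inclusive boundary) move
    to role ``excluded`` with reason ``insufficient_coverage``; members with
    no window row at all (empty window) are treated as zero coverage.
    """
    days = ((windows["end"] - windows["start"]).dt.days + 1).clip(lower=0)
    months = pd.Series(days.to_numpy() / DAYS_PER_MONTH,
                       index=windows["member_id"]).groupby(level=0).max()
    out = assignments.copy()
    in_cohort = out["role"].isin(["case", "control"])
    cov = out["member_id"].map(months).fillna(0.0)
    # small epsilon so an exactly-6.0-month window is kept despite float division
    short = in_cohort & (cov < min_months - 1e-9)
    out.loc[short, "role"] = "excluded"
    out.loc[short, "exclusion_reason"] = "insufficient_coverage"
    out.loc[short, "group"] = pd.NA
    return out


def build_cohort(members: pd.DataFrame, claims: pd.DataFrame, *,
                 sma: CodeSet, neuromuscular: CodeSet, pregnancy: CodeSet,
                 group: str,
                 exclude_pregnant_controls: bool = False) -> pd.DataFrame:
    """Run selection steps 1–5 for one group.

    Returns one row per member: ``member_id, role
    (case/control/excluded/ineligible), group, first_sma_date,
    exclusion_reason``.  ``ineligible`` marks members that are simply not in
    this group-window universe (no SMA codes and out of the control age
    range, or cases belonging to another group).  The coverage gate
    (step 6) runs separately once windows exist — see
    :func:`apply_min_coverage`.
    """
    if group not in GROUP_BOUNDS:
        raise ValueError(f"unknown group {group!r}")

    out = pd.DataFrame({"member_id": members["member_id"]})
    out["role"] = "ineligible"
    out["group"] = pd.NA
    out["first_sma_date"] = pd.NaT
    out["exclusion_reason"] = pd.NA
    out = out.set_index("member_id")

    candidates = identify_sma_candidates(claims, sma)
    out.loc[candidates.attrs["single_visit"],
            ["role", "exclusion_reason"]] = ["excluded", "single_visit"]

    kept = apply_final_diagnosis_rule(candidates, claims, neuromuscular, sma)
    out.loc[kept.attrs["excluded_final_dx"],
            ["role", "exclusion_reason"]] = ["excluded", "final_dx_not_sma"]

    kept = apply_pregnancy_exclusion(kept, claims, pregnancy)
    out.loc[kept.attrs["excluded_pregnancy"],
            ["role", "exclusion_reason"]] = ["excluded", "pregnancy_codes"]

    strat = stratify_cases(kept, members)
    over_age = strat["group"].isna()
    out.loc[strat.loc[over_age, "member_id"],
            ["role", "exclusion_reason"]] = ["excluded", "age_out_of_range"]
    group_cases = strat[strat["group"] == group]
    out.loc[group_cases["member_id"], "role"] = "case"
    out.loc[group_cases["member_id"], "group"] = group
    out.loc[group_cases["member_id"], "first_sma_date"] = \
        group_cases.set_index("member_id")["first_sma_date"]
    # cases of other groups stay "ineligible" for this run

    if not group_cases.empty:
        controls = select_controls(members, claims, sma, group_cases)
        ctrl_ids = controls["member_id"]
        if exclude_pregnant_controls:
            flagged = set(claims.loc[pregnancy.match(claims["icd9"]), "member_id"])
            preg_ctrl = ctrl_ids[ctrl_ids.isin(flagged)]
            out.loc[preg_ctrl, ["role", "exclusion_reason"]] = \
                ["excluded", "pregnancy_codes"]
            ctrl_ids = ctrl_ids[~ctrl_ids.isin(flagged)]
        out.loc[ctrl_ids, "role"] = "control"
        out.loc[ctrl_ids, "group"] = group

    return out.reset_index()
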