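"""Cohort-characteristics summaries, Manhattan-plot export, provenance.

The cohort summary mirrors the usual claims-study descriptive table:
population, percent female, mean age at enrollment, mean enrollment months,
mean age at first SMA diagnosis (cases), and utilization measured as
distinct days with ≥1 diagnosis code per six enrolled months.  Arm
comparisons use a two-sided Welch t-test for continuous rows and a
two-proportion z-test for percent female (the choices are recorded in the
metadata every exported table carries).
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.proportion import proportions_ztest

from .claims_model import DAYS_PER_MONTH, age_at
from .phewas import PhewasRun
from .vocab import SystemMap, Vocabulary

__all__ = ["utilization", "summarize_cohort", "export_manhattan", "run_metadata"]

MANHATTAN_THRESHOLDS = (5e-2, 5e-4)
_P_FLOOR = np.nextafter(0.0, 1.0)


def utilization(window_claims: pd.DataFrame, windows: pd.DataFrame) -> pd.Series:
    """Distinct claim dates per 6 enrolled months, per member.

    Members in ``windows`` with no claims get 0.  Zero-length windows are a
    caller error (the coverage gate removes them).
    """
    days = (windows["end"] - windows["start"]).dt.days + 1
    if (days <= 0).any():
        raise ValueError("zero-length analysis window")
    months = pd.Series((days / DAYS_PER_MONTH).to_numpy(), index=windows["member_id"])
    dates = (window_claims.drop_duplicates(["member_id", "service_date"])
             .groupby("member_id")["service_date"].size())
    dates = dates.reindex(months.index, fill_value=0)
    return dates / (months / 6.0)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return float(ttest_ind(a, b, equal_var=False).pvalue)


def summarize_cohort(run: PhewasRun, members: pd.DataFrame,
                     claims: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table for one (group × window) run: one row per arm plus
    a p-value row comparing them."""
    design = run.design.set_index("member_id")
    win = run.windows
    util = utilization(run.window_claims, win)

    cases = design[design["sma"] == 1]
    ctrls = design[design["sma"] == 0]
    first_sma = run.assignments.set_index("member_id")["first_sma_date"]
    m_idx = members.set_index("member_id")

    def _arm_row(arm: pd.DataFrame, label: str) -> dict:
        ids = arm.index
        row = {
            "arm": label,
            "population": int(len(arm)),
            "pct_female": 100.0 * float(arm["female"].mean()) if len(arm) else np.nan,
            "mean_age_at_enrollment": float(arm["age_at_enrollment"].mean()),
            "mean_enrollment_months": float(arm["enrollment_months"].mean()),
            "mean_days_with_codes_per_6mo": float(util.loc[ids].mean()),
        }
        if label == "sma":
            sub = m_idx.loc[ids].reset_index()
            row["mean_age_at_first_sma"] = float(
                age_at(sub, first_sma.loc[ids].to_numpy()).mean())
        else:
            row["mean_age_at_first_sma"] = np.nan
        return row

    rows = [_arm_row(cases, "sma"), _arm_row(ctrls, "ctrl")]
    if len(cases) >= 2 and len(ctrls) >= 2:
        n_f = np.array([cases["female"].sum(), ctrls["female"].sum()])
        n = np.array([len(cases), len(ctrls)])
        with np.errstate(invalid="ignore"):
            p_female = float(proportions_ztest(n_f, n)[1])
        rows.append({
            "arm": "p_value", "population": np.nan,
            "pct_female": p_female,
            "mean_age_at_enrollment": _welch(cases["age_at_enrollment"].to_numpy(),
                                             ctrls["age_at_enrollment"].to_numpy()),
            "mean_enrollment_months": _welch(cases["enrollment_months"].to_numpy(),
                                             ctrls["enrollment_months"].to_numpy()),
            "mean_days_with_codes_per_6mo": _welch(util.loc[cases.index].to_numpy(),
                                                   util.loc[ctrls.index].to_numpy()),
            "mean_age_at_first_sma": np.nan,
        })
    summary = pd.DataFrame(rows)
    summary.attrs["tests"] = {"continuous": "welch_t_two_sided",
                              "proportion": "two_proportion_z"}
    return summary


def export_manhattan(results: pd.DataFrame, sm: SystemMap,
                     thresholds: tuple[float, ...] = MANHATTAN_THRESHOLDS
                     ) -> tuple[pd.DataFrame, dict]:
    """Plot-ready records: one per result row, grouped by system, with
    −log10 adjusted p (p = 0 clamped to the smallest positive double and
    flagged).  Threshold metadata is emitted alongside as −log10 values."""
    out = results[["phewas_code", "phenotype", "odds_ratio", "p_adjusted"]].copy()
    out["system_label"] = sm.map_codes(out["phewas_code"]).fillna("unassigned")
    clamped = out["p_adjusted"] <= 0
    out["clamped"] = clamped
    p = out["p_adjusted"].clip(lower=_P_FLOOR)
    out["neg_log10_p_adjusted"] = -np.log10(p)
    out = out.sort_values(["system_label", "phewas_code"]).reset_index(drop=True)
    meta = {"thresholds_p": list(thresholds),
            "thresholds_neg_log10": [-float(np.log10(t)) for t in thresholds],
            "n_clamped": int(clamped.sum())}
    return out[["phewas_code", "phenotype", "system_label",
                "neg_log10_p_adjusted", "odds_ratio", "clamped"]], meta


def run_metadata(run: PhewasRun, vocab: Vocabulary,
                 members: pd.DataFrame | None = None,
                 seed: int | None = None, extra: dict | None = None) -> dict:
    """Provenance attached to every exported table: config hash, seed,
    vocabulary digests, window kind, group label, and which age mode
    (day-precision birth_date vs year arithmetic) the data supported."""
    cfg = {k: getattr(run.config, k) for k in run.config.__dataclass_fields__}
    if members is not None and "birth_date" in members.columns:
        n_bd = int(members["birth_date"].notna().sum())
        age_mode = ("birth_date" if n_bd == len(members)
                    else "birth_year" if n_bd == 0 else "mixed")
    else:
        age_mode = "birth_year"
    meta = {
        "group": run.group,
        "window_kind": run.window_kind,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12],
        "seed": seed,
        "vocabulary_digests": vocab.digests(),
        "n_members_in_design": int(len(run.design)),
        "n_unmapped_claims": run.n_unmapped_claims,
        "age_mode": age_mode,
    }
    if extra:
        meta.update(extra)
    return meta
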