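"""Temporal trajectory analysis: system-level models and ordering.

For the pre-degeneration window only, phenotypes with adjusted p < 0.05
are grouped by physiological system; each system gets

* a system-level adjusted OR from the same logistic regression, with the
  outcome "any claim in the window mapping to any phenotype of the system";
* the median, over contributing cases, of days from the first system
  diagnosis to the case's inflection point (negative = before);
* a pooled R² diagnostic of offset magnitude against enrollment duration —
  a *low* value supports the ordering not being an artifact of how long
  members happened to be enrolled.

Systems with ≥5% prevalence among cases are arranged into the timeline,
earliest median first.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .phewas import AnalysisConfig, PhewasRun, fit_phenotype_model
from .vocab import SystemMap, Vocabulary

__all__ = ["group_significant_by_system", "fit_system_model",
           "median_days_to_inflection", "enrollment_duration_r2",
           "build_timeline", "run_trajectory", "TrajectoryResult"]

UNASSIGNED = "unassigned"


def group_significant_by_system(results: pd.DataFrame, sm: SystemMap,
                                alpha: float = 0.05) -> dict[str, list[str]]:
    """Partition phenotypes with p_adjusted < alpha (strict) by system;
    significant phenotypes missing from the system map fall into the
    ``unassigned`` bucket."""
    sig = results[results["p_adjusted"] < alpha]
    out: dict[str, list[str]] = {}
    for code in sig["phewas_code"]:
        system = sm.system(code) or UNASSIGNED
        out.setdefault(system, []).append(code)
    return {k: sorted(v) for k, v in sorted(out.items())}


def fit_system_model(codes: list[str], run: PhewasRun, vocab: Vocabulary):
    """System-level regression: outcome = any window claim mapping to any
    phenotype in ``codes``; covariates as in the phenotype-level model.
    Returns (FitResult, prevalence_sma, prevalence_ctrl)."""
    if not codes:
        raise ValueError("empty system phenotype set")
    mapped = run.window_claims.copy()
    mapped["phewas_code"] = vocab.phewas_map.map_codes(mapped["icd9"])
    carriers = set(mapped.loc[mapped["phewas_code"].isin(codes), "member_id"])
    design = run.design
    y = design["member_id"].isin(carriers).astype(float).to_numpy()
    n_sma = (design["sma"] == 1).sum()
    n_ctrl = (design["sma"] == 0).sum()
    prev_sma = float(((design["sma"] == 1) & (y == 1)).sum() / n_sma)
    prev_ctrl = float(((design["sma"] == 0) & (y == 1)).sum() / n_ctrl)
    fit = fit_phenotype_model(y, design, run.config)
    return fit, prev_sma, prev_ctrl


def _first_system_offsets(codes: list[str], run: PhewasRun,
                          vocab: Vocabulary) -> pd.Series:
    """Per contributing case: (first window date of any ICD9 mapping into
    the system) − inflection date, in days (negative)."""
    case_ids = set(run.design.loc[run.design["sma"] == 1, "member_id"])
    mapped = run.window_claims[run.window_claims["member_id"].isin(case_ids)].copy()
    mapped["phewas_code"] = vocab.phewas_map.map_codes(mapped["icd9"])
    hits = mapped[mapped["phewas_code"].isin(codes)]
    first = hits.groupby("member_id")["service_date"].min()
    inflection = run.windows.set_index("member_id")["inflection_date"]
    offsets = (first - inflection.loc[first.index]).dt.days.astype(float)
    return offsets


def median_days_to_inflection(codes: list[str], run: PhewasRun,
                              vocab: Vocabulary) -> tuple[float, int, pd.Series]:
    """Median offset over contributing cases (midpoint average for even
    counts); returns (median, n_contributing, per-case offsets).  With no
    contributing cases the median is NaN."""
    offsets = _first_system_offsets(codes, run, vocab)
    if len(offsets) == 0:
        return float("nan"), 0, offsets
    return float(np.median(offsets.to_numpy())), int(len(offsets)), offsets


def enrollment_duration_r2(offsets_by_system: dict[str, pd.Series],
                           design: pd.DataFrame) -> tuple[float, int]:
    """Pooled R² of |offset| (days) on enrollment months in the window,
    over all (case, system) contributions within a group.

    Needs ≥3 points and nonzero predictor variance; otherwise (NaN, n).
    """
    months = design.set_index("member_id")["enrollment_months"]
    xs, ys = [], []
    for offsets in offsets_by_system.values():
        xs.append(months.loc[offsets.index].to_numpy())
        ys.append(np.abs(offsets.to_numpy()))
    if not xs:
        return float("nan"), 0
    x, y = np.concatenate(xs), np.concatenate(ys)
    if len(x) < 3:
        raise ValueError(f"R^2 diagnostic needs >=3 points, got {len(x)}")
    if np.ptp(x) == 0:
        return float("nan"), int(len(x))
    res = linregress(x, y)
    return float(res.rvalue ** 2), int(len(x))


def build_timeline(trajectories: pd.DataFrame,
                   min_prevalence: float = 0.05) -> pd.DataFrame:
    """Timeline rows for systems with case prevalence ≥ ``min_prevalence``,
    sorted earliest (most negative median) first."""
    eps = 1e-12
    keep = trajectories[trajectories["prevalence_sma"] >= min_prevalence - eps]
    return (keep.sort_values(["median_days_before_inflection", "system"])
            [["system", "median_days_before_inflection", "prevalence_sma",
              "odds_ratio"]].reset_index(drop=True))


@dataclasses.dataclass
class TrajectoryResult:
    group: str
    #: system, odds_ratio, prevalence_ctrl, prevalence_sma,
    #: median_days_before_inflection, n_cases_contributing, fit_status
    trajectories: pd.DataFrame
    timeline: pd.DataFrame
    r_squared_vs_enrollment: float
    n_points: int


def run_trajectory(run: PhewasRun, vocab: Vocabulary,
                   config: AnalysisConfig | None = None,
                   min_prevalence: float = 0.05) -> TrajectoryResult:
    """System grouping, system-level fits, medians, timeline, R² diagnostic
    for one pre-degeneration screening run."""
    if run.window_kind != "pre_degeneration":
        raise ValueError("trajectories are defined for the pre-degeneration window")
    cfg = config or run.config
    by_system = group_significant_by_system(run.results, vocab.system_map, cfg.alpha)

    rows, offsets_by_system = [], {}
    for system, codes in by_system.items():
        fit, prev_sma, prev_ctrl = fit_system_model(codes, run, vocab)
        median, n_cases, offsets = median_days_to_inflection(codes, run, vocab)
        offsets_by_system[system] = offsets
        rows.append({
            "system": system, "odds_ratio": fit.odds_ratio,
            "prevalence_ctrl": prev_ctrl, "prevalence_sma": prev_sma,
            "median_days_before_inflection": median,
            "n_cases_contributing": n_cases, "fit_status": fit.fit_status,
        })
    trajectories = pd.DataFrame(rows, columns=["system", "odds_ratio",
                                               "prevalence_ctrl", "prevalence_sma",
                                               "median_days_before_inflection",
                                               "n_cases_contributing", "fit_status"])
    timeline = build_timeline(trajectories, min_prevalence)
    if offsets_by_system and sum(len(o) for o in offsets_by_system.values()) >= 3:
        r2, n_points = enrollment_duration_r2(offsets_by_system, run.design)
    else:
        r2, n_points = float("nan"), 0
    return TrajectoryResult(group=run.group, trajectories=trajectories,
                            timeline=timeline, r_squared_vs_enrollment=r2,
                            n_points=n_points)
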