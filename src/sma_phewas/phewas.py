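"""Phenome-wide screening: prevalence, 1% filter, adjusted logistic
regression, Benjamini–Hochberg FDR.

For one (group × window) analysis, each PheWAS group with member-level
prevalence ≥1% in *either* arm is tested with maximum-likelihood logistic
regression

    phenotype ~ sma + gender + age_at_enrollment + enrollment_months,

where the outcome is "≥1 claim in the member's window mapping to the
group", ``sma`` is the case indicator, and ``enrollment_months`` counts
months inside the analysis window.  The adjusted odds ratio is
``exp(coef(sma))`` with a Wald p-value; BH step-up adjustment is applied
across all phenotypes tested in the run.  Extreme imbalance is reported
as-is with a ``separation_flagged`` status (mirroring screens that print
near-separated odds ratios); an optional Firth-type penalized fit is
available for users who prefer shrinkage.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .claims_model import DAYS_PER_MONTH, age_at
from .vocab import PhewasMap, Vocabulary
from . import cohort as _cohort
from . import windows as _windows

__all__ = ["AnalysisConfig", "FitResult", "compute_prevalence",
           "filter_by_prevalence", "build_design", "fit_phenotype_model",
           "fit_firth", "adjust_fdr", "run_phewas"]


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and policy flags for one analysis run."""

    prevalence_threshold: float = 0.01
    alpha: float = 0.05           # significance cut on adjusted p-values
    min_coverage_months: float = 6.0
    truncate_controls: bool = True
    drop_unknown_gender: bool = True
    exclude_pregnant_controls: bool = False
    firth: bool = False
    #: |log-OR| beyond this flags quasi-separation
    separation_beta_bound: float = 15.0
    max_iterations: int = 200


@dataclasses.dataclass
class FitResult:
    odds_ratio: float
    p_value: float
    beta: float
    se: float
    fit_status: str  # ok | separation_flagged | not_converged | skipped


def compute_prevalence(arm_members: pd.Series | list, window_claims: pd.DataFrame,
                       pm: PhewasMap) -> pd.Series:
    """Member-level prevalence per PheWAS group within one arm.

    prevalence = (# arm members with ≥1 mapped claim in window) / (# arm
    members); a member with many claims in a group counts once.
    """
    ids = pd.Index(arm_members).unique()
    if len(ids) == 0:
        raise ValueError("empty arm")
    sub = window_claims[window_claims["member_id"].isin(set(ids))].copy()
    sub["phewas_code"] = pm.map_codes(sub["icd9"])
    mapped = sub.dropna(subset=["phewas_code"])
    counts = (mapped.drop_duplicates(["member_id", "phewas_code"])
              .groupby("phewas_code", sort=True)["member_id"].size())
    return counts / len(ids)


def filter_by_prevalence(prev_sma: pd.Series, prev_ctrl: pd.Series,
                         threshold: float = 0.01) -> list[str]:
    """PheWAS groups with prevalence ≥ threshold in either arm (inclusive)."""
    all_codes = prev_sma.index.union(prev_ctrl.index)
    ps = prev_sma.reindex(all_codes, fill_value=0.0)
    pc = prev_ctrl.reindex(all_codes, fill_value=0.0)
    eps = 1e-12  # guard the inclusive boundary against float representation
    keep = (ps >= threshold - eps) | (pc >= threshold - eps)
    return sorted(all_codes[keep])


def build_design(members: pd.DataFrame, assignments: pd.DataFrame,
                 windows: pd.DataFrame, *, drop_unknown_gender: bool = True) -> pd.DataFrame:
    """One covariate row per eligible cohort member.

    Columns: ``member_id, sma, female, age_at_enrollment,
    enrollment_months`` (months of enrollment inside the analysis window).
    """
    cohort = assignments[assignments["role"].isin(["case", "control"])]
    win = windows.set_index("member_id")
    keep = cohort[cohort["member_id"].isin(win.index)]
    m = members.set_index("member_id").loc[keep["member_id"]].reset_index()
    if drop_unknown_gender:
        known = (m["gender"] != "unknown").to_numpy()
        keep, m = keep[known], m[known]
    w = win.loc[keep["member_id"]]
    months = ((w["end"] - w["start"]).dt.days + 1) / DAYS_PER_MONTH
    return pd.DataFrame({
        "member_id": keep["member_id"].to_numpy(),
        "sma": (keep["role"] == "case").astype(float).to_numpy(),
        "female": (m["gender"] == "female").astype(float).to_numpy(),
        "age_at_enrollment": age_at(m, m["enroll_start"]).to_numpy(),
        "enrollment_months": months.to_numpy(),
    })


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = ["sma", "female", "age_at_enrollment", "enrollment_months"]
    # drop constant covariates (not the exposure) to keep the fit full-rank
    use = ["sma"] + [c for c in cols[1:] if design[c].nunique() > 1]
    X = np.column_stack([np.ones(len(design))] + [design[c].to_numpy() for c in use])
    return X, ["const"] + use


def fit_phenotype_model(y: np.ndarray, design: pd.DataFrame,
                        config: AnalysisConfig | None = None) -> FitResult:
    """ML logistic regression of a binary outcome on the SMA indicator plus
    covariates; returns the adjusted OR and Wald p for the SMA coefficient.

    Degenerate designs do not crash: a constant outcome is ``skipped``;
    non-convergence and quasi-separation are flagged, with the (extreme)
    estimate reported as-is unless ``config.firth`` asks for the penalized
    fit instead.
    """
    cfg = config or AnalysisConfig()
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        return FitResult(np.nan, np.nan, np.nan, np.nan, "skipped")
    if design["sma"].nunique() < 2:
        raise ValueError("design needs both exposed and unexposed members")
    X, names = _design_matrix(design)
    j = names.index("sma")

    if cfg.firth:
        beta, se, converged = fit_firth(y, X, max_iter=cfg.max_iterations)
        status = "ok" if converged else "not_converged"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=cfg.max_iterations,
                                         warn_convergence=False)
                beta_vec, se_vec = res.params, res.bse
                converged = bool(res.mle_retvals.get("converged", True))
            except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
                return FitResult(np.inf, np.nan, np.inf, np.nan, "separation_flagged")
        beta, se = float(beta_vec[j]), float(se_vec[j])
        # a diverging exposure estimate is (quasi-)separation even when the
        # optimizer also hit its iteration cap
        if abs(beta) > cfg.separation_beta_bound or not np.isfinite(se):
            status = "separation_flagged"
        elif not converged:
            status = "not_converged"
        else:
            status = "ok"
    if cfg.firth:
        beta, se = float(beta[j]), float(se[j])
        if abs(beta) > cfg.separation_beta_bound:
            status = "separation_flagged"
    p = 2.0 * norm.sf(abs(beta / se)) if se and np.isfinite(se) and se > 0 else np.nan
    return FitResult(float(np.exp(beta)), float(p) if p == p else np.nan,
                     beta, se, status)


def fit_firth(y: np.ndarray, X: np.ndarray, max_iter: int = 100,
              tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth-type penalized logistic regression (Jeffreys-prior score
    correction), Newton iterations with step-halving.

    Keeps estimates finite under separation; returns (beta, se, converged).
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        XtW = X.T * W
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X * W[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving for stability
        for _ in range(20):
            cand = beta + step
            if np.all(np.abs(cand) < 1e4):
                break
            step /= 2.0
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    W = expit(eta) * (1 - expit(eta))
    info = (X.T * W) @ X
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se, converged


def adjust_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q`` is the target FDR level used when thresholding downstream; the
    adjusted values themselves do not depend on it.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def run_phewas(members: pd.DataFrame, claims: pd.DataFrame, vocab: Vocabulary,
               *, group: str, window_kind: str,
               config: AnalysisConfig | None = None) -> "PhewasRun":
    """The full screening for one (group × window) analysis.

    Builds the cohort, the windows, the coverage gate, prevalences, the 1%
    filter, per-phenotype fits, and BH adjustment across all tested
    phenotypes.  Returns a :class:`PhewasRun` with the results table sorted
    by adjusted p-value.
    """
    cfg = config or AnalysisConfig()
    assignments = _cohort.build_cohort(
        members, claims, sma=vocab.sma, neuromuscular=vocab.neuromuscular,
        pregnancy=vocab.pregnancy, group=group,
        exclude_pregnant_controls=cfg.exclude_pregnant_controls)
    windows = _windows.build_windows(assignments, members, claims, window_kind,
                                     vocab.neuromuscular,
                                     truncate_controls=cfg.truncate_controls)
    assignments = _cohort.apply_min_coverage(assignments, windows,
                                             cfg.min_coverage_months)
    windows = windows[windows["member_id"].isin(
        set(assignments.loc[assignments["role"].isin(["case", "control"]),
                            "member_id"]))].reset_index(drop=True)

    design = build_design(members, assignments, windows,
                          drop_unknown_gender=cfg.drop_unknown_gender)
    wclaims = _windows.claims_in_window(claims, windows)
    wclaims = wclaims[wclaims["member_id"].isin(set(design["member_id"]))]

    case_ids = design.loc[design["sma"] == 1, "member_id"]
    ctrl_ids = design.loc[design["sma"] == 0, "member_id"]
    if len(case_ids) == 0 or len(ctrl_ids) == 0:
        raise ValueError(f"group {group}/{window_kind}: an arm is empty after gating")

    prev_sma = compute_prevalence(case_ids, wclaims, vocab.phewas_map)
    prev_ctrl = compute_prevalence(ctrl_ids, wclaims, vocab.phewas_map)
    tested = filter_by_prevalence(prev_sma, prev_ctrl, cfg.prevalence_threshold)

    mapped = wclaims.copy()
    mapped["phewas_code"] = vocab.phewas_map.map_codes(mapped["icd9"])
    n_unmapped = int(mapped["phewas_code"].isna().sum())
    carriers = {code: set(g["member_id"])
                for code, g in mapped.dropna(subset=["phewas_code"])
                .drop_duplicates(["member_id", "phewas_code"]).groupby("phewas_code")}

    rows = []
    ids = design["member_id"].to_numpy()
    pos = {mid: i for i, mid in enumerate(ids)}
    for code in tested:
        y = np.zeros(len(ids))
        y[[pos[m] for m in carriers.get(code, ()) if m in pos]] = 1.0
        fit = fit_phenotype_model(y, design, cfg)
        if fit.fit_status == "skipped":
            continue
        rows.append({
            "phewas_code": code,
            "phenotype": vocab.phewas_map.label(code),
            "odds_ratio": fit.odds_ratio,
            "beta": fit.beta, "se": fit.se,
            "p_raw": fit.p_value,
            "prevalence_sma": float(prev_sma.get(code, 0.0)),
            "prevalence_ctrl": float(prev_ctrl.get(code, 0.0)),
            "fit_status": fit.fit_status,
        })
    results = pd.DataFrame(rows, columns=["phewas_code", "phenotype", "odds_ratio",
                                          "beta", "se", "p_raw", "prevalence_sma",
                                          "prevalence_ctrl", "fit_status"])
    if len(results):
        usable = results["p_raw"].notna()
        results["p_adjusted"] = np.nan
        results.loc[usable, "p_adjusted"] = adjust_fdr(results.loc[usable, "p_raw"])
        results = results.sort_values(["p_adjusted", "phewas_code"],
                                      na_position="last").reset_index(drop=True)
    else:
        results["p_adjusted"] = pd.Series(dtype=float)
        warnings.warn(f"group {group}/{window_kind}: no phenotype passed the "
                      "prevalence filter", stacklevel=2)
    return PhewasRun(group=group, window_kind=window_kind, config=cfg,
                     assignments=assignments, windows=windows, design=design,
                     window_claims=wclaims, results=results,
                     n_unmapped_claims=n_unmapped)


@dataclasses.dataclass
class PhewasRun:
    """Everything produced by one (group × window) screening."""

    group: str
    window_kind: str
    config: AnalysisConfig
    assignments: pd.DataFrame
    windows: pd.DataFrame
    design: pd.DataFrame
    window_claims: pd.DataFrame
    results: pd.DataFrame
    n_unmapped_claims: int
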