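"""Synthetic longitudinal claims with planted, recoverable ground truth.

The real study population (a proprietary insurer database) is not
available, so every downstream stage is exercised on simulated member and
claims tables whose generative model matches the analysis model:

* Each member gets a gender, an age at enrollment, and a continuous
  enrollment span on a simulated calendar starting 2008-01-01.
* Case-like members carry ≥2 SMA diagnosis codes on distinct service dates
  plus a neuromuscular-degeneration code at a planted *inflection date*
  (the first sign of neuromuscular degeneration).  The first SMA code
  coincides with the inflection, so the pre-degeneration window contains no
  neuromuscular codes — exactly the structure the selection rules assume.
* Phenotype occurrence is Bernoulli per (member, phenotype) with
  ``logit = logit(baseline) + log(OR)·case + β_f·female + β_a·(age−ā) +
  β_m·(months−m̄)``, so the screening regression is correctly specified and
  adjusted-OR recovery is a sharp test.  Case carriers receive their first
  phenotype claim at ``inflection + Normal(offset_mean, offset_sd)`` days
  (negative = before degeneration), truncated into the enrollment span;
  control carriers at a uniform date within enrollment.
* Contamination scenarios plant the failure modes the selection rules must
  reject: pregnancy-billing pseudo-cases, members whose *final*
  neuromuscular diagnosis is not SMA, and single-SMA-code members.

All randomness is counter-based: every draw is a pure function of
``(seed, role, member index within role, draw tag)`` via a splitmix64
finalizer, so the same config yields byte-identical tables and changing one
arm's size never reshuffles another arm's members.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri
from scipy.stats import poisson

from .claims_model import DAYS_PER_MONTH, DAYS_PER_YEAR
from .fixtures import fixture_vocabulary
from .vocab import PhewasMap, SystemMap, Vocabulary

__all__ = ["EffectSpec", "Contamination", "CovariateEffects", "SimConfig",
           "GroundTruth", "SimResult", "generate_population", "truth_report"]

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)


def _mix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer (vectorized, wrapping uint64 arithmetic)
    with np.errstate(over="ignore"):
        x = x.copy()
        x ^= x >> _U64(30)
        x *= _U64(0xBF58476D1CE4E5B9)
        x ^= x >> _U64(27)
        x *= _U64(0x94D049BB133111EB)
        x ^= x >> _U64(31)
    return x


def _tag_hash(tag: str) -> np.uint64:
    return _U64(int.from_bytes(hashlib.blake2b(tag.encode(), digest_size=8).digest(), "little"))


def _uniforms(seed: int, tag: str, idx: np.ndarray) -> np.ndarray:
    """Uniform(0,1) draws, one per counter in ``idx`` (uint64 array)."""
    with np.errstate(over="ignore"):
        base = _mix64(np.array([_U64(seed & 0xFFFFFFFFFFFFFFFF)]))[0] ^ _tag_hash(tag)
        state = _mix64(np.array([base]))[0] + idx * _GOLDEN
    z = _mix64(_mix64(state))
    return (z >> _U64(11)) * (2.0 ** -53)


def _normals(seed: int, tag: str, idx: np.ndarray) -> np.ndarray:
    u = np.clip(_uniforms(seed, tag, idx), 1e-12, 1 - 1e-12)
    return ndtri(u)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """One planted phenotype effect.

    ``conditional_odds_ratio`` is the effect of case status holding the
    covariates fixed; ``baseline_prob`` is the control probability at the
    reference covariates (male, age and enrollment length at the midpoints
    of their sampling ranges).  ``onset_offset_mean_days`` is negative for
    onsets before the inflection.
    """

    phewas_code: str
    conditional_odds_ratio: float
    baseline_prob: float
    onset_offset_mean_days: float = -90.0
    onset_offset_sd_days: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prob < 1.0:
            raise ValueError(f"{self.phewas_code}: baseline_prob must be in (0,1)")
        if self.conditional_odds_ratio <= 0:
            raise ValueError(f"{self.phewas_code}: odds ratio must be > 0")
        if self.onset_offset_sd_days < 0:
            raise ValueError(f"{self.phewas_code}: offset sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class Contamination:
    """Fractions (of n_cases) of planted pseudo-cases to add."""

    pregnancy_frac: float = 0.0
    wrong_final_dx_frac: float = 0.0
    single_code_frac: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.astuple(self):
            if not 0.0 <= f <= 1.0:
                raise ValueError("contamination fractions must be in [0,1]")


@dataclasses.dataclass(frozen=True)
class CovariateEffects:
    """Covariate→outcome log-odds coefficients in the generative model.

    Zero by default (the analysis model is then over-specified but still
    consistent); nonzero values create genuine confounding pressure and
    test the covariate adjustment.
    """

    beta_female: float = 0.0
    beta_age_per_year: float = 0.0
    beta_enrollment_per_month: float = 0.0


@dataclasses.dataclass(frozen=True)
class SimConfig:
    n_cases: int
    n_controls: int
    seed: int = 0
    #: uniform range, months
    enrollment_length_months: tuple[float, float] = (24.0, 72.0)
    #: uniform range, years; pick per study-group scenario (A: infants, ...)
    age_at_enrollment_years: tuple[float, float] = (0.0, 0.5)
    gender_prob_female: float = 0.5
    effects: tuple[EffectSpec, ...] = ()
    null_phenotypes: int = 0
    null_baseline_prob: float = 0.05
    sma_code_count_per_case: int = 2
    sma_code_spacing_days: int = 30
    #: uniform range, days from enroll_start to the inflection point
    inflection_delay_days: tuple[float, float] = (270.0, 540.0)
    covariate_effects: CovariateEffects = CovariateEffects()
    contamination: Contamination = Contamination()
    #: fraction of controls carrying a non-SMA neuromuscular code
    control_neuromuscular_frac: float = 0.0
    #: expected unmapped "routine visit" claims per enrolled month
    background_rate_per_month: float = 0.0
    calendar_start: str = "2008-01-01"

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.null_phenotypes < 0:
            raise ValueError("counts must be >= 0")
        if self.sma_code_count_per_case < 2:
            raise ValueError("cases need at least 2 SMA codes")
        if not 0.0 < self.null_baseline_prob < 1.0:
            raise ValueError("null_baseline_prob must be in (0,1)")
        if not 0.0 <= self.gender_prob_female <= 1.0:
            raise ValueError("gender_prob_female must be in [0,1]")
        min_len_days = self.enrollment_length_months[0] * DAYS_PER_MONTH
        extra = self.sma_code_spacing_days if self.contamination.wrong_final_dx_frac > 0 else 0
        tail = ((self.sma_code_count_per_case - 1) * self.sma_code_spacing_days + extra)
        if self.inflection_delay_days[1] + tail >= min_len_days:
            raise ValueError(
                "infeasible config: inflection_delay_days max "
                f"({self.inflection_delay_days[1]:.0f}) plus {tail} days of post-"
                "inflection codes does not fit inside the minimum enrollment of "
                f"{min_len_days:.0f} days; lengthen enrollment or shorten the delay")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows, for use as a test oracle."""

    #: member_id, role (case/control/contaminant_*), female, age_at_enrollment,
    #: enrollment_months, inflection_date (NaT for controls)
    members: pd.DataFrame
    #: phewas_code, is_effect, conditional_odds_ratio, baseline_prob,
    #: onset_offset_mean_days, onset_offset_sd_days
    phenotypes: pd.DataFrame
    #: member_id, phewas_code, onset_date — every planted phenotype event
    events: pd.DataFrame
    #: member_id, service_date, icd9, cause — one row per generated claim
    claim_causes: pd.DataFrame


@dataclasses.dataclass
class SimResult:
    members: pd.DataFrame
    claims: pd.DataFrame
    truth: GroundTruth
    vocabulary: Vocabulary


_NULL_SYSTEM = "Other/Symptoms"
_BACKGROUND_ICD9 = "V700"  # routine exam; deliberately unmapped
_DEGENERATION_ICD9 = "7282"
_WRONG_DX_ICD9 = "3590"    # muscular dystrophy
_PREGNANCY_ICD9 = "V220"
_CTRL_NM_ICD9 = "3590"


def _extended_vocabulary(base: Vocabulary, null_codes: Sequence[str]) -> Vocabulary:
    """Add the synthetic null phenotypes to the base vocabulary's maps."""
    if not null_codes:
        return base
    pm = base.phewas_map.entries
    extra_pm = pd.DataFrame({
        "icd9": [f"N{i:03d}" for i in range(len(null_codes))],
        "phewas_code": list(null_codes),
        "phenotype_label": [f"Null phenotype {i}" for i in range(len(null_codes))],
    })
    sm = base.system_map.entries
    extra_sm = pd.DataFrame({"phewas_code": list(null_codes),
                             "system_label": _NULL_SYSTEM})
    return dataclasses.replace(
        base,
        phewas_map=PhewasMap(pd.concat([pm, extra_pm], ignore_index=True)),
        system_map=SystemMap(pd.concat([sm, extra_sm], ignore_index=True)),
    )


def generate_population(cfg: SimConfig,
                        vocabulary: Vocabulary | None = None) -> SimResult:
    """Generate members, claims, and the ground truth behind them.

    Deterministic given ``cfg`` (same config → byte-identical tables).
    Effects must reference PheWAS groups present in ``vocabulary`` (default:
    the bundled fixture vocabulary); null phenotypes get synthetic codes
    ``null_000…`` appended to the returned vocabulary.
    """
    base_vocab = fixture_vocabulary() if vocabulary is None else vocabulary
    null_codes = [f"null_{i:03d}" for i in range(cfg.null_phenotypes)]
    vocab = _extended_vocabulary(base_vocab, null_codes)

    for eff in cfg.effects:
        if not vocab.phewas_map.icd9_codes_for(eff.phewas_code):
            raise ValueError(f"effect references unknown PheWAS group {eff.phewas_code!r}")

    cal0 = pd.Timestamp(cfg.calendar_start)
    n_preg = round(cfg.contamination.pregnancy_frac * cfg.n_cases)
    n_wrong = round(cfg.contamination.wrong_final_dx_frac * cfg.n_cases)
    n_single = round(cfg.contamination.single_code_frac * cfg.n_cases)
    blocks = [("case", cfg.n_cases), ("contaminant_pregnancy", n_preg),
              ("contaminant_wrong_final_dx", n_wrong),
              ("contaminant_single_code", n_single), ("control", cfg.n_controls)]

    a_lo, a_hi = cfg.age_at_enrollment_years
    m_lo, m_hi = cfg.enrollment_length_months
    d_lo, d_hi = cfg.inflection_delay_days
    age_mid = (a_lo + a_hi) / 2.0
    months_mid = (m_lo + m_hi) / 2.0
    cov = cfg.covariate_effects

    member_rows, claim_parts, event_parts = [], [], []
    next_global = 0
    for role, n in blocks:
        if n == 0:
            continue
        idx = np.arange(n, dtype=np.uint64)
        ids = np.array([f"M{gi:07d}" for gi in range(next_global, next_global + n)])
        next_global += n
        case_like = role != "control"

        female = _uniforms(cfg.seed, f"{role}/gender", idx) < cfg.gender_prob_female
        if role == "contaminant_pregnancy":
            female[:] = True
        age = a_lo + _uniforms(cfg.seed, f"{role}/age", idx) * (a_hi - a_lo)
        months = m_lo + _uniforms(cfg.seed, f"{role}/months", idx) * (m_hi - m_lo)
        len_days = np.maximum(np.rint(months * DAYS_PER_MONTH).astype(np.int64), 1)
        start = np.floor(_uniforms(cfg.seed, f"{role}/start", idx) * 365).astype(np.int64)
        end = start + len_days - 1
        months_exact = len_days / DAYS_PER_MONTH

        if case_like:
            delay = np.rint(d_lo + _uniforms(cfg.seed, f"{role}/delay", idx)
                            * (d_hi - d_lo)).astype(np.int64)
            inflect = start + delay
        else:
            inflect = np.full(n, -1, dtype=np.int64)

        # --- SMA / neuromuscular code streams --------------------------------
        if case_like:
            n_sma = 1 if role == "contaminant_single_code" else cfg.sma_code_count_per_case
            for k in range(n_sma):
                day = inflect + k * cfg.sma_code_spacing_days
                claim_parts.append((ids, day, np.repeat("33510", n), "sma_dx"))
            if role != "contaminant_single_code":
                claim_parts.append((ids, inflect,
                                    np.repeat(_DEGENERATION_ICD9, n), "degeneration"))
            if role == "contaminant_pregnancy":
                claim_parts.append((ids, inflect,
                                    np.repeat(_PREGNANCY_ICD9, n), "pregnancy_billing"))
            if role == "contaminant_wrong_final_dx":
                last_sma = inflect + (n_sma - 1) * cfg.sma_code_spacing_days
                claim_parts.append((ids, last_sma + cfg.sma_code_spacing_days,
                                    np.repeat(_WRONG_DX_ICD9, n), "wrong_final_dx"))
        elif cfg.control_neuromuscular_frac > 0:
            hit = _uniforms(cfg.seed, f"{role}/nm", idx) < cfg.control_neuromuscular_frac
            day = start + np.floor(_uniforms(cfg.seed, f"{role}/nm_day", idx)
                                   * len_days).astype(np.int64)
            claim_parts.append((ids[hit], day[hit],
                                np.repeat(_CTRL_NM_ICD9, int(hit.sum())), "control_nm"))

        # --- phenotype streams ----------------------------------------------
        specs = list(cfg.effects) + [
            EffectSpec(code, 1.0, cfg.null_baseline_prob) for code in null_codes]
        for j, eff in enumerate(specs):
            eta = (logit(eff.baseline_prob)
                   + np.log(eff.conditional_odds_ratio) * float(case_like)
                   + cov.beta_female * female.astype(float)
                   + cov.beta_age_per_year * (age - age_mid)
                   + cov.beta_enrollment_per_month * (months_exact - months_mid))
            occurs = _uniforms(cfg.seed, f"{role}/ph{j}/occ", idx) < expit(eta)
            k = int(occurs.sum())
            if k == 0:
                continue
            if case_like:
                offs = eff.onset_offset_mean_days + eff.onset_offset_sd_days * \
                    _normals(cfg.seed, f"{role}/ph{j}/onset", idx)
                onset = inflect + np.rint(offs).astype(np.int64)
                onset = np.clip(onset, start, end)
            else:
                onset = start + np.floor(
                    _uniforms(cfg.seed, f"{role}/ph{j}/onset", idx) * len_days
                ).astype(np.int64)
            icd9 = vocab.phewas_map.icd9_codes_for(eff.phewas_code)[0]
            claim_parts.append((ids[occurs], onset[occurs], np.repeat(icd9, k),
                                f"phenotype:{eff.phewas_code}"))
            event_parts.append(pd.DataFrame({
                "member_id": ids[occurs], "phewas_code": eff.phewas_code,
                "onset_day": onset[occurs]}))

        # --- background utilization (unmapped routine-visit claims) ----------
        if cfg.background_rate_per_month > 0:
            lam = cfg.background_rate_per_month * months_exact
            # Poisson count via inverse-CDF on one uniform per member,
            # then one uniform per (member, slot) for the date
            max_k = int(np.ceil(lam.max() + 6 * np.sqrt(lam.max() + 1)))
            u = _uniforms(cfg.seed, f"{role}/bg/count", idx)
            counts = np.minimum(poisson.ppf(u, lam).astype(np.int64), max_k)
            rep_ids = np.repeat(ids, counts)
            rep_start = np.repeat(start, counts)
            rep_len = np.repeat(len_days, counts)
            slot = np.concatenate([np.arange(c, dtype=np.uint64) for c in counts]) \
                if counts.sum() else np.array([], dtype=np.uint64)
            rep_idx = np.repeat(idx, counts)
            with np.errstate(over="ignore"):
                counter = rep_idx + slot * _U64(0x5851F42D4C957F2D)
            day = rep_start + np.floor(
                _uniforms(cfg.seed, f"{role}/bg/day", counter) * rep_len).astype(np.int64)
            claim_parts.append((rep_ids, day, np.repeat(_BACKGROUND_ICD9, len(rep_ids)),
                                "background"))

        member_rows.append(pd.DataFrame({
            "member_id": ids, "role": role, "female": female,
            "age_at_enrollment": age, "enrollment_months": months_exact,
            "start_day": start, "end_day": end, "inflect_day": inflect,
        }))

    truth_members = (pd.concat(member_rows, ignore_index=True) if member_rows
                     else pd.DataFrame(columns=["member_id", "role", "female",
                                                "age_at_enrollment", "enrollment_months",
                                                "start_day", "end_day", "inflect_day"]))

    def _day_to_date(days: np.ndarray | pd.Series) -> pd.Series:
        idx = days.index if isinstance(days, pd.Series) else None
        return pd.Series(cal0 + pd.to_timedelta(np.asarray(days, dtype=np.int64),
                                                unit="D"), index=idx)

    # members table
    start_dates = _day_to_date(truth_members["start_day"])
    birth = start_dates - pd.to_timedelta(
        np.rint(truth_members["age_at_enrollment"].to_numpy() * DAYS_PER_YEAR), unit="D")
    members = pd.DataFrame({
        "member_id": truth_members["member_id"],
        "gender": np.where(truth_members["female"], "female", "male"),
        "birth_year": birth.dt.year,
        "birth_date": birth,
        "enroll_start": start_dates,
        "enroll_end": _day_to_date(truth_members["end_day"]),
    })

    # claims table with causes
    if claim_parts:
        cc = pd.DataFrame({
            "member_id": np.concatenate([p[0] for p in claim_parts]),
            "day": np.concatenate([np.asarray(p[1], dtype=np.int64) for p in claim_parts]),
            "icd9": np.concatenate([p[2] for p in claim_parts]),
            "cause": np.concatenate([np.repeat(p[3], len(p[0])) for p in claim_parts]),
        })
    else:
        cc = pd.DataFrame(columns=["member_id", "day", "icd9", "cause"])
    cc["service_date"] = _day_to_date(cc["day"]) if len(cc) else pd.Series([], dtype="datetime64[ns]")
    cc = cc.sort_values(["member_id", "day", "icd9", "cause"],
                        kind="mergesort").reset_index(drop=True)
    claims = cc[["member_id", "service_date", "icd9"]].copy()

    events = (pd.concat(event_parts, ignore_index=True) if event_parts
              else pd.DataFrame(columns=["member_id", "phewas_code", "onset_day"]))
    events["onset_date"] = _day_to_date(events["onset_day"]) if len(events) else \
        pd.Series([], dtype="datetime64[ns]")

    gt_members = truth_members.copy()
    gt_members["inflection_date"] = _day_to_date(gt_members["inflect_day"].clip(lower=0))
    gt_members.loc[gt_members["inflect_day"] < 0, "inflection_date"] = pd.NaT

    specs_all = list(cfg.effects) + [EffectSpec(c, 1.0, cfg.null_baseline_prob)
                                     for c in null_codes]
    phenotypes = pd.DataFrame({
        "phewas_code": [s.phewas_code for s in specs_all],
        "is_effect": [i < len(cfg.effects) for i in range(len(specs_all))],
        "conditional_odds_ratio": [s.conditional_odds_ratio for s in specs_all],
        "baseline_prob": [s.baseline_prob for s in specs_all],
        "onset_offset_mean_days": [s.onset_offset_mean_days for s in specs_all],
        "onset_offset_sd_days": [s.onset_offset_sd_days for s in specs_all],
    })

    truth = GroundTruth(
        members=gt_members[["member_id", "role", "female", "age_at_enrollment",
                            "enrollment_months", "inflection_date"]],
        phenotypes=phenotypes,
        events=events[["member_id", "phewas_code", "onset_date"]],
        claim_causes=cc[["member_id", "service_date", "icd9", "cause"]],
    )
    return SimResult(members=members, claims=claims, truth=truth, vocabulary=vocab)


def truth_report(gt: GroundTruth) -> pd.DataFrame:
    """Per-phenotype planted parameters and realized quantities.

    One row per phenotype (effects and nulls alike, even with zero realized
    carriers): planted OR, realized member-level prevalence among true cases
    and true controls, and the planted median onset offset.
    """
    case_ids = set(gt.members.loc[gt.members["role"] == "case", "member_id"])
    ctrl_ids = set(gt.members.loc[gt.members["role"] == "control", "member_id"])
    carriers = gt.events.drop_duplicates(["member_id", "phewas_code"])
    rows = []
    for ph in gt.phenotypes.itertuples():
        ids = set(carriers.loc[carriers["phewas_code"] == ph.phewas_code, "member_id"])
        rows.append({
            "phewas_code": ph.phewas_code,
            "is_effect": ph.is_effect,
            "planted_odds_ratio": ph.conditional_odds_ratio,
            "prevalence_case": len(ids & case_ids) / len(case_ids) if case_ids else np.nan,
            "prevalence_control": len(ids & ctrl_ids) / len(ctrl_ids) if ctrl_ids else np.nan,
            "planted_median_offset_days": ph.onset_offset_mean_days,
        })
    return pd.DataFrame(rows)
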