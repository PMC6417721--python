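"""Core claims-data containers, code/date normalization, and table I/O.

The whole pipeline operates on two flat tables:

* **members** — one row per insured person: ``member_id``, ``gender``
  (female/male/unknown), ``birth_year``, optional ``birth_date``,
  ``enroll_start``, ``enroll_end`` (a single continuous enrollment span).
* **claims** — one row per dated diagnosis event: ``member_id``,
  ``service_date``, ``icd9`` (stored in canonical, dot-free form).

Both are plain :class:`pandas.DataFrame` objects; the dataclasses
:class:`Member` and :class:`Claim` document the row contracts and are handy
for constructing small fixtures.  Readers validate row-level invariants and
report rejected rows with line numbers instead of failing wholesale.

Claims schemas disagree on dotted versus undotted ICD9 codes ("335.10" vs
"33510"); every code entering the pipeline is first passed through
:func:`normalize_code` and all downstream matching happens on canonical
forms only.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "Gender",
    "Member",
    "Claim",
    "FormatError",
    "CodeError",
    "ReadReport",
    "normalize_code",
    "normalize_codes",
    "age_at",
    "read_members",
    "read_claims",
    "write_members",
    "write_claims",
]

#: Fixed month length (days) used for *all* month arithmetic, so results do
#: not depend on calendar conventions.
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

MEMBER_REQUIRED_COLUMNS = ("member_id", "gender", "birth_year", "enroll_start", "enroll_end")
CLAIM_REQUIRED_COLUMNS = ("member_id", "service_date", "icd9")

#: Default vocabulary for mapping free-text gender strings; anything else
#: becomes ``unknown``.
GENDER_VOCAB = {
    "f": "female", "female": "female", "w": "female",
    "m": "male", "male": "male",
}


class Gender(str, enum.Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class FormatError(ValueError):
    """A table is structurally unusable (e.g. a required column is missing)."""


class CodeError(ValueError):
    """A diagnosis code is empty or unusable after normalization."""


@dataclasses.dataclass(frozen=True)
class Member:
    """One insured person.

    ``birth_date`` is optional: claims extracts usually carry only a birth
    year, but day-level ages (fractional years for infants) need a full
    date.  :func:`age_at` uses whichever is present.
    """

    member_id: str
    gender: str
    birth_year: int
    enroll_start: _dt.date
    enroll_end: _dt.date
    birth_date: _dt.date | None = None

    def __post_init__(self) -> None:
        for field in ("enroll_start", "enroll_end", "birth_date"):
            value = getattr(self, field)
            if isinstance(value, str):
                object.__setattr__(self, field, _dt.date.fromisoformat(value))
        if self.enroll_start > self.enroll_end:
            raise ValueError(f"{self.member_id}: enroll_start after enroll_end")
        if self.birth_year > self.enroll_end.year:
            raise ValueError(f"{self.member_id}: born after enrollment end")
        if self.birth_date is not None and self.birth_date.year != self.birth_year:
            raise ValueError(f"{self.member_id}: birth_date year != birth_year")


@dataclasses.dataclass(frozen=True)
class Claim:
    """One dated diagnosis event."""

    member_id: str
    service_date: _dt.date
    icd9: str

    def __post_init__(self) -> None:
        if isinstance(self.service_date, str):
            object.__setattr__(self, "service_date",
                               _dt.date.fromisoformat(self.service_date))
        if not self.icd9:
            raise CodeError(f"{self.member_id}: empty diagnosis code")
        object.__setattr__(self, "icd9", normalize_code(self.icd9))


@dataclasses.dataclass
class ReadReport:
    """Row-level outcome of reading a delimited table."""

    path: str
    n_rows: int = 0
    n_accepted: int = 0
    #: (1-based line number incl. header, reason) for each rejected row.
    rejected: list[tuple[int, str]] = dataclasses.field(default_factory=list)
    #: Free-form counters (e.g. claims whose member is absent from the
    #: member table — retained, but flagged for the caller).
    flags: dict[str, int] = dataclasses.field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# Code and date normalization
# ---------------------------------------------------------------------------

def normalize_code(raw: str) -> str:
    """Canonicalize an ICD9 code: strip whitespace, drop separator dots,
    uppercase (preserving V/E prefixes).  Idempotent.

    Raises :class:`CodeError` if nothing is left after stripping.
    """
    if raw is None:
        raise CodeError("diagnosis code is None")
    canonical = str(raw).replace(".", "").strip().upper()
    if not canonical:
        raise CodeError(f"diagnosis code {raw!r} empty after normalization")
    return canonical


def normalize_codes(codes: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_code`; empty results become ``NaN``
    (callers decide whether to reject the rows)."""
    out = codes.astype("string").str.replace(".", "", regex=False).str.strip().str.upper()
    return out.mask(out.str.len().fillna(0) == 0)


def age_at(members: pd.DataFrame, dates) -> pd.Series:
    """Age in years of each member at ``dates`` (scalar or aligned Series).

    Members with a ``birth_date`` get day-precision ages
    (``days / 365.25``); the rest fall back to calendar-year arithmetic
    (``year(date) - birth_year``), which is integer-valued.  A date before
    the birth reference is a data error.
    """
    if np.isscalar(dates) or isinstance(dates, (str, _dt.date, pd.Timestamp)):
        dates = pd.Series(pd.Timestamp(dates), index=members.index)
    else:
        dates = pd.to_datetime(pd.Series(dates))
        dates.index = members.index

    if "birth_date" in members.columns:
        birth_date = pd.to_datetime(members["birth_date"])
    else:
        birth_date = pd.Series(pd.NaT, index=members.index)
    has_bd = birth_date.notna()

    age = pd.Series(np.nan, index=members.index, dtype=float)
    age[has_bd] = (dates[has_bd] - birth_date[has_bd]).dt.days / DAYS_PER_YEAR
    age[~has_bd] = dates[~has_bd].dt.year - members.loc[~has_bd, "birth_year"].astype(int)
    if (age < 0).any():
        bad = members.loc[age < 0, "member_id"].tolist()[:5]
        raise ValueError(f"date precedes birth reference for members {bad}")
    return age


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        # autodetect: sniff the header line
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_members(path: str | Path, sep: str | None = None,
                 gender_vocab: dict[str, str] | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read a members table, rejecting rows that violate invariants.

    Returns the accepted rows (typed: dates as datetime64, birth_year int)
    and a :class:`ReadReport` listing each rejected row with its 1-based
    line number and a reason.  Gender strings outside the vocabulary map to
    ``unknown``.
    """
    raw = _read_table(path, sep)
    _require_columns(raw, MEMBER_REQUIRED_COLUMNS, path)
    report = ReadReport(path=str(path), n_rows=len(raw))
    vocab = GENDER_VOCAB if gender_vocab is None else gender_vocab

    df = pd.DataFrame(index=raw.index)
    df["member_id"] = raw["member_id"].str.strip()
    df["gender"] = raw["gender"].str.strip().str.lower().map(vocab).fillna("unknown")
    df["birth_year"] = pd.to_numeric(raw["birth_year"], errors="coerce")
    df["birth_date"] = (pd.to_datetime(raw["birth_date"], errors="coerce", format="%Y-%m-%d")
                        if "birth_date" in raw.columns else pd.NaT)
    df["enroll_start"] = pd.to_datetime(raw["enroll_start"], errors="coerce", format="%Y-%m-%d")
    df["enroll_end"] = pd.to_datetime(raw["enroll_end"], errors="coerce", format="%Y-%m-%d")

    reason = pd.Series("", index=raw.index, dtype=object)

    def _flag(mask: pd.Series, why: str) -> None:
        mask = mask.fillna(False) & (reason == "")
        reason[mask] = why

    _flag(df["member_id"] == "", "empty member_id")
    _flag(df["birth_year"].isna(), "unparseable birth_year")
    _flag(df["enroll_start"].isna(), "unparseable enroll_start")
    _flag(df["enroll_end"].isna(), "unparseable enroll_end")
    has_raw_bd = ("birth_date" in raw.columns) and True
    if has_raw_bd:
        _flag((raw["birth_date"].str.strip() != "") & df["birth_date"].isna(),
              "unparseable birth_date")
    _flag(df["enroll_start"] > df["enroll_end"], "enroll_end before enroll_start")
    _flag(df["birth_year"] > df["enroll_end"].dt.year, "born after enrollment end")
    _flag(df["birth_date"].notna() & (df["birth_date"].dt.year != df["birth_year"]),
          "birth_date year != birth_year")

    bad = reason != ""
    # +2: 1-based numbering plus the header line
    report.rejected = [(int(i) + 2, r) for i, r in reason[bad].items()]
    out = df[~bad].copy()
    out["birth_year"] = out["birth_year"].astype(int)
    report.n_accepted = len(out)
    return out.reset_index(drop=True), report


def read_claims(path: str | Path, sep: str | None = None,
                known_members: Iterable[str] | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read a claims table; codes are canonicalized, blank-code or bad-date
    rows rejected.  Duplicate (member, date, code) rows are retained —
    de-duplication is a downstream policy.  If ``known_members`` is given,
    claims for members outside it are retained but counted in
    ``report.flags["unknown_member"]``.
    """
    raw = _read_table(path, sep)
    _require_columns(raw, CLAIM_REQUIRED_COLUMNS, path)
    report = ReadReport(path=str(path), n_rows=len(raw))

    df = pd.DataFrame(index=raw.index)
    df["member_id"] = raw["member_id"].str.strip()
    df["service_date"] = pd.to_datetime(raw["service_date"], errors="coerce", format="%Y-%m-%d")
    df["icd9"] = normalize_codes(raw["icd9"])

    reason = pd.Series("", index=raw.index, dtype=object)
    reason[(df["member_id"] == "") & (reason == "")] = "empty member_id"
    reason[df["service_date"].isna() & (reason == "")] = "unparseable service_date"
    reason[df["icd9"].isna() & (reason == "")] = "blank diagnosis code"

    bad = reason != ""
    report.rejected = [(int(i) + 2, r) for i, r in reason[bad].items()]
    out = df[~bad].copy()
    out["icd9"] = out["icd9"].astype(str)
    if known_members is not None:
        unknown = ~out["member_id"].isin(set(known_members))
        if unknown.any():
            report.flags["unknown_member"] = int(unknown.sum())
    report.n_accepted = len(out)
    return out.reset_index(drop=True), report


def _date_col(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s).dt.strftime("%Y-%m-%d")


def write_members(members: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    out = members.copy()
    for col in ("enroll_start", "enroll_end"):
        out[col] = _date_col(out[col])
    if "birth_date" in out.columns:
        bd = pd.to_datetime(out["birth_date"])
        out["birth_date"] = bd.dt.strftime("%Y-%m-%d").where(bd.notna(), "")
    cols = ["member_id", "gender", "birth_year"] + (
        ["birth_date"] if "birth_date" in out.columns else []) + ["enroll_start", "enroll_end"]
    out[cols].to_csv(path, sep=sep, index=False)


def write_claims(claims: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    out = claims.copy()
    out["service_date"] = _date_col(out["service_date"])
    out[list(CLAIM_REQUIRED_COLUMNS)].to_csv(path, sep=sep, index=False)


def members_frame(members: Iterable[Member]) -> pd.DataFrame:
    """Build a members table from :class:`Member` records (fixture helper)."""
    rows = [dataclasses.asdict(m) for m in members]
    df = pd.DataFrame(rows)
    for col in ("birth_date", "enroll_start", "enroll_end"):
        df[col] = pd.to_datetime(df[col])
    return df[["member_id", "gender", "birth_year", "birth_date", "enroll_start", "enroll_end"]]


def claims_frame(claims: Iterable[Claim]) -> pd.DataFrame:
    """Build a claims table from :class:`Claim` records, normalizing codes."""
    rows = [dataclasses.asdict(c) for c in claims]
    df = pd.DataFrame(rows, columns=["member_id", "service_date", "icd9"])
    if len(df):
        df["service_date"] = pd.to_datetime(df["service_date"])
        df["icd9"] = df["icd9"].map(normalize_code)
    return df
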