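"""Per-member analysis windows.

Two window kinds drive the two analyses:

* ``entire`` — the member's whole enrollment span.
* ``pre_degeneration`` — enrollment start up to the day *before* the
  member's inflection point (their first claim bearing any
  neuromuscular-disease or degeneration code).  "Prior to" is read
  strictly: diagnoses on the inflection date are part of the degeneration
  presentation and are excluded from the window.

Controls are by default also truncated at their own inflection point if
they carry neuromuscular codes (``truncate_controls``); controls without
such codes keep their full enrollment.
"""

from __future__ import annotations

import pandas as pd

from .vocab import CodeSet

__all__ = ["find_inflection_point", "build_windows", "claims_in_window"]

WINDOW_KINDS = ("entire", "pre_degeneration")


def find_inflection_point(claims: pd.DataFrame, neuromuscular: CodeSet) -> pd.Series:
    """Earliest service date per member carrying any neuromuscular-set code.

    Members without such claims are absent from the returned Series (the
    SMA codes themselves are neuromuscular, so every case has one).
    """
    nm = claims[neuromuscular.match(claims["icd9"])]
    return nm.groupby("member_id")["service_date"].min()


def build_windows(assignments: pd.DataFrame, members: pd.DataFrame,
                  claims: pd.DataFrame, kind: str, neuromuscular: CodeSet,
                  truncate_controls: bool = True) -> pd.DataFrame:
    """One :class:`AnalysisWindow` row per cohort member (cases + controls).

    Columns: ``member_id, kind, start, end, inflection_date``.  Members
    whose window is empty (inflection on or before enrollment start) are
    dropped.  In ``pre_degeneration`` mode a case without an inflection
    date is impossible — cases carry SMA codes — and raises.
    """
    if kind not in WINDOW_KINDS:
        raise ValueError(f"unknown window kind {kind!r}")
    cohort = assignments[assignments["role"].isin(["case", "control"])]
    m = members.set_index("member_id").loc[cohort["member_id"]]

    win = pd.DataFrame({
        "member_id": cohort["member_id"].to_numpy(),
        "kind": kind,
        "start": m["enroll_start"].to_numpy(),
        "end": m["enroll_end"].to_numpy(),
        "inflection_date": pd.NaT,
    })
    inflection = find_inflection_point(claims, neuromuscular)
    win["inflection_date"] = win["member_id"].map(inflection)

    if kind == "pre_degeneration":
        is_case = win["member_id"].isin(
            set(cohort.loc[cohort["role"] == "case", "member_id"]))
        if (is_case & win["inflection_date"].isna()).any():
            raise AssertionError("case without inflection date: cases carry SMA codes")
        truncate = is_case | (truncate_controls & win["inflection_date"].notna())
        capped = win["inflection_date"] - pd.Timedelta(days=1)
        win.loc[truncate, "end"] = pd.DataFrame(
            {"a": win.loc[truncate, "end"], "b": capped[truncate]}).min(axis=1)
        win = win[win["start"] <= win["end"]].reset_index(drop=True)
    else:
        win = win.reset_index(drop=True)
    return win


def claims_in_window(claims: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Claims falling inside each member's window (inclusive of both ends;
    for pre-degeneration windows the end precedes the inflection date, so
    all returned claims strictly precede it)."""
    merged = claims.merge(windows[["member_id", "start", "end"]], on="member_id")
    inside = (merged["service_date"] >= merged["start"]) & \
             (merged["service_date"] <= merged["end"])
    return merged.loc[inside, list(claims.columns)].reset_index(drop=True)
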