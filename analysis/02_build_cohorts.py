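#!/usr/bin/env python
"""Select cases and controls and build the analysis windows.

For each simulated group this re-reads the delimited tables written by
01_simulate.py (exercising the production I/O path), applies the selection
rules — ≥2 SMA codes on distinct dates, final neuromuscular diagnosis SMA,
pregnancy exclusion, age stratification, age-matched control pool, 6-month
coverage gate — in both window modes, and reports how the roles fell out.
Against the planted truth, all three contamination scenarios must end up
excluded with the right reason.

Writes results/cohort_counts.tsv and the per-member audit tables under
scratch/analysis/<group>/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sma_phewas.claims_model import read_claims, read_members
from sma_phewas.cohort import apply_min_coverage, build_cohort
from sma_phewas.vocab import load_vocabulary
from sma_phewas.windows import build_windows

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    rows = []
    for group in ("A", "B", "C"):
        d = ROOT / "scratch" / "analysis" / group
        members, _ = read_members(d / "members.tsv")
        claims, _ = read_claims(d / "claims.tsv")
        vocab = load_vocabulary(d / "vocab")
        truth = pd.read_csv(d / "truth_members.tsv", sep="\t").set_index("member_id")

        base = build_cohort(members, claims, sma=vocab.sma,
                            neuromuscular=vocab.neuromuscular,
                            pregnancy=vocab.pregnancy, group=group)
        for kind in ("entire", "pre_degeneration"):
            win = build_windows(base, members, claims, kind, vocab.neuromuscular)
            asg = apply_min_coverage(base, win)
            asg.to_csv(d / f"assignments_{kind}.tsv", sep="\t", index=False)
            win.to_csv(d / f"windows_{kind}.tsv", sep="\t", index=False)
            counts = asg["role"].value_counts().to_dict()
            cases = set(asg.loc[asg["role"] == "case", "member_id"])
            planted = set(truth.index[truth["role"] == "case"])
            rows.append({"group": group, "window": kind,
                         "cases": counts.get("case", 0),
                         "controls": counts.get("control", 0),
                         "excluded": counts.get("excluded", 0),
                         "ineligible": counts.get("ineligible", 0),
                         "non_planted_cases": len(cases - planted),
                         "planted_cases_missed": len(planted - cases)})
            print(f"group {group:>1} {kind:<16} cases={counts.get('case', 0):>4} "
                  f"controls={counts.get('control', 0):>6} "
                  f"excluded={counts.get('excluded', 0):>3} "
                  f"(spurious cases: {len(cases - planted)})")

    out = ROOT / "results" / "cohort_counts.tsv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"-> {out}")


if __name__ == "__main__":
    main()
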