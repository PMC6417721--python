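#!/usr/bin/env python
"""Simulate the synthetic claims study: three severity-group scenarios.

No real claims data ship with this project, so the study runs on synthetic
universes with planted truth, one per severity group:

* Group A — infantile-onset cases (enrolled in the first half-year of
  life), with planted cardiovascular/skeletal defects far before the first
  neuromuscular sign and gastrointestinal problems shortly before it.
* Group B — juvenile-onset cases with a broader set of planted systemic
  effects (metabolic earliest, then gastrointestinal, cardiovascular,
  skeletal, neurological).
* Group C — adult-onset cases, including male-reproductive involvement.

Each universe adds 15 null phenotypes and 10% of each contamination
scenario (pregnancy-billing pseudo-cases, wrong-final-diagnosis members,
single-code members).  Tables are written under scratch/analysis/<group>/
for the downstream steps; a compact planted-truth summary goes to
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sma_phewas.claims_model import write_claims, write_members
from sma_phewas.synthetic_claims import (Contamination, EffectSpec, SimConfig,
                                         generate_population, truth_report)

ROOT = Path(__file__).resolve().parents[1]

SCENARIOS = {
    "A": dict(
        n_cases=80, n_controls=6_000,
        age_at_enrollment_years=(0.0, 0.5),
        effects=(EffectSpec("395.3", 8.0, 0.02, -142, 10.0),
                 EffectSpec("737.3", 5.0, 0.07, -141, 10.0),
                 EffectSpec("350.3", 9.0, 0.02, -38, 10.0),
                 EffectSpec("532", 6.0, 0.02, -8, 3.0)),
    ),
    "B": dict(
        n_cases=150, n_controls=10_000,
        age_at_enrollment_years=(3.0, 18.0),
        enrollment_length_months=(36.0, 84.0),
        inflection_delay_days=(360.0, 720.0),
        effects=(EffectSpec("276.8", 4.0, 0.04, -300, 20.0),
                 EffectSpec("563", 3.5, 0.10, -260, 20.0),
                 EffectSpec("747.11", 6.0, 0.01, -250, 20.0),
                 EffectSpec("754.7", 5.0, 0.04, -220, 20.0),
                 EffectSpec("350.3", 9.0, 0.03, -170, 20.0)),
    ),
    "C": dict(
        n_cases=200, n_controls=12_000,
        age_at_enrollment_years=(25.0, 55.0),
        enrollment_length_months=(36.0, 84.0),
        inflection_delay_days=(360.0, 720.0),
        effects=(EffectSpec("427.6", 3.3, 0.01, -280, 20.0),
                 EffectSpec("563", 2.4, 0.06, -270, 20.0),
                 EffectSpec("257.1", 2.8, 0.02, -230, 20.0),
                 EffectSpec("350.3", 3.0, 0.07, -150, 20.0)),
    ),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    summaries = []
    for group, kw in SCENARIOS.items():
        cfg = SimConfig(seed=args.seed * 100 + ord(group), null_phenotypes=15,
                        contamination=Contamination(0.1, 0.1, 0.1), **kw)
        sim = generate_population(cfg)
        out = ROOT / "scratch" / "analysis" / group
        out.mkdir(parents=True, exist_ok=True)
        write_members(sim.members, out / "members.tsv")
        write_claims(sim.claims, out / "claims.tsv")
        sim.vocabulary.write(out / "vocab")
        sim.truth.members.to_csv(out / "truth_members.tsv", sep="\t", index=False)
        rep = truth_report(sim.truth)
        rep.insert(0, "group", group)
        summaries.append(rep[rep["is_effect"]])
        n_case = (sim.truth.members["role"] == "case").sum()
        print(f"group {group}: {len(sim.members):>6} members "
              f"({n_case} true cases), {len(sim.claims):>7} claims -> {out}")

    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    pd.concat(summaries).to_csv(res / "planted_truth_summary.tsv",
                                sep="\t", index=False)
    print(f"planted effects summary -> {res / 'planted_truth_summary.tsv'}")


if __name__ == "__main__":
    main()
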