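# sma-phewas

Phenome-wide screening and temporal-trajectory analysis of **systemic
(non-neuromuscular) phenotypes in spinal muscular atrophy (SMA)** from
longitudinal administrative-claims data.

SMA is caused by loss of the ubiquitously expressed SMN protein but is
usually studied as a pure motor-neuron disease. Given member demographics
and dated ICD9 diagnosis codes from an insurance claims feed, this package

1. **selects cases and controls** — ≥2 SMA codes on distinct service
   dates, final neuromuscular diagnosis must be SMA, pregnancy-billing
   exclusions, age-at-first-diagnosis groups A `[0,2)` / B `[2,21)` /
   C `[21,65]` years, age-matched control pools, 6-month coverage gate;
2. **builds per-member analysis windows** — entire coverage, and the
   *pre-degeneration* window ending strictly before the inflection point
   (the first claim carrying any neuromuscular disease or degeneration
   code);
3. **screens the phenome** — ICD9 → PheWAS-group (phecode) aggregation, a
   1% member-level prevalence filter (either arm), covariate-adjusted
   logistic regression
   `phenotype ~ sma + gender + age_at_enrollment + enrollment_months`,
   and Benjamini–Hochberg FDR across all phenotypes tested in a run; the
   adjusted odds ratio is `exp(coef(sma))` with a Wald p-value;
4. **orders the trajectory** — significant phenotypes pooled by
   physiological system, system-level ORs, and the median days between
   first system diagnosis and the inflection point (negative = before),
   with an R²-vs-enrollment-duration diagnostic against coverage-length
   artifacts.

Real insurer databases are proprietary, so the package ships a
**synthetic claims generator** (`sma_phewas.synthetic_claims`) whose
generative model matches the analysis model: planted conditional odds
ratios, planted inflection dates and per-system onset offsets, and planted
contamination (pregnancy-coded pseudo-cases, wrong-final-diagnosis members,
single-code members). Every downstream stage is validated by recovering
that truth.

## Worked example

```python
from sma_phewas import (SimConfig, EffectSpec, Contamination,
                        generate_population, run_phewas, run_trajectory)

cfg = SimConfig(
    n_cases=150, n_controls=5000, seed=42,
    effects=(EffectSpec("395.3", 8.0, 0.01, onset_offset_mean_days=-140),
             EffectSpec("563",   4.0, 0.05, onset_offset_mean_days=-80),
             EffectSpec("350.3", 6.0, 0.03, onset_offset_mean_days=-40)),
    null_phenotypes=20,
    contamination=Contamination(0.1, 0.1, 0.1))
sim = generate_population(cfg)
run = run_phewas(sim.members, sim.claims, sim.vocabulary,
                 group="A", window_kind="pre_degeneration")
print(run.results.head(3)[["phewas_code", "phenotype", "odds_ratio",
                           "p_adjusted", "prevalence_sma"]])
traj = run_trajectory(run, sim.vocabulary)
print(traj.timeline)
```

prints (seed 42):

```
  phewas_code                               phenotype  odds_ratio  p_adjusted  prevalence_sma
0         563                            Constipation    4.153461    0.000009        0.166667
1       350.3                    Lack of coordination    4.178639    0.000042        0.146667
2       395.3  Nonrheumatic tricuspid valve disorders    5.199092    0.009956        0.066667

             system  median_days_before_inflection  prevalence_sma  odds_ratio
0    Cardiovascular                         -140.0        0.066667    5.199092
1  Gastrointestinal                          -80.0        0.166667    4.153461
2      Neurological                          -40.0        0.146667    4.178639
```

The three planted effects head the screen with adjusted odds ratios near
their planted values (8, 4, 6 before sampling noise), the 20 null
phenotypes stay above the FDR threshold, and the trajectory stage recovers
the planted onset offsets (−140/−80/−40 days before the first
neuromuscular sign) exactly, in the planted order.

The same flows are available from a shell:

```sh
sma-phewas simulate --config sim.yaml --out-dir data/
sma-phewas run --members data/members.tsv --claims data/claims.tsv \
               --vocab-dir data/vocab --group A --window pre --out-dir out/
```

The scripts under `analysis/` run the full study narrative — simulate
three severity-group universes, build cohorts, screen both windows, order
trajectories — writing compact tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_build_cohorts.py
python analysis/03_phewas_screen.py
python analysis/04_trajectories.py
```

## Vocabularies

Production use requires three user-supplied vocabulary inputs (see
`sma_phewas.vocab`): named ICD9 code sets for SMA, neuromuscular
disease/degeneration, and pregnancy (one code per line, prefix or exact
matching); an ICD9 → phecode map (`icd9, phewas_code, phenotype_label`);
and a phecode → physiological-system map. The bundled fixture vocabulary
(`sma_phewas.fixtures`) is a compact stand-in used by tests, docs, and the
synthetic study; the public phecode table is not redistributed.

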