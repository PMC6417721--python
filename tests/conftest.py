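import pandas as pd
import pytest

from sma_phewas import (Contamination, EffectSpec, SimConfig, fixture_vocabulary,
                        generate_population, twelve_member_cohort)


@pytest.fixture(scope="session")
def vocab():
    return fixture_vocabulary()


@pytest.fixture(scope="session")
def twelve():
    """(members, claims, expected assignments) for the hand-built cohort."""
    return twelve_member_cohort()


@pytest.fixture(scope="session")
def planted_sim():
    """A moderate synthetic universe with three planted system effects,
    twenty null phenotypes, and all three contamination scenarios."""
    cfg = SimConfig(
        n_cases=150, n_controls=5000, seed=42,
        effects=(
            EffectSpec("395.3", 8.0, 0.01, onset_offset_mean_days=-140),
            EffectSpec("563", 4.0, 0.05, onset_offset_mean_days=-80),
            EffectSpec("350.3", 6.0, 0.03, onset_offset_mean_days=-40),
        ),
        null_phenotypes=20,
        contamination=Contamination(pregnancy_frac=0.1, wrong_final_dx_frac=0.1,
                                    single_code_frac=0.1),
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def planted_run(planted_sim):
    from sma_phewas.phewas import run_phewas
    return run_phewas(planted_sim.members, planted_sim.claims,
                      planted_sim.vocabulary, group="A",
                      window_kind="pre_degeneration")
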