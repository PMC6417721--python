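import warnings

import numpy as np
import pandas as pd
import pytest

from sma_phewas.phewas import (AnalysisConfig, adjust_fdr, compute_prevalence,
                               filter_by_prevalence, fit_firth,
                               fit_phenotype_model, run_phewas)


def bh_stepup_oracle(p):
    """Independent brute-force BH step-up: sort ascending, adj_(i) =
    min_{j>=i} min(1, m p_(j) / j), mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        adj_sorted[rank_i] = min(
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_i, m))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _design(n_cases, n_ctrl, rng=None, constant_covariates=True):
    n = n_cases + n_ctrl
    if constant_covariates or rng is None:
        female = np.zeros(n)
        age = np.zeros(n)
        months = np.full(n, 36.0)
    else:
        female = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(0, 20, n)
        months = rng.uniform(12, 60, n)
    return pd.DataFrame({
        "member_id": [f"m{i}" for i in range(n)],
        "sma": np.r_[np.ones(n_cases), np.zeros(n_ctrl)],
        "female": female, "age_at_enrollment": age, "enrollment_months": months,
    })


class TestPrevalence:
    def _wclaims(self, rows):
        return pd.DataFrame(rows, columns=["member_id", "service_date", "icd9"])

    def test_member_level_counting(self, vocab):
        # 2 of 31 members carry the group; one of them 5 times
        rows = [("m0", pd.Timestamp("2010-01-01"), "4242")] * 5 \
            + [("m1", pd.Timestamp("2010-02-01"), "4242")]
        prev = compute_prevalence([f"m{i}" for i in range(31)],
                                  self._wclaims(rows), vocab.phewas_map)
        assert prev.loc["395.3"] == pytest.approx(2 / 31)

    def test_zero_prevalence_when_no_carriers(self, vocab):
        prev = compute_prevalence([f"m{i}" for i in range(10)],
                                  self._wclaims([]), vocab.phewas_map)
        assert prev.get("395.3", 0.0) == 0.0

    def test_empty_arm_is_an_error(self, vocab):
        with pytest.raises(ValueError):
            compute_prevalence([], self._wclaims([]), vocab.phewas_map)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("p_sma, p_ctrl, kept", [
        (0.012, 0.0001, True),   # either-arm logic
        (0.0001, 0.012, True),
        (0.005, 0.005, False),
        (0.01, 0.0, True),       # boundary inclusive
        (0.0, 0.01, True),
        (0.0099, 0.0099, False),
    ])
    def test_boundary_and_or_logic(self, p_sma, p_ctrl, kept):
        out = filter_by_prevalence(pd.Series({"X": p_sma}), pd.Series({"X": p_ctrl}))
        assert (out == ["X"]) is kept


class TestFit:
    def test_or_equals_cross_product_on_2x2(self):
        # cases 20/100 vs controls 10/100 -> OR = (20*90)/(80*10) = 2.25
        design = _design(100, 100)
        y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        fit = fit_phenotype_model(y, design)
        assert fit.fit_status == "ok"
        assert fit.odds_ratio == pytest.approx(2.25, rel=1e-6)

    def test_equal_prevalence_gives_or_one(self):
        design = _design(100, 100)
        y = np.r_[np.ones(10), np.zeros(90), np.ones(10), np.zeros(90)]
        assert fit_phenotype_model(y, design).odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_zero_control_positives_flags_separation(self):
        design = _design(50, 200)
        y = np.r_[np.ones(20), np.zeros(30), np.zeros(200)]
        assert fit_phenotype_model(y, design).fit_status == "separation_flagged"

    def test_constant_outcome_skipped_not_crashed(self):
        design = _design(10, 10)
        assert fit_phenotype_model(np.zeros(20), design).fit_status == "skipped"

    def test_single_arm_design_rejected(self):
        design = _design(20, 0)
        with pytest.raises(ValueError):
            fit_phenotype_model(np.r_[np.ones(5), np.zeros(15)], design)

    def test_firth_is_finite_under_separation(self):
        design = _design(50, 200)
        y = np.r_[np.ones(20), np.zeros(30), np.zeros(200)]
        fit = fit_phenotype_model(y, design, AnalysisConfig(firth=True))
        assert np.isfinite(fit.odds_ratio) and np.isfinite(fit.p_value)

    def test_firth_close_to_mle_on_balanced_data(self):
        design = _design(200, 200)
        y = np.r_[np.ones(60), np.zeros(140), np.ones(30), np.zeros(170)]
        mle = fit_phenotype_model(y, design)
        firth = fit_phenotype_model(y, design, AnalysisConfig(firth=True))
        assert firth.odds_ratio == pytest.approx(mle.odds_ratio, rel=0.05)


class TestAdjustFdr:
    @pytest.mark.parametrize("p, expected", [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.005, 0.1), (0.01, 0.1)),
        ((0.5,), (0.5,)),
    ])
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(adjust_fdr(p), expected, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(adjust_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.1, 1.2])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        assert (adjust_fdr(p) >= p - 1e-15).all()


class TestRunPhewas:
    def test_planted_effects_rank_above_nulls(self, planted_run, planted_sim):
        results = planted_run.results
        truth = planted_sim.truth.phenotypes
        planted = set(truth.loc[truth["is_effect"], "phewas_code"])
        top = set(results.head(len(planted))["phewas_code"])
        assert top == planted

    def test_bh_family_is_all_tested_phenotypes(self, planted_run):
        results = planted_run.results
        usable = results[results["p_raw"].notna()]
        np.testing.assert_allclose(usable["p_adjusted"].to_numpy(),
                                   bh_stepup_oracle(usable["p_raw"].to_numpy()),
                                   atol=1e-12)

    def test_adjusted_p_geq_raw_and_prevalences_valid(self, planted_run):
        r = planted_run.results
        ok = r[r["fit_status"] == "ok"]
        assert (ok["p_adjusted"] >= ok["p_raw"] - 1e-15).all()
        for col in ("prevalence_sma", "prevalence_ctrl"):
            assert r[col].between(0, 1).all()
        assert (ok["odds_ratio"] > 0).all()

    def test_empty_filter_warns_and_returns_empty(self, vocab):
        from sma_phewas.synthetic_claims import SimConfig, generate_population
        sim = generate_population(SimConfig(n_cases=30, n_controls=300, seed=5))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            run = run_phewas(sim.members, sim.claims, sim.vocabulary,
                             group="A", window_kind="pre_degeneration")
        assert run.results.empty
        assert any("prevalence filter" in str(w.message) for w in caught)
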