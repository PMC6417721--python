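import numpy as np
import pandas as pd
import pytest

from sma_phewas.trajectory import (build_timeline, enrollment_duration_r2,
                                   fit_system_model, group_significant_by_system,
                                   median_days_to_inflection, run_trajectory)


def median_oracle(values):
    """Brute-force sort-based median: midpoint average for even counts."""
    v = sorted(values)
    n = len(v)
    return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2


class TestGrouping:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["phewas_code", "p_adjusted"])

    def test_threshold_is_strict(self, vocab):
        res = self._results([("395.3", 0.049), ("563", 0.05), ("350.3", 0.051)])
        out = group_significant_by_system(res, vocab.system_map)
        assert out == {"Cardiovascular": ["395.3"]}

    def test_unmapped_significant_goes_to_unassigned(self, vocab):
        out = group_significant_by_system(
            self._results([("not-a-code", 0.001)]), vocab.system_map)
        assert out == {"unassigned": ["not-a-code"]}

    def test_no_significant_is_empty(self, vocab):
        assert group_significant_by_system(
            self._results([("395.3", 0.9)]), vocab.system_map) == {}

    def test_same_system_phenotypes_pool(self, vocab):
        out = group_significant_by_system(
            self._results([("532", 0.01), ("563", 0.02)]), vocab.system_map)
        assert out == {"Gastrointestinal": ["532", "563"]}


class TestSystemModel:
    def test_single_phenotype_system_reduces_to_phenotype_row(
            self, planted_run, planted_sim):
        vocab = planted_sim.vocabulary
        row = planted_run.results.set_index("phewas_code").loc["395.3"]
        fit, prev_sma, prev_ctrl = fit_system_model(["395.3"], planted_run, vocab)
        assert fit.odds_ratio == pytest.approx(row["odds_ratio"], rel=1e-9)
        assert prev_sma == pytest.approx(row["prevalence_sma"])

    def test_union_outcome_prevalence_at_least_each_marginal(
            self, planted_run, planted_sim):
        vocab = planted_sim.vocabulary
        r = planted_run.results.set_index("phewas_code")
        _, prev_union, _ = fit_system_model(["563", "350.3"], planted_run, vocab)
        assert prev_union >= r.loc["563", "prevalence_sma"] - 1e-12
        assert prev_union >= r.loc["350.3", "prevalence_sma"] - 1e-12

    def test_empty_set_rejected(self, planted_run, planted_sim):
        with pytest.raises(ValueError):
            fit_system_model([], planted_run, planted_sim.vocabulary)


class TestMedian:
    def test_exact_recovery_with_zero_sd(self, planted_run, planted_sim):
        vocab = planted_sim.vocabulary
        for codes, planted in [(["395.3"], -140.0), (["563"], -80.0),
                               (["350.3"], -40.0)]:
            median, n, _ = median_days_to_inflection(codes, planted_run, vocab)
            assert n > 0 and median == planted

    def test_no_contributors_gives_nan(self, planted_run, planted_sim):
        median, n, _ = median_days_to_inflection(["754.7"], planted_run,
                                                 planted_sim.vocabulary)
        assert n == 0 and np.isnan(median)

    @pytest.mark.parametrize("values, expected", [
        ([-10], -10), ([-142, -100, -8], -100), ([-400, -20, -10, -10], -15),
    ])
    def test_midpoint_convention(self, values, expected):
        assert median_oracle(values) == expected
        assert np.median(values) == expected

    def test_numpy_median_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            v = -rng.integers(1, 500, size=rng.integers(1, 30))
            assert np.median(v) == median_oracle(v.tolist())


class TestR2:
    def test_perfectly_linear_points(self):
        design = pd.DataFrame({"member_id": [f"m{i}" for i in range(5)],
                               "enrollment_months": [10.0, 20, 30, 40, 50]})
        offsets = pd.Series([-5.0, -10, -15, -20, -25],
                            index=[f"m{i}" for i in range(5)])
        r2, n = enrollment_duration_r2({"sys": offsets}, design)
        assert r2 == pytest.approx(1.0)
        assert n == 5

    def test_independent_offsets_give_small_r2(self):
        rng = np.random.default_rng(31)
        ids = [f"m{i}" for i in range(500)]
        design = pd.DataFrame({"member_id": ids,
                               "enrollment_months": rng.uniform(12, 60, 500)})
        offsets = pd.Series(-rng.uniform(10, 400, 500), index=ids)
        r2, _ = enrollment_duration_r2({"sys": offsets}, design)
        assert r2 < 0.1

    def test_two_points_violate_precondition(self):
        design = pd.DataFrame({"member_id": ["a", "b"],
                               "enrollment_months": [10.0, 20.0]})
        with pytest.raises(ValueError):
            enrollment_duration_r2({"s": pd.Series([-5.0, -9.0], index=["a", "b"])},
                                   design)

    def test_zero_variance_predictor_flagged(self):
        ids = ["a", "b", "c"]
        design = pd.DataFrame({"member_id": ids, "enrollment_months": 36.0})
        r2, n = enrollment_duration_r2({"s": pd.Series([-1.0, -2, -3], index=ids)},
                                       design)
        assert np.isnan(r2) and n == 3


class TestTimeline:
    def _traj(self, rows):
        return pd.DataFrame(rows, columns=["system", "odds_ratio", "prevalence_ctrl",
                                           "prevalence_sma",
                                           "median_days_before_inflection"])

    def test_five_percent_cut(self):
        t = self._traj([("A", 2.0, 0.01, 0.04, -50), ("B", 2.0, 0.01, 0.06, -40)])
        out = build_timeline(t)
        assert out["system"].tolist() == ["B"]

    def test_ordered_most_negative_first(self):
        t = self._traj([("Neurological", 2.0, 0.01, 0.3, -40),
                        ("Cardiovascular", 2.0, 0.01, 0.3, -140)])
        assert build_timeline(t)["system"].tolist() == ["Cardiovascular",
                                                        "Neurological"]

    def test_empty_input(self):
        assert build_timeline(self._traj([])).empty


class TestRunTrajectory:
    def test_planted_ordering_recovered(self, planted_run, planted_sim):
        traj = run_trajectory(planted_run, planted_sim.vocabulary)
        got = traj.timeline["system"].tolist()
        assert got == ["Cardiovascular", "Gastrointestinal", "Neurological"]
        medians = traj.trajectories.set_index("system")["median_days_before_inflection"]
        assert medians.loc["Cardiovascular"] == -140
        assert medians.loc["Gastrointestinal"] == -80
        assert medians.loc["Neurological"] == -40

    def test_all_pre_window_medians_negative(self, planted_run, planted_sim):
        traj = run_trajectory(planted_run, planted_sim.vocabulary)
        assert (traj.trajectories["median_days_before_inflection"] < 0).all()

    def test_r2_diagnostic_small_for_inflection_locked_onsets(
            self, planted_run, planted_sim):
        traj = run_trajectory(planted_run, planted_sim.vocabulary)
        assert traj.n_points >= 3
        assert traj.r_squared_vs_enrollment < 0.1

    def test_entire_window_rejected(self, planted_sim):
        from sma_phewas.phewas import run_phewas
        run = run_phewas(planted_sim.members, planted_sim.claims,
                         planted_sim.vocabulary, group="A", window_kind="entire")
        with pytest.raises(ValueError):
            run_trajectory(run, planted_sim.vocabulary)
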