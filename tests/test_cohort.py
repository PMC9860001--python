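"""Cohort statistics: Spearman map, PSQA metric screen, efficiency split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tomometrics as tm
from tomometrics import GeneratorProfile, generate_cohort
from tomometrics.cohort import classify_correlation, spearman_with_p
from tomometrics.errors import ParameterError


@pytest.fixture(scope="module")
def small_table():
    rng = np.random.default_rng(77)
    n = 12
    base = rng.normal(size=n)
    frame = pd.DataFrame(
        {
            "a": base,
            "b": np.exp(base),          # monotone copy of a
            "c": rng.normal(size=n),    # independent
            "d": -base + rng.normal(scale=0.05, size=n),
        },
        index=pd.Index([f"p{i}" for i in range(n)], name="plan_id"),
    )
    return frame


class TestCorrelationMap:
    def test_classes_follow_fixed_boundaries(self):
        assert classify_correlation(0.1) == "very weak"
        assert classify_correlation(-0.25) == "weak"
        assert classify_correlation(0.45) == "moderate"
        assert classify_correlation(-0.7) == "strong"
        assert classify_correlation(0.85) == "very strong"
        assert classify_correlation(1.0) == "very strong"

    def test_self_and_monotone_copies(self, small_table):
        report = tm.correlation_map(small_table)
        assert report.rho.loc["a", "a"] == 1.0
        assert report.rho.loc["a", "b"] == pytest.approx(1.0)  # rank invariance
        assert report.classes.loc["a", "b"] == "very strong"
        assert report.significant.loc["a", "b"]

    def test_matches_rank_then_pearson_oracle(self, small_table):
        report = tm.correlation_map(small_table)
        for a in small_table.columns:
            for b in small_table.columns:
                if a == b:
                    continue
                ranks_a = stats.rankdata(small_table[a])
                ranks_b = stats.rankdata(small_table[b])
                oracle = np.corrcoef(ranks_a, ranks_b)[0, 1]
                assert report.rho.loc[a, b] == pytest.approx(oracle, abs=1e-12)
                ref = stats.spearmanr(small_table[a], small_table[b])
                assert report.p.loc[a, b] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_column_flagged(self, small_table):
        frame = small_table.assign(const=1.0)
        report = tm.correlation_map(frame)
        assert np.isnan(report.rho.loc["const", "a"])
        assert report.classes.loc["const", "a"] == "not available"

    def test_too_few_plans_rejected(self, small_table):
        with pytest.raises(ParameterError):
            tm.correlation_map(small_table.iloc[:2])


class TestSelectMetrics:
    def test_redundant_monotone_copy_is_pruned(self, small_table):
        psqa = pd.DataFrame({"PR_3G2": -small_table["a"] + 0.01 * np.arange(len(small_table))},
                            index=small_table.index)
        result = tm.select_metrics(small_table, psqa, "PR_3G2")
        sig_names = [n for n, _ in result.significant]
        sel_names = [n for n, _ in result.selected]
        assert "a" in sig_names and "b" in sig_names
        # a and b are perfectly inter-correlated: only one survives stage 2
        assert not ("a" in sel_names and "b" in sel_names)
        # no selected pair may remain strongly inter-correlated
        for x in sel_names:
            for y in sel_names:
                if x != y:
                    rho, _ = spearman_with_p(
                        small_table[x].to_numpy(), small_table[y].to_numpy()
                    )
                    assert abs(rho) < 0.6

    def test_single_significant_metric_returned_unchanged(self):
        rng = np.random.default_rng(5)
        n = 30
        sig = np.linspace(0, 1, n)
        frame = pd.DataFrame(
            {"hit": sig, "noise": rng.normal(size=n)},
            index=pd.Index([f"p{i}" for i in range(n)], name="plan_id"),
        )
        psqa = pd.DataFrame({"PR_3G2": sig + rng.normal(scale=0.1, size=n)},
                            index=frame.index)
        result = tm.select_metrics(frame, psqa, "PR_3G2")
        assert [n_ for n_, _ in result.selected] == ["hit"]

    def test_missing_endpoint_column_rejected(self, small_table):
        psqa = pd.DataFrame({"other": np.zeros(len(small_table))}, index=small_table.index)
        with pytest.raises(ParameterError):
            tm.select_metrics(small_table, psqa, "PR_3G2")

    def test_empty_selection_is_a_valid_outcome(self, small_table):
        rng = np.random.default_rng(123)
        psqa = pd.DataFrame({"PR_2L2": rng.normal(size=len(small_table))},
                            index=small_table.index)
        result = tm.select_metrics(small_table, psqa, "PR_2L2", alpha=1e-6)
        assert result.selected == [] and result.significant == []


@pytest.fixture(scope="module")
def cohort():
    mix = [
        (GeneratorProfile(flot_shape="flat_with_end_peak", n_projections=80), 1.0),
        (GeneratorProfile(flot_shape="bimodal", n_projections=80), 1.0),
    ]
    plans = generate_cohort(24, mix, master_seed=31)
    return plans, tm.extract(plans)


class TestEfficiencySplit:
    def test_split_recovers_generator_labels(self, cohort):
        plans, table = cohort
        split = tm.efficiency_split(table, plans=plans)
        assert split.q25 < split.q75
        # quartile groups stay within the cohort-size bound
        cap = int(np.ceil(len(plans) / 4)) + 1
        assert len(split.efficient_ids) <= cap
        assert len(split.inefficient_ids) <= cap
        assert all("flat_with_end_peak" in i for i in split.efficient_ids)
        assert all("bimodal" in i for i in split.inefficient_ids)

    def test_histograms_normalized_and_separated(self, cohort):
        plans, table = cohort
        split = tm.efficiency_split(table, plans=plans)
        h = split.histograms
        assert h is not None
        assert h["efficient_mean"].sum() == pytest.approx(1.0, abs=1e-9)
        assert h["inefficient_mean"].sum() == pytest.approx(1.0, abs=1e-9)
        # the efficient group carries the marked last-bin peak
        assert h["efficient_mean"].iloc[-1] > h["inefficient_mean"].iloc[-1]

    def test_group_means_differ_on_discriminating_metrics(self, cohort):
        plans, table = cohort
        split = tm.efficiency_split(table, plans=plans)
        assert split.summary.loc["CFNS75", "sig_0.01"]

    def test_identical_plans_degenerate(self):
        plan_rows = {f"p{i}": 0.5 for i in range(10)}
        frame = pd.DataFrame({"CFNS75": pd.Series(plan_rows)})
        frame.index.name = "plan_id"
        with pytest.raises(ParameterError):
            tm.efficiency_split(frame)

    def test_too_small_cohort_rejected(self):
        frame = pd.DataFrame({"CFNS75": np.linspace(0, 1, 5)})
        with pytest.raises(ParameterError):
            tm.efficiency_split(frame)
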