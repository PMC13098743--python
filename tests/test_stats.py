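import numpy as np
import pandas as pd
import pytest
from _oracles import enumerate_signed_rank_p

from hybriddo.biomarkers import HemoTrace, SubjectSession
from hybriddo.stats import (
    InsufficientDataError,
    WindowSpec,
    bloodgas_table,
    build_results_tables,
    cerebral_vs_peripheral_test,
    cohort_summary,
    format_p,
    paired_prepost_test,
    relative_change_test,
    round_half_up,
    signed_rank_test,
    window_means,
)


class TestSignedRankEngine:
    def test_all_positive_differences_hit_the_enumeration_floor(self):
        d = np.arange(1.0, 14.0)  # 13 strictly positive differences
        stat, p, n, note = signed_rank_test(d, "greater")
        assert n == 13 and note == "exact"
        assert p == pytest.approx(2.0**-13, rel=1e-12)

    def test_symmetric_pairs_are_null_consistent(self):
        d = np.array([1.0, -1.5, 2.0, -2.5, 3.0, -3.5, 4.0, -4.5])
        _, p, _, _ = signed_rank_test(d, "greater")
        assert p >= 0.5

    def test_all_zero_differences_flagged(self):
        stat, p, n, note = signed_rank_test(np.zeros(10), "greater")
        assert p == 1.0 and n == 0 and note == "all_zero_differences"

    def test_too_few_pairs_refused(self):
        with pytest.raises(InsufficientDataError):
            signed_rank_test(np.array([1.0, 2.0, 3.0, 4.0]), "greater")

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_enumeration_on_random_patterns(self, alternative):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = rng.integers(5, 11)
            d = rng.normal(0.3, 1.0, n)
            d = np.where(d == 0, 0.1, d)
            _, p, _, _ = signed_rank_test(d, alternative)
            assert p == pytest.approx(
                enumerate_signed_rank_p(d, alternative), rel=1e-9
            )

    def test_p_never_below_enumeration_minimum(self):
        rng = np.random.default_rng(3)
        for n in range(5, 15):
            d = np.abs(rng.normal(1, 0.2, n))  # all positive
            _, p, n_used, _ = signed_rank_test(d, "greater")
            assert p >= 2.0**-n_used - 1e-15

    def test_tied_magnitudes_still_exact(self):
        d = np.array([1.0, 1.0, 1.0, 2.0, 2.0, -1.0, 3.0, 3.0])
        _, p, _, note = signed_rank_test(d, "greater")
        assert note == "exact"
        assert p == pytest.approx(enumerate_signed_rank_p(d, "greater"), rel=1e-9)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.2, 1.0, 30)
        _, p, _, note = signed_rank_test(d, "greater")
        assert note == "normal_approx_cc" and 0.0 < p < 1.0


class TestPairedAndRelativeTests:
    def test_reference_cohort_hgb_and_hct_significant_increase(self, reference_cohort):
        df = reference_cohort[reference_cohort["included"]].dropna(subset=["hgb_pre_gdl"])
        for pre_col, post_col in [
            ("hgb_pre_gdl", "hgb_post_gdl"),
            ("hct_pre_pct", "hct_post_pct"),
        ]:
            res = paired_prepost_test(
                df[pre_col].to_numpy(), df[post_col].to_numpy(), "two-sided"
            )
            assert res.n == 13
            assert res.p_value < 0.001 and res.p_text == "<0.001"
            assert res.direction_arrow == "up"

    def test_identical_vectors_give_p_one(self):
        v = np.arange(1.0, 9.0)
        res = paired_prepost_test(v, v)
        assert res.p_value == 1.0 and res.direction_arrow == "none"

    def test_one_sided_relative_change_direction(self):
        post = np.array([1.5, 1.6, 1.7, 1.8, 1.4, 1.55, 1.62])
        pre = np.ones(7)
        res = relative_change_test(post, pre, "greater", variable="rbfi")
        assert res.significant and res.direction_arrow == "up"
        res_wrong_side = relative_change_test(post, pre, "less", variable="roef")
        assert not res_wrong_side.significant

    def test_cerebral_vs_peripheral_up_means_peripheral_higher(self):
        cerebral = np.array([1.0, 1.1, 1.05, 0.95, 1.02, 1.08, 0.9])
        peripheral = cerebral + 0.5
        res = cerebral_vs_peripheral_test(cerebral, peripheral)
        assert res.significant and res.direction_arrow == "up"
        same = cerebral_vs_peripheral_test(cerebral, cerebral)
        assert same.p_value == 1.0 and same.direction_arrow == "none"


class TestSummaries:
    def test_reference_cohort_blood_gas_summaries(self, reference_cohort):
        df = reference_cohort[reference_cohort["included"]]
        s = cohort_summary(df["hgb_pre_gdl"].dropna())
        assert round_half_up(s["mean"], 1) == 8.1
        assert round_half_up(s["sd"], 2) == 0.48
        s = cohort_summary(df["hct_post_pct"].dropna())
        assert round_half_up(s["mean"], 1) == 27.4
        assert round_half_up(s["sd"], 1) == 1.8

    def test_degenerate_summary(self):
        s = cohort_summary(np.full(6, 4.2))
        assert s["sd"] == 0.0 and s["q3"] - s["q1"] == 0.0

    def test_p_formatting(self):
        assert format_p(0.0005) == "<0.001"
        assert format_p(0.07) == "0.07"
        assert format_p(1.0) == "1"

    def test_round_half_up(self):
        assert round_half_up(0.485, 2) == 0.49
        assert round_half_up(2.846, 0) == 3.0
        assert round_half_up(-0.485, 2) == -0.49


def make_session(subject, step_by_var, t_end=12000.0, start=3000.0, end=9000.0):
    t = np.arange(0.0, t_end, 10.0)
    traces = {}
    for (loc, var), (base, step) in step_by_var.items():
        v = np.where(t < end, base, base + step)
        traces[(loc, var)] = HemoTrace(loc, var, t, v)
    return SubjectSession(
        subject,
        traces,
        None,
        [],
        {"transfusion_start": start, "transfusion_end": end},
    )


class TestWindowsAndTables:
    def test_window_means_and_post_bin_count(self):
        s = make_session("S1", {("cerebral", "rbfi"): (1.0, 0.5)})
        wm = window_means(s, WindowSpec())
        row = wm.iloc[0]
        assert row["pre_mean"] == pytest.approx(1.0)
        assert row["post_mean"] == pytest.approx(1.5)
        assert row["n_post_bins"] == 36  # 6 min of 10-s bins, half-open
        assert row["n_pre_bins"] == 300

    def test_empty_window_excludes_variable(self):
        t = np.arange(9500.0, 12000.0, 10.0)  # no pre-window samples
        s = SubjectSession(
            "S1",
            {("cerebral", "rbfi"): HemoTrace("cerebral", "rbfi", t, np.ones(t.size))},
            None,
            [],
            {"transfusion_start": 3000.0, "transfusion_end": 9000.0},
        )
        assert window_means(s).empty

    def test_results_table_marks_untestable_variables(self):
        sessions = [
            make_session(f"S{i}", {("peripheral", "rbfi"): (1.0, 0.7)}) for i in range(6)
        ]
        means = pd.concat([window_means(s) for s in sessions], ignore_index=True)
        table = build_results_tables(means)
        rbfi = table[table["variable"] == "rbfi"].iloc[0]
        assert rbfi["peripheral_p_text"] != "not tested"
        assert rbfi["cerebral_p_text"] == "not tested"
        assert rbfi["cvp_p_text"] == "not tested"
        roef = table[table["variable"] == "roef"].iloc[0]
        assert roef["peripheral_p_text"] == "not tested"

    def test_bloodgas_table_reproduces_reference_rows(self, reference_cohort):
        df = reference_cohort[reference_cohort["included"]].rename(
            columns={
                "hgb_pre_gdl": "hgb_pre",
                "hgb_post_gdl": "hgb_post",
                "hct_pre_pct": "hct_pre",
                "hct_post_pct": "hct_post",
            }
        )
        table = bloodgas_table(df)
        hgb = table[table["variable"] == "hgb"].iloc[0]
        assert round_half_up(hgb["pre_mean"], 1) == 8.1
        assert round_half_up(hgb["post_mean"], 1) == 9.1
        assert hgb["p_text"] == "<0.001" and hgb["dir"] == "up"
        hct = table[table["variable"] == "hct"].iloc[0]
        assert round_half_up(hct["pre_mean"], 1) == 24.5
        assert hct["p_text"] == "<0.001" and hct["dir"] == "up"
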