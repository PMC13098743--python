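import numpy as np
import pandas as pd
import pytest

from hybriddo.biomarkers import (
    BloodGasSample,
    HemoTrace,
    PhysioConstants,
    VitalsTrace,
    cao2,
    delta_trace,
    downsample_10s,
    hgb_from_hct,
    impute_post_hct,
    mro2_trace,
    oef_from_sto2,
    relative_trace,
    synchronize,
)
from hybriddo.forward import ValidationError
from hybriddo.io import load_reference_cohort


def bloodgas_three(hct_pre, hct_mid, hct_post):
    return [
        BloodGasSample(600.0, hgb_from_hct(hct_pre), hct_pre, 40.0, "pre"),
        BloodGasSample(5000.0, hgb_from_hct(hct_mid), hct_mid, 40.0, "mid"),
        BloodGasSample(10000.0, hgb_from_hct(hct_post), hct_post, 40.0, "post"),
    ]


class TestOxygenEquations:
    @pytest.mark.parametrize("hct, hgb", [(26.0, 8.84), (24.5, 8.33)])
    def test_hgb_from_hct(self, hct, hgb):
        assert hgb_from_hct(hct) == pytest.approx(hgb, abs=0.005)

    def test_hct_out_of_range_rejected(self):
        for bad in (0.0, -5.0, 100.0):
            with pytest.raises(ValidationError):
                hgb_from_hct(bad)

    @pytest.mark.parametrize(
        "hgb, sao2, expected",
        [(8.84, 1.0, 12.0224), (8.84, 0.0, 0.0), (10.0, 0.97, 13.192)],
    )
    def test_cao2(self, hgb, sao2, expected):
        assert cao2(hgb, sao2) == pytest.approx(expected, abs=1e-6)

    def test_oef_no_extraction_when_tissue_equals_arterial(self):
        assert oef_from_sto2(0.97, 0.97, gamma=0.75) == pytest.approx(0.0, abs=1e-12)

    def test_oef_venous_compartment_estimate(self):
        # svo2 = (0.65 - 0.25*0.98)/0.75 = 0.54; oef = (0.98-0.54)/0.98
        assert oef_from_sto2(0.65, 0.98, gamma=0.75) == pytest.approx(0.44898, abs=1e-4)

    def test_oef_all_venous_limit(self):
        sto2, sao2 = 0.62, 0.96
        assert oef_from_sto2(sto2, sao2, gamma=1.0) == pytest.approx(
            (sao2 - sto2) / sao2
        )

    def test_oef_zero_arterial_rejected(self):
        with pytest.raises(ValidationError):
            oef_from_sto2(0.6, 0.0)


class TestMro2:
    T = np.arange(0.0, 12000.0, 10.0)

    def make_traces(self, bfi=1.0, oef=1.0, sao2=1.0):
        mk = lambda var, val: HemoTrace("cerebral", var, self.T, np.full(self.T.size, val))
        return mk("bfi", bfi), mk("oef", oef), mk("sao2", sao2)

    def test_multiplicative_identity_up_to_cao2(self):
        bfi, oef, sao2 = self.make_traces()
        bg = bloodgas_three(25.0, 25.0, 25.0)
        out = mro2_trace(bfi, oef, sao2, bg, 3000.0, 9000.0)
        # constant unit flow/extraction/saturation: mro2 = cao2(hgb(25%))
        np.testing.assert_allclose(out.values, 1.36 * 8.5)

    def test_linear_in_flow(self):
        bg = bloodgas_three(25.0, 25.0, 25.0)
        b1, o, s = self.make_traces(bfi=1.0)
        b2, _, _ = self.make_traces(bfi=2.0)
        m1 = mro2_trace(b1, o, s, bg, 3000.0, 9000.0)
        m2 = mro2_trace(b2, o, s, bg, 3000.0, 9000.0)
        np.testing.assert_allclose(m2.values, 2.0 * m1.values)

    def test_period_constant_hct_switches_at_marks(self):
        bfi, oef, sao2 = self.make_traces()
        bg = bloodgas_three(24.5, 26.0, 27.4)
        out = mro2_trace(bfi, oef, sao2, bg, 3000.0, 9000.0)
        pre = out.values[out.timestamps < 3000.0]
        mid = out.values[(out.timestamps >= 3000.0) & (out.timestamps < 9000.0)]
        post = out.values[out.timestamps >= 9000.0]
        assert np.all(pre == pre[0]) and np.all(post == post[0])
        assert post[0] / pre[0] == pytest.approx(27.4 / 24.5, abs=1e-9)
        assert mid[0] / pre[0] == pytest.approx(26.0 / 24.5, abs=1e-9)

    def test_missing_period_hct_raises(self):
        bfi, oef, sao2 = self.make_traces()
        bg = bloodgas_three(24.5, 26.0, 27.4)[:2]
        with pytest.raises(ValidationError, match="post"):
            mro2_trace(bfi, oef, sao2, bg, 3000.0, 9000.0)


class TestImputation:
    def test_mean_of_matching_donors(self):
        cohort = pd.DataFrame(
            {"hct_pre_pct": [24.0, 24.0, 30.0], "hct_post_pct": [27.0, 27.0, 33.0]}
        )
        assert impute_post_hct(24.0, cohort) == pytest.approx(27.0)
        cohort.loc[1, "hct_post_pct"] = 28.0
        assert impute_post_hct(24.0, cohort) == pytest.approx(27.5)

    def test_reference_cohort_donors_for_pre_24(self):
        """Subjects whose pre-HCT was 24% ended at {28, 27, 26, 27} -> 27.0."""
        df = load_reference_cohort(included_only=True)
        cohort = df.rename(
            columns={"hct_pre_pct": "hct_pre_pct", "hct_post_pct": "hct_post_pct"}
        )
        val = impute_post_hct(24.0, cohort, tolerance=0.5)
        assert val == pytest.approx(27.0)
        assert 25.0 <= val <= 32.0  # inside the observed post range

    def test_fallback_to_cohort_mean_with_warning(self):
        cohort = pd.DataFrame({"hct_pre_pct": [30.0], "hct_post_pct": [33.0]})
        with pytest.warns(UserWarning, match="cohort mean"):
            assert impute_post_hct(20.0, cohort) == pytest.approx(33.0)


class TestBaselineReferencing:
    T = np.arange(0.0, 6000.0, 10.0)

    def test_constant_trace_normalizes_to_one_and_zero(self):
        tr = HemoTrace("cerebral", "bfi", self.T, np.full(self.T.size, 3.7))
        r = relative_trace(tr, (0.0, 1800.0))
        d = delta_trace(tr, (0.0, 1800.0))
        np.testing.assert_allclose(r.values, 1.0)
        np.testing.assert_allclose(d.values, 0.0)

    def test_step_change_gives_the_programmed_effect(self):
        v = np.where(self.T < 1800.0, 1.0, 1.68)
        r = relative_trace(HemoTrace("peripheral", "bfi", self.T, v), (0.0, 1800.0))
        assert r.values[self.T >= 1800.0].mean() == pytest.approx(1.68)
        v2 = np.where(self.T < 1800.0, 0.05, 0.054)
        d = delta_trace(HemoTrace("cerebral", "hbo2", self.T, v2), (0.0, 1800.0))
        assert d.values[self.T >= 1800.0].mean() == pytest.approx(0.0040, abs=1e-12)

    def test_normalization_invariants_on_random_traces(self):
        rng = np.random.default_rng(17)
        win = (0.0, 1800.0)
        sel = self.T < 1800.0
        for _ in range(200):
            v = rng.lognormal(0.0, 0.5, self.T.size)
            tr = HemoTrace("cerebral", "bfi", self.T, v)
            assert relative_trace(tr, win).values[sel].mean() == pytest.approx(1.0, abs=1e-12)
            d = delta_trace(tr, win)
            assert d.values[sel].mean() == pytest.approx(0.0, abs=1e-12)
            # delta + baseline mean reconstructs the original exactly
            np.testing.assert_allclose(d.values + d.baseline_stat, v, rtol=1e-12)

    def test_short_baseline_rejected(self):
        tr = HemoTrace("cerebral", "bfi", self.T, np.ones(self.T.size))
        with pytest.raises(ValidationError):
            relative_trace(tr, (0.0, 15.0))


class TestDownsampling:
    def test_constant_high_rate_trace(self):
        t = np.arange(0.0, 60.0, 1 / 400.0)  # 400 Hz
        tb, vb = downsample_10s(t, np.full(t.size, 2.5))
        assert tb.size == 6
        np.testing.assert_allclose(vb, 2.5)

    def test_bin_count_bound(self):
        t = np.arange(0.0, 600.0, 0.5)
        tb, _ = downsample_10s(t, np.ones(t.size))
        assert tb.size <= 60

    def test_linear_ramp_bin_means_at_midpoints(self):
        t = np.arange(0.0, 100.0, 0.1)
        tb, vb = downsample_10s(t, t)
        brute = [t[(t >= a) & (t < a + 10.0)].mean() for a in tb]
        np.testing.assert_allclose(vb, brute)
        np.testing.assert_allclose(vb, tb + 4.95, atol=1e-9)

    def test_boundary_sample_joins_later_bin(self):
        tb, vb = downsample_10s(np.array([9.999, 10.0]), np.array([1.0, 5.0]))
        np.testing.assert_array_equal(tb, [0.0, 10.0])
        np.testing.assert_array_equal(vb, [1.0, 5.0])


class TestSynchronize:
    def make_inputs(self):
        t = np.arange(0.0, 1200.0, 1.0)
        optical = {("cerebral", "sto2"): (t, np.full(t.size, 0.65))}
        vitals = VitalsTrace(t, np.full(t.size, 0.97), np.full(t.size, 85.0), np.full(t.size, 75.0))
        events = {"transfusion_start": 600.0, "transfusion_end": 1100.0}
        return optical, vitals, events

    def test_zero_offsets_preserve_timestamps(self):
        optical, vitals, events = self.make_inputs()
        s = synchronize(optical, vitals, events, subject_id="S")
        assert s.traces[("cerebral", "sto2")].timestamps[0] == 0.0
        assert s.transfusion_start == 600.0

    def test_vitals_offset_shifts_only_vitals(self):
        optical, vitals, events = self.make_inputs()
        s = synchronize(optical, vitals, events, offsets={"vitals": 5.0})
        assert s.vitals.timestamps[0] == 0.0  # 0+5 falls in bin [0,10)
        assert s.vitals.timestamps[-1] == 1200.0  # last sample pushed to a later bin
        assert s.traces[("cerebral", "sto2")].timestamps[-1] == 1190.0

    def test_missing_transfusion_marks_is_hard_error(self):
        optical, vitals, _ = self.make_inputs()
        with pytest.raises(ValidationError, match="transfusion_end"):
            synchronize(optical, vitals, {"transfusion_start": 600.0})

    def test_percent_scale_sao2_converted_with_warning(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.warns(UserWarning, match="percent"):
            v = VitalsTrace(t, np.full(t.size, 97.0), np.zeros(t.size), np.zeros(t.size))
        np.testing.assert_allclose(v.sao2, 0.97)
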