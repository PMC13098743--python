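import numpy as np
import pytest
from hypothesis import given, strategies as st

from hybriddo.forward import (
    DCSConfig,
    MediumGeometry,
    OpticalProperties,
    ValidationError,
    convolve_with_irf,
    dcs_g1,
    siegert_g2,
    td_reflectance,
)
from hybriddo.inversion import (
    DTOFRecord,
    G2Record,
    IRFRecord,
    average_musp,
    chromophores_from_mua,
    fit_dtof,
    fit_g2,
    mua_for_dcs,
    mua_from_chromophores,
)

BIN_PS = 25.0
N_BINS = 400
TGRID = (np.arange(N_BINS) + 0.5) * BIN_PS


def delta_irf(wavelength=690.0):
    k = np.zeros(N_BINS)
    k[0] = 1.0
    return IRFRecord(BIN_PS, k, wavelength)


def make_dtof(mua, musp, geom, irf, total=5e5, rng=None, wavelength=690.0):
    curve = td_reflectance(OpticalProperties(wavelength, mua, musp), geom, TGRID)
    meas = convolve_with_irf(curve, irf.counts / irf.counts.sum(), BIN_PS)
    meas = meas / meas.sum() * total
    counts = rng.poisson(meas) if rng is not None else np.round(meas).astype(np.int64)
    return DTOFRecord(0.0, wavelength, BIN_PS, counts, "cerebral")


class TestChromophores:
    def test_forward_inverse_round_trip(self, ext_table):
        mua690 = mua_from_chromophores(0.040, 0.020, 690.0, ext_table)
        mua830 = mua_from_chromophores(0.040, 0.020, 830.0, ext_table)
        c = chromophores_from_mua(mua690, mua830, ext_table)
        assert c.hbo2 == pytest.approx(0.040, abs=1e-10)
        assert c.hhb == pytest.approx(0.020, abs=1e-10)
        assert c.sto2 == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert not c.flagged

    def test_fully_oxygenated_limit(self, ext_table):
        mua690 = mua_from_chromophores(0.05, 0.0, 690.0, ext_table)
        mua830 = mua_from_chromophores(0.05, 0.0, 830.0, ext_table)
        c = chromophores_from_mua(mua690, mua830, ext_table)
        assert c.sto2 == pytest.approx(1.0, abs=1e-9)

    def test_homogeneity_preserves_saturation(self, ext_table):
        mua690 = mua_from_chromophores(0.03, 0.015, 690.0, ext_table)
        mua830 = mua_from_chromophores(0.03, 0.015, 830.0, ext_table)
        c1 = chromophores_from_mua(mua690, mua830, ext_table)
        c2 = chromophores_from_mua(2 * mua690, 2 * mua830, ext_table)
        assert c2.hbo2 == pytest.approx(2 * c1.hbo2, rel=1e-12)
        assert c2.sto2 == pytest.approx(c1.sto2, rel=1e-12)

    @given(hbo2=st.floats(0.005, 0.08), hhb=st.floats(0.005, 0.08))
    def test_mutual_inverse_on_random_concentrations(self, hbo2, hhb):
        from hybriddo.inversion import load_extinction_table

        table = load_extinction_table()
        c = chromophores_from_mua(
            mua_from_chromophores(hbo2, hhb, 690.0, table),
            mua_from_chromophores(hbo2, hhb, 830.0, table),
            table,
        )
        assert c.hbo2 == pytest.approx(hbo2, abs=1e-10)
        assert c.hhb == pytest.approx(hhb, abs=1e-10)

    def test_negative_solution_flagged_not_clipped(self, ext_table):
        # absorption pair inconsistent with both concentrations positive
        c = chromophores_from_mua(0.001, 0.05, ext_table)
        assert c.flagged and c.hhb < 0


class TestScatteringAndAbsorptionAveraging:
    def test_average_musp(self):
        p690 = OpticalProperties(690, 0.01, 1.0)
        p830 = OpticalProperties(830, 0.01, 0.8)
        assert average_musp(p690, p830) == pytest.approx(0.9)
        assert average_musp(p690, p690) == pytest.approx(1.0)
        assert average_musp(None, p830) == pytest.approx(0.8)
        with pytest.raises(ValidationError):
            average_musp(None, None)

    def test_mua_for_dcs_modes(self):
        p690 = OpticalProperties(690, 0.010, 1.0)
        p830 = OpticalProperties(830, 0.014, 0.8)
        assert mua_for_dcs(p690, p830, "mean") == pytest.approx(0.012)
        interp = mua_for_dcs(p690, p830, "interpolate")
        assert interp == pytest.approx(0.010 + 0.004 * (785 - 690) / (830 - 690))
        assert mua_for_dcs(p690, None) == pytest.approx(0.010)


class TestFitDtof:
    def test_noiseless_round_trip_lattice(self, trs_geometry):
        """Forward->fit recovers the generating (mua, musp) to 1%."""
        irf = delta_irf()
        for mua in (0.008, 0.015, 0.03):
            for musp in (0.6, 1.0, 1.6):
                rec = make_dtof(mua, musp, trs_geometry, irf)
                res = fit_dtof(rec, irf, trs_geometry)
                assert res.converged
                assert res.props.mua == pytest.approx(mua, rel=0.01)
                assert res.props.musp == pytest.approx(musp, rel=0.01)

    def test_noisy_recovery_median_error(self, trs_geometry):
        irf = delta_irf()
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(30):
            rec = make_dtof(0.015, 1.0, trs_geometry, irf, total=5e5, rng=rng)
            res = fit_dtof(rec, irf, trs_geometry)
            assert res.converged
            errs.append(
                (abs(res.props.mua / 0.015 - 1), abs(res.props.musp / 1.0 - 1))
            )
        errs = np.array(errs)
        assert np.median(errs[:, 0]) < 0.05
        assert np.median(errs[:, 1]) < 0.10

    def test_pure_background_flagged_not_raised(self, trs_geometry):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, N_BINS)
        rec = DTOFRecord(0.0, 690.0, BIN_PS, counts, "cerebral")
        res = fit_dtof(rec, delta_irf(), trs_geometry)
        assert not res.converged or res.chi2_reduced > 10.0

    def test_monotone_absorption_sensitivity(self, trs_geometry):
        irf = delta_irf()
        fitted = []
        for mua in np.linspace(0.006, 0.03, 6):
            res = fit_dtof(make_dtof(mua, 1.0, trs_geometry, irf), irf, trs_geometry)
            fitted.append(res.props.mua)
        assert np.all(np.diff(fitted) > 0)

    def test_deterministic(self, trs_geometry):
        irf = delta_irf()
        rec = make_dtof(0.012, 1.1, trs_geometry, irf, rng=np.random.default_rng(1))
        r1 = fit_dtof(rec, irf, trs_geometry)
        r2 = fit_dtof(rec, irf, trs_geometry)
        assert (r1.props.mua, r1.props.musp, r1.shift) == (
            r2.props.mua,
            r2.props.musp,
            r2.shift,
        )


class TestFitG2:
    TAU = np.geomspace(1e-7, 1e-1, 60)

    def make_g2(self, bfi, beta, props, geom, rng=None, sd=0.005):
        g2 = siegert_g2(dcs_g1(props, geom, DCSConfig(bfi=bfi, beta=beta), self.TAU), beta)
        if rng is not None:
            g2 = g2 + rng.normal(0.0, sd, g2.size)
        return G2Record(0.0, self.TAU, g2, 50.0, "cerebral")

    def test_noiseless_round_trip_lattice(self, props_785, dcs_geometry):
        for bfi in (3e-9, 1e-8, 5e-8):
            for beta in (0.4, 0.5):
                rec = self.make_g2(bfi, beta, props_785, dcs_geometry)
                res = fit_g2(rec, props_785, dcs_geometry)
                assert res.converged
                assert res.bfi == pytest.approx(bfi, rel=0.01)
                assert res.beta == pytest.approx(beta, rel=0.01)

    def test_noisy_recovery_median_error(self, props_785, dcs_geometry):
        rng = np.random.default_rng(11)
        errs = [
            abs(
                fit_g2(
                    self.make_g2(1e-8, 0.5, props_785, dcs_geometry, rng=rng),
                    props_785,
                    dcs_geometry,
                ).bfi
                / 1e-8
                - 1
            )
            for _ in range(30)
        ]
        assert np.median(errs) < 0.05

    def test_flat_curve_flagged(self, props_785, dcs_geometry):
        rec = G2Record(0.0, self.TAU, np.ones_like(self.TAU), 50.0, "cerebral")
        res = fit_g2(rec, props_785, dcs_geometry)
        assert not res.converged and res.reason == "no_correlation"

    def test_deterministic(self, props_785, dcs_geometry):
        rec = self.make_g2(1e-8, 0.5, props_785, dcs_geometry, rng=np.random.default_rng(2))
        r1 = fit_g2(rec, props_785, dcs_geometry)
        r2 = fit_g2(rec, props_785, dcs_geometry)
        assert (r1.bfi, r1.beta) == (r2.bfi, r2.beta)
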