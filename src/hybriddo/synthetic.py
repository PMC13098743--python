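"""Seeded generator of synthetic transfusion sessions and cohorts.

A session follows the monitored-transfusion protocol: ~30 min of baseline,
a 2-3 h red-blood-cell transfusion, 30 min of post-transfusion observation,
with three arterial blood draws (one per period, the middle one at the
half-bag point). Ground truth consists of smooth per-location time courses
of microvascular oxy-/deoxy-hemoglobin, blood-flow index, arterial
saturation and hematocrit: baseline levels plus a sigmoidal ramp across the
transfusion epoch carrying the programmed effects, plus AR(1) physiological
noise. Raw instrument data are then simulated from the truth — TRS photon
time-of-flight histograms (two wavelengths, IRF-convolved, Poisson counts)
and DCS intensity autocorrelations (Siegert, additive noise scaled with
detector count rate) — alongside vitals, noisy blood-gas assays and event
marks, so the full inverse pipeline is exercised without any recorded data.

Default effect sizes are the cohort endpoint contrasts the generator
emulates: peripheral blood flow +68%, cerebral flow unchanged, oxygen
extraction fraction down 7% (cerebral) and 8% (peripheral),
deoxy-hemoglobin unchanged, hematocrit +2.9 points. The extraction-fraction
drop and the constant deoxy-hemoglobin are the primitive dials; the oxy-
and total-hemoglobin increases emerge through the saturation identity
(HbO2 = StO2/(1-StO2) * Hhb) and land at a few micromolar — the same
magnitudes the emulated cohort reports — so the truth is internally
consistent with every equation the pipeline applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .biomarkers import BloodGasSample, VitalsTrace, hgb_from_hct
from .forward import (
    DCSConfig,
    MediumGeometry,
    OpticalProperties,
    convolve_with_irf,
    dcs_g1,
    siegert_g2,
    td_reflectance,
)
from .inversion import (
    DTOFRecord,
    G2Record,
    IRFRecord,
    load_extinction_table,
    mua_from_chromophores,
)

__all__ = [
    "ProtocolSpec",
    "EffectSpec",
    "InstrumentSpec",
    "SyntheticTruth",
    "RawSessionBundle",
    "make_ground_truth",
    "simulate_raw",
    "generate_cohort",
    "gaussian_irf",
]

LOCATIONS = ("cerebral", "peripheral")


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of the monitored-transfusion protocol, minutes."""

    baseline_min: float = 30.0
    transfusion_min: float = 150.0  # protocol range 120-180
    post_min: float = 30.0
    draw_offset_min: float = 10.0  # pre/post draws this far into their period

    def __post_init__(self) -> None:
        if min(self.baseline_min, self.transfusion_min, self.post_min) <= 0:
            raise ValueError("protocol durations must be positive")
        if self.draw_offset_min >= min(self.baseline_min, self.post_min):
            raise ValueError("blood draws must fall inside their periods")

    @property
    def transfusion_start(self) -> float:
        return self.baseline_min * 60.0

    @property
    def transfusion_end(self) -> float:
        return (self.baseline_min + self.transfusion_min) * 60.0

    @property
    def total_seconds(self) -> float:
        return (self.baseline_min + self.transfusion_min + self.post_min) * 60.0

    @property
    def draw_times(self) -> tuple[float, float, float]:
        return (
            self.draw_offset_min * 60.0,
            self.transfusion_start + 0.5 * self.transfusion_min * 60.0,
            self.transfusion_end + self.draw_offset_min * 60.0,
        )


@dataclass(frozen=True)
class EffectSpec:
    """Programmed transfusion effects and their between-subject spreads.

    Fractional flow and extraction-fraction changes and the absolute
    deoxy-hemoglobin delta (mM) are applied through a sigmoidal ramp
    spanning the transfusion epoch; per-subject effects are drawn normally
    around the means with the stated SDs (30% of the mean where no cohort
    spread is reported). Oxy- and total-hemoglobin changes are emergent,
    not dialed.
    """

    bf_change: dict = field(
        default_factory=lambda: {"cerebral": 0.0, "peripheral": 0.68}
    )
    bf_change_sd: dict = field(
        default_factory=lambda: {"cerebral": 0.08, "peripheral": 0.20}
    )
    oef_change: dict = field(
        default_factory=lambda: {"cerebral": -0.07, "peripheral": -0.08}
    )
    oef_change_sd: dict = field(
        default_factory=lambda: {"cerebral": 0.021, "peripheral": 0.024}
    )
    dhhb: dict = field(
        default_factory=lambda: {"cerebral": 0.0, "peripheral": 0.0}
    )
    dhhb_sd: dict = field(
        default_factory=lambda: {"cerebral": 0.0004, "peripheral": 0.0004}
    )
    gamma_venous: float = 0.75  # ties StO2 to the OEF dial
    hct_change: float = 2.9  # absolute %
    hct_change_sd: float = 0.8
    hct_pre_mean: float = 24.5
    hct_pre_sd: float = 1.6
    paco2_mean: float = 39.4
    paco2_sd: float = 4.3
    paco2_change: float = 0.6
    paco2_change_sd: float = 2.0
    sao2_baseline: float = 0.97
    # baseline physiology per location
    hbt_baseline: dict = field(
        default_factory=lambda: {"cerebral": 0.060, "peripheral": 0.048}
    )
    sto2_baseline: dict = field(
        default_factory=lambda: {"cerebral": 0.65, "peripheral": 0.70}
    )
    sto2_baseline_sd: float = 0.03
    bfi_baseline: dict = field(
        default_factory=lambda: {"cerebral": 1.5e-8, "peripheral": 0.8e-8}
    )
    baseline_cv: float = 0.10  # between-subject spread of baselines
    # AR(1) physiological noise (per 10-s step)
    ar1_phi: float = 0.9
    noise_hb_sd: float = 0.0006  # mM, on hbo2 and hhb
    noise_bfi_cv: float = 0.03  # multiplicative on bfi
    noise_sao2_sd: float = 0.003
    noise_scale: float = 1.0  # 0 switches physiological noise off

    def zeroed(self) -> "EffectSpec":
        """A null copy: no programmed effects, noise retained."""
        zero = {loc: 0.0 for loc in LOCATIONS}
        return replace(
            self,
            bf_change=zero.copy(),
            oef_change=zero.copy(),
            dhhb=zero.copy(),
            hct_change=0.0,
            paco2_change=0.0,
        )


@dataclass(frozen=True)
class InstrumentSpec:
    """Hybrid device emulation: TRS histogramming and DCS correlation."""

    trs_rho: float = 30.0  # mm
    dcs_rho: float = 25.0  # mm
    n_tissue: float = 1.4
    n_outside: float = 1.0
    wavelengths: tuple = (690.0, 830.0)
    bin_width_ps: float = 25.0
    n_bins: int = 400
    irf_sigma_ps: float = 100.0
    irf_t0_ps: float = 1000.0
    dtof_total_counts: float = 5e5
    background_counts_per_bin: float = 2.0
    acq_period_s: float = 1.0
    dcs_wavelength: float = 785.0
    beta: float = 0.5
    tau_min_s: float = 1e-7
    tau_max_s: float = 1e-1
    n_tau: int = 60
    g2_noise_sd: float = 0.005  # at the reference 20 kHz count rate
    count_rate_khz: dict = field(
        default_factory=lambda: {"cerebral": 30.0, "peripheral": 60.0}
    )
    # reduced scattering per location and wavelength, 1/mm
    musp: dict = field(
        default_factory=lambda: {
            "cerebral": {690.0: 1.10, 830.0: 0.95},
            "peripheral": {690.0: 0.90, 830.0: 0.80},
        }
    )

    @property
    def tau_grid(self) -> np.ndarray:
        return np.geomspace(self.tau_min_s, self.tau_max_s, self.n_tau)

    def geometry(self, modality: str) -> MediumGeometry:
        rho = self.trs_rho if modality == "trs" else self.dcs_rho
        return MediumGeometry(rho=rho, n_tissue=self.n_tissue, n_outside=self.n_outside)


@dataclass
class SyntheticTruth:
    """Ground-truth registry for one subject-session."""

    subject_id: str
    t: np.ndarray  # truth grid, s
    hbo2: dict  # location -> mM array
    hhb: dict
    bfi: dict  # location -> cm^2/s array
    sao2: np.ndarray
    hct: np.ndarray  # % on the truth grid
    paco2: np.ndarray
    protocol: ProtocolSpec
    effects_drawn: dict
    seed: int

    @property
    def events(self) -> dict:
        return {
            "transfusion_start": self.protocol.transfusion_start,
            "transfusion_end": self.protocol.transfusion_end,
            "blood_draws": list(self.protocol.draw_times),
        }

    def hbt(self, loc: str) -> np.ndarray:
        return self.hbo2[loc] + self.hhb[loc]

    def sto2(self, loc: str) -> np.ndarray:
        return self.hbo2[loc] / self.hbt(loc)


@dataclass
class RawSessionBundle:
    """Simulated raw instrument data for one subject-session."""

    subject_id: str
    dtofs: list  # DTOFRecord
    irfs: dict  # wavelength -> IRFRecord
    g2s: list  # G2Record
    vitals: VitalsTrace
    bloodgas: list  # BloodGasSample
    events: dict
    masks: list = field(default_factory=list)
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    seed: int = 0
    truth: SyntheticTruth | None = None


def _sigmoid_ramp(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smooth 0->1 ramp across [start, end], exactly 0/1 at the ends."""
    x = 6.0 * (t - 0.5 * (start + end)) / (end - start)
    s = 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))
    lo, hi = 1.0 / (1.0 + np.exp(3.0)), 1.0 / (1.0 + np.exp(-3.0))
    return np.clip((s - lo) / (hi - lo), 0.0, 1.0)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def make_ground_truth(
    protocol: ProtocolSpec = ProtocolSpec(),
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
    dt: float = 10.0,
    subject_id: str = "S01",
) -> SyntheticTruth:
    """Draw one subject's ground-truth physiology, deterministic per seed."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.total_seconds, dt)
    ramp = _sigmoid_ramp(t, protocol.transfusion_start, protocol.transfusion_end)
    ns = effects.noise_scale

    drawn: dict = {}
    hbo2, hhb, bfi = {}, {}, {}
    gamma = effects.gamma_venous
    sao2_b = effects.sao2_baseline
    for loc in LOCATIONS:
        hbt0 = effects.hbt_baseline[loc] * (
            1.0 + rng.normal(0.0, effects.baseline_cv)
        )
        sto2_0 = float(
            np.clip(
                effects.sto2_baseline[loc]
                + rng.normal(0.0, effects.sto2_baseline_sd),
                0.35,
                0.9,
            )
        )
        bfi0 = effects.bfi_baseline[loc] * float(
            np.exp(rng.normal(0.0, effects.baseline_cv))
        )
        d_oef = rng.normal(effects.oef_change[loc], effects.oef_change_sd[loc])
        d_hhb = rng.normal(effects.dhhb[loc], effects.dhhb_sd[loc])
        d_bf = rng.normal(effects.bf_change[loc], effects.bf_change_sd[loc])
        # saturation course implied by the extraction-fraction ramp
        svo2_0 = (sto2_0 - (1.0 - gamma) * sao2_b) / gamma
        oef_t = (sao2_b - svo2_0) / sao2_b * (1.0 + d_oef * ramp)
        sto2_t = gamma * sao2_b * (1.0 - oef_t) + (1.0 - gamma) * sao2_b
        hhb0 = (1.0 - sto2_0) * hbt0
        hhb_clean = hhb0 + d_hhb * ramp
        drawn[loc] = {
            "hbt0": hbt0,
            "sto2_0": sto2_0,
            "bfi0": bfi0,
            "oef_change": d_oef,
            "dhhb": d_hhb,
            "bf_change": d_bf,
        }
        o = sto2_t / (1.0 - sto2_t) * hhb_clean + _ar1(
            rng, t.size, effects.ar1_phi, effects.noise_hb_sd * ns
        )
        h = hhb_clean + _ar1(
            rng, t.size, effects.ar1_phi, effects.noise_hb_sd * ns
        )
        if np.any(o <= 0.0) or np.any(h <= 0.0):
            warnings.warn(
                f"{loc}: effects drove a concentration non-positive; clipping",
                stacklevel=2,
            )
            o = np.clip(o, 1e-4, None)
            h = np.clip(h, 1e-4, None)
        hbo2[loc], hhb[loc] = o, h
        bfi[loc] = (
            bfi0
            * (1.0 + d_bf * ramp)
            * (1.0 + _ar1(rng, t.size, effects.ar1_phi, effects.noise_bfi_cv * ns))
        )
        bfi[loc] = np.clip(bfi[loc], 1e-12, None)

    sao2 = np.clip(
        effects.sao2_baseline
        + _ar1(rng, t.size, effects.ar1_phi, effects.noise_sao2_sd * ns),
        0.5,
        1.0,
    )
    hct_pre = float(np.clip(rng.normal(effects.hct_pre_mean, effects.hct_pre_sd), 15, 45))
    d_hct = rng.normal(effects.hct_change, effects.hct_change_sd)
    hct = hct_pre + d_hct * ramp
    paco2_0 = rng.normal(effects.paco2_mean, effects.paco2_sd)
    paco2 = paco2_0 + rng.normal(effects.paco2_change, effects.paco2_change_sd) * ramp
    drawn["hct_pre"] = hct_pre
    drawn["hct_change"] = d_hct

    return SyntheticTruth(
        subject_id, t, hbo2, hhb, bfi, sao2, hct, paco2, protocol, drawn, seed
    )


def gaussian_irf(instrument: InstrumentSpec, wavelength: float) -> IRFRecord:
    """Unit-area Gaussian IRF centered at ``irf_t0_ps``."""
    t = (np.arange(instrument.n_bins) + 0.5) * instrument.bin_width_ps
    k = np.exp(-0.5 * ((t - instrument.irf_t0_ps) / instrument.irf_sigma_ps) ** 2)
    return IRFRecord(instrument.bin_width_ps, k / k.sum(), wavelength)


def simulate_raw(
    truth: SyntheticTruth,
    instrument: InstrumentSpec = InstrumentSpec(),
    seed: int = 0,
    noise: bool = True,
    keep_truth: bool = True,
) -> RawSessionBundle:
    """Simulate the raw instrument streams of one session from its truth.

    TRS: per acquisition, concentrations map to absorption through the
    bundled extinction table, the semi-infinite model is evaluated,
    IRF-convolved, scaled to the configured total counts over a flat dark
    background and Poisson-sampled. DCS: the Brownian correlation model with
    TRS-consistent averaged properties is Siegert-mapped and perturbed by
    additive Gaussian noise scaled inversely with the root count rate.
    """
    rng = np.random.default_rng(seed)
    table = load_extinction_table()
    geom_trs = instrument.geometry("trs")
    geom_dcs = instrument.geometry("dcs")
    tau = instrument.tau_grid
    tgrid_ps = (np.arange(instrument.n_bins) + 0.5) * instrument.bin_width_ps
    irfs = {w: gaussian_irf(instrument, w) for w in instrument.wavelengths}

    # acquisition clock: truth grid resampled at the acquisition period
    t_acq = np.arange(0.0, truth.t[-1] + truth.t[1] - truth.t[0], instrument.acq_period_s)
    t_acq = t_acq[t_acq <= truth.t[-1]]

    def tr(x):
        return np.interp(t_acq, truth.t, x)

    dtofs, g2s = [], []
    for loc in LOCATIONS:
        hbo2, hhb = tr(truth.hbo2[loc]), tr(truth.hhb[loc])
        bfi = tr(truth.bfi[loc])
        mus = instrument.musp[loc]
        cr = instrument.count_rate_khz[loc]
        sd_g2 = instrument.g2_noise_sd * np.sqrt(20.0 / cr)
        for i, ts in enumerate(t_acq):
            muas = {}
            for w in instrument.wavelengths:
                mua = mua_from_chromophores(hbo2[i], hhb[i], w, table)
                muas[w] = mua
                props = OpticalProperties(w, mua, mus[w])
                curve = td_reflectance(props, geom_trs, tgrid_ps)
                meas = convolve_with_irf(curve, irfs[w].counts, instrument.bin_width_ps)
                meas = meas / meas.sum() * instrument.dtof_total_counts
                lam = meas + instrument.background_counts_per_bin
                counts = rng.poisson(lam) if noise else np.round(lam).astype(np.int64)
                dtofs.append(
                    DTOFRecord(float(ts), w, instrument.bin_width_ps, counts, loc)
                )
            mua785 = 0.5 * (muas[instrument.wavelengths[0]] + muas[instrument.wavelengths[1]])
            musp785 = 0.5 * (mus[instrument.wavelengths[0]] + mus[instrument.wavelengths[1]])
            props785 = OpticalProperties(instrument.dcs_wavelength, mua785, musp785)
            cfg = DCSConfig(instrument.dcs_wavelength, float(bfi[i]), instrument.beta)
            g2 = siegert_g2(dcs_g1(props785, geom_dcs, cfg, tau), instrument.beta)
            if noise:
                g2 = g2 + rng.normal(0.0, sd_g2, size=g2.size)
            g2s.append(G2Record(float(ts), tau, g2, cr, loc))

    # vitals at 1 Hz (config detail; fusion happens at 10-s bins anyway)
    t_vit = np.arange(0.0, truth.t[-1], 1.0)
    sao2_v = np.interp(t_vit, truth.t, truth.sao2)
    if noise:
        sao2_v = np.clip(sao2_v + rng.normal(0.0, 0.002, t_vit.size), 0.0, 1.0)
    vitals = VitalsTrace(
        t_vit,
        sao2_v,
        np.full(t_vit.size, 85.0) + (rng.normal(0.0, 3.0, t_vit.size) if noise else 0.0),
        np.full(t_vit.size, 75.0) + (rng.normal(0.0, 2.0, t_vit.size) if noise else 0.0),
    )

    bloodgas = []
    for period, t_draw in zip(("pre", "mid", "post"), truth.protocol.draw_times):
        hct_true = float(np.interp(t_draw, truth.t, truth.hct))
        hct_meas = hct_true + (rng.normal(0.0, 0.5) if noise else 0.0)
        hgb_meas = hgb_from_hct(hct_true) + (rng.normal(0.0, 0.1) if noise else 0.0)
        paco2 = float(np.interp(t_draw, truth.t, truth.paco2))
        bloodgas.append(
            BloodGasSample(
                time=float(t_draw),
                hgb=float(hgb_meas),
                hct=float(np.clip(hct_meas, 1.0, 99.0)),
                paco2=paco2,
                period=period,
            )
        )

    return RawSessionBundle(
        subject_id=truth.subject_id,
        dtofs=dtofs,
        irfs=irfs,
        g2s=g2s,
        vitals=vitals,
        bloodgas=bloodgas,
        events=truth.events,
        masks=[],
        instrument=instrument,
        seed=seed,
        truth=truth if keep_truth else None,
    )


def generate_cohort(
    n_subjects: int = 14,
    protocol: ProtocolSpec = ProtocolSpec(),
    effects: EffectSpec = EffectSpec(),
    instrument: InstrumentSpec = InstrumentSpec(),
    seed: int = 0,
    raw: bool = True,
    noise: bool = True,
    missingness: bool = False,
    truth_dt: float = 10.0,
) -> list:
    """Generate an independent-seeded cohort of session bundles.

    With ``missingness`` the first two subjects lose their cerebral optical
    streams and the third its post-transfusion blood draw, mimicking the
    emulated cohort's pattern (12 of 14 with cerebral traces, one subject
    with the post hematocrit imputed). With ``raw=False`` only the truth
    registries are returned (the fast trace-level path).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for i, child in enumerate(children):
        s_truth, s_raw = child.generate_state(2) % (2**31)
        truth = make_ground_truth(
            protocol, effects, seed=int(s_truth), dt=truth_dt, subject_id=f"S{i + 1:02d}"
        )
        if not raw:
            out.append(truth)
            continue
        bundle = simulate_raw(truth, instrument, seed=int(s_raw), noise=noise)
        if missingness and i < 2:
            bundle.dtofs = [d for d in bundle.dtofs if d.location != "cerebral"]
            bundle.g2s = [g for g in bundle.g2s if g.location != "cerebral"]
        if missingness and i == 2:
            bundle.bloodgas = [s for s in bundle.bloodgas if s.period != "post"]
        out.append(bundle)
    return out
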