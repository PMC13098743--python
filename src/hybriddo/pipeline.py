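"""Orchestration: raw session bundle -> fitted traces -> derived biomarkers
-> cohort statistics.

``process_bundle`` runs the inverse problems record by record (with QC),
fuses everything on the 10-s time base and derives the baseline-referenced
biomarkers. ``process_cohort`` adds the cohort-level hematocrit imputation
for subjects lacking a post-transfusion draw. ``truth_to_session`` is the
fast trace-level path that derives the same biomarkers directly from a
synthetic ground-truth registry, bypassing the raw-instrument inversion —
used for statistical calibration where only the cohort battery is under
test. ``analyze_cohort`` produces the blood-gas and optical results tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .biomarkers import (
    BloodGasSample,
    HemoTrace,
    PhysioConstants,
    SubjectSession,
    VitalsTrace,
    delta_trace,
    hgb_from_hct,
    impute_post_hct,
    mro2_trace,
    oef_from_sto2,
    relative_trace,
    synchronize,
)
from .config import RunConfig
from .forward import MediumGeometry, ValidationError
from .inversion import (
    average_musp,
    chromophores_from_mua,
    fit_dtof,
    fit_g2,
    mua_for_dcs,
    OpticalProperties,
)
from .qc import apply_masks, qc_dcs, qc_trs, trs_snr
from .stats import (
    WindowSpec,
    bloodgas_table,
    build_results_tables,
    cohort_window_means,
)
from .synthetic import RawSessionBundle, SyntheticTruth

__all__ = [
    "process_bundle",
    "process_cohort",
    "derive_session_traces",
    "truth_to_session",
    "analyze_cohort",
    "bloodgas_frame",
]


def _fit_trs_records(bundle: RawSessionBundle, config: RunConfig):
    """Fit every QC-passing DTOF; returns per-(location, wavelength) series
    of (timestamp, props) plus the QC rows. Warm-started along time."""
    geom = MediumGeometry(
        bundle.instrument.trs_rho, config.n_tissue, config.n_outside
    )
    fits: dict = {}
    qc_rows = []
    order = sorted(
        range(len(bundle.dtofs)),
        key=lambda i: (bundle.dtofs[i].location, bundle.dtofs[i].wavelength,
                       bundle.dtofs[i].timestamp),
    )
    warm: dict = {}
    for i in order:
        rec = bundle.dtofs[i]
        key = (rec.location, rec.wavelength)
        rid = f"trs/{rec.location}/{rec.wavelength:.0f}/{rec.timestamp:.0f}"
        snr = trs_snr(rec)
        qc = qc_trs(snr, record_id=rid)
        if not qc.passed:
            qc_rows.append(_qc_row(qc, rec.timestamp, rec.location, "trs"))
            continue
        res = fit_dtof(
            rec,
            bundle.irfs[rec.wavelength],
            geom,
            rise_frac=config.rise_frac,
            tail_frac=config.tail_frac,
            fit_shift=config.fit_shift,
            x0=warm.get(key),
        )
        if not res.converged:
            qc_rows.append(
                _qc_row(qc, rec.timestamp, rec.location, "trs", reason="fit_failure")
            )
            continue
        warm[key] = (res.props.mua, res.props.musp)
        fits.setdefault(key, []).append((rec.timestamp, res.props))
        qc_rows.append(_qc_row(qc, rec.timestamp, rec.location, "trs"))
    return fits, qc_rows


def _qc_row(qc, timestamp, location, modality, reason=None):
    passed = qc.passed if reason is None else False
    return {
        "record_id": qc.record_id,
        "timestamp": timestamp,
        "location": location,
        "modality": modality,
        "snr": qc.snr,
        "count_rate": qc.count_rate,
        "beta": qc.beta,
        "passed": passed,
        "reason": reason or qc.reason,
    }


def process_bundle(
    bundle: RawSessionBundle,
    config: RunConfig = RunConfig(),
    cohort_hct: pd.DataFrame | None = None,
) -> tuple[SubjectSession, pd.DataFrame]:
    """Full single-subject processing: fits, QC, fusion, derived traces.

    ``cohort_hct`` (columns hct_pre_pct/hct_post_pct) enables imputation of
    a missing post-transfusion hematocrit from matched cohort donors.
    """
    fits, qc_rows = _fit_trs_records(bundle, config)
    geom_dcs = MediumGeometry(
        bundle.instrument.dcs_rho, config.n_tissue, config.n_outside
    )

    # chromophores where both wavelengths fitted at the same acquisition
    optical: dict = {}
    props_lookup: dict = {}
    locations = sorted({loc for loc, _ in fits})
    for loc in locations:
        by_w = {
            w: dict(fits.get((loc, w), [])) for w in bundle.instrument.wavelengths
        }
        w1, w2 = bundle.instrument.wavelengths
        common = sorted(set(by_w[w1]) & set(by_w[w2]))
        ts_list, hbo2, hhb, hbt, sto2 = [], [], [], [], []
        for ts in common:
            p1, p2 = by_w[w1][ts], by_w[w2][ts]
            props_lookup.setdefault(loc, []).append((ts, p1, p2))
            chrom = chromophores_from_mua(p1.mua, p2.mua, _table())
            if chrom.flagged:
                continue
            ts_list.append(ts)
            hbo2.append(chrom.hbo2)
            hhb.append(chrom.hhb)
            hbt.append(chrom.hbt)
            sto2.append(chrom.sto2)
        if ts_list:
            optical[(loc, "hbo2")] = (ts_list, hbo2)
            optical[(loc, "hhb")] = (ts_list, hhb)
            optical[(loc, "hbt")] = (ts_list, hbt)
            optical[(loc, "sto2")] = (ts_list, sto2)

    # DCS fits with TRS-derived properties (nearest acquisition)
    warm_bfi: dict = {}
    for rec in sorted(bundle.g2s, key=lambda r: (r.location, r.timestamp)):
        rid = f"dcs/{rec.location}/{rec.timestamp:.0f}"
        pl = props_lookup.get(rec.location)
        if not pl:
            continue
        ts_arr = np.array([p[0] for p in pl])
        j = int(np.argmin(np.abs(ts_arr - rec.timestamp)))
        _, p690, p830 = pl[j]
        props785 = OpticalProperties(
            785.0,
            mua_for_dcs(p690, p830, mode=config.mua_dcs_mode),
            average_musp(p690, p830),
        )
        res = fit_g2(
            rec,
            props785,
            geom_dcs,
            cut_frac=config.g2_cut_frac,
            bfi0=warm_bfi.get(rec.location, 1e-8),
        )
        if res.converged:
            warm_bfi[rec.location] = res.bfi
        qc = qc_dcs(rec, res.beta if res.converged else np.nan,
                    mode=config.dcs_qc_mode, record_id=rid)
        reason = None if res.converged else "fit_failure"
        qc_rows.append(_qc_row(qc, rec.timestamp, rec.location, "dcs", reason=reason))
        if qc.passed and res.converged:
            optical.setdefault((rec.location, "bfi"), ([], []))
            optical[(rec.location, "bfi")][0].append(rec.timestamp)
            optical[(rec.location, "bfi")][1].append(res.bfi)

    session = synchronize(
        optical,
        bundle.vitals,
        dict(bundle.events),
        subject_id=bundle.subject_id,
        bloodgas=bundle.bloodgas,
        masks=bundle.masks,
        bin_seconds=config.bin_seconds,
    )
    session.meta["config"] = config.to_dict()
    session = derive_session_traces(session, config, cohort_hct=cohort_hct)
    return session, pd.DataFrame(qc_rows)


_EXT_TABLE = None


def _table():
    global _EXT_TABLE
    if _EXT_TABLE is None:
        from .inversion import load_extinction_table

        _EXT_TABLE = load_extinction_table()
    return _EXT_TABLE


def derive_session_traces(
    session: SubjectSession,
    config: RunConfig = RunConfig(),
    cohort_hct: pd.DataFrame | None = None,
) -> SubjectSession:
    """Derive OEF, MRO2 and the baseline-referenced traces in place.

    Expects absolute binned traces (hbo2/hhb/hbt/sto2 and bfi per location)
    plus binned vitals and the blood-gas samples. Applies artifact masks
    first; masking removes bins, never alters them.
    """
    constants = PhysioConstants(
        k=config.k_o2_per_g, mchc=config.mchc_g_per_l, gamma_venous=config.gamma_venous
    )
    if session.masks:
        for key, tr in list(session.traces.items()):
            t, v, _ = apply_masks(tr.timestamps, tr.values, session.masks)
            session.traces[key] = HemoTrace(tr.location, tr.variable, t, v)
        if session.vitals is not None:
            keep_t, sao2, _ = apply_masks(
                session.vitals.timestamps, session.vitals.sao2, session.masks
            )
            _, mapv, _ = apply_masks(
                session.vitals.timestamps, session.vitals.map_mmhg, session.masks
            )
            _, hrv, _ = apply_masks(
                session.vitals.timestamps, session.vitals.hr_bpm, session.masks
            )
            session.vitals = VitalsTrace(keep_t, sao2, mapv, hrv)

    # period hematocrits, imputing a missing post draw when possible
    bloodgas = list(session.bloodgas)
    periods = {s.period for s in bloodgas}
    if "post" not in periods and "pre" in periods and cohort_hct is not None:
        pre_hct = next(s.hct for s in bloodgas if s.period == "pre")
        hct_post = impute_post_hct(
            pre_hct, cohort_hct, tolerance=config.hct_impute_tolerance
        )
        bloodgas.append(
            BloodGasSample(
                time=session.transfusion_end + config.post_window_seconds,
                hgb=hgb_from_hct(hct_post, constants),
                hct=hct_post,
                paco2=np.nan,
                period="post",
            )
        )
        session.meta["imputed_post_hct"] = hct_post
        session.bloodgas = bloodgas

    baseline = (0.0, session.transfusion_start)
    sao2_by_loc = None
    if session.vitals is not None:
        sao2_by_loc = HemoTrace(
            "cerebral", "sao2", session.vitals.timestamps, session.vitals.sao2
        )

    locations = sorted({loc for loc, _ in session.traces})
    for loc in locations:
        sto2 = session.traces.get((loc, "sto2"))
        bfi = session.traces.get((loc, "bfi"))
        if sto2 is not None and sao2_by_loc is not None:
            t = np.intersect1d(sto2.timestamps, sao2_by_loc.timestamps)
            sv = sto2.values[np.searchsorted(sto2.timestamps, t)]
            av = sao2_by_loc.values[np.searchsorted(sao2_by_loc.timestamps, t)]
            oef = oef_from_sto2(sv, av, gamma=constants.gamma_venous)
            session.traces[(loc, "oef")] = HemoTrace(loc, "oef", t, oef)
        oef_tr = session.traces.get((loc, "oef"))
        if bfi is not None and oef_tr is not None and sao2_by_loc is not None:
            try:
                session.traces[(loc, "mro2")] = mro2_trace(
                    bfi,
                    oef_tr,
                    HemoTrace(loc, "sao2", sao2_by_loc.timestamps, sao2_by_loc.values),
                    bloodgas,
                    session.transfusion_start,
                    session.transfusion_end,
                    constants,
                )
            except ValidationError as exc:
                warnings.warn(
                    f"{session.subject_id}/{loc}: MRO2 skipped ({exc})", stacklevel=2
                )
        for var in ("bfi", "oef", "mro2"):
            tr = session.traces.get((loc, var))
            if tr is not None:
                try:
                    session.traces[(loc, "r" + var)] = relative_trace(tr, baseline)
                except ValidationError:
                    pass
        for var in ("hbo2", "hhb", "hbt"):
            tr = session.traces.get((loc, var))
            if tr is not None:
                try:
                    session.traces[(loc, "d" + var)] = delta_trace(tr, baseline)
                except ValidationError:
                    pass
    return session


def truth_to_session(
    truth: SyntheticTruth, config: RunConfig = RunConfig()
) -> SubjectSession:
    """Trace-level path: biomarkers straight from a ground-truth registry."""
    optical = {}
    for loc in truth.hbo2:
        optical[(loc, "hbo2")] = (truth.t, truth.hbo2[loc])
        optical[(loc, "hhb")] = (truth.t, truth.hhb[loc])
        optical[(loc, "hbt")] = (truth.t, truth.hbt(loc))
        optical[(loc, "sto2")] = (truth.t, truth.sto2(loc))
        optical[(loc, "bfi")] = (truth.t, truth.bfi[loc])
    vitals = VitalsTrace(
        truth.t, truth.sao2, np.full(truth.t.size, 85.0), np.full(truth.t.size, 75.0)
    )
    bloodgas = []
    for period, t_draw in zip(("pre", "mid", "post"), truth.protocol.draw_times):
        hct = float(np.interp(t_draw, truth.t, truth.hct))
        bloodgas.append(
            BloodGasSample(
                time=float(t_draw),
                hgb=hgb_from_hct(hct),
                hct=hct,
                paco2=float(np.interp(t_draw, truth.t, truth.paco2)),
                period=period,
            )
        )
    session = synchronize(
        optical,
        vitals,
        dict(truth.events),
        subject_id=truth.subject_id,
        bloodgas=bloodgas,
        bin_seconds=config.bin_seconds,
    )
    return derive_session_traces(session, config)


def bloodgas_frame(sessions: list) -> pd.DataFrame:
    """One row per subject with pre/post blood-gas columns."""
    rows = []
    for s in sessions:
        row = {"subject": s.subject_id}
        for sample in s.bloodgas:
            if sample.period in ("pre", "post"):
                row[f"hgb_{sample.period}"] = sample.hgb
                row[f"hct_{sample.period}"] = sample.hct
                row[f"paco2_{sample.period}"] = sample.paco2
        rows.append(row)
    return pd.DataFrame(rows)


def process_cohort(
    bundles: list, config: RunConfig = RunConfig()
) -> tuple[list, pd.DataFrame]:
    """Process every bundle, with cohort-level post-HCT imputation.

    Subjects that fail entirely are recorded in the QC frame and skipped,
    so partial cohorts still analyze.
    """
    hct_rows = []
    for b in bundles:
        by_p = {s.period: s.hct for s in b.bloodgas}
        hct_rows.append(
            {"hct_pre_pct": by_p.get("pre", np.nan), "hct_post_pct": by_p.get("post", np.nan)}
        )
    cohort_hct = pd.DataFrame(hct_rows)

    sessions, qc_frames = [], []
    for b in bundles:
        try:
            session, qc = process_bundle(b, config, cohort_hct=cohort_hct)
        except Exception as exc:  # keep the cohort going
            warnings.warn(f"subject {b.subject_id} failed: {exc}", stacklevel=2)
            qc_frames.append(
                pd.DataFrame(
                    [{"record_id": b.subject_id, "modality": "session",
                      "passed": False, "reason": "fit_failure"}]
                )
            )
            continue
        qc["subject"] = b.subject_id
        sessions.append(session)
        qc_frames.append(qc)
    qc_all = pd.concat(qc_frames, ignore_index=True) if qc_frames else pd.DataFrame()
    return sessions, qc_all


def analyze_cohort(sessions: list, config: RunConfig = RunConfig()) -> dict:
    """The cohort battery: window means, optical tests table, blood-gas table."""
    if len(sessions) < 5:
        raise ValueError(
            f"cohort analysis needs at least 5 subjects, got {len(sessions)}"
        )
    spec = WindowSpec(post_length=config.post_window_seconds)
    means = cohort_window_means(sessions, spec)
    optical = build_results_tables(means, config.directions, alpha=config.alpha)
    bg = bloodgas_table(bloodgas_frame(sessions), alpha=config.alpha)
    return {"window_means": means, "optical_table": optical, "bloodgas_table": bg}
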