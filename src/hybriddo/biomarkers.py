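"""Derived physiology: oxygen content, extraction fraction, metabolic rate,
baseline-referenced traces, and the 10-s fusion time base.

The metabolic rate of oxygen is the product of the flow term, the oxygen
extraction fraction, and the arterial oxygen content,

    MRO2 = BFI * OEF * CaO2,        CaO2 = k * Hgb * SaO2,

with k = 1.36 mL O2 per g hemoglobin and the arterial hemoglobin tied to
hematocrit through the mean corpuscular hemoglobin concentration,
Hgb [g/dL] = HCT/100 * MCHC/10 (MCHC = 340 g/L). Because invasive blood
gases exist only at three protocol draws, HCT is held constant within each
protocol period (pre / transfusion / post), switching at the transfusion
start and end marks. OEF is estimated from tissue saturation through an
assumed venous compartment fraction gamma:

    SvO2 = (StO2 - (1-gamma)*SaO2) / gamma,   OEF = (SaO2 - SvO2) / SaO2,

reducing to (SaO2-StO2)/SaO2 at gamma = 1. Flow and metabolic traces are
reported relative to the pre-transfusion baseline mean (r-traces); the
hemoglobin concentrations as baseline-subtracted differences (delta-traces).
All streams are fused on non-overlapping half-open 10-s bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import ValidationError

__all__ = [
    "PhysioConstants",
    "BloodGasSample",
    "VitalsTrace",
    "HemoTrace",
    "SubjectSession",
    "hgb_from_hct",
    "cao2",
    "oef_from_sto2",
    "hct_for_time",
    "mro2_trace",
    "impute_post_hct",
    "relative_trace",
    "delta_trace",
    "downsample_10s",
    "synchronize",
    "sao2_as_fraction",
]

PERIODS = ("pre", "mid", "post")
BIN_SECONDS = 10.0


@dataclass(frozen=True)
class PhysioConstants:
    """Constants entering the oxygen equations; echoed into run metadata."""

    k: float = 1.36  # mL O2 per g Hgb
    mchc: float = 340.0  # g/L
    gamma_venous: float = 0.75  # venous compartment fraction


@dataclass(frozen=True)
class BloodGasSample:
    """One timed invasive arterial sample with its protocol-period label."""

    time: float  # s
    hgb: float  # g/dL
    hct: float  # %
    paco2: float  # mmHg
    period: str  # pre | mid | post
    hgbo2: float | None = None
    hgbr: float | None = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if not (0.0 < self.hct < 100.0):
            raise ValidationError(f"hct out of range: {self.hct}")
        if self.hgb <= 0:
            raise ValidationError(f"hgb must be positive: {self.hgb}")


@dataclass
class VitalsTrace:
    """Vitals streams on a shared timestamp grid (SaO2 as a fraction)."""

    timestamps: np.ndarray
    sao2: np.ndarray
    map_mmhg: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.sao2 = sao2_as_fraction(np.asarray(self.sao2, dtype=float))


@dataclass
class HemoTrace:
    """One biomarker time series at one location on the session clock."""

    location: str
    variable: str
    timestamps: np.ndarray  # bin start times, s
    values: np.ndarray
    baseline_stat: float | None = None  # pre-window mean used for r/delta

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.size != self.values.size:
            raise ValidationError("timestamps and values must align")


@dataclass
class SubjectSession:
    """A synchronized subject-session: traces, vitals, blood gases, marks."""

    subject_id: str
    traces: dict  # (location, variable) -> HemoTrace
    vitals: VitalsTrace | None
    bloodgas: list
    events: dict  # label -> time s (blood_draws -> list of times)
    masks: list = field(default_factory=list)
    geometry: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def transfusion_start(self) -> float:
        return self.events["transfusion_start"]

    @property
    def transfusion_end(self) -> float:
        return self.events["transfusion_end"]


def sao2_as_fraction(sao2: np.ndarray) -> np.ndarray:
    """Auto-detect percent-scale oximetry and convert to a fraction."""
    sao2 = np.asarray(sao2, dtype=float)
    if sao2.size and np.nanmax(sao2) > 1.5:
        warnings.warn("SaO2 appears percent-scaled; dividing by 100", stacklevel=2)
        return sao2 / 100.0
    return sao2


def hgb_from_hct(hct: float, constants: PhysioConstants = PhysioConstants()) -> float:
    """Arterial hemoglobin (g/dL) from hematocrit (%) via the MCHC."""
    if not (0.0 < hct < 100.0):
        raise ValidationError(f"hct out of range: {hct}")
    return hct / 100.0 * constants.mchc / 10.0


def cao2(
    hgb: float, sao2, constants: PhysioConstants = PhysioConstants()
):
    """Arterial oxygen content, mL O2/dL."""
    sao2 = np.asarray(sao2, dtype=float)
    if np.any((sao2 < 0.0) | (sao2 > 1.0)):
        raise ValidationError("sao2 must lie in [0, 1]")
    out = constants.k * hgb * sao2
    return float(out) if out.ndim == 0 else out


def oef_from_sto2(sto2, sao2, gamma: float = 0.75):
    """Oxygen extraction fraction from tissue and arterial saturations.

    Values outside [0, 1] are returned as computed (the caller flags them);
    sao2 = 0 is undefined and raises.
    """
    sto2 = np.asarray(sto2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if np.any(sao2 <= 0.0):
        raise ValidationError("sao2 must be positive for OEF")
    svo2 = (sto2 - (1.0 - gamma) * sao2) / gamma
    out = (sao2 - svo2) / sao2
    return float(out) if out.ndim == 0 else out


def hct_for_time(
    t, bloodgas: list, transfusion_start: float, transfusion_end: float
):
    """Period-constant HCT: pre before the start mark, mid during the
    transfusion, post from the end mark on."""
    by_period = {s.period: s.hct for s in bloodgas}
    missing = [p for p in PERIODS if p not in by_period]
    if missing:
        raise ValidationError(f"missing HCT for period(s): {missing}")
    t = np.asarray(t, dtype=float)
    out = np.where(
        t < transfusion_start,
        by_period["pre"],
        np.where(t < transfusion_end, by_period["mid"], by_period["post"]),
    )
    return float(out) if out.ndim == 0 else out


def mro2_trace(
    bfi_trace: HemoTrace,
    oef_trace: HemoTrace,
    sao2_trace: HemoTrace,
    bloodgas: list,
    transfusion_start: float,
    transfusion_end: float,
    constants: PhysioConstants = PhysioConstants(),
) -> HemoTrace:
    """MRO2 = BFI * OEF * CaO2 on the bins shared by all three inputs.

    CaO2 carries the HCT correction through the period-constant hematocrit;
    the BFI itself enters uncorrected.
    """
    t = np.intersect1d(bfi_trace.timestamps, oef_trace.timestamps)
    t = np.intersect1d(t, sao2_trace.timestamps)

    def at(trace):
        idx = np.searchsorted(trace.timestamps, t)
        return trace.values[idx]

    hct = hct_for_time(t, bloodgas, transfusion_start, transfusion_end)
    hgb = hct / 100.0 * constants.mchc / 10.0
    sao2 = at(sao2_trace)
    values = at(bfi_trace) * at(oef_trace) * constants.k * hgb * sao2
    return HemoTrace(bfi_trace.location, "mro2", t, values)


def impute_post_hct(
    pre_hct: float,
    cohort: pd.DataFrame,
    tolerance: float = 0.5,
) -> float:
    """Post-transfusion HCT for a subject lacking the final blood draw.

    Mean of the post values of donors whose pre-transfusion HCT matched the
    subject's (within ``tolerance`` % absolute); falls back to the cohort
    mean post-HCT with a warning when no donor matches. ``cohort`` needs
    columns ``hct_pre_pct`` and ``hct_post_pct``.
    """
    rows = cohort.dropna(subset=["hct_pre_pct", "hct_post_pct"])
    donors = rows[np.abs(rows["hct_pre_pct"] - pre_hct) <= tolerance]
    if donors.empty:
        warnings.warn(
            "no donor with matching pre-HCT; using cohort mean post-HCT",
            stacklevel=2,
        )
        return float(rows["hct_post_pct"].mean())
    return float(donors["hct_post_pct"].mean())


def _baseline_mean(trace: HemoTrace, baseline_window, min_bins: int = 3) -> float:
    a, b = baseline_window
    sel = (trace.timestamps >= a) & (trace.timestamps < b)
    if sel.sum() < min_bins:
        raise ValidationError(
            f"baseline window holds {int(sel.sum())} bins (< {min_bins})"
        )
    return float(trace.values[sel].mean())


def relative_trace(trace: HemoTrace, baseline_window) -> HemoTrace:
    """r-variable: the trace divided by its pre-transfusion baseline mean."""
    base = _baseline_mean(trace, baseline_window)
    if abs(base) < 1e-12:
        raise ValidationError("baseline mean is zero; relative trace undefined")
    return HemoTrace(
        trace.location,
        "r" + trace.variable,
        trace.timestamps,
        trace.values / base,
        baseline_stat=base,
    )


def delta_trace(trace: HemoTrace, baseline_window) -> HemoTrace:
    """delta-variable: the trace minus its pre-transfusion baseline mean."""
    base = _baseline_mean(trace, baseline_window)
    return HemoTrace(
        trace.location,
        "d" + trace.variable,
        trace.timestamps,
        trace.values - base,
        baseline_stat=base,
    )


def downsample_10s(
    timestamps: np.ndarray,
    values: np.ndarray,
    bin_seconds: float = BIN_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean over non-overlapping [k*bin, (k+1)*bin) bins; empty bins absent.

    Returns (bin start times, bin means). A timestamp exactly on a boundary
    belongs to the later bin (half-open convention).
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return t, v
    if np.any(np.diff(t) < 0):
        raise ValidationError("timestamps must be sorted")
    idx = np.floor(t / bin_seconds).astype(np.int64)
    uniq, inverse = np.unique(idx, return_inverse=True)
    sums = np.bincount(inverse, weights=v)
    cnts = np.bincount(inverse)
    return uniq * bin_seconds, sums / cnts


def synchronize(
    optical: dict,
    vitals: VitalsTrace | None,
    events: dict,
    offsets: dict | None = None,
    subject_id: str = "",
    bloodgas: list | None = None,
    masks: list | None = None,
    bin_seconds: float = BIN_SECONDS,
) -> SubjectSession:
    """Fuse raw streams onto the 10-s master time base of the session clock.

    ``optical`` maps (location, variable) to (timestamps, values) pairs;
    ``offsets`` maps stream names ('vitals', 'optical', 'events') to clock
    offsets in seconds, added to that stream's native times. Sessions
    without both transfusion marks are unprocessable.
    """
    offsets = offsets or {}
    events = {
        k: (
            [t + offsets.get("events", 0.0) for t in v]
            if isinstance(v, (list, tuple, np.ndarray))
            else v + offsets.get("events", 0.0)
        )
        for k, v in events.items()
    }
    for mark in ("transfusion_start", "transfusion_end"):
        if mark not in events:
            raise ValidationError(f"missing required event mark {mark!r}")

    traces = {}
    for (loc, var), (t, v) in optical.items():
        tb, vb = downsample_10s(
            np.asarray(t, dtype=float) + offsets.get("optical", 0.0), v, bin_seconds
        )
        traces[(loc, var)] = HemoTrace(loc, var, tb, vb)

    binned_vitals = None
    if vitals is not None:
        tv = vitals.timestamps + offsets.get("vitals", 0.0)
        tb, sao2 = downsample_10s(tv, vitals.sao2, bin_seconds)
        _, mapv = downsample_10s(tv, vitals.map_mmhg, bin_seconds)
        _, hrv = downsample_10s(tv, vitals.hr_bpm, bin_seconds)
        binned_vitals = VitalsTrace(tb, sao2, mapv, hrv)

    return SubjectSession(
        subject_id=subject_id,
        traces=traces,
        vitals=binned_vitals,
        bloodgas=list(bloodgas or []),
        events=events,
        masks=list(masks or []),
    )
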