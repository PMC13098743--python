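"""Rejection criteria and artifact masking for the optical records.

TRS curves are kept when the DTOF signal-to-noise ratio — peak counts over
the standard deviation of a background stretch preceding the rising edge —
exceeds 10 (strictly). DCS curves are rejected at an averaged detector
count rate below 10 kHz or a fitted coherence factor beta below 0.4; the
two criteria can alternatively be required jointly ("and" mode). Event
marks and accelerometer output are consumed as masked time intervals,
half-open [t_start, t_end), and masking removes samples without ever
altering the survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inversion import DTOFRecord, G2Record

__all__ = [
    "QCResult",
    "ArtifactMask",
    "trs_snr",
    "qc_trs",
    "qc_dcs",
    "normalize_intervals",
    "in_any_interval",
    "apply_masks",
    "SNR_THRESHOLD",
    "COUNT_RATE_THRESHOLD_KHZ",
    "BETA_THRESHOLD",
]

SNR_THRESHOLD = 10.0
COUNT_RATE_THRESHOLD_KHZ = 10.0
BETA_THRESHOLD = 0.4

REASONS = ("ok", "low_snr", "low_count_rate", "low_beta", "artifact_mask", "fit_failure")


@dataclass(frozen=True)
class QCResult:
    record_id: str
    passed: bool
    reason: str
    snr: float = np.nan
    count_rate: float = np.nan
    beta: float = np.nan

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown QC reason {self.reason!r}")
        if self.passed != (self.reason == "ok"):
            raise ValueError("passed must be equivalent to reason == 'ok'")


@dataclass
class ArtifactMask:
    """Masked time intervals [t_start, t_end), seconds on the session clock."""

    intervals: list[tuple[float, float]]
    source: str = "event_mark"  # event_mark | accelerometer | manual

    def __post_init__(self) -> None:
        for a, b in self.intervals:
            if not a < b:
                raise ValueError(f"interval must have t_start < t_end, got ({a}, {b})")
        self.intervals = normalize_intervals(self.intervals)


def normalize_intervals(intervals):
    """Sort and merge overlapping/abutting half-open intervals."""
    if not intervals:
        return []
    out = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((float(a), float(b)))
    return out


def trs_snr(
    dtof: DTOFRecord,
    bg_fraction: float = 0.1,
    min_bg_bins: int = 20,
) -> float:
    """SNR of a DTOF: peak counts over the background standard deviation.

    The background window is taken from the bins preceding the rising-edge
    half-maximum crossing: the first ``bg_fraction`` of the histogram, capped
    at the crossing, at least ``min_bg_bins`` bins. A zero-variance
    background yields +inf with a warning.
    """
    counts = dtof.counts.astype(float)
    peak = int(np.argmax(counts))
    half = 0.5 * counts[peak]
    above = np.nonzero(counts[: peak + 1] >= half)[0]
    crossing = int(above[0]) if above.size else peak
    n_bg = min(max(int(round(bg_fraction * counts.size)), min_bg_bins), crossing)
    if n_bg < min_bg_bins:
        warnings.warn(
            f"background window holds only {n_bg} bins (< {min_bg_bins})",
            stacklevel=2,
        )
        n_bg = max(n_bg, 1)
    bg_std = counts[:n_bg].std()
    if bg_std == 0.0:
        warnings.warn("zero background variance; SNR set to +inf", stacklevel=2)
        return np.inf
    return float(counts.max() / bg_std)


def qc_trs(snr: float, record_id: str = "") -> QCResult:
    """Pass a TRS record iff SNR strictly exceeds the threshold of 10."""
    passed = bool(snr > SNR_THRESHOLD)
    return QCResult(record_id, passed, "ok" if passed else "low_snr", snr=snr)


def qc_dcs(
    rec: G2Record,
    fitted_beta: float,
    mode: str = "or",
    record_id: str = "",
) -> QCResult:
    """Reject a DCS record on low count rate and/or low beta.

    In the default ``or`` mode either failing criterion rejects (each alone
    marks an unusable curve); ``and`` mode requires both to fail, the
    literal conjunction reading. The reason records the first failing
    criterion, count rate checked first.
    """
    low_rate = rec.count_rate < COUNT_RATE_THRESHOLD_KHZ
    low_beta = (not np.isfinite(fitted_beta)) or fitted_beta < BETA_THRESHOLD
    rejected = (low_rate and low_beta) if mode == "and" else (low_rate or low_beta)
    if mode not in ("or", "and"):
        raise ValueError(f"unknown DCS QC mode {mode!r}")
    if not rejected:
        return QCResult(
            record_id, True, "ok", count_rate=rec.count_rate, beta=fitted_beta
        )
    reason = "low_count_rate" if low_rate else "low_beta"
    return QCResult(
        record_id, False, reason, count_rate=rec.count_rate, beta=fitted_beta
    )


def in_any_interval(t: np.ndarray, intervals) -> np.ndarray:
    """Boolean membership of timestamps in half-open [a, b) intervals."""
    t = np.asarray(t, dtype=float)
    hit = np.zeros(t.shape, dtype=bool)
    for a, b in intervals:
        hit |= (t >= a) & (t < b)
    return hit


def apply_masks(timestamps: np.ndarray, values: np.ndarray, masks) -> tuple:
    """Drop samples inside any masked interval; survivors are untouched.

    Returns (timestamps, values, n_removed). An empty survivor set is the
    caller's signal to exclude the subject-variable from statistics.
    """
    intervals = []
    for m in masks:
        intervals.extend(m.intervals)
    hit = in_any_interval(timestamps, normalize_intervals(intervals))
    n_removed = int(hit.sum())
    if n_removed == timestamps.size and timestamps.size > 0:
        warnings.warn("mask removed every sample of the trace", stacklevel=2)
    return np.asarray(timestamps)[~hit], np.asarray(values)[~hit], n_removed
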