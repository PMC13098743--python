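"""Cohort-level pre/post statistical battery.

Per-subject window means (entire pre-transfusion baseline; the 6 minutes
following the transfusion-end mark) feed three nonparametric comparisons:

* relative change vs. zero — one-sample Wilcoxon signed-rank of the
  per-subject (post - pre) means, one-sided in the direction physiology
  predicts for each variable (flow, metabolic rate and oxy/total hemoglobin
  up; extraction fraction and deoxy-hemoglobin down);
* paired pre/post comparison of invasive blood-gas values;
* paired cerebral-vs-peripheral contrast of the post-transfusion means,
  restricted to subjects with both placements.

The signed-rank null is exact for n <= 25 (after zero removal, tie-free
magnitudes), otherwise a normal approximation with continuity correction.
p-values below 0.001 are reported as "<0.001"; no multiple-testing
correction is applied. Summaries are mean(SD) plus median and quartiles by
linear interpolation between order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biomarkers import SubjectSession

__all__ = [
    "ALPHA",
    "EXPECTED_DIRECTIONS",
    "InsufficientDataError",
    "WindowSpec",
    "TestResult",
    "signed_rank_test",
    "window_means",
    "cohort_window_means",
    "relative_change_test",
    "paired_prepost_test",
    "cerebral_vs_peripheral_test",
    "cohort_summary",
    "build_results_tables",
    "bloodgas_table",
    "format_p",
    "round_half_up",
]

ALPHA = 0.05
EXACT_N_MAX = 25
MIN_N = 5
POST_WINDOW_SECONDS = 360.0

#: one-sided alternatives per derived variable (the battery's defaults)
EXPECTED_DIRECTIONS = {
    "rbfi": "greater",
    "rmro2": "greater",
    "dhbo2": "greater",
    "dhbt": "greater",
    "roef": "less",
    "dhhb": "less",
}


class InsufficientDataError(ValueError):
    """Raised when a test lacks the minimum number of usable pairs."""


@dataclass(frozen=True)
class WindowSpec:
    """Pre window [session start, transfusion start); post window of 6 min
    from the transfusion-end mark. Bins belong by their start times."""

    session_start: float = 0.0
    post_length: float = POST_WINDOW_SECONDS

    def pre(self, session: SubjectSession) -> tuple[float, float]:
        return (self.session_start, session.transfusion_start)

    def post(self, session: SubjectSession) -> tuple[float, float]:
        return (session.transfusion_end, session.transfusion_end + self.post_length)


@dataclass
class TestResult:
    variable: str
    comparison: str  # post_vs_baseline | paired_prepost | cerebral_vs_peripheral
    alternative: str  # greater | less | two-sided
    n: int
    statistic: float
    p_value: float
    direction_arrow: str  # up | down | none
    significant: bool
    median_change: float = np.nan
    note: str = ""

    @property
    def p_text(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    """Printed p-value convention: everything below 0.001 as '<0.001'."""
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.2g}"


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the printed-table convention."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def _exact_signed_rank_p(d: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact signed-rank p by the shift algorithm (handles tied magnitudes).

    Builds the null distribution of the positive-rank sum W+ over all 2^n
    equiprobable sign assignments of the observed midranks (doubled to stay
    integral) by iterated convolution. Returns (W+, p).
    """
    ranks2 = np.rint(2.0 * sps.rankdata(np.abs(d))).astype(np.int64)
    w_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** d.size
    upper = float(counts[w_obs:].sum())
    lower = float(counts[: w_obs + 1].sum())
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    else:
        p = min(1.0, 2.0 * min(upper, lower))
    return w_obs / 2.0, p


def signed_rank_test(
    diffs: np.ndarray,
    alternative: str = "two-sided",
    exact_n_max: int = EXACT_N_MAX,
) -> tuple[float, float, int, str]:
    """Wilcoxon signed-rank of paired differences against zero.

    Zeros are removed before ranking; the null is exact (shift-algorithm
    enumeration of all sign assignments, tied magnitudes allowed) when the
    surviving n is at most ``exact_n_max``, otherwise normal-approximate
    with continuity correction. All-zero input returns p = 1 flagged;
    empty input is refused. Returns (statistic W+, p, n_used, note).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise InsufficientDataError("no finite paired differences")
    nz = d[d != 0.0]
    if nz.size == 0:
        return 0.0, 1.0, 0, "all_zero_differences"
    if nz.size < MIN_N:
        raise InsufficientDataError(
            f"only {nz.size} nonzero paired differences (< {MIN_N})"
        )
    if nz.size <= exact_n_max:
        stat, p = _exact_signed_rank_p(nz, alternative)
        return stat, p, int(nz.size), "exact"
    res = sps.wilcoxon(nz, alternative=alternative, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue), int(nz.size), "normal_approx_cc"


def _arrow(median_change: float, significant: bool) -> str:
    if not significant or median_change == 0.0:
        return "none"
    return "up" if median_change > 0 else "down"


def window_means(
    session: SubjectSession, spec: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """Per-variable/location pre and post window means for one subject.

    Means are taken over the surviving 10-s bins; a variable whose pre or
    post window is empty is omitted (and thereby excluded from its tests).
    """
    rows = []
    pre_a, pre_b = spec.pre(session)
    post_a, post_b = spec.post(session)
    for (loc, var), trace in session.traces.items():
        t, v = trace.timestamps, trace.values
        pre_sel = (t >= pre_a) & (t < pre_b)
        post_sel = (t >= post_a) & (t < post_b)
        if not pre_sel.any() or not post_sel.any():
            continue
        rows.append(
            {
                "subject": session.subject_id,
                "location": loc,
                "variable": var,
                "pre_mean": float(v[pre_sel].mean()),
                "post_mean": float(v[post_sel].mean()),
                "n_pre_bins": int(pre_sel.sum()),
                "n_post_bins": int(post_sel.sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "location",
            "variable",
            "pre_mean",
            "post_mean",
            "n_pre_bins",
            "n_post_bins",
        ],
    )


def cohort_window_means(
    sessions: list, spec: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """Stacked window means over a cohort of processed sessions."""
    frames = [window_means(s, spec) for s in sessions]
    if not frames:
        return window_means(
            SubjectSession("", {}, None, [], {"transfusion_start": 0.0, "transfusion_end": 1.0})
        )
    return pd.concat(frames, ignore_index=True)


def relative_change_test(
    post_means: np.ndarray,
    pre_means: np.ndarray,
    alternative: str,
    variable: str = "",
    alpha: float = ALPHA,
) -> TestResult:
    """Test whether the baseline-referenced post distribution moved from 0.

    The per-subject pre-window mean is subtracted from the post-window mean
    and the resulting relative means are tested against zero by a one-sample
    signed-rank test, one-sided in the expected direction.
    """
    d = np.asarray(post_means, dtype=float) - np.asarray(pre_means, dtype=float)
    stat, p, n, note = signed_rank_test(d, alternative)
    sig = bool(p < alpha)
    med = float(np.median(d))
    return TestResult(
        variable, "post_vs_baseline", alternative, n, stat, p, _arrow(med, sig), sig, med, note
    )


def paired_prepost_test(
    pre: np.ndarray,
    post: np.ndarray,
    alternative: str = "two-sided",
    variable: str = "",
    alpha: float = ALPHA,
) -> TestResult:
    """Paired signed-rank comparison of pre vs post values (NA pairs drop)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    keep = np.isfinite(pre) & np.isfinite(post)
    d = post[keep] - pre[keep]
    stat, p, n, note = signed_rank_test(d, alternative)
    sig = bool(p < alpha)
    med = float(np.median(d))
    return TestResult(
        variable, "paired_prepost", alternative, n, stat, p, _arrow(med, sig), sig, med, note
    )


def cerebral_vs_peripheral_test(
    post_means_cerebral: np.ndarray,
    post_means_peripheral: np.ndarray,
    variable: str = "",
    alpha: float = ALPHA,
) -> TestResult:
    """Paired contrast of post-transfusion means between placements.

    Subjects lacking either placement must be excluded by the caller
    (vectors are subject-matched). An 'up' arrow means the peripheral
    values ran significantly higher than the cerebral ones.
    """
    d = np.asarray(post_means_peripheral, dtype=float) - np.asarray(
        post_means_cerebral, dtype=float
    )
    stat, p, n, note = signed_rank_test(d, "two-sided")
    sig = bool(p < alpha)
    med = float(np.median(d))
    return TestResult(
        variable,
        "cerebral_vs_peripheral",
        "two-sided",
        n,
        stat,
        p,
        _arrow(med, sig),
        sig,
        med,
        note,
    )


def cohort_summary(values: np.ndarray) -> dict:
    """mean, sample SD, median and quartiles (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise InsufficientDataError("summary needs at least 2 values")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "median": float(np.median(v)),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
    }


def build_results_tables(
    means: pd.DataFrame,
    directions: dict | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """The optical results table: one row per derived variable.

    ``means`` is the stacked cohort window-means frame. Each row carries the
    baseline-change test per placement and the post-transfusion
    cerebral-vs-peripheral contrast; variables that cannot be tested are
    emitted with a 'not tested' status rather than dropped.
    """
    directions = directions or EXPECTED_DIRECTIONS
    rows = []
    for var in directions:
        row = {"variable": var}
        sub = means[means["variable"] == var]
        for loc in ("cerebral", "peripheral"):
            cell = sub[sub["location"] == loc]
            try:
                res = relative_change_test(
                    cell["post_mean"].to_numpy(),
                    cell["pre_mean"].to_numpy(),
                    directions[var],
                    variable=var,
                    alpha=alpha,
                )
                row[f"{loc}_p"] = res.p_value
                row[f"{loc}_p_text"] = res.p_text
                row[f"{loc}_dir"] = res.direction_arrow
                row[f"{loc}_n"] = res.n
            except InsufficientDataError:
                row[f"{loc}_p"] = np.nan
                row[f"{loc}_p_text"] = "not tested"
                row[f"{loc}_dir"] = "none"
                row[f"{loc}_n"] = int(len(cell))
        both = sub.pivot_table(
            index="subject", columns="location", values="post_mean", aggfunc="first"
        )
        try:
            if not {"cerebral", "peripheral"}.issubset(both.columns):
                raise InsufficientDataError("a placement is entirely missing")
            both = both.dropna(subset=["cerebral", "peripheral"])
            res = cerebral_vs_peripheral_test(
                both["cerebral"].to_numpy(),
                both["peripheral"].to_numpy(),
                variable=var,
                alpha=alpha,
            )
            row["cvp_p"] = res.p_value
            row["cvp_p_text"] = res.p_text
            row["cvp_dir"] = res.direction_arrow
            row["cvp_n"] = res.n
        except InsufficientDataError:
            row["cvp_p"] = np.nan
            row["cvp_p_text"] = "not tested"
            row["cvp_dir"] = "none"
            row["cvp_n"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def bloodgas_table(cohort: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Blood-gas summary: mean(SD) pre/post and the paired test per analyte.

    ``cohort`` holds one row per subject with ``<analyte>_pre``/``_post``
    columns (hgb in g/dL, hct in %, paco2 in mmHg where present).
    """
    rows = []
    for analyte in ("hgb", "hct", "paco2"):
        pre_col, post_col = f"{analyte}_pre", f"{analyte}_post"
        if pre_col not in cohort or post_col not in cohort:
            continue
        sub = cohort.dropna(subset=[pre_col, post_col])
        pre, post = sub[pre_col].to_numpy(), sub[post_col].to_numpy()
        s_pre, s_post = cohort_summary(pre), cohort_summary(post)
        res = paired_prepost_test(pre, post, "two-sided", variable=analyte, alpha=alpha)
        rows.append(
            {
                "variable": analyte,
                "n": res.n,
                "pre_mean": s_pre["mean"],
                "pre_sd": s_pre["sd"],
                "post_mean": s_post["mean"],
                "post_sd": s_post["sd"],
                "p": res.p_value,
                "p_text": res.p_text,
                "dir": res.direction_arrow,
            }
        )
    return pd.DataFrame(rows)
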