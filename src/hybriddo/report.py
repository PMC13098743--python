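"""Plain-text report rendering of the cohort result tables."""

from __future__ import annotations

import pandas as pd

from .stats import round_half_up

__all__ = ["render_report"]

_ARROWS = {"up": "↑", "down": "↓", "none": "—"}

_BG_UNITS = {"hgb": "g/dL", "hct": "%", "paco2": "mmHg"}
_BG_DECIMALS = {"hgb": 1, "hct": 1, "paco2": 1}

_VAR_LABELS = {
    "rbfi": "rBF",
    "roef": "rOEF",
    "rmro2": "rMRO2",
    "dhbo2": "d[HbO2]",
    "dhhb": "d[Hhb]",
    "dhbt": "d[HbT]",
}


def _fmt_mean_sd(mean: float, sd: float, decimals: int) -> str:
    return f"{round_half_up(mean, decimals):g}({round_half_up(sd, decimals + 1):g})"


def render_report(bloodgas: pd.DataFrame, optical: pd.DataFrame) -> str:
    """Markdown report with the blood-gas and optical-variable tables."""
    lines = ["# Transfusion-session cohort report", ""]
    if bloodgas is not None and not bloodgas.empty:
        lines += [
            "## Blood-gas variables (pre vs post transfusion)",
            "",
            "| Variable | Pre | Post | Dir. | p-value |",
            "|---|---|---|---|---|",
        ]
        for _, r in bloodgas.iterrows():
            var = r["variable"]
            dec = _BG_DECIMALS.get(var, 1)
            lines.append(
                f"| {var} ({_BG_UNITS.get(var, '')}) "
                f"| {_fmt_mean_sd(r['pre_mean'], r['pre_sd'], dec)} "
                f"| {_fmt_mean_sd(r['post_mean'], r['post_sd'], dec)} "
                f"| {_ARROWS[r['dir']]} | {r['p_text']} |"
            )
        lines.append("")
    if optical is not None and not optical.empty:
        lines += [
            "## Optically derived variables",
            "",
            "post-transfusion change vs baseline per placement; last column is "
            "the post-transfusion cerebral-vs-peripheral contrast "
            "(an up arrow: peripheral higher).",
            "",
            "| Variable | Cerebral p | Dir. | Peripheral p | Dir. | C vs P p | Dir. |",
            "|---|---|---|---|---|---|---|",
        ]
        for _, r in optical.iterrows():
            lines.append(
                f"| {_VAR_LABELS.get(r['variable'], r['variable'])} "
                f"| {r['cerebral_p_text']} | {_ARROWS[r['cerebral_dir']]} "
                f"| {r['peripheral_p_text']} | {_ARROWS[r['peripheral_dir']]} "
                f"| {r['cvp_p_text']} | {_ARROWS[r['cvp_dir']]} |"
            )
        lines.append("")
    return "\n".join(lines)
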