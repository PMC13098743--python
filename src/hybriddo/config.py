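"""Run configuration: every tunable threshold and constant in one place.

Defaults reproduce the monitored-study conditions (SNR > 10, 10 kHz / 0.4
DCS rejection, 10-s bins, 6-min post window, k = 1.36, MCHC = 340 g/L,
venous fraction 0.75, alpha = 0.05). The full configuration is echoed into
run metadata so results are self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .stats import EXPECTED_DIRECTIONS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # QC thresholds
    snr_threshold: float = 10.0
    count_rate_threshold_khz: float = 10.0
    beta_threshold: float = 0.4
    dcs_qc_mode: str = "or"
    # physiology constants
    k_o2_per_g: float = 1.36
    mchc_g_per_l: float = 340.0
    gamma_venous: float = 0.75
    # fusion and windows
    bin_seconds: float = 10.0
    post_window_seconds: float = 360.0
    # inverse-problem settings
    rise_frac: float = 0.8
    tail_frac: float = 0.01
    fit_shift: bool = True
    g2_cut_frac: float = 0.03
    mua_dcs_mode: str = "mean"  # mean | interpolate
    # statistics
    alpha: float = 0.05
    exact_n_max: int = 25
    directions: dict = field(default_factory=lambda: dict(EXPECTED_DIRECTIONS))
    # misc
    hct_impute_tolerance: float = 0.5
    n_tissue: float = 1.4
    n_outside: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
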