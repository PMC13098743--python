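"""Inverse problems: DTOF fitting for optical properties, two-wavelength
chromophore inversion, and g2 fitting for the blood-flow index.

The TRS inverse problem matches a measured photon time-of-flight histogram
against the semi-infinite diffusion model convolved with the instrument
response function (IRF), with the curve amplitude and a temporal shift
treated as nuisance parameters and Poisson weighting of the residuals.
Fitted absorption at two wavelengths is converted to microvascular oxy- and
deoxy-hemoglobin concentrations through a bundled extinction-coefficient
table, giving StO2. The DCS inverse problem fits the measured intensity
autocorrelation for (BFI, beta) using TRS-derived optical properties, the
device convention of this hybrid approach.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .forward import (
    DCSConfig,
    MediumGeometry,
    OpticalProperties,
    ValidationError,
    dcs_g1,
    siegert_g2,
    td_reflectance,
)

__all__ = [
    "DTOFRecord",
    "IRFRecord",
    "G2Record",
    "ChromophoreState",
    "ExtinctionTable",
    "load_extinction_table",
    "DTOFFitResult",
    "G2FitResult",
    "fit_dtof",
    "fit_g2",
    "chromophores_from_mua",
    "mua_from_chromophores",
    "average_musp",
    "mua_for_dcs",
]

LOCATIONS = ("cerebral", "peripheral")
TRS_WAVELENGTHS = (690.0, 830.0)


@dataclass
class DTOFRecord:
    """One photon time-of-flight histogram at one wavelength and timestamp."""

    timestamp: float  # s from session start
    wavelength: float  # nm, 690 or 830
    bin_width: float  # ps
    counts: np.ndarray
    location: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size < 100:
            raise ValidationError("DTOF must hold at least 100 bins")
        if np.any(self.counts < 0):
            raise ValidationError("DTOF counts must be nonnegative")
        if self.wavelength not in TRS_WAVELENGTHS:
            raise ValidationError(f"unsupported TRS wavelength {self.wavelength}")
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown location {self.location!r}")

    @property
    def time_grid(self) -> np.ndarray:
        """Bin-center arrival times, ps."""
        return (np.arange(self.counts.size) + 0.5) * self.bin_width


@dataclass
class IRFRecord:
    """Instrument response function paired with DTOFs of one wavelength."""

    bin_width: float  # ps
    counts: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValidationError("IRF counts must be nonnegative")


@dataclass
class G2Record:
    """One intensity-autocorrelation curve with its detector count rate."""

    timestamp: float  # s
    tau: np.ndarray  # s
    g2: np.ndarray
    count_rate: float  # kHz, averaged over detector channels
    location: str

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if np.any(np.diff(self.tau) <= 0):
            raise ValidationError("tau grid must be increasing")
        if self.count_rate < 0:
            raise ValidationError("count_rate must be >= 0")
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown location {self.location!r}")


@dataclass(frozen=True)
class ChromophoreState:
    """Microvascular hemoglobin concentrations (mM) and saturation."""

    hbo2: float
    hhb: float
    flagged: bool = False  # negative-concentration solution

    @property
    def hbt(self) -> float:
        return self.hbo2 + self.hhb

    @property
    def sto2(self) -> float:
        return self.hbo2 / self.hbt


class ExtinctionTable:
    """Immutable molar extinction table, 1/(mM*mm), ln(10) convention."""

    def __init__(self, wavelengths, eps_hbo2, eps_hhb, provenance: str = ""):
        self._eps = {
            float(w): (float(o), float(d))
            for w, o, d in zip(wavelengths, eps_hbo2, eps_hhb)
        }
        self.provenance = provenance
        for w, (o, d) in self._eps.items():
            if o <= 0 or d <= 0:
                raise ValidationError(f"non-positive extinction entry at {w} nm")

    def epsilons(self, wavelength: float) -> tuple[float, float]:
        """(eps_hbo2, eps_hhb) at a tabulated wavelength."""
        return self._eps[float(wavelength)]

    def matrix(self, wavelengths=TRS_WAVELENGTHS) -> np.ndarray:
        """Rows (eps_hbo2, eps_hhb) per wavelength; the 2x2 system matrix."""
        return np.array([self.epsilons(w) for w in wavelengths])


def load_extinction_table() -> ExtinctionTable:
    """Load the bundled extinction-coefficient compilation."""
    ref = importlib.resources.files("hybriddo").joinpath(
        "data/extinction_coefficients.csv"
    )
    with ref.open() as fh:
        header = [ln for ln in fh if ln.startswith("#")]
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return ExtinctionTable(
        df["wavelength_nm"],
        df["eps_hbo2_per_mM_mm"],
        df["eps_hhb_per_mM_mm"],
        provenance="".join(h.lstrip("# ").rstrip() + "\n" for h in header),
    )


def mua_from_chromophores(
    hbo2: float, hhb: float, wavelength: float, table: ExtinctionTable
) -> float:
    """Forward map: absorption (1/mm) from concentrations (mM)."""
    eo, ed = table.epsilons(wavelength)
    return np.log(10.0) * (eo * hbo2 + ed * hhb)


def chromophores_from_mua(
    mua_690: float, mua_830: float, table: ExtinctionTable
) -> ChromophoreState:
    """Invert the 2x2 Beer-Lambert system for (HbO2, Hhb).

    Solves mua(lambda) = ln(10) * (eps_hbo2*HbO2 + eps_hhb*Hhb) at 690 and
    830 nm. Negative-concentration solutions are flagged, not clipped.
    """
    if mua_690 <= 0 or mua_830 <= 0:
        raise ValidationError("absorption coefficients must be positive")
    E = np.log(10.0) * table.matrix()
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValidationError("singular extinction matrix")
    hbo2, hhb = np.linalg.solve(E, np.array([mua_690, mua_830]))
    return ChromophoreState(hbo2=hbo2, hhb=hhb, flagged=bool(hbo2 < 0 or hhb < 0))


def average_musp(
    props_690: OpticalProperties | None, props_830: OpticalProperties | None
) -> float:
    """Reduced scattering fed to the DCS model: mean over TRS wavelengths.

    Falls back to the single available wavelength when one fit is missing.
    """
    present = [p.musp for p in (props_690, props_830) if p is not None]
    if not present:
        raise ValidationError("no valid TRS scattering available")
    return float(np.mean(present))


def mua_for_dcs(
    props_690: OpticalProperties | None,
    props_830: OpticalProperties | None,
    mode: str = "mean",
    dcs_wavelength: float = 785.0,
) -> float:
    """Absorption handed to the DCS model at the DCS laser line.

    ``mean`` averages the two TRS absorptions (parallel to the scattering
    convention); ``interpolate`` linearly interpolates in wavelength.
    """
    if props_690 is None or props_830 is None:
        present = [p.mua for p in (props_690, props_830) if p is not None]
        if not present:
            raise ValidationError("no valid TRS absorption available")
        return float(present[0])
    if mode == "mean":
        return 0.5 * (props_690.mua + props_830.mua)
    if mode == "interpolate":
        w = (dcs_wavelength - props_690.wavelength) / (
            props_830.wavelength - props_690.wavelength
        )
        return float((1.0 - w) * props_690.mua + w * props_830.mua)
    raise ValidationError(f"unknown mua_for_dcs mode {mode!r}")


# ---------------------------------------------------------------------------
# DTOF fitting


@dataclass
class DTOFFitResult:
    props: OpticalProperties | None
    amplitude: float
    shift: float  # ps
    converged: bool
    reason: str = "ok"
    chi2_reduced: float = np.nan
    n_points: int = 0
    window: tuple[int, int] = (0, 0)


def _fit_window(counts: np.ndarray, rise_frac: float, tail_frac: float):
    """Window from rise_frac of peak on the rising edge to tail_frac on
    the falling tail (half-open indices)."""
    peak = int(np.argmax(counts))
    cmax = counts[peak]
    above = np.nonzero(counts[: peak + 1] >= rise_frac * cmax)[0]
    lo = int(above[0]) if above.size else 0
    tail = np.nonzero(counts[peak:] >= tail_frac * cmax)[0]
    hi = peak + int(tail[-1]) + 1 if tail.size else counts.size
    return lo, hi


def fit_dtof(
    dtof: DTOFRecord,
    irf: IRFRecord,
    geom: MediumGeometry,
    rise_frac: float = 0.8,
    tail_frac: float = 0.01,
    fit_shift: bool = True,
    subtract_background: bool = True,
    x0: tuple[float, float] | None = None,
    max_nfev: int = 200,
) -> DTOFFitResult:
    """Fit a measured DTOF for (mua, musp) with amplitude/shift nuisances.

    Poisson-weighted least squares of model*IRF against the counts inside
    the [rise_frac-of-peak, tail_frac-of-peak] window. The amplitude is
    profiled out analytically at every iteration; an optional sub-bin
    temporal shift absorbs IRF/DTOF timing offsets; the dark-count floor,
    estimated from the bins preceding the rising edge, is subtracted so it
    does not bias the tail. Non-convergence and unphysical optima are
    flagged, never raised.
    """
    if not np.isclose(dtof.bin_width, irf.bin_width):
        raise ValidationError("DTOF and IRF bin widths differ")

    counts = dtof.counts.astype(float)
    if counts.max() <= 0:
        return DTOFFitResult(None, 0.0, 0.0, False, "empty_curve")
    if subtract_background:
        peak = int(np.argmax(counts))
        above = np.nonzero(counts[: peak + 1] >= 0.5 * counts[peak])[0]
        crossing = int(above[0]) if above.size else 0
        n_bg = min(max(int(round(0.1 * counts.size)), 20), max(crossing - 2, 0))
        bg = counts[:n_bg].mean() if n_bg >= 5 else 0.0
        # a genuine dark floor is flat and far below the peak; anything
        # larger means the window caught the rising edge — leave it alone
        if bg < 0.02 * counts[peak]:
            counts = counts - bg
    lo, hi = _fit_window(counts, rise_frac, tail_frac)
    if hi - lo < 10:
        return DTOFFitResult(None, 0.0, 0.0, False, "window_too_small")

    t = dtof.time_grid
    kernel = irf.counts / irf.counts.sum()
    # restrict the convolution to the kernel's numerical support
    support = np.nonzero(kernel > 1e-12 * kernel.max())[0]
    k0, k1 = int(support[0]), int(support[-1]) + 1
    kernel_trim = kernel[k0:k1]
    n = counts.size
    y = counts[lo:hi]
    sigma = np.sqrt(np.maximum(counts[lo:hi], 1.0))

    def model(mua, musp, shift):
        props = OpticalProperties(dtof.wavelength, mua, musp)
        curve = td_reflectance(props, geom, t)
        conv = np.convolve(curve, kernel_trim)
        meas = np.zeros(n)
        meas[k0:] = conv[: n - k0]
        if shift != 0.0:
            meas = np.interp(t - shift, t, meas, left=0.0, right=0.0)
        return meas[lo:hi]

    def residuals(x):
        mua, musp = np.exp(x[0]), np.exp(x[1])
        shift = x[2] if fit_shift else 0.0
        m = model(mua, musp, shift)
        denom = np.dot(m / sigma, m / sigma)
        if denom <= 0 or not np.isfinite(denom):
            return np.full_like(y, 1e6)
        amp = np.dot(m / sigma, y / sigma) / denom
        return (amp * m - y) / sigma

    mua0, musp0 = x0 if x0 is not None else (0.01, 1.0)
    p0 = [np.log(mua0), np.log(musp0)] + ([0.0] if fit_shift else [0.0])
    try:
        sol = least_squares(
            residuals, p0, method="lm", max_nfev=max_nfev, xtol=1e-8, ftol=1e-8
        )
    except Exception:
        return DTOFFitResult(None, 0.0, 0.0, False, "fit_failure")

    mua, musp = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    shift = float(sol.x[2]) if fit_shift else 0.0
    physical = 1e-4 < mua < 0.2 and 0.05 < musp < 10.0
    if not (sol.success and physical and np.isfinite(sol.cost)):
        return DTOFFitResult(None, 0.0, shift, False, "fit_failure")

    m = model(mua, musp, shift)
    amp = float(np.dot(m / sigma, y / sigma) / np.dot(m / sigma, m / sigma))
    dof = max(y.size - (3 if fit_shift else 2), 1)
    chi2 = float(2.0 * sol.cost / dof)
    return DTOFFitResult(
        OpticalProperties(dtof.wavelength, mua, musp),
        amp,
        shift,
        True,
        "ok",
        chi2,
        y.size,
        (lo, hi),
    )


# ---------------------------------------------------------------------------
# g2 fitting


@dataclass
class G2FitResult:
    bfi: float
    beta: float
    converged: bool
    reason: str = "ok"
    rss: float = np.nan
    n_points: int = 0


def _g2_fit_range(tau: np.ndarray, g2: np.ndarray, cut_frac: float) -> int:
    """Index one past the last lag kept: where plateau-normalized g2-1
    first stays below ``cut_frac``."""
    plateau = float(np.mean(g2[: max(3, g2.size // 20)]) - 1.0)
    if plateau <= 0:
        return g2.size
    norm = (g2 - 1.0) / plateau
    below = np.nonzero(norm < cut_frac)[0]
    return int(below[0]) + 1 if below.size else g2.size


def fit_g2(
    rec: G2Record,
    props_dcs: OpticalProperties,
    geom: MediumGeometry,
    cut_frac: float = 0.03,
    bfi0: float = 1e-8,
    beta0: float | None = None,
    max_nfev: int = 200,
) -> G2FitResult:
    """Fit (BFI, beta) to a measured intensity autocorrelation.

    Joint least squares of the Siegert-mapped Brownian correlation-diffusion
    model over the range from the smallest lag to the lag where the
    plateau-normalized g2-1 falls below ``cut_frac``. beta doubles as the
    amplitude of g2-1. Degenerate flat curves are flagged, never raised.
    """
    plateau = float(np.mean(rec.g2[: max(3, rec.g2.size // 20)]) - 1.0)
    if plateau < 0.05:
        return G2FitResult(np.nan, np.nan, False, "no_correlation")
    hi = _g2_fit_range(rec.tau, rec.g2, cut_frac)
    if hi < 5:
        return G2FitResult(np.nan, np.nan, False, "range_too_small")
    tau, y = rec.tau[:hi], rec.g2[:hi]

    def residuals(x):
        bfi, beta = np.exp(x[0]), np.exp(x[1])
        cfg = DCSConfig(bfi=bfi, beta=min(beta, 1.0))
        g1 = dcs_g1(props_dcs, geom, cfg, tau)
        return siegert_g2(g1, min(beta, 1.0)) - y

    start_beta = min(max(plateau, 0.05), 1.0) if beta0 is None else beta0
    p0 = [np.log(bfi0), np.log(start_beta)]
    try:
        sol = least_squares(
            residuals,
            p0,
            method="trf",
            bounds=([-40.0, -5.0], [0.0, 0.0]),
            max_nfev=max_nfev,
            xtol=1e-12,
            ftol=1e-12,
        )
    except Exception:
        return G2FitResult(np.nan, np.nan, False, "fit_failure")

    bfi, beta = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    if not (sol.success and np.isfinite(sol.cost)):
        return G2FitResult(bfi, beta, False, "fit_failure")
    return G2FitResult(bfi, beta, True, "ok", float(2.0 * sol.cost), y.size)
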