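"""Enzyme-kinetics stage: calibration, initial rates, Michaelis–Menten fits.

The deacetylase assay monitors fluorescence released after proteolytic
cleavage of the deacetylated product peptide.  The analysis chain is

1. fit a linear calibration (known product amounts vs. signal),
2. convert progress-curve signal to product concentration (µM),
3. estimate the initial velocity from a linear regression over the early,
   low-conversion part of each curve,
4. fit v = Vmax·S/(Km + S) across a substrate titration,
5. summarise k_cat = Vmax/[E] and the specificity constant k_cat/K_m.

Canonical internal units are µM and minutes; unit conversions happen only
in :func:`summarize_kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Calibration",
    "CalibrationCurve",
    "ProgressCurve",
    "RateEstimate",
    "MMFit",
    "KineticSummary",
    "fit_calibration",
    "convert_to_product",
    "estimate_initial_rate",
    "fit_michaelis_menten",
    "summarize_kinetics",
]


class DegenerateCalibrationError(ValueError):
    """Calibration slope indistinguishable from zero: signal carries no product information."""


class InsufficientDataError(ValueError):
    """Too few usable points for the requested regression."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Known product amounts (µM) paired with measured fluorescence signal."""

    product: tuple[float, ...]
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.product) != len(self.signal):
            raise ValueError("product and signal must have equal length")
        if len(self.product) < 3:
            raise ValueError("calibration needs at least 3 points")
        if min(self.product) < 0:
            raise ValueError("product amounts must be non-negative")
        if len(set(self.product)) == 1:
            raise ValueError("product amounts must not all be equal")


@dataclass(frozen=True)
class Calibration:
    """Linear signal = slope·product + intercept map with its goodness of fit."""

    slope: float
    intercept: float
    r2: float

    def to_product(self, signal: np.ndarray | float) -> np.ndarray | float:
        """Inverse map: fluorescence signal → product concentration (µM)."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass
class ProgressCurve:
    """One time-resolved assay trace for a single enzyme/substrate condition.

    ``signals`` holds raw fluorescence until :func:`convert_to_product` is
    applied, after which it holds product concentration in µM and
    ``converted`` is True.
    """

    times: np.ndarray  # minutes
    signals: np.ndarray  # fluorescence units, or µM product once converted
    enzyme_conc: float  # µM
    s_pep: float  # µM peptide substrate
    s_nad: float  # µM NAD+ co-substrate
    converted: bool = False
    truth: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Initial velocity from a linear regression over an early-time window."""

    v: float  # µM product / min
    stderr: float
    window: tuple[int, int]  # [start, stop) indices of the points used
    r2: float


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters with asymptotic standard errors."""

    vmax: float  # µM/min
    km: float  # µM
    vmax_se: float
    km_se: float
    converged: bool
    residual_ss: float

    def predict(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.vmax * np.asarray(s, dtype=float) / (self.km + np.asarray(s, dtype=float))


@dataclass(frozen=True)
class KineticSummary:
    """Turnover number and specificity constant in conventional units."""

    kcat_per_min: float
    kcat_per_s: float
    km_pep: float  # µM
    km_nad: float  # µM
    specificity: float  # M^-1 s^-1, k_cat / K_m(peptide)
    converged: bool


def fit_calibration(curve: CalibrationCurve) -> Calibration:
    """Least-squares line through the calibration points.

    Raises :class:`DegenerateCalibrationError` when the fitted slope is
    below 1e-12 of the observed signal range, i.e. when the inverse map
    signal → product would be numerically meaningless.
    """
    x = np.asarray(curve.product, dtype=float)
    y = np.asarray(curve.signal, dtype=float)
    res = stats.linregress(x, y)
    signal_range = float(np.ptp(y))
    if abs(res.slope) <= 1e-12 * max(signal_range, 1.0):
        raise DegenerateCalibrationError(
            f"calibration slope {res.slope!r} is degenerate relative to signal range {signal_range!r}"
        )
    return Calibration(slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2))


def convert_to_product(curve: ProgressCurve, calibration: Calibration) -> ProgressCurve:
    """Convert a raw-fluorescence progress curve to product concentration (µM).

    Subtracting the fitted intercept also removes constant background
    fluorescence (e.g. from the nicotinamide quench).
    """
    if curve.converted:
        raise ValueError("curve is already in product units")
    return ProgressCurve(
        times=curve.times.copy(),
        signals=np.asarray(calibration.to_product(curve.signals), dtype=float),
        enzyme_conc=curve.enzyme_conc,
        s_pep=curve.s_pep,
        s_nad=curve.s_nad,
        converted=True,
        truth=curve.truth,
    )


def estimate_initial_rate(curve: ProgressCurve, max_conversion: float = 0.10) -> RateEstimate:
    """Initial velocity as the slope of a regression over the steady-state window.

    The window is the longest prefix of the curve over which cumulative
    substrate conversion (product / initial peptide) stays at or below
    ``max_conversion``; at least 3 points are required.  This is the
    standard initial-velocity criterion: within the window the substrate
    is effectively undepleted so the time course is linear.
    """
    if not curve.converted:
        raise ValueError("curve must be converted to product units first")
    if not (0 < max_conversion <= 0.5):
        raise ValueError("max_conversion must be in (0, 0.5]")
    conversion = curve.signals / curve.s_pep
    ok = np.flatnonzero(conversion > max_conversion)
    stop = int(ok[0]) if ok.size else len(curve.times)
    if stop < 3:
        raise InsufficientDataError(
            f"only {stop} points below {max_conversion:.0%} conversion; need at least 3"
        )
    res = stats.linregress(curve.times[:stop], curve.signals[:stop])
    return RateEstimate(
        v=float(res.slope),
        stderr=float(res.stderr),
        window=(0, stop),
        r2=float(res.rvalue**2),
    )


def _mm(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(rates: Sequence[tuple[float, float]]) -> MMFit:
    """Nonlinear least squares of v = Vmax·S/(Km + S) on (S, v) pairs.

    Initialisation: Vmax0 = max observed v; Km0 = the substrate
    concentration whose rate is closest to Vmax0/2.  Parameters are
    constrained positive.  Non-convergence is flagged rather than raised.
    """
    pts = sorted((float(s), float(v)) for s, v in rates)
    s = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if len(np.unique(s)) < 4:
        raise InsufficientDataError("need at least 4 distinct substrate concentrations")
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise InsufficientDataError("all rates non-positive; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    try:
        popt, pcov = optimize.curve_fit(
            _mm,
            s,
            v,
            p0=[vmax0, max(km0, 1e-9)],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
            # rates are O(1e-3) µM/min while Km is O(10) µM: loose default
            # tolerances stop early on such scale-mismatched problems
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        converged = bool(np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov))))
    except RuntimeError:
        return MMFit(vmax=np.nan, km=np.nan, vmax_se=np.nan, km_se=np.nan,
                     converged=False, residual_ss=np.nan)
    resid = v - _mm(s, *popt)
    se = np.sqrt(np.diag(pcov))
    return MMFit(
        vmax=float(popt[0]),
        km=float(popt[1]),
        vmax_se=float(se[0]),
        km_se=float(se[1]),
        converged=converged,
        residual_ss=float(resid @ resid),
    )


def summarize_kinetics(fit_pep: MMFit, fit_nad: MMFit, enzyme_conc: float) -> KineticSummary:
    """Derive k_cat and the specificity constant from the two titration fits.

    k_cat is defined as Vmax (from the peptide titration) divided by total
    enzyme concentration.  The specificity constant k_cat/K_m uses the
    peptide K_m converted to molar: specificity = kcat_per_s / (km_pep·1e-6).
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    converged = fit_pep.converged and fit_nad.converged
    kcat_per_min = fit_pep.vmax / enzyme_conc
    kcat_per_s = kcat_per_min / 60.0
    specificity = kcat_per_s / (fit_pep.km * 1e-6) if fit_pep.km > 0 else np.nan
    return KineticSummary(
        kcat_per_min=float(kcat_per_min),
        kcat_per_s=float(kcat_per_s),
        km_pep=float(fit_pep.km),
        km_nad=float(fit_nad.km),
        specificity=float(specificity),
        converged=converged,
    )
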