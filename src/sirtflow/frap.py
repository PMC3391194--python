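"""Fluorescence recovery after photobleaching: normalisation, fitting, comparison.

A bleached nuclear region refills with unbleached fluorophore as the tagged
protein exchanges; a single-exponential recovery

    F(t) = F0 + (Finf - F0) * (1 - exp(-t / tau))

summarises mobility by the half-time t1/2 = tau*ln(2) and the immobile
fraction (1 - Finf) / (1 - F0) on a trace normalised to pre-bleach = 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from statsmodels.stats.multitest import multipletests

__all__ = ["FrapTrace", "FrapFit", "normalize_trace", "fit_recovery", "compare_halftimes"]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class FrapTrace:
    """Intensity time series: ``n_pre`` pre-bleach frames, ``n_bleach``
    bleach frames, then the recovery segment, at uniform frame spacing."""

    times_s: np.ndarray
    intensities: np.ndarray
    n_pre: int
    n_bleach: int
    truth: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.n_recovery < 5:
            raise ValueError("recovery segment must have at least 5 frames")

    @property
    def n_recovery(self) -> int:
        return len(self.times_s) - self.n_pre - self.n_bleach

    @property
    def recovery_times(self) -> np.ndarray:
        """Times of post-bleach frames, measured from the first one."""
        t = self.times_s[self.n_pre + self.n_bleach:]
        return t - t[0]

    @property
    def recovery_intensities(self) -> np.ndarray:
        return self.intensities[self.n_pre + self.n_bleach:]


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential recovery parameters on the normalised scale."""

    f0: float
    finf: float
    tau_s: float
    t_half_s: float
    immobile_fraction: float
    residual_ss: float
    converged: bool
    clipped: bool = False  # immobile fraction fell outside [0, 1] and was clipped


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Divide all intensities by the pre-bleach mean (idempotent)."""
    pre = float(np.mean(trace.intensities[: trace.n_pre]))
    if pre <= 0:
        raise ValueError("pre-bleach mean must be positive")
    return FrapTrace(
        times_s=trace.times_s.copy(),
        intensities=trace.intensities / pre,
        n_pre=trace.n_pre,
        n_bleach=trace.n_bleach,
        truth=trace.truth,
    )


def _recovery(t: np.ndarray, f0: float, finf: float, tau: float) -> np.ndarray:
    return f0 + (finf - f0) * (1.0 - np.exp(-t / tau))


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Least-squares single-exponential fit over the post-bleach frames.

    Bleach frames are excluded; time zero is the first post-bleach frame.
    Initialisation: f0 = first post-bleach value, finf = mean of the last 3
    frames, tau = time at which the trace first crosses halfway between
    them.  A fit with finf < f0 (no recovery) or failed optimisation is
    returned flagged rather than raised.
    """
    t = trace.recovery_times
    y = trace.recovery_intensities
    f0_0 = float(y[0])
    finf_0 = float(np.mean(y[-3:]))
    halfway = 0.5 * (f0_0 + finf_0)
    above = np.flatnonzero(y >= halfway) if finf_0 >= f0_0 else np.flatnonzero(y <= halfway)
    tau_0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 4.0
    tau_0 = max(tau_0, float(t[1]))
    try:
        popt, _ = optimize.curve_fit(
            _recovery, t, y,
            p0=[f0_0, finf_0, tau_0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt = np.array([f0_0, finf_0, tau_0])
        converged = False
    f0, finf, tau = (float(v) for v in popt)
    resid = y - _recovery(t, f0, finf, tau)
    if finf < f0:
        converged = False  # no net recovery; exponential parameters unreliable
    immobile_raw = (1.0 - finf) / (1.0 - f0) if f0 < 1.0 else np.nan
    clipped = bool(np.isfinite(immobile_raw) and not (0.0 <= immobile_raw <= 1.0))
    if clipped:
        logger.info("immobile fraction %.4f clipped into [0, 1]", immobile_raw)
    immobile = float(np.clip(immobile_raw, 0.0, 1.0)) if np.isfinite(immobile_raw) else np.nan
    return FrapFit(
        f0=f0, finf=finf, tau_s=tau, t_half_s=tau * LN2,
        immobile_fraction=immobile, residual_ss=float(resid @ resid),
        converged=converged, clipped=clipped,
    )


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample test with an exact-equality shortcut for the
    zero-variance degenerate case."""
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_halftimes(groups: Mapping[str, Sequence[float]]):
    """Pairwise Welch tests on half-times with BH correction across pairs.

    Returns a list of dicts (group_a, group_b, statistic, p, q).
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    rows = []
    for a, b in itertools.combinations(names, 2):
        stat, p = _welch(np.asarray(groups[a], dtype=float), np.asarray(groups[b], dtype=float))
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p": p})
    if rows:
        q = multipletests([r["p"] for r in rows], method="fdr_bh")[1]
        for r, qv in zip(rows, q):
            r["q"] = float(qv)
    return rows
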