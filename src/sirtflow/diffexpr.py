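"""Per-probe differential expression on log2 matrices, FDR, profile overlap.

The input is an already-normalised log2 intensity matrix whose columns are
named ``<condition>_<replicate>`` with condition letters a–h (eight
treatment arms, triplicate).  Each contrast is a per-probe two-group linear
model (equivalently a pooled-variance t test) on the log2 values; p-values
are corrected by Benjamini–Hochberg across all probes of the contrast, and
probes are called up/down by a signed linear fold-change threshold combined
with the FDR cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sirtflow.simulate import CONDITIONS

__all__ = [
    "Contrast",
    "ProfileOverlap",
    "validate_matrix",
    "condition_of",
    "fit_contrast",
    "adjust_bh",
    "call_de",
    "overlap_profiles",
    "profile_similarity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    """A test-vs-reference condition pair, e.g. h (vector + stimulus) vs g (vector)."""

    test: str
    ref: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.test == self.ref:
            raise ValueError("test and reference conditions must differ")
        for c in (self.test, self.ref):
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition label {c!r}")


@dataclass(frozen=True)
class ProfileOverlap:
    """Direction-consistent intersection of two differential call sets."""

    up: frozenset[str]
    down: frozenset[str]

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def condition_of(column: str) -> str:
    """Condition letter of a sample column named '<condition>_<replicate>'."""
    cond, _, rep = column.rpartition("_")
    if cond not in CONDITIONS or not rep.isdigit():
        raise ValueError(f"malformed sample column {column!r}")
    return cond


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Sanity checks: no missing values, valid labels, plausibly log2 scale."""
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    for col in matrix.columns:
        condition_of(col)
    if matrix.to_numpy().max() >= 30:
        raise ValueError("values >= 30 suggest the matrix is not log2 scale")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2**lfc for lfc >= 0, else -2**(-lfc).

    This display convention makes the up/down thresholds symmetric at
    +1.5 / -1.5 on the linear scale.
    """
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(lfc >= 0, 2.0 ** lfc, -(2.0 ** (-lfc)))


def fit_contrast(matrix: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-probe pooled-variance two-group comparison on log2 values.

    Returns a DataFrame indexed by probe with columns log2fc, fold_change,
    p, q and call.  Probes with zero residual variance get p = 1 when the
    group means are equal and the smallest positive float otherwise (and
    are logged); everything else is an ordinary two-sided t test with
    n1 + n2 - 2 degrees of freedom.
    """
    validate_matrix(matrix)
    cols_t = [c for c in matrix.columns if condition_of(c) == contrast.test]
    cols_r = [c for c in matrix.columns if condition_of(c) == contrast.ref]
    if len(cols_t) < 2 or len(cols_r) < 2:
        raise ValueError("both conditions need at least 2 replicates")
    xt = matrix[cols_t].to_numpy(dtype=float)
    xr = matrix[cols_r].to_numpy(dtype=float)
    n1, n2 = xt.shape[1], xr.shape[1]
    mt, mr = xt.mean(axis=1), xr.mean(axis=1)
    log2fc = mt - mr
    ss = ((xt - mt[:, None]) ** 2).sum(axis=1) + ((xr - mr[:, None]) ** 2).sum(axis=1)
    dof = n1 + n2 - 2
    pooled_var = ss / dof
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = np.empty(len(matrix))
    degenerate = se == 0.0
    if degenerate.any():
        logger.info("%d probes with zero residual variance", int(degenerate.sum()))
        p[degenerate] = np.where(log2fc[degenerate] == 0.0, 1.0, np.finfo(float).tiny)
    ok = ~degenerate
    tstat = np.zeros(len(matrix))
    tstat[ok] = log2fc[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": signed_fold_change(log2fc),
            "t": tstat,
            "p": p,
            "q": adjust_bh(p),
        },
        index=matrix.index,
    )
    return call_de(out)


def call_de(detable: pd.DataFrame, fc_threshold: float = 1.5,
            q_threshold: float = 0.05, use_q: bool = True) -> pd.DataFrame:
    """Assign up/down/ns calls by strict fold-change and FDR thresholds.

    A probe is up when fold_change > fc_threshold (strictly) and its
    adjusted q <= q_threshold; down symmetrically for fold_change below
    -fc_threshold.  Set ``use_q=False`` to threshold raw p-values instead.
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sig = detable["q"] if use_q else detable["p"]
    up = (detable["fold_change"] > fc_threshold) & (sig <= q_threshold)
    down = (detable["fold_change"] < -fc_threshold) & (sig <= q_threshold)
    out = detable.copy()
    out["call"] = np.select([up, down], ["up", "down"], default="ns")
    return out


def de_counts(detable: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) counts of called probes."""
    calls = detable["call"]
    return int((calls == "up").sum()), int((calls == "down").sum())


def overlap_profiles(a: pd.DataFrame, b: pd.DataFrame) -> ProfileOverlap:
    """Direction-consistent overlap of two call tables on the same universe."""
    if set(a.index) != set(b.index):
        raise ValueError("call tables cover different probe universes")
    up_a = set(a.index[a["call"] == "up"])
    up_b = set(b.index[b["call"] == "up"])
    dn_a = set(a.index[a["call"] == "down"])
    dn_b = set(b.index[b["call"] == "down"])
    return ProfileOverlap(up=frozenset(up_a & up_b), down=frozenset(dn_a & dn_b))


def profile_similarity(a: set[str] | frozenset[str], b: set[str] | frozenset[str],
                       method: str = "containment") -> float:
    """Fraction of profile ``a`` shared with profile ``b``.

    ``containment`` (default) is |a ∩ b| / |a|; ``jaccard`` is
    |a ∩ b| / |a ∪ b|.
    """
    if not a:
        raise ValueError("profile a must be non-empty")
    inter = len(set(a) & set(b))
    if method == "containment":
        return inter / len(a)
    if method == "jaccard":
        return inter / len(set(a) | set(b))
    raise ValueError(f"unknown similarity method {method!r}")
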