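"""Gene-set statistics: TF over-connectivity and PAGE pathway scoring.

Over-connectivity asks whether a query gene set (e.g. a stimulus-response
profile of n genes) overlaps a transcription factor's regulon (R targets in
a database of N genes) more than chance.  With k = |query ∩ regulon|,

    expected = n·R/N
    ratio    = k / expected
    z        = (k − expected) / sqrt(n·(R/N)·(1−R/N)·(N−n)/(N−1))
    p        = P(X ≥ k)  for X ~ Hypergeometric(N, R, n) when z ≥ 0,
               P(X ≤ k)  otherwise.

PAGE scores a gene set against a genome-wide fold-change vector by the
standardised deviation of the set mean from the background mean:
z = (mean(member) − µ)·sqrt(m)/σ with a two-sided normal p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sirtflow.diffexpr import adjust_bh
from sirtflow.simulate import RegulonDB

__all__ = [
    "ConnectivityRow",
    "PageRow",
    "tf_connectivity",
    "connectivity_table",
    "page_score",
    "page_table",
]


@dataclass(frozen=True)
class ConnectivityRow:
    """One regulator's over-connectivity statistics against a query set."""

    tf: str
    actual: int  # k, overlap with the query
    r: int  # regulon size in the database
    expected: float  # n*R/N
    ratio: float  # actual / expected
    p: float  # hypergeometric tail probability
    z: float  # (actual - expected) / sqrt(hypergeometric variance)
    z_defined: bool = True


@dataclass(frozen=True)
class PageRow:
    """One pathway's PAGE score."""

    pathway: str
    m: int  # member genes with a fold-change value
    z: float
    p: float
    n_significant_members: int = 0


def _connectivity_stats(k: int, r: int, n: int, big_n: int) -> ConnectivityRow | None:
    expected = n * r / big_n
    p_gene = r / big_n
    var = n * p_gene * (1.0 - p_gene) * (big_n - n) / (big_n - 1)
    if var <= 0:
        return ConnectivityRow(tf="", actual=k, r=r, expected=expected,
                               ratio=k / expected if expected else math.nan,
                               p=math.nan, z=math.nan, z_defined=False)
    z = (k - expected) / math.sqrt(var)
    # scipy convention: hypergeom(M=population, n=successes, N=draws)
    if z >= 0:
        p = float(stats.hypergeom.sf(k - 1, big_n, r, n))  # P(X >= k)
    else:
        p = float(stats.hypergeom.cdf(k, big_n, r, n))  # P(X <= k)
    return ConnectivityRow(tf="", actual=k, r=r, expected=expected,
                           ratio=k / expected, p=p, z=z, z_defined=True)


def tf_connectivity(query: Iterable[str], db: RegulonDB) -> list[ConnectivityRow]:
    """Over-connectivity statistics for every regulon against one query.

    The query must be drawn from the database universe of ``db.universe_n``
    genes; rows are returned sorted by ascending p.  Regulons for which the
    hypergeometric variance vanishes (R = N or query = universe) come back
    flagged ``z_defined=False``.
    """
    q = frozenset(query)
    n = len(q)
    big_n = db.universe_n
    if not (1 <= n < big_n + 1):
        raise ValueError("query must be non-empty and no larger than the universe")
    rows: list[ConnectivityRow] = []
    for tf, regulon in db.regulons.items():
        if len(regulon) > big_n:
            raise ValueError(f"regulon {tf!r} larger than the universe")
        k = len(q & regulon)
        base = _connectivity_stats(k, len(regulon), n, big_n)
        rows.append(ConnectivityRow(tf=tf, actual=base.actual, r=base.r,
                                    expected=base.expected, ratio=base.ratio,
                                    p=base.p, z=base.z, z_defined=base.z_defined))
    rows.sort(key=lambda row: (math.inf if math.isnan(row.p) else row.p))
    return rows


def connectivity_table(rows: Sequence[ConnectivityRow]) -> pd.DataFrame:
    """Tabular view with BH correction across regulators."""
    df = pd.DataFrame(
        {
            "tf": [r.tf for r in rows],
            "actual": [r.actual for r in rows],
            "r": [r.r for r in rows],
            "expected": [r.expected for r in rows],
            "ratio": [r.ratio for r in rows],
            "p": [r.p for r in rows],
            "z": [r.z for r in rows],
        }
    )
    defined = ~df["p"].isna()
    df["q"] = np.nan
    if defined.any():
        df.loc[defined, "q"] = adjust_bh(df.loc[defined, "p"].to_numpy())
    return df


def page_score(member_values: Sequence[float], all_values: Sequence[float],
               pathway: str = "") -> PageRow:
    """PAGE z-score of one gene set against the genome-wide distribution.

    ``all_values`` supplies the background mean µ and (population) standard
    deviation σ; z = (mean(member) − µ)·sqrt(m)/σ and p is two-sided
    normal.  σ = 0 is an error (no spread to standardise against).
    """
    member = np.asarray(member_values, dtype=float)
    allv = np.asarray(all_values, dtype=float)
    if member.size < 1:
        raise ValueError("member set must be non-empty")
    if allv.size < member.size:
        raise ValueError("background must be at least as large as the member set")
    mu = float(allv.mean())
    sigma = float(allv.std())
    if sigma == 0.0:
        raise ValueError("background standard deviation is zero")
    z = (float(member.mean()) - mu) * math.sqrt(member.size) / sigma
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return PageRow(pathway=pathway, m=int(member.size), z=z, p=p)


def page_table(fold_changes: Mapping[str, float] | pd.Series,
               pathways: Mapping[str, Iterable[str]],
               significant: Iterable[str] = ()) -> pd.DataFrame:
    """PAGE scores for a pathway collection with BH correction across pathways.

    ``fold_changes`` maps gene → fold change genome-wide; pathway members
    without a value are ignored (the chip did not measure them).
    ``significant`` optionally names the significant query genes so the
    bookkeeping column n_significant_members can be reported.
    """
    fc = pd.Series(fold_changes, dtype=float)
    sig = frozenset(significant)
    rows = []
    for name, members in pathways.items():
        members = frozenset(members)
        on_chip = [g for g in members if g in fc.index]
        if not on_chip:
            continue
        row = page_score(fc.loc[on_chip].to_numpy(), fc.to_numpy(), pathway=name)
        rows.append(
            {
                "pathway": name,
                "m": row.m,
                "z": row.z,
                "p": row.p,
                "n_significant_members": len(members & sig),
            }
        )
    df = pd.DataFrame(rows, columns=["pathway", "m", "z", "p", "n_significant_members"])
    if len(df):
        df["q"] = adjust_bh(df["p"].to_numpy())
        df = df.sort_values("p", ignore_index=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
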