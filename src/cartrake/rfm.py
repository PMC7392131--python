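"""Recency-frequency-monetary loyalty scoring from transaction history.

Each participant gets quintile bins (1-5) on three dimensions — days since
last purchase (more recent is better), count of distinct purchase events,
and total spend — combined into a composite score ``100*R + 10*F + M``
bounded in [111, 555].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["rfm_scores", "quintile_bins", "compare_scores_by_group"]


def quintile_bins(values: np.ndarray | pd.Series, ascending: bool = True) -> np.ndarray:
    """Quintile bin 1..5 by average rank, floor-mapped to bins.

    ``ascending=True`` gives higher bins to higher values.  A constant
    vector (including n=1) maps everyone to the middle bin 3.  With all
    values distinct and n divisible by 5, bins are exactly balanced.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return np.array([], dtype=int)
    if np.all(arr == arr[0]):
        return np.full(arr.size, 3, dtype=int)
    ranks = stats.rankdata(arr if ascending else -arr, method="average")
    bins = np.ceil(5.0 * ranks / arr.size).astype(int)
    return np.clip(bins, 1, 5)


def rfm_scores(
    transactions: pd.DataFrame,
    reference_date: str | pd.Timestamp,
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Per-participant RFM table.

    Recency is days from the last purchase to ``reference_date`` (which
    must not precede any transaction); frequency counts distinct
    (participant, timestamp) events; monetary is the EUR total.
    Participants appear only if they have at least one transaction.
    """
    if transactions.empty:
        raise ValidationError("no transactions to score")
    ref = pd.Timestamp(reference_date)
    ts = pd.to_datetime(transactions["timestamp"])
    if ts.max() > ref:
        raise ValidationError("reference_date precedes some transactions")
    grouped = transactions.assign(timestamp=ts).groupby(id_col, observed=True)
    out = pd.DataFrame(
        {
            "recency": (ref - grouped["timestamp"].max()).dt.days.astype(float),
            "frequency": grouped["timestamp"].nunique().astype(float),
            "monetary": grouped["eur"].sum(),
        }
    )
    out["r_bin"] = quintile_bins(out["recency"], ascending=False)  # recent = low days = high bin
    out["f_bin"] = quintile_bins(out["frequency"])
    out["m_bin"] = quintile_bins(out["monetary"])
    out["score"] = 100 * out["r_bin"] + 10 * out["f_bin"] + out["m_bin"]
    out.index.name = id_col
    return out.reset_index()


def compare_scores_by_group(
    scores: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> dict:
    """Median [IQR] per group plus one-way ANOVA F and Kruskal-Wallis H.

    Groups with no observations are dropped; at least two non-empty
    groups are required.
    """
    s = pd.Series(np.asarray(scores, dtype=float), name="score")
    g = pd.Series(np.asarray(groups, dtype=object), name="group", index=s.index)
    keep = s.notna() & g.notna()
    s, g = s[keep], g[keep]
    samples = [grp.to_numpy() for _, grp in s.groupby(g, observed=True)]
    if len(samples) < 2:
        raise ValidationError("need at least two non-empty groups")
    summary = (
        s.groupby(g, observed=True)
        .agg(n="size", median="median", q1=lambda x: x.quantile(0.25), q3=lambda x: x.quantile(0.75))
        .reset_index()
    )
    if all(np.all(x == samples[0][0]) for x in samples):
        f_stat, f_p = 0.0, 1.0
        h_stat, h_p = 0.0, 1.0
    else:
        f_stat, f_p = stats.f_oneway(*samples)
        h_stat, h_p = stats.kruskal(*samples)
    return {
        "summary": summary,
        "anova_f": float(f_stat),
        "anova_p": float(f_p),
        "kruskal_h": float(h_stat),
        "kruskal_p": float(h_p),
        "df": len(samples) - 1,
    }
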