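"""Food-group mapping and per-participant purchase summarization.

Product-group codes are collapsed into seven indicator food groups (plus
``unassigned``); per participant we accumulate EUR and kg totals over the
observation period together with each group's share of all grocery
purchases.  Summaries report median [IQR], unweighted and weighted with
poststratification weights, and the relative change between the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "FOOD_GROUPS",
    "UNASSIGNED",
    "CoverageReport",
    "read_mapping",
    "write_mapping",
    "map_products",
    "participant_food_summary",
    "weighted_quantile",
    "relative_change",
    "summarize_food_groups",
]

FOOD_GROUPS = [
    "vegetables",
    "skimmed milk & sour milk",
    "sugar-sweetened beverages",
    "rye bread",
    "red meat & processed meat",
    "fat spreads",
    "sweets & chocolate",
]
UNASSIGNED = "unassigned"

_MEASURES = ["eur", "eur_share", "kg", "kg_share"]


@dataclass(frozen=True)
class CoverageReport:
    """How much of the product-group taxonomy maps to a study food group."""

    n_codes: int
    n_assigned: int

    @property
    def pct_assigned(self) -> float:
        if self.n_codes == 0:
            return 0.0
        return round(100.0 * self.n_assigned / self.n_codes, 1)


def read_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = ["product_group_code", "food_group"]
    if list(df.columns) != required:
        raise FormatError(f"{path}: mapping columns must be {required}")
    if df["product_group_code"].duplicated().any():
        raise FormatError(f"{path}: duplicated product_group_code")
    return df


def write_mapping(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping.to_csv(path, index=False)


def map_products(
    transactions: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, CoverageReport]:
    """Attach a ``food_group`` column; codes not mapped become unassigned.

    Coverage is reported over the mapping's code list: the count and
    percentage (one decimal) of codes assigned to a study food group.
    """
    lookup = mapping.set_index("product_group_code")["food_group"]
    assigned = lookup.notna() & (lookup != UNASSIGNED)
    out = transactions.copy()
    out["food_group"] = (
        out["product_group_code"].map(lookup).fillna(UNASSIGNED).replace("", UNASSIGNED)
    )
    return out, CoverageReport(n_codes=len(lookup), n_assigned=int(assigned.sum()))


def participant_food_summary(
    transactions: pd.DataFrame,
    food_groups: Sequence[str] = tuple(FOOD_GROUPS),
    participants: Sequence | None = None,
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Long-format per-participant, per-food-group purchase totals.

    One row per (participant, food group) with EUR/kg totals, the group's
    percentage share of that participant's all-grocery EUR/kg (unassigned
    purchases included in the denominator), and the all-grocery totals.
    Participants with zero grocery total keep their rows but get missing
    shares.  ``participants`` optionally forces the id set (to include
    consenters who never purchased anything).
    """
    for col in (id_col, "food_group", "eur", "kg"):
        if col not in transactions.columns:
            raise ValidationError(f"transactions missing column {col!r}")
    if ((transactions["eur"] < 0) | (transactions["kg"] < 0)).any():
        raise ValidationError("negative eur or kg in transactions")
    if participants is None:
        ids = pd.Index(transactions[id_col].unique(), name=id_col)
    else:
        ids = pd.Index(participants, name=id_col)
    totals = (
        transactions.groupby(id_col, observed=True)[["eur", "kg"]]
        .sum()
        .reindex(ids, fill_value=0.0)
        .rename(columns={"eur": "total_eur", "kg": "total_kg"})
    )
    by_group = (
        transactions[transactions["food_group"].isin(food_groups)]
        .groupby([id_col, "food_group"], observed=True)[["eur", "kg"]]
        .sum()
    )
    full_index = pd.MultiIndex.from_product([ids, list(food_groups)], names=[id_col, "food_group"])
    by_group = by_group.reindex(full_index, fill_value=0.0).reset_index()
    out = by_group.merge(totals, left_on=id_col, right_index=True)
    out["eur_share"] = np.where(
        out["total_eur"] > 0, 100.0 * out["eur"] / out["total_eur"], np.nan
    )
    out["kg_share"] = np.where(out["total_kg"] > 0, 100.0 * out["kg"] / out["total_kg"], np.nan)
    return out


def weighted_quantile(
    values: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    q: float,
) -> float:
    """Left-continuous weighted quantile.

    Returns the smallest value whose cumulative normalized weight reaches
    ``q``.  With equal weights this reduces to the plain inverted-CDF
    quantile; it is invariant to rescaling all weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("empty input")
    if v.shape != w.shape:
        raise ValidationError("values and weights must align")
    if (w < 0).any() or not (w > 0).any():
        raise ValidationError("weights must be non-negative with a positive sum")
    if not 0.0 <= q <= 1.0:
        raise ValidationError("q must lie in [0, 1]")
    keep = ~np.isnan(v)
    v, w = v[keep], w[keep]
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(v[min(idx, v.size - 1)])


def relative_change(unweighted: float, weighted: float) -> float:
    """Weighted-vs-unweighted median change, percent to one decimal."""
    if unweighted == 0:
        return float("nan")
    return round(100.0 * (weighted / unweighted - 1.0), 1)


def _quantiles(values: pd.Series, weights: pd.Series | None) -> tuple[float, float, float]:
    v = values.dropna()
    if v.empty:
        return (np.nan, np.nan, np.nan)
    if weights is None:
        return tuple(float(v.quantile(p)) for p in (0.5, 0.25, 0.75))
    w = weights.loc[v.index]
    return tuple(weighted_quantile(v, w, p) for p in (0.5, 0.25, 0.75))


def summarize_food_groups(
    summaries: pd.DataFrame,
    weights: pd.Series | None = None,
    by: pd.Series | None = None,
    mode: str = "all",
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Median [IQR] of EUR, kg and their shares per food group.

    ``weights`` (indexed by participant id) adds weighted counterparts and
    the relative percent change of the weighted over the unweighted
    median.  ``by`` (participant id -> stratum) stratifies the summary.
    ``mode='purchasers'`` restricts each group's summary to participants
    with a positive EUR total in that group; the default includes zeros.
    """
    if mode not in ("all", "purchasers"):
        raise ValidationError("mode must be 'all' or 'purchasers'")
    df = summaries
    if weights is not None:
        unknown = weights.index.difference(pd.Index(df[id_col].unique()))
        if len(unknown):
            raise ValidationError(f"weights carry unknown participant ids, e.g. {unknown[0]!r}")
    if by is not None:
        df = df.merge(by.rename("_stratum"), left_on=id_col, right_index=True, how="inner")
        strata = [(s, grp) for s, grp in df.groupby("_stratum", observed=True)]
    else:
        strata = [(None, df)]
    rows = []
    for stratum, frame in strata:
        for group, gdf in frame.groupby("food_group", observed=True, sort=False):
            if mode == "purchasers":
                gdf = gdf[gdf["eur"] > 0]
            row: dict = {"food_group": group, "n": len(gdf)}
            if stratum is not None:
                row["stratum"] = stratum
            w = None
            if weights is not None:
                w = weights.reindex(gdf[id_col]).to_numpy()
                w = pd.Series(w, index=gdf.index)
                ok = w.notna()
                gdf, w = gdf[ok], w[ok]
            for measure in _MEASURES:
                med, q1, q3 = _quantiles(gdf[measure], None)
                row[f"{measure}_median"] = med
                row[f"{measure}_q1"] = q1
                row[f"{measure}_q3"] = q3
                if weights is not None:
                    wmed, wq1, wq3 = _quantiles(gdf[measure], w)
                    row[f"{measure}_wmedian"] = wmed
                    row[f"{measure}_wq1"] = wq1
                    row[f"{measure}_wq3"] = wq3
            if weights is not None:
                row["rel_change_eur"] = relative_change(row["eur_median"], row["eur_wmedian"])
                row["rel_change_kg"] = relative_change(row["kg_median"], row["kg_wmedian"])
            rows.append(row)
    out = pd.DataFrame(rows)
    lead = [c for c in ("stratum", "food_group", "n") if c in out.columns]
    return out[lead + [c for c in out.columns if c not in lead]]
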