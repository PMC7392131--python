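"""Comparisons across the five degree-of-loyalty groups.

Categorical variables get per-group count/percentage distributions with a
Pearson chi-square test; purchase and score variables get median [IQR]
summaries with Kruskal-Wallis (and ANOVA for scores).  p-values use
asymptotic reference distributions; exact permutation versions exist only
as test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .rfm import compare_scores_by_group

__all__ = [
    "TestResult",
    "chi_square_test",
    "kruskal_wallis_test",
    "loyalty_profile",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float


def chi_square_test(contingency: pd.DataFrame | np.ndarray) -> TestResult:
    """Pearson chi-square on an r x c count table, df = (r-1)(c-1)."""
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValidationError("need a two-dimensional table with >= 2 rows and columns")
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    expected = stats.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValidationError(
            "zero expected count; collapse sparse categories before testing"
        )
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return TestResult("chi-square", float(stat), int(df), float(p))


def kruskal_wallis_test(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across groups, df = k - 1."""
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups, dtype=object), index=v.index)
    keep = v.notna() & g.notna()
    v, g = v[keep], g[keep]
    samples = [grp.to_numpy() for _, grp in v.groupby(g, observed=True)]
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    if sum(len(s) for s in samples) < 3:
        raise ValidationError("need at least three observations in total")
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        return TestResult("kruskal-wallis", 0.0, len(samples) - 1, 1.0)
    stat, p = stats.kruskal(*samples)
    return TestResult("kruskal-wallis", float(stat), len(samples) - 1, float(p))


def _categorical_block(
    participants: pd.DataFrame, variable: str, loyalty_col: str
) -> tuple[pd.DataFrame, TestResult | None]:
    sub = participants[[variable, loyalty_col]].dropna()
    counts = pd.crosstab(sub[variable], sub[loyalty_col])
    pct = 100.0 * counts / counts.sum(axis=0)
    block = pd.concat({"n": counts, "pct": pct.round(2)}, axis=1)
    test = None
    if counts.shape[0] >= 2 and counts.shape[1] >= 2:
        try:
            test = chi_square_test(counts)
        except ValidationError:
            warnings.warn(f"chi-square skipped for {variable!r} (sparse table)", stacklevel=2)
    return block, test


def loyalty_profile(
    participants: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    summaries: pd.DataFrame | None = None,
    weights: pd.Series | None = None,
    loyalty_col: str = "loyalty",
    variables: list[str] | None = None,
    id_col: str = "id",
) -> dict:
    """Profile of the cohort across the degree-of-loyalty groups.

    Returns a dict with: ``loyalty_counts`` (group sizes and percentages),
    ``characteristics`` per sociodemographic variable (counts, column
    percentages, chi-square), optional ``rfm`` (median [IQR] per group with
    ANOVA/Kruskal-Wallis), optional ``food`` (per-group food medians with
    Kruskal-Wallis) and optional ``weights_by_group``.  Rows with missing
    loyalty are excluded and counted.
    """
    if loyalty_col not in participants.columns:
        raise ValidationError(f"no {loyalty_col!r} column")
    has_loyalty = participants[loyalty_col].notna()
    cohort = participants.loc[has_loyalty]
    counts = cohort[loyalty_col].value_counts().sort_index()
    loyalty_counts = pd.DataFrame(
        {"n": counts, "pct": (100.0 * counts / counts.sum()).round(2)}
    )
    empty = counts[counts == 0]
    if len(empty):
        warnings.warn(f"empty loyalty groups dropped: {list(empty.index)}", stacklevel=2)

    if variables is None:
        default = ["sex", "age_group", "marital_status", "education", "occupation", "children"]
        variables = [v for v in default if v in cohort.columns]
    characteristics = {}
    for var in variables:
        block, test = _categorical_block(cohort, var, loyalty_col)
        characteristics[var] = {"table": block, "test": test}

    report: dict = {
        "loyalty_counts": loyalty_counts,
        "n_missing_loyalty": int((~has_loyalty).sum()),
        "characteristics": characteristics,
    }

    loyalty_by_id = cohort.set_index(id_col)[loyalty_col]
    if scores is not None:
        merged = scores.merge(
            loyalty_by_id.rename(loyalty_col),
            left_on=scores.columns[0], right_index=True, how="inner",
        )
        report["rfm"] = compare_scores_by_group(merged["score"], merged[loyalty_col])
    if summaries is not None:
        sid = summaries.columns[0]
        merged = summaries.merge(
            loyalty_by_id.rename(loyalty_col), left_on=sid, right_index=True, how="inner"
        )
        food_rows = []
        for group, gdf in merged.groupby("food_group", observed=True, sort=False):
            row = {"food_group": group}
            for measure in ("eur", "eur_share", "kg", "kg_share"):
                med = gdf.groupby(loyalty_col, observed=True)[measure].median()
                for cat, m in med.items():
                    row[f"{measure}|{cat}"] = m
                kw = kruskal_wallis_test(gdf[measure], gdf[loyalty_col])
                row[f"{measure}_kw_h"] = kw.statistic
                row[f"{measure}_kw_p"] = kw.p_value
            food_rows.append(row)
        report["food"] = pd.DataFrame(food_rows)
        totals = merged.drop_duplicates(subset=sid)
        report["total_purchases"] = (
            totals.groupby(loyalty_col, observed=True)["total_eur"]
            .agg(median="median", q1=lambda x: x.quantile(0.25), q3=lambda x: x.quantile(0.75))
        )
    if weights is not None:
        wmerged = weights.rename("weight").to_frame().join(loyalty_by_id, how="inner")
        report["weights_by_group"] = compare_scores_by_group(
            wmerged["weight"], wmerged[loyalty_col]
        )
    return report
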