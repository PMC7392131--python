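"""Reference margin tables and sample contingency tabulation.

A *margin* is a one-way or two-way table of reference-population counts
used as a calibration target.  Margin CSVs carry the variable names in the
header, one category tuple per row, and a final ``count`` column::

    sex,age_group,count
    woman,<=29,401148
    ...

Harmonization files (``variable,from_category,to_category``) collapse
sample categories into the reference scheme explicitly; nothing is ever
remapped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "MarginSpec",
    "ContingencyTable",
    "ValidationIssue",
    "ValidationReport",
    "read_margin_table",
    "write_margin_table",
    "margin_from_sample",
    "tabulate_sample",
    "validate_margins",
    "read_harmonization",
    "harmonize_categories",
]


@dataclass(frozen=True)
class MarginSpec:
    """A calibration target: counts indexed by category tuples.

    Parameters
    ----------
    variables:
        Ordered names of the one or two classification variables.
    table:
        Counts (or population totals) as a Series whose index holds the
        category labels (MultiIndex for two-way tables).
    source:
        Free-text provenance label.
    """

    variables: tuple[str, ...]
    table: pd.Series
    source: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.variables) <= 2:
            raise ValidationError(
                f"margins must be one- or two-way, got {len(self.variables)} variables"
            )
        if (self.table.to_numpy() < 0).any():
            raise ValidationError("margin counts must be non-negative")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate category tuples in margin table")

    @property
    def total(self) -> float:
        return float(self.table.sum())

    @property
    def is_rakeable(self) -> bool:
        """True when every cell is strictly positive."""
        return bool((self.table.to_numpy() > 0).all())

    def categories(self, variable: str) -> list:
        pos = self.variables.index(variable)
        if len(self.variables) == 1:
            return list(self.table.index.unique())
        return list(self.table.index.get_level_values(pos).unique())

    def scaled_to(self, total: float) -> "MarginSpec":
        """Return a copy whose counts sum to ``total`` (proportions kept)."""
        if self.total <= 0:
            raise ValidationError("cannot rescale a margin with zero total")
        return MarginSpec(self.variables, self.table * (total / self.total), self.source)


@dataclass(frozen=True)
class ContingencyTable:
    """Weighted sample cross-tabulation on the same layout as a MarginSpec."""

    variables: tuple[str, ...]
    table: pd.Series
    n_excluded_missing: int = 0

    @property
    def total(self) -> float:
        return float(self.table.sum())


def read_margin_table(path: str | Path, source: str | None = None) -> MarginSpec:
    """Read and validate a margin CSV.

    The header must contain at least one variable column followed by a
    final ``count`` column.  Duplicate category tuples and negative counts
    are rejected with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected variable column(s) plus a count column")
    if df.columns[-1] != "count":
        raise FormatError(f"{path}: last column must be named 'count', got {df.columns[-1]!r}")
    variables = tuple(df.columns[:-1])
    if len(variables) > 2:
        raise FormatError(f"{path}: at most two classification variables supported")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise FormatError(f"{path}: non-numeric count at line {row}")
    neg = counts < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 2
        raise FormatError(f"{path}: negative count at line {row}")
    keys = df[list(variables)]
    dup = keys.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2
        raise FormatError(f"{path}: duplicated category tuple at line {row}")
    if len(variables) == 1:
        index = pd.Index(keys.iloc[:, 0], name=variables[0])
    else:
        index = pd.MultiIndex.from_frame(keys)
    table = pd.Series(counts.to_numpy(dtype=float), index=index, name="count")
    return MarginSpec(variables, table, source or str(path))


def write_margin_table(spec: MarginSpec, path: str | Path) -> None:
    df = spec.table.rename("count").reset_index()
    df.columns = list(spec.variables) + ["count"]
    df.to_csv(path, index=False)


def margin_from_sample(
    sample: pd.DataFrame, variables: Sequence[str], source: str = ""
) -> MarginSpec:
    """Tabulate a finite-population truth table directly into a MarginSpec."""
    ct = tabulate_sample(sample, variables)
    return MarginSpec(tuple(variables), ct.table, source)


def tabulate_sample(
    sample: pd.DataFrame,
    variables: Sequence[str],
    weights: pd.Series | np.ndarray | None = None,
) -> ContingencyTable:
    """Cross-tabulate sample rows, optionally weighted.

    Rows missing any of ``variables`` are excluded and counted in
    ``n_excluded_missing``.  Cell totals sum to the included rows' weight
    sum.
    """
    variables = list(variables)
    for v in variables:
        if v not in sample.columns:
            raise ValidationError(f"unknown variable {v!r}")
    if weights is None:
        w = pd.Series(1.0, index=sample.index)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=sample.index)
    keep = sample[variables].notna().all(axis=1)
    n_excluded = int((~keep).sum())
    sub = sample.loc[keep, variables]
    if sub.empty:
        if len(variables) == 1:
            idx = pd.Index([], name=variables[0])
        else:
            idx = pd.MultiIndex.from_arrays([[] for _ in variables], names=variables)
        return ContingencyTable(tuple(variables), pd.Series([], index=idx, dtype=float), n_excluded)
    grouped = w.loc[keep].groupby([sub[v] for v in variables], observed=True).sum()
    grouped.index.names = variables
    return ContingencyTable(tuple(variables), grouped, n_excluded)


@dataclass(frozen=True)
class ValidationIssue:
    margin: str
    kind: str  # "zero_cell" | "category_mismatch" | "empty_sample_cell"
    detail: str
    blocking: bool


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def blocking(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.blocking]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "margins valid: no issues"
        return "\n".join(
            f"[{'BLOCK' if i.blocking else 'warn'}] {i.margin} {i.kind}: {i.detail}"
            for i in self.issues
        )


def validate_margins(margins: Sequence[MarginSpec], sample: pd.DataFrame) -> ValidationReport:
    """Check that raking over ``margins`` is well posed for ``sample``.

    Reports zero margin cells (not rakeable), category-set mismatches
    between margin and sample, and positive-target cells holding no sample
    units (no units can carry that mass).
    """
    report = ValidationReport()
    for spec in margins:
        name = "x".join(spec.variables)
        zero = spec.table[spec.table <= 0]
        for key in zero.index:
            report.issues.append(
                ValidationIssue(name, "zero_cell", f"margin cell {key!r} is not positive", True)
            )
        mismatch = False
        for v in spec.variables:
            if v not in sample.columns:
                report.issues.append(
                    ValidationIssue(name, "category_mismatch", f"variable {v!r} absent from sample", True)
                )
                mismatch = True
                continue
            sample_cats = set(sample[v].dropna().unique())
            margin_cats = set(spec.categories(v))
            for c in sorted(margin_cats - sample_cats, key=str):
                report.issues.append(
                    ValidationIssue(
                        name, "category_mismatch",
                        f"margin category {c!r} of {v!r} absent from sample", True,
                    )
                )
                mismatch = True
            for c in sorted(sample_cats - margin_cats, key=str):
                report.issues.append(
                    ValidationIssue(
                        name, "category_mismatch",
                        f"sample category {c!r} of {v!r} absent from margin", True,
                    )
                )
                mismatch = True
        if mismatch:
            continue
        ct = tabulate_sample(sample, spec.variables)
        observed = ct.table.reindex(spec.table.index, fill_value=0.0)
        empty = spec.table[(spec.table > 0) & (observed <= 0)]
        for key in empty.index:
            report.issues.append(
                ValidationIssue(
                    name, "empty_sample_cell",
                    f"no sample units in cell {key!r} with positive target", True,
                )
            )
    return report


def read_harmonization(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = ["variable", "from_category", "to_category"]
    if list(df.columns) != required:
        raise FormatError(f"{path}: harmonization columns must be {required}")
    return df


def harmonize_categories(sample: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Collapse categories per an explicit harmonization table.

    Returns a copy; every remap is declarative (e.g. folding "Cohabiting"
    into "Single" to match a reference scheme).
    """
    out = sample.copy()
    for variable, grp in mapping.groupby("variable"):
        if variable not in out.columns:
            raise ValidationError(f"harmonization references unknown variable {variable!r}")
        remap = dict(zip(grp["from_category"], grp["to_category"]))
        col = out[variable]
        if isinstance(col.dtype, pd.CategoricalDtype):
            col = col.astype(object)
        out[variable] = col.replace(remap)
    return out
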