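"""Unit-level raking: multi-margin poststratification weights.

The core loop sweeps the margin list in order; for each margin every
unit's weight is multiplied by ``target_cell / current_weighted_cell`` for
the cell the unit falls in.  Sweeps repeat until the maximum relative
discrepancy over all margin cells drops below tolerance.  Trimming clamps
the converged weights into fixed bounds (no re-raking afterwards) and a
final rescale fixes the weight sum.

Two-phase construction handles questionnaire missingness: complete cases
are raked on the full margin set, while the reduced margins (typically
sex x age, available for nearly everyone) are raked on the whole eligible
sample and assigned only to the incomplete units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DivergenceError, ValidationError
from .margins import MarginSpec

__all__ = [
    "RakingControl",
    "WeightResult",
    "rake",
    "trim_weights",
    "rescale_weights",
    "margin_discrepancy",
    "two_phase_weights",
]

PHASE_FULL = "phase-1 full-margin"
PHASE_REDUCED = "phase-2 reduced-margin"


@dataclass(frozen=True)
class RakingControl:
    """Iteration, convergence and trimming controls.

    Defaults: converge when the max relative margin-cell discrepancy is
    at most 1e-7, cap at 200 sweeps, trim into [0.1, 10].
    """

    max_iterations: int = 200
    tolerance: float = 1e-7
    margin_order: str = "as-given"  # or "sorted" (by margin name)
    trim_lower: float = 0.1
    trim_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if not 0 < self.trim_lower < self.trim_upper:
            raise ConfigurationError("trim bounds require 0 < lower < upper")
        if self.margin_order not in ("as-given", "sorted"):
            raise ConfigurationError("margin_order must be 'as-given' or 'sorted'")


@dataclass
class WeightResult:
    """Per-unit weights plus convergence and trimming diagnostics."""

    weights: pd.Series
    iterations: int
    converged: bool
    max_discrepancy: float
    n_trimmed_lower: int = 0
    n_trimmed_upper: int = 0
    phase: pd.Series | None = None
    n_excluded: int = 0

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def _order_margins(margins: Sequence[MarginSpec], control: RakingControl) -> list[MarginSpec]:
    if control.margin_order == "sorted":
        return sorted(margins, key=lambda m: "x".join(m.variables))
    return list(margins)


def _margin_codes(sample: pd.DataFrame, spec: MarginSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map each sample row to its margin cell; return (codes, targets)."""
    for v in spec.variables:
        if v not in sample.columns:
            raise ValidationError(f"margin variable {v!r} absent from sample")
        if sample[v].isna().any():
            raise ValidationError(
                f"sample has missing values in margin variable {v!r}; "
                "exclude or route those units through the reduced-margin phase"
            )
    if len(spec.variables) == 1:
        keys = pd.Index(sample[spec.variables[0]])
    else:
        keys = pd.MultiIndex.from_frame(sample[list(spec.variables)].astype(object))
    codes = spec.table.index.get_indexer(keys)
    if (codes < 0).any():
        bad = keys[codes < 0][0]
        raise ValidationError(
            f"sample cell {bad!r} not present in margin {'x'.join(spec.variables)}"
        )
    return codes.astype(np.intp), spec.table.to_numpy(dtype=float)


def rake(
    sample: pd.DataFrame,
    margins: Sequence[MarginSpec],
    control: RakingControl | None = None,
) -> WeightResult:
    """Iterative proportional fitting at the unit level.

    Initial weights are uniform at ``margin_total / n`` so the starting
    weight sum matches the reference population.  Returns untrimmed,
    unscaled weights; compose with :func:`trim_weights` and
    :func:`rescale_weights` (or use :func:`two_phase_weights`).
    """
    control = control or RakingControl()
    if not margins:
        raise ConfigurationError("at least one margin is required")
    for spec in margins:
        if not spec.is_rakeable:
            raise ValidationError(
                f"margin {'x'.join(spec.variables)} has a zero cell and is not rakeable"
            )
    ordered = _order_margins(margins, control)
    n = len(sample)
    if n == 0:
        raise ValidationError("empty sample")
    prepared = [_margin_codes(sample, spec) for spec in ordered]
    pop_total = ordered[0].total
    w = np.full(n, pop_total / n, dtype=float)

    def max_disc(weights: np.ndarray) -> float:
        worst = 0.0
        for codes, targets in prepared:
            totals = np.bincount(codes, weights=weights, minlength=len(targets))
            worst = max(worst, float(np.max(np.abs(totals - targets) / targets)))
        return worst

    iterations = 0
    disc = max_disc(w)
    converged = disc <= control.tolerance
    while not converged and iterations < control.max_iterations:
        for (codes, targets), spec in zip(prepared, ordered):
            totals = np.bincount(codes, weights=w, minlength=len(targets))
            dead = (totals <= 0) & (targets > 0)
            if dead.any():
                cell = spec.table.index[int(np.flatnonzero(dead)[0])]
                raise DivergenceError(
                    f"margin {'x'.join(spec.variables)} cell {cell!r}: "
                    "zero weighted sample total against a positive target"
                )
            w *= (targets / totals)[codes]
        iterations += 1
        disc = max_disc(w)
        converged = disc <= control.tolerance
    if not converged:
        warnings.warn(
            f"raking did not converge in {iterations} sweeps "
            f"(max relative discrepancy {disc:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return WeightResult(
        weights=pd.Series(w, index=sample.index, name="weight"),
        iterations=iterations,
        converged=converged,
        max_discrepancy=disc,
    )


def trim_weights(
    weights: pd.Series, lower: float = 0.1, upper: float = 10.0
) -> tuple[pd.Series, int, int]:
    """Clamp weights into ``[lower, upper]``; no re-raking afterwards.

    Returns the trimmed weights and the counts clamped at each bound.
    """
    if not lower < upper:
        raise ConfigurationError("trim bounds require lower < upper")
    arr = weights.to_numpy(dtype=float)
    n_low = int((arr < lower).sum())
    n_high = int((arr > upper).sum())
    return pd.Series(np.clip(arr, lower, upper), index=weights.index, name=weights.name), n_low, n_high


def rescale_weights(weights: pd.Series, total: float) -> pd.Series:
    """Multiply all weights so their sum equals ``total`` exactly."""
    s = float(weights.sum())
    if s <= 0:
        raise ValidationError("cannot rescale: weight sum is not positive")
    return weights * (total / s)


def margin_discrepancy(
    sample: pd.DataFrame,
    weights: pd.Series | np.ndarray,
    margins: Sequence[MarginSpec],
) -> float:
    """Max relative deviation of weighted cell totals from margin targets.

    Zero-target cells are excluded (they are rejected upstream by margin
    validation for raking use).
    """
    w = np.asarray(weights, dtype=float)
    worst = 0.0
    for spec in margins:
        codes, targets = _margin_codes(sample, spec)
        totals = np.bincount(codes, weights=w, minlength=len(targets))
        pos = targets > 0
        if pos.any():
            worst = max(worst, float(np.max(np.abs(totals[pos] - targets[pos]) / targets[pos])))
    return worst


def two_phase_weights(
    sample: pd.DataFrame,
    full_margins: Sequence[MarginSpec],
    reduced_margins: Sequence[MarginSpec],
    control: RakingControl | None = None,
    rescale_total: float | None = None,
) -> WeightResult:
    """Two-phase poststratification with trimming and a final rescale.

    Phase 1 rakes the complete cases (non-missing on every full-margin
    variable) against ``full_margins``.  Phase 2 rakes the whole eligible
    sample (non-missing on the reduced-margin variables) against
    ``reduced_margins`` but assigns those weights only to units that were
    incomplete in phase 1.  Units missing a reduced-margin variable are
    excluded and counted.  Each phase's weights are put on the mean-1
    scale before trimming so the trim bounds act on relative weights;
    the concatenated vector is trimmed then rescaled to the eligible-unit
    count (or ``rescale_total``).
    """
    control = control or RakingControl()
    full_vars = sorted({v for m in full_margins for v in m.variables})
    reduced_vars = sorted({v for m in reduced_margins for v in m.variables})
    eligible_mask = sample[reduced_vars].notna().all(axis=1)
    n_excluded = int((~eligible_mask).sum())
    eligible = sample.loc[eligible_mask]
    if eligible.empty:
        raise ValidationError("no units are non-missing on the reduced-margin variables")
    complete_mask = eligible[full_vars].notna().all(axis=1)
    complete = eligible.loc[complete_mask]
    incomplete = eligible.loc[~complete_mask]

    pieces: list[pd.Series] = []
    phases: list[pd.Series] = []
    iterations = 0
    converged = True
    max_disc = 0.0
    if not complete.empty:
        res1 = rake(complete, full_margins, control)
        w1 = res1.weights / res1.weights.mean()
        pieces.append(w1)
        phases.append(pd.Series(PHASE_FULL, index=w1.index))
        iterations = max(iterations, res1.iterations)
        converged = converged and res1.converged
        max_disc = max(max_disc, res1.max_discrepancy)
    if not incomplete.empty:
        res2 = rake(eligible, reduced_margins, control)
        w2 = (res2.weights / res2.weights.mean()).loc[incomplete.index]
        pieces.append(w2)
        phases.append(pd.Series(PHASE_REDUCED, index=w2.index))
        iterations = max(iterations, res2.iterations)
        converged = converged and res2.converged
        max_disc = max(max_disc, res2.max_discrepancy)

    combined = pd.concat(pieces).reindex(eligible.index)
    phase = pd.concat(phases).reindex(eligible.index)
    trimmed, n_low, n_high = trim_weights(combined, control.trim_lower, control.trim_upper)
    total = float(len(eligible)) if rescale_total is None else float(rescale_total)
    final = rescale_weights(trimmed, total)
    return WeightResult(
        weights=final,
        iterations=iterations,
        converged=converged,
        max_discrepancy=max_disc,
        n_trimmed_lower=n_low,
        n_trimmed_upper=n_high,
        phase=phase.rename("phase"),
        n_excluded=n_excluded,
    )
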