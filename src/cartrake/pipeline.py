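"""End-to-end orchestration: simulate or ingest a cohort, build two-phase
raking weights, score RFM, summarize food groups, and write the
bias-characterization report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import CartrakeError, ValidationError
from .food_groups import (
    UNASSIGNED,
    map_products,
    participant_food_summary,
    summarize_food_groups,
    write_mapping,
)
from .group_analysis import loyalty_profile
from .margins import MarginSpec, margin_from_sample, tabulate_sample, validate_margins, write_margin_table
from .raking import RakingControl, WeightResult, two_phase_weights
from .reporting import format_percent
from .rfm import rfm_scores
from .synthetic import GeneratorConfig, default_config, simulate_cohort

__all__ = [
    "DEFAULT_MARGIN_SETS",
    "RunConfig",
    "RunReport",
    "recruitment_flow",
    "build_product_mapping",
    "run_pipeline",
]

log = logging.getLogger("cartrake")

#: the margin layout used throughout: eight two-way tables plus the
#: children-in-household one-way table; the reduced set is sex x age only
DEFAULT_MARGIN_SETS = {
    "full": [
        ("sex", "age_group"),
        ("sex", "education"),
        ("sex", "marital_status"),
        ("sex", "occupation"),
        ("age_group", "education"),
        ("age_group", "marital_status"),
        ("age_group", "occupation"),
        ("education", "occupation"),
        ("children",),
    ],
    "reduced": [("sex", "age_group")],
}


@dataclass
class RunConfig:
    generator: GeneratorConfig
    full_margin_vars: Sequence[tuple] = field(
        default_factory=lambda: list(DEFAULT_MARGIN_SETS["full"])
    )
    reduced_margin_vars: Sequence[tuple] = field(
        default_factory=lambda: list(DEFAULT_MARGIN_SETS["reduced"])
    )
    control: RakingControl = field(default_factory=RakingControl)
    output_dir: str | Path = "cartrake_run"
    reference_date: str = "2018-12-31"
    write_transactions: bool = False


@dataclass
class RunReport:
    weights: WeightResult
    recruitment: dict
    characteristics: pd.DataFrame
    food_table: pd.DataFrame
    profile: dict
    output_dir: Path


def recruitment_flow(
    contacted: int,
    consented: int,
    responded: int,
    purchasers: int,
    card_owners: int | None = None,
) -> dict:
    """Stage-by-stage recruitment percentages.

    Consent and response rates are whole percents of their predecessor
    stage; the purchaser share is one decimal of the consented count.
    """
    counts = dict(contacted=contacted, consented=consented, responded=responded, purchasers=purchasers)
    for name, value in counts.items():
        if value < 0:
            raise ValidationError(f"{name} count is negative")
    if consented > contacted:
        raise ValidationError("consented exceeds contacted")
    if responded > consented:
        raise ValidationError("responded exceeds consented")
    if purchasers > consented:
        raise ValidationError("purchasers exceeds consented")
    flow = dict(counts)
    if card_owners is not None:
        if contacted > card_owners:
            raise ValidationError("contacted exceeds card owners")
        flow["card_owners"] = card_owners
        flow["contacted_pct"] = format_percent(contacted, card_owners, 0) if card_owners else 0.0
    flow["consent_pct"] = format_percent(consented, contacted, 0) if contacted else 0.0
    flow["response_pct"] = format_percent(responded, consented, 0) if consented else 0.0
    flow["purchaser_pct"] = format_percent(purchasers, consented, 1) if consented else 0.0
    return flow


def build_product_mapping(purchase_model) -> pd.DataFrame:
    """Product-code -> food-group mapping implied by a purchase model.

    Groups outside the seven study food groups map to ``unassigned``."""
    from .food_groups import FOOD_GROUPS

    rows = []
    for group, model in purchase_model.items():
        label = group if group in FOOD_GROUPS else UNASSIGNED
        for code in model.product_codes:
            rows.append({"product_group_code": code, "food_group": label})
    return pd.DataFrame(rows)


def _characteristics_table(
    sample: pd.DataFrame,
    weights: pd.Series,
    population: pd.DataFrame,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Unweighted vs weighted vs population category distributions."""
    rows = []
    for var in variables:
        pop = tabulate_sample(population, [var]).table
        unw = tabulate_sample(sample, [var]).table
        wtd = tabulate_sample(sample, [var], weights=weights.reindex(sample.index).fillna(0.0)).table
        cats = pop.index.union(unw.index)
        for cat in cats:
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "n_unweighted": float(unw.get(cat, 0.0)),
                    "pct_unweighted": format_percent(unw.get(cat, 0.0), unw.sum(), 2),
                    "n_weighted": float(wtd.get(cat, 0.0)),
                    "pct_weighted": format_percent(wtd.get(cat, 0.0), wtd.sum(), 2),
                    "pct_population": format_percent(pop.get(cat, 0.0), pop.sum(), 2),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Generate a cohort, correct its selection bias, and report.

    Deterministic given the generator seed: reruns produce byte-identical
    outputs.  Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        log.info("cartrake %s", __version__)
        log.info("config: %s", asdict(config.generator))

        stage = "synthetic-cohort"
        cohort = simulate_cohort(config.generator)
        participants = cohort.participants.set_index("id", drop=False)

        stage = "margins"
        margins_dir = outdir / "margins"
        margins_dir.mkdir(exist_ok=True)
        full_margins = []
        for vars_ in config.full_margin_vars:
            spec = margin_from_sample(cohort.population, list(vars_), source="synthetic-population")
            write_margin_table(spec, margins_dir / ("margin_" + "_x_".join(vars_) + ".csv"))
            full_margins.append(spec)
        reduced_margins = [
            margin_from_sample(cohort.population, list(vars_), source="synthetic-population")
            for vars_ in config.reduced_margin_vars
        ]
        full_vars = sorted({v for m in full_margins for v in m.variables})
        complete = participants.dropna(subset=full_vars)
        report = validate_margins(full_margins, complete)
        for issue in report.issues:
            log.warning("margin issue: %s", issue)
        if report.blocking:
            raise ValidationError(
                f"{len(report.blocking)} blocking margin issues; first: {report.blocking[0]}"
            )

        stage = "raking"
        weights = two_phase_weights(participants, full_margins, reduced_margins, config.control)
        log.info(
            "raking: iterations=%d converged=%s max_discrepancy=%.3g trimmed_low=%d trimmed_high=%d excluded=%d",
            weights.iterations, weights.converged, weights.max_discrepancy,
            weights.n_trimmed_lower, weights.n_trimmed_upper, weights.n_excluded,
        )
        wdf = pd.DataFrame(
            {"id": weights.weights.index, "weight": weights.weights.to_numpy(),
             "phase": weights.phase.to_numpy()}
        )
        wdf.to_csv(outdir / "weights.csv", index=False)

        stage = "rfm"
        scores = rfm_scores(cohort.transactions, config.reference_date)
        scores.to_csv(outdir / "rfm.csv", index=False)

        stage = "food-groups"
        mapping = build_product_mapping(config.generator.purchase_model)
        write_mapping(mapping, outdir / "product_mapping.csv")
        tagged, coverage = map_products(cohort.transactions, mapping)
        log.info(
            "food-group coverage: %d/%d codes assigned (%.1f%%)",
            coverage.n_assigned, coverage.n_codes, coverage.pct_assigned,
        )
        summaries = participant_food_summary(tagged, participants=participants.index)
        summaries.to_csv(outdir / "food_summary.csv", index=False)
        food_table = summarize_food_groups(summaries, weights=weights.weights)
        food_table.to_csv(outdir / "table_food.csv", index=False)

        stage = "characteristics"
        weighted_sample = participants.loc[weights.weights.index]
        characteristics = _characteristics_table(
            weighted_sample, weights.weights, cohort.population,
            [v for v in ("sex", "age_group", "marital_status", "education", "occupation", "children")
             if v in participants.columns],
        )
        characteristics.to_csv(outdir / "table_characteristics.csv", index=False)

        stage = "loyalty-profile"
        profile = loyalty_profile(
            cohort.participants, scores=scores, summaries=summaries, weights=weights.weights
        )
        profile["loyalty_counts"].to_csv(outdir / "loyalty_counts.csv")
        if "food" in profile:
            profile["food"].to_csv(outdir / "food_by_loyalty.csv", index=False)
        if "rfm" in profile:
            log.info(
                "rfm by loyalty: F=%.2f (p=%.3g) H=%.2f (p=%.3g)",
                profile["rfm"]["anova_f"], profile["rfm"]["anova_p"],
                profile["rfm"]["kruskal_h"], profile["rfm"]["kruskal_p"],
            )

        stage = "recruitment-flow"
        purchaser_ids = set(cohort.transactions["participant_id"].unique())
        flow = recruitment_flow(
            contacted=len(cohort.population),
            consented=len(participants),
            responded=int(participants["responded"].sum()),
            purchasers=int(participants.index.isin(purchaser_ids).sum()),
        )
        pd.DataFrame([flow]).to_csv(outdir / "recruitment_flow.csv", index=False)
        log.info("recruitment flow: %s", flow)

        stage = "transactions"
        if config.write_transactions:
            cohort.transactions.to_csv(
                outdir / "transactions.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S"
            )
        cohort.participants.to_csv(outdir / "participants.csv", index=False)

        return RunReport(
            weights=weights,
            recruitment=flow,
            characteristics=characteristics,
            food_table=food_table,
            profile=profile,
            output_dir=outdir,
        )
    except CartrakeError as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise CartrakeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def default_run_config(
    population_size: int = 200_000, seed: int = 0, output_dir: str | Path = "cartrake_run", **overrides
) -> RunConfig:
    return RunConfig(
        generator=default_config(population_size=population_size, seed=seed, **overrides),
        output_dir=output_dir,
    )
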