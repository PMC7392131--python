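"""Synthetic cohort generator: population, biased consent, nonresponse,
transactions and loyalty categories.

The generator produces the statistical structure the downstream analysis
assumes: a reference population with realistic two-way sociodemographic
associations, a logistic consent mechanism that over/under-represents
configured groups, questionnaire nonresponse that blanks only the
questionnaire fields, and right-skewed zero-inflated purchase totals that
scale with a latent degree-of-loyalty share.

Covariates are drawn sequentially (sex, age, then education / occupation /
marital status conditional on age, then children conditional on age and
marital status) so that one-way marginals hit their configured targets
exactly in expectation while two-way tables carry real association.

Columns prefixed ``_oracle`` (true inclusion probability, latent loyalty
share) exist for testing only and must never be consumed by analysis
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigurationError, ValidationError

__all__ = [
    "LOYALTY_CATEGORIES",
    "QUESTIONNAIRE_FIELDS",
    "ORACLE_PREFIX",
    "VariableScheme",
    "PurchaseGroupModel",
    "GeneratorConfig",
    "CohortData",
    "default_config",
    "joint_from_margins",
    "generate_population",
    "population_joint",
    "implied_marginals",
    "sample_consenters",
    "apply_nonresponse",
    "generate_transactions",
    "assign_loyalty",
    "simulate_cohort",
]

LOYALTY_CATEGORIES = ["0%-20%", "21%-40%", "41%-60%", "61%-80%", "81%-100%"]
#: fields sourced from the questionnaire (blanked by nonresponse); sex and
#: age come from the retailer database and are never blanked this way
QUESTIONNAIRE_FIELDS = ["marital_status", "education", "occupation", "children", "loyalty"]
ORACLE_PREFIX = "_oracle"

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class VariableScheme:
    """One categorical variable: either a root marginal or a conditional.

    Root variables carry ``probs``; conditional variables carry ``parents``
    plus a ``conditional`` table mapping each parent category tuple to a
    probability vector over ``categories``.
    """

    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...] | None = None
    parents: tuple[str, ...] = ()
    conditional: Mapping[tuple, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ConfigurationError(f"{self.name}: duplicated category labels")
        if self.parents:
            if self.conditional is None:
                raise ConfigurationError(f"{self.name}: conditional table required with parents")
            for key, p in self.conditional.items():
                self._check_probs(p, f"{self.name}|{key}")
        else:
            if self.probs is None:
                raise ConfigurationError(f"{self.name}: marginal probabilities required")
            self._check_probs(self.probs, self.name)

    def _check_probs(self, probs: Sequence[float], label: str) -> None:
        arr = np.asarray(probs, dtype=float)
        if len(arr) != len(self.categories):
            raise ConfigurationError(f"{label}: {len(arr)} probabilities for {len(self.categories)} categories")
        if (arr < 0).any() or (arr > 1).any():
            raise ConfigurationError(f"{label}: probabilities must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError(f"{label}: probabilities sum to {arr.sum()!r}, not 1")


@dataclass(frozen=True)
class PurchaseGroupModel:
    """Zero-inflated log-normal purchase model for one food group."""

    zero_inflation: float
    log_mean_eur: float
    log_sd_eur: float
    kg_per_eur: float
    kg_noise_sd: float = 0.2
    events_mean: float = 10.0
    product_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ConfigurationError("zero_inflation must lie in [0, 1]")
        if self.log_sd_eur <= 0:
            raise ConfigurationError("log_sd_eur must be positive")
        if self.kg_per_eur <= 0:
            raise ConfigurationError("kg_per_eur must be positive")
        if self.kg_noise_sd < 0:
            raise ConfigurationError("kg_noise_sd must be non-negative")
        if self.events_mean < 0:
            raise ConfigurationError("events_mean must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    population_size: int
    category_schemes: tuple[VariableScheme, ...]
    selection_coefs: Mapping = field(default_factory=dict)
    nonresponse_rate: float = 0.22
    nonresponse_mechanism: str = "completely-at-random"
    nonresponse_coefs: Mapping = field(default_factory=dict)
    purchase_model: Mapping[str, PurchaseGroupModel] = field(default_factory=dict)
    loyalty_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    loyalty_share_beta: tuple[float, float] = (3.2, 1.6)
    registry_missing_rate: float = 0.0
    period_start: str = "2017-01-01"
    period_end: str = "2018-12-31"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ConfigurationError("population_size must be >= 1")
        if not 0.0 <= self.nonresponse_rate <= 1.0:
            raise ConfigurationError("nonresponse_rate must lie in [0, 1]")
        if not 0.0 <= self.registry_missing_rate <= 1.0:
            raise ConfigurationError("registry_missing_rate must lie in [0, 1]")
        if len(self.loyalty_multipliers) != len(LOYALTY_CATEGORIES):
            raise ConfigurationError("loyalty_multipliers needs one value per loyalty category")
        if any(m <= 0 for m in self.loyalty_multipliers):
            raise ConfigurationError("loyalty_multipliers must be positive")
        if self.nonresponse_mechanism not in ("completely-at-random", "covariate-dependent"):
            raise ConfigurationError(
                "nonresponse_mechanism must be 'completely-at-random' or 'covariate-dependent'"
            )

    def scheme(self, name: str) -> VariableScheme:
        for s in self.category_schemes:
            if s.name == name:
                return s
        raise ConfigurationError(f"unknown variable {name!r}")


@dataclass
class CohortData:
    """Everything one simulated study run produces."""

    population: pd.DataFrame
    participants: pd.DataFrame
    transactions: pd.DataFrame


def joint_from_margins(
    p_row: Sequence[float],
    p_col: Sequence[float],
    log_odds: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> np.ndarray:
    """Joint probability table with given marginals and association tilts.

    Starts from the independence table multiplied by ``exp(log_odds)`` and
    proportionally rescales rows and columns until both marginals match.
    Used only to build generator conditionals, never by the weighting code.
    """
    p_row = np.asarray(p_row, dtype=float)
    p_col = np.asarray(p_col, dtype=float)
    seed = np.outer(p_row, p_col)
    if log_odds is not None:
        seed = seed * np.exp(np.asarray(log_odds, dtype=float))
    joint = seed / seed.sum()
    for _ in range(max_iter):
        joint *= (p_row / joint.sum(axis=1))[:, None]
        joint *= p_col / joint.sum(axis=0)
        if np.abs(joint.sum(axis=1) - p_row).max() < tol:
            break
    return joint


def _conditional_from_joint(
    joint: np.ndarray,
    parent_cats: Sequence[str],
    child_cats: Sequence[str],
    floor: float = 0.025,
) -> dict[tuple, tuple[float, ...]]:
    # floor keeps every (parent, child) cell realistically occupied so the
    # two-way raking margins never face empty sample cells at study scale
    cond = joint / joint.sum(axis=1, keepdims=True)
    cond = np.maximum(cond, floor)
    cond = cond / cond.sum(axis=1, keepdims=True)
    return {(p,): tuple(cond[i]) for i, p in enumerate(parent_cats)}


def default_config(population_size: int = 50_000, seed: int = 0, **overrides) -> GeneratorConfig:
    """A ready-to-run configuration shaped like a Finnish adult cohort study.

    Marginal targets follow national one-way distributions; associations
    (education and occupation strongly tied to age, etc.) are injected via
    log-odds tilts and re-margined so one-way targets still hold exactly.
    Consent favours women, the higher-educated and the employed, and
    disfavours the youngest and oldest age groups.
    """
    sex = VariableScheme("sex", ("woman", "man"), (0.5112, 0.4888))
    age_cats = ("<=29", "30-39", "40-49", "50-59", "60-69", ">=70")
    age_probs = (0.1804, 0.1580, 0.1486, 0.1652, 0.1658, 0.1820)
    age = VariableScheme("age_group", age_cats, age_probs)

    edu_cats = ("primary", "upper_secondary", "bachelor", "master")
    edu_probs = (0.2501, 0.4278, 0.2149, 0.1072)
    # older cohorts lean to primary education, prime-age to degrees
    edu_tilt = np.array(
        [
            [-1.2, 0.5, 0.2, -0.3],
            [-1.0, -0.2, 0.5, 0.6],
            [-0.6, 0.0, 0.4, 0.4],
            [0.0, 0.2, 0.0, 0.0],
            [0.6, 0.1, -0.2, -0.2],
            [1.6, -0.4, -0.6, -0.6],
        ]
    )
    edu = VariableScheme(
        "education", edu_cats, parents=("age_group",),
        conditional=_conditional_from_joint(
            joint_from_margins(age_probs, edu_probs, edu_tilt), age_cats, edu_cats
        ),
    )

    occ_cats = ("employed", "unemployed", "student", "retired", "other")
    occ_probs = (0.5235, 0.0666, 0.0518, 0.3182, 0.0399)
    occ_tilt = np.array(
        [
            [0.4, 0.5, 2.2, -2.2, 0.6],
            [1.2, 0.4, 0.2, -2.0, 0.4],
            [1.4, 0.3, -0.8, -2.0, 0.2],
            [1.2, 0.3, -1.5, -0.8, 0.0],
            [-0.2, -0.2, -2.0, 1.8, -0.3],
            [-1.8, -1.2, -1.8, 2.2, -0.5],
        ]
    )
    occ = VariableScheme(
        "occupation", occ_cats, parents=("age_group",),
        conditional=_conditional_from_joint(
            joint_from_margins(age_probs, occ_probs, occ_tilt), age_cats, occ_cats
        ),
    )

    mar_cats = ("married", "single", "divorced", "widowed")
    mar_probs = (0.4477, 0.3598, 0.1292, 0.0633)
    mar_tilt = np.array(
        [
            [-2.0, 2.0, -2.0, -2.2],
            [-0.1, 0.6, -0.5, -2.0],
            [0.4, -0.1, 0.3, -1.5],
            [0.5, -0.4, 0.5, -1.0],
            [0.6, -0.7, 0.4, 0.5],
            [0.3, -0.9, -0.1, 2.0],
        ]
    )
    mar = VariableScheme(
        "marital_status", mar_cats, parents=("age_group",),
        conditional=_conditional_from_joint(
            joint_from_margins(age_probs, mar_probs, mar_tilt), age_cats, mar_cats
        ),
    )

    children = _children_scheme(
        target_yes=0.3848,
        age_probs=age_probs,
        age_cats=age_cats,
        marital_scheme=mar,
        age_tilt={"<=29": -0.4, "30-39": 1.8, "40-49": 1.6, "50-59": -0.6, "60-69": -2.5, ">=70": -3.5},
        marital_tilt={"married": 0.8, "single": -0.8, "divorced": 0.0, "widowed": -1.0},
    )

    selection_coefs = {
        "intercept": float(logit(0.04)) - 0.55,
        ("sex", "woman"): 0.6,
        ("education", "bachelor"): 0.5,
        ("education", "master"): 0.7,
        ("occupation", "employed"): 0.4,
        ("age_group", "<=29"): -0.4,
        ("age_group", ">=70"): -1.1,
    }

    purchase_model = {
        "vegetables": PurchaseGroupModel(0.03, 5.30, 1.00, 0.27, 0.25, 12.0, ("pg1001", "pg1002", "pg1003")),
        "skimmed milk & sour milk": PurchaseGroupModel(0.26, 3.10, 1.40, 1.02, 0.25, 8.0, ("pg2001", "pg2002")),
        "sugar-sweetened beverages": PurchaseGroupModel(0.04, 3.80, 1.10, 0.52, 0.25, 8.0, ("pg3001", "pg3002")),
        "rye bread": PurchaseGroupModel(0.04, 3.90, 1.00, 0.25, 0.20, 8.0, ("pg4001",)),
        "red meat & processed meat": PurchaseGroupModel(0.03, 5.60, 1.05, 0.12, 0.20, 12.0, ("pg5001", "pg5002", "pg5003")),
        "fat spreads": PurchaseGroupModel(0.04, 3.95, 1.00, 0.19, 0.20, 6.0, ("pg6001",)),
        "sweets & chocolate": PurchaseGroupModel(0.03, 4.75, 1.00, 0.09, 0.20, 10.0, ("pg7001", "pg7002")),
        "other groceries": PurchaseGroupModel(0.01, 7.20, 0.85, 0.30, 0.25, 20.0, ("pg9001", "pg9002", "pg9003", "pg9004")),
    }

    cfg = dict(
        population_size=population_size,
        category_schemes=(sex, age, edu, occ, mar, children),
        selection_coefs=selection_coefs,
        nonresponse_rate=0.22,
        purchase_model=purchase_model,
        loyalty_multipliers=(0.30, 0.60, 1.00, 1.50, 2.20),
        loyalty_share_beta=(3.2, 1.6),
        registry_missing_rate=0.0005,
        seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def _children_scheme(
    target_yes: float,
    age_probs: Sequence[float],
    age_cats: Sequence[str],
    marital_scheme: VariableScheme,
    age_tilt: Mapping[str, float],
    marital_tilt: Mapping[str, float],
) -> VariableScheme:
    """Children-under-18 flag conditional on (age, marital status).

    P(yes | age, marital) = expit(b + tilt_age + tilt_marital) with the
    intercept b solved so the implied overall marginal equals target_yes.
    """
    p_age = np.asarray(age_probs, dtype=float)
    joint_weights = []
    tilts = []
    keys = []
    for i, a in enumerate(age_cats):
        cond = np.asarray(marital_scheme.conditional[(a,)], dtype=float)
        for j, m in enumerate(marital_scheme.categories):
            joint_weights.append(p_age[i] * cond[j])
            tilts.append(age_tilt[a] + marital_tilt[m])
            keys.append((a, m))
    jw = np.asarray(joint_weights)
    tl = np.asarray(tilts)

    def marginal(b: float) -> float:
        return float(np.sum(jw * expit(b + tl)) - target_yes)

    b = brentq(marginal, -30.0, 30.0)
    conditional = {k: (1.0 - expit(b + t), expit(b + t)) for k, t in zip(keys, tl)}
    return VariableScheme(
        "children", ("no", "yes"), parents=("age_group", "marital_status"),
        conditional=conditional,
    )


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the reference population; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    out = pd.DataFrame({"id": np.arange(1, n + 1)})
    for scheme in config.category_schemes:
        cats = np.asarray(scheme.categories, dtype=object)
        if not scheme.parents:
            codes = rng.choice(len(cats), size=n, p=np.asarray(scheme.probs, dtype=float))
        else:
            parent_vals = [out[p].to_numpy() for p in scheme.parents]
            key_index = {k: i for i, k in enumerate(scheme.conditional)}
            combo = np.array(
                [key_index[k] for k in zip(*parent_vals)], dtype=np.intp
            )
            probs = np.array([scheme.conditional[k] for k in scheme.conditional], dtype=float)
            cum = np.cumsum(probs, axis=1)
            u = rng.random(n)
            codes = (u[:, None] > cum[combo]).sum(axis=1)
        out[scheme.name] = cats[codes]
    return out


def population_joint(config: GeneratorConfig) -> pd.DataFrame:
    """Exact joint distribution implied by the config (chain enumeration)."""
    rows = pd.DataFrame({"_prob": [1.0]})
    for scheme in config.category_schemes:
        if not scheme.parents:
            block = pd.DataFrame({scheme.name: scheme.categories, "_p": scheme.probs})
            rows = rows.merge(block, how="cross")
        else:
            records = []
            for key, probs in scheme.conditional.items():
                for cat, p in zip(scheme.categories, probs):
                    records.append(dict(zip(scheme.parents, key), **{scheme.name: cat, "_p": p}))
            block = pd.DataFrame(records)
            rows = rows.merge(block, on=list(scheme.parents), how="left")
        rows["_prob"] = rows["_prob"] * rows.pop("_p")
    return rows


def implied_marginals(config: GeneratorConfig) -> dict[str, pd.Series]:
    joint = population_joint(config)
    return {
        s.name: joint.groupby(s.name, observed=True)["_prob"].sum().reindex(list(s.categories))
        for s in config.category_schemes
    }


def _linear_predictor(frame: pd.DataFrame, coefs: Mapping) -> np.ndarray:
    lp = np.full(len(frame), float(coefs.get("intercept", 0.0)))
    for key, value in coefs.items():
        if key == "intercept":
            continue
        try:
            var, cat = key
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"coefficient key {key!r} must be (variable, category)") from exc
        if var not in frame.columns:
            raise ConfigurationError(f"coefficient references unknown variable {var!r}")
        if cat not in set(frame[var].dropna().unique()):
            raise ConfigurationError(f"coefficient references unknown category {cat!r} of {var!r}")
        lp += float(value) * (frame[var] == cat).to_numpy(dtype=float)
    return lp


def sample_consenters(
    population: pd.DataFrame, selection_coefs: Mapping, seed: int
) -> pd.DataFrame:
    """Bernoulli consent with logistic inclusion probabilities.

    The returned frame carries ``_oracle_inclusion_prob``, the true
    per-unit inclusion probability; it exists so tests can verify the
    weighting recovers it, and must never feed the analysis itself.
    """
    rng = np.random.default_rng(seed)
    p = expit(_linear_predictor(population, selection_coefs))
    take = rng.random(len(population)) < p
    out = population.loc[take].copy()
    out[f"{ORACLE_PREFIX}_inclusion_prob"] = p[take]
    return out.reset_index(drop=True)


def apply_nonresponse(
    participants: pd.DataFrame,
    rate: float,
    mechanism: str = "completely-at-random",
    seed: int = 0,
    coefs: Mapping | None = None,
) -> pd.DataFrame:
    """Blank the questionnaire fields for nonresponders.

    Sex and age come from the retailer database and stay intact.  Under
    the covariate-dependent mechanism the nonresponse probability is
    ``expit(logit(rate) + linear predictor(coefs))``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("nonresponse rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = participants.copy()
    if rate == 0.0:
        out["responded"] = True
        return out
    if mechanism == "completely-at-random":
        p = np.full(len(out), rate)
    elif mechanism == "covariate-dependent":
        base = float(logit(min(max(rate, 1e-12), 1 - 1e-12)))
        p = expit(base + _linear_predictor(out, coefs or {}))
        if rate == 1.0:
            p = np.ones(len(out))
    else:
        raise ConfigurationError(f"unknown nonresponse mechanism {mechanism!r}")
    nonresp = rng.random(len(out)) < p
    fields = [f for f in QUESTIONNAIRE_FIELDS if f in out.columns]
    for f in fields:
        col = out[f]
        if isinstance(col.dtype, pd.CategoricalDtype):
            out[f] = col.astype(object)
        out.loc[nonresp, f] = np.nan
    out["responded"] = ~nonresp
    return out


def generate_transactions(
    participants: pd.DataFrame,
    purchase_model: Mapping[str, PurchaseGroupModel],
    period_start: str = "2017-01-01",
    period_end: str = "2018-12-31",
    seed: int = 0,
    loyalty_multipliers: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate purchase events over the observation period.

    Per participant and food group: a Bernoulli purchase indicator (1 -
    zero_inflation), a log-normal conditional total in EUR scaled by the
    participant's loyalty multiplier, a proportional kg total with
    log-normal noise, and the total split over ``1 + Poisson(events_mean)``
    time-stamped events.
    """
    start = pd.Timestamp(period_start)
    end = pd.Timestamp(period_end)
    if not start < end:
        raise ConfigurationError("period_start must precede period_end")
    rng = np.random.default_rng(seed)
    n = len(participants)
    ids = participants["id"].to_numpy()
    if loyalty_multipliers is not None and "_latent_loyalty_cat" in participants.columns:
        mult = np.asarray(loyalty_multipliers, dtype=float)[
            participants["_latent_loyalty_cat"].to_numpy(dtype=np.intp)
        ]
    else:
        mult = np.ones(n)
    span = int((end - start).total_seconds())
    frames = []
    for group, model in purchase_model.items():
        buy = rng.random(n) >= model.zero_inflation
        nbuy = int(buy.sum())
        if nbuy == 0:
            continue
        total_eur = rng.lognormal(model.log_mean_eur, model.log_sd_eur, nbuy) * mult[buy]
        kg_noise = rng.lognormal(-0.5 * model.kg_noise_sd**2, model.kg_noise_sd, nbuy)
        total_kg = total_eur * model.kg_per_eur * kg_noise
        # loyal customers shop more often as well as spend more, so the
        # event intensity scales with the multiplier (drives R and F)
        k = 1 + rng.poisson(model.events_mean * mult[buy])
        n_events = int(k.sum())
        shares = rng.gamma(1.0, 1.0, n_events)
        starts = np.concatenate(([0], np.cumsum(k)[:-1]))
        denom = np.add.reduceat(shares, starts)
        shares = shares / np.repeat(denom, k)
        codes = model.product_codes or (f"pg-{group}",)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(ids[buy], k),
                    "timestamp": start + pd.to_timedelta(rng.integers(0, span, n_events), unit="s"),
                    "product_group_code": rng.choice(np.asarray(codes, dtype=object), n_events),
                    "eur": np.repeat(total_eur, k) * shares,
                    "kg": np.repeat(total_kg, k) * shares,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "timestamp", "product_group_code", "eur", "kg"]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    # split events can round below positivity only at float underflow; guard anyway
    return out


def assign_loyalty(
    participants: pd.DataFrame,
    focal_spend: pd.Series | np.ndarray,
    total_spend: pd.Series | np.ndarray,
) -> pd.Series:
    """Five-category loyalty share bin per participant.

    The share 100*focal/total falls in bins with edges at 20/40/60/80;
    a value exactly on an edge goes to the lower-labelled bin.  Zero total
    spend yields a missing category.
    """
    focal = np.asarray(focal_spend, dtype=float)
    total = np.asarray(total_spend, dtype=float)
    if (focal < 0).any() or (total < 0).any():
        raise ValidationError("spend amounts must be non-negative")
    if (focal > total * (1 + 1e-12)).any():
        raise ValidationError("focal spend cannot exceed total spend")
    share = np.divide(100.0 * focal, total, out=np.full_like(focal, np.nan), where=total > 0)
    idx = np.digitize(share, [20.0, 40.0, 60.0, 80.0], right=True)
    labels = np.asarray(LOYALTY_CATEGORIES, dtype=object)
    out = pd.Series(labels[np.clip(idx, 0, 4)], index=participants.index, name="loyalty", dtype=object)
    out[~np.isfinite(share)] = np.nan
    return out


def simulate_cohort(config: GeneratorConfig) -> CohortData:
    """Run the full generative chain with one root seed.

    population -> biased consent -> latent loyalty share -> transactions
    (scaled by the latent loyalty multiplier) -> self-reported loyalty
    category from focal/total spend -> questionnaire nonresponse ->
    trace registry missingness on sex/age for a handful of units.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    sub = [int(s.generate_state(1)[0]) for s in seeds]
    population = generate_population(config)
    participants = sample_consenters(population, config.selection_coefs, sub[0])

    rng = np.random.default_rng(sub[1])
    a, b = config.loyalty_share_beta
    share = rng.beta(a, b, len(participants))
    latent_cat = np.clip(np.digitize(100.0 * share, [20.0, 40.0, 60.0, 80.0], right=True), 0, 4)
    participants[f"{ORACLE_PREFIX}_loyalty_share"] = share
    participants["_latent_loyalty_cat"] = latent_cat

    transactions = generate_transactions(
        participants,
        config.purchase_model,
        config.period_start,
        config.period_end,
        sub[2],
        config.loyalty_multipliers,
    )
    focal = (
        transactions.groupby("participant_id")["eur"].sum()
        .reindex(participants["id"], fill_value=0.0)
        .to_numpy()
    )
    total = np.divide(focal, share, out=np.zeros_like(focal), where=share > 0)
    participants["loyalty"] = assign_loyalty(participants, focal, total)
    participants = participants.drop(columns=["_latent_loyalty_cat"])

    participants = apply_nonresponse(
        participants,
        config.nonresponse_rate,
        config.nonresponse_mechanism,
        sub[3],
        config.nonresponse_coefs,
    )
    if config.registry_missing_rate > 0:
        rng2 = np.random.default_rng(sub[4])
        gone = rng2.random(len(participants)) < config.registry_missing_rate
        participants.loc[gone, ["sex", "age_group"]] = np.nan
    return CohortData(population=population, participants=participants, transactions=transactions)
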