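"""FFQ intake processing: g/day conversion, food groups, energy adjustment,
cohort exclusions, and exposure categorization.

Categorical food-frequency responses are converted to grams per day with the
product-sum method: intake = frequency weight (times/day) x serving-size
multiplier x standard serving grams, summed over the items of a food group.
The default frequency weights map the nine-level scale ("never or rarely"
up to "2+ per day") to {0, 1/30, 2.5/30, 1/7, 2.5/7, 5.5/7, 1, 1.5, 2.5}
times/day and the standard meat serving to 99 g (midpoint of 3-4 oz,
85-113 g); both live in configuration, not code, so they can be matched
to a specific questionnaire without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeightMap",
    "DEFAULT_FREQUENCY_WEIGHTS",
    "SERVING_MULTIPLIERS",
    "FOOD_GROUPS",
    "product_sum_intake",
    "aggregate_groups",
    "residual_energy_adjust",
    "ExclusionRule",
    "default_exclusion_rules",
    "apply_exclusions",
    "categorize_exposure",
]

DEFAULT_FREQUENCY_WEIGHTS = {
    "never_or_rarely": 0.0,
    "1_per_month": 1.0 / 30.0,
    "2_3_per_month": 2.5 / 30.0,
    "1_per_week": 1.0 / 7.0,
    "2_4_per_week": 2.5 / 7.0,
    "5_6_per_week": 5.5 / 7.0,
    "1_per_day": 1.0,
    "1_2_per_day": 1.5,
    "2_plus_per_day": 2.5,
}

SERVING_MULTIPLIERS = {"half": 0.5, "standard": 1.0, "one_and_half": 1.5}

# unprocessed red = two beef/lamb items; pork is processed because the
# instrument's single pork item is dominated by processed products
FOOD_GROUPS = {
    "unprocessed_red": ["hamburger_ground_beef", "beef_lamb_main_dish"],
    "processed": ["processed_beef_lamb", "processed_poultry", "pork"],
    "poultry": ["poultry_main_dish"],
    "fish": ["fish_main_dish"],
}


@dataclass
class WeightMap:
    """Frequency weights (times/day), serving multipliers and serving grams."""

    frequency_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_WEIGHTS)
    )
    serving_multipliers: dict = field(default_factory=lambda: dict(SERVING_MULTIPLIERS))
    serving_grams: dict | float = 99.0  # per item, or one default for all

    def validate(self):
        levels = list(self.frequency_weights.values())
        if any(w < 0 for w in levels):
            raise ValueError("frequency weights must be nonnegative")
        if any(b < a for a, b in zip(levels, levels[1:])):
            raise ValueError("frequency weights must be nondecreasing across levels")
        first = next(iter(self.frequency_weights))
        if self.frequency_weights[first] != 0.0:
            raise ValueError(f"lowest frequency level {first!r} must map to 0")

    def grams(self, item: str) -> float:
        if isinstance(self.serving_grams, dict):
            return float(self.serving_grams.get(item, 99.0))
        return float(self.serving_grams)


def product_sum_intake(responses: pd.DataFrame, weight_map: WeightMap | None = None) -> pd.DataFrame:
    """Per-subject, per-item g/day from long-format categorical responses.

    ``responses`` columns: subject_id, item_id, frequency_category,
    serving_category. Unknown category labels are rejected naming the row.
    """
    wm = weight_map or WeightMap()
    wm.validate()
    freq = responses["frequency_category"].map(wm.frequency_weights)
    if freq.isna().any():
        i = int(freq.index[freq.isna()][0])
        raise ValueError(
            f"row {i}: unknown frequency category "
            f"{responses.loc[i, 'frequency_category']!r}"
        )
    serv = responses["serving_category"].map(wm.serving_multipliers)
    if serv.isna().any():
        i = int(serv.index[serv.isna()][0])
        raise ValueError(
            f"row {i}: unknown serving category {responses.loc[i, 'serving_category']!r}"
        )
    grams = responses["item_id"].map(wm.grams)
    out = responses[["subject_id", "item_id"]].copy()
    out["g_per_day"] = freq.to_numpy() * serv.to_numpy() * grams.to_numpy()
    return out


def aggregate_groups(
    item_intakes: pd.DataFrame, food_group_map: dict | None = None
) -> pd.DataFrame:
    """Sum item g/day into food groups; adds combined red+processed.

    ``item_intakes``: output of :func:`product_sum_intake`. Groups must be
    disjoint; an item in two groups is a configuration error.
    """
    groups = food_group_map or FOOD_GROUPS
    seen: dict[str, str] = {}
    for gname, items in groups.items():
        for it in items:
            if it in seen:
                raise ValueError(f"item {it!r} assigned to both {seen[it]!r} and {gname!r}")
            seen[it] = gname
    wide = item_intakes.pivot_table(
        index="subject_id", columns="item_id", values="g_per_day", aggfunc="sum", fill_value=0.0
    )
    out = pd.DataFrame(index=wide.index)
    for gname, items in groups.items():
        present = [it for it in items if it in wide.columns]
        out[gname] = wide[present].sum(axis=1) if present else 0.0
    if {"unprocessed_red", "processed"} <= set(out.columns):
        out["combined_red_processed"] = out["unprocessed_red"] + out["processed"]
    return out.reset_index()


def residual_energy_adjust(intake, total_energy):
    """Residual-method energy adjustment.

    OLS of intake on total energy; the adjusted value is the residual plus
    the mean intake, so the mean is preserved and the adjusted column is
    exactly uncorrelated with energy. Idempotent.
    """
    y = np.asarray(intake, dtype=float)
    e = np.asarray(total_energy, dtype=float)
    if len(y) < 3:
        raise ValueError("residual adjustment needs n >= 3")
    if np.var(e) == 0:
        raise ValueError("degenerate regressor: total energy is constant")
    ec = e - e.mean()
    slope = (ec @ (y - y.mean())) / (ec @ ec)
    adjusted = y - slope * ec
    if isinstance(intake, pd.Series):
        return pd.Series(adjusted, index=intake.index, name=intake.name)
    return adjusted


@dataclass
class ExclusionRule:
    reason: str
    predicate: object  # callable(DataFrame) -> boolean mask

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.predicate(df), dtype=bool)


def default_exclusion_rules(
    energy_low: float = 500.0, energy_high: float = 4500.0, min_age: float = 25.0
) -> list[ExclusionRule]:
    """Baseline cohort filters, applied in a fixed, auditable order.

    Energy bounds are strict inequalities (<500 or >4500 kcal/day excluded;
    exactly 500/4500 retained). Rules referring to absent columns are
    skipped; rows with missing required fields fall under the missing-data
    reasons.
    """

    def col(df, name):
        return df[name] if name in df.columns else pd.Series(np.nan, index=df.index)

    return [
        ExclusionRule(
            "missing_dietary",
            lambda df: col(df, "ffq_unprocessed_red").isna() | col(df, "ffq_processed").isna()
            if "ffq_unprocessed_red" in df.columns
            else np.zeros(len(df), bool),
        ),
        ExclusionRule(
            "energy_out_of_range",
            lambda df: (col(df, "energy") < energy_low) | (col(df, "energy") > energy_high),
        ),
        ExclusionRule(
            "missing_age_sex_race",
            lambda df: col(df, "entry_age").isna() | col(df, "sex").isna() | col(df, "race").isna(),
        ),
        ExclusionRule("age_under_25", lambda df: col(df, "entry_age") < min_age),
        ExclusionRule(
            "prevalent_disease",
            lambda df: (col(df, "prevalent_cancer").fillna(0) > 0)
            | (col(df, "prevalent_cvd").fillna(0) > 0),
        ),
    ]


def apply_exclusions(
    cohort: pd.DataFrame, rules: list[ExclusionRule] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows failing any filter; each row counted once, first match wins.

    Returns the filtered cohort and a ledger of counts per reason (the
    counts sum to rows removed).
    """
    rules = rules if rules is not None else default_exclusion_rules()
    reason = np.full(len(cohort), "", dtype=object)
    for rule in rules:
        hit = rule.mask(cohort) & (reason == "")
        reason[hit] = rule.reason
    keep = reason == ""
    ledger = pd.DataFrame(
        {
            "reason": [r.reason for r in rules],
            "n_excluded": [int((reason == r.reason).sum()) for r in rules],
        }
    )
    return cohort.loc[keep].copy(), ledger


def categorize_exposure(
    adjusted_intake, basis: str = "consumers", raw_intake=None
) -> tuple[pd.Series, dict]:
    """Five-level exposure category: zero-intake plus quartiles of consumers.

    Level 0 iff (raw) intake == 0; quartile cut points computed among the
    reference set named by ``basis`` ("consumers", the default, or "total").
    Returns integer codes 0-4 and the per-level median of the adjusted
    intake, as used by the quartile-median trend test (the zero level's
    median is 0 by construction only when zero subjects sit at 0 on the
    adjusted scale; we report their actual median).
    """
    x = pd.Series(np.asarray(adjusted_intake, dtype=float))
    raw = x if raw_intake is None else pd.Series(np.asarray(raw_intake, dtype=float))
    if (raw < 0).any():
        raise ValueError("intakes must be nonnegative")
    zero = raw == 0
    consumers = x[~zero]
    if consumers.nunique() < 4:
        raise ValueError("fewer than 4 distinct nonzero intake values; cannot form quartiles")
    ref = consumers if basis == "consumers" else x
    if basis not in ("consumers", "total"):
        raise ValueError("basis must be 'consumers' or 'total'")
    cuts = np.quantile(ref, [0.25, 0.5, 0.75])
    if len(np.unique(cuts)) < 3:
        raise ValueError("degenerate quartile cut points in reference set")
    codes = np.where(zero, 0, 1 + np.searchsorted(cuts, x, side="left"))
    codes = pd.Series(codes.astype(int), index=x.index)
    medians = {int(lvl): float(x[codes == lvl].median()) for lvl in sorted(codes.unique())}
    return codes, medians
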