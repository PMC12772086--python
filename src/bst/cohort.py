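"""Cohort construction rules: inclusion filters, visit selection, recodes.

The questionnaire arm keeps dogs strictly older than 1 year (eating
patterns are not established earlier), strictly younger than 19 (higher
ages are likely data-entry errors) and with owner-reported 9-point BCS
strictly above 3 (lower scores are clinically underweight).  The clinic arm
keeps one randomly selected visit per dog to avoid correlated residuals and
collapses the 5-point BCS to three categories (1-2 underweight, 3 ideal,
4-5 overweight/obese) because the extreme scores are rarely used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RecodeError, SchemaError

TERTILE_LABELS = ("low", "medium", "high")
BCS3_FROM_5PT = {1: "underweight", 2: "underweight", 3: "ideal",
                 4: "overweight_obese", 5: "overweight_obese"}


@dataclass
class FilterReport:
    """Per-rule exclusion bookkeeping (one record may fail several rules)."""

    n_input: int
    n_excluded_by_rule: dict
    n_retained: int

    def to_json_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_excluded_by_rule": {k: int(v) for k, v in self.n_excluded_by_rule.items()},
            "n_retained": int(self.n_retained),
        }


def apply_questionnaire_filters(
    scored: pd.DataFrame,
    age_col: str = "age_years",
    bcs_col: str = "bcs_owner_9pt",
    min_age: float = 1.0,
    max_age: float = 19.0,
    min_bcs: float = 3.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the inclusion rules age > 1, age < 19, BCS present and > 3.

    All inequalities are strict; boundary values are excluded.  Returns the
    retained rows and a :class:`FilterReport` itemising each rule.
    """
    for col in (age_col, bcs_col):
        if col not in scored.columns:
            raise SchemaError("filter input lacks a required column", missing=[col])
    age = pd.to_numeric(scored[age_col], errors="coerce")
    bcs = pd.to_numeric(scored[bcs_col], errors="coerce")
    rules = {
        f"age_not_greater_than_{min_age:g}": ~(age > min_age),
        f"age_not_less_than_{max_age:g}": ~(age < max_age),
        "bcs_missing": bcs.isna(),
        f"bcs_not_greater_than_{min_bcs:g}": bcs.notna() & ~(bcs > min_bcs),
    }
    failed = np.zeros(len(scored), dtype=bool)
    counts = {}
    for name, mask in rules.items():
        mask = mask.fillna(True).to_numpy()
        counts[name] = int(mask.sum())
        failed |= mask
    kept = scored.loc[~failed].copy()
    report = FilterReport(len(scored), counts, len(kept))
    return kept, report


def select_random_visit(visits: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one uniformly chosen visit per ``dog_id``.

    The choice is reproducible for a given seed and invariant to the input
    row order (rows are ranked by (dog_id, visit_id) before drawing).
    """
    if "dog_id" not in visits.columns:
        raise SchemaError("visit table lacks a required column", missing=["dog_id"])
    if len(visits) == 0:
        return visits.copy()
    sort_cols = ["dog_id"] + (["visit_id"] if "visit_id" in visits.columns else [])
    ordered = visits.sort_values(sort_cols, kind="stable")
    dog = ordered["dog_id"].to_numpy()
    uniq, start, counts = np.unique(dog, return_index=True, return_counts=True)
    # np.unique sorts dog ids, so the draw order is canonical
    rng = np.random.default_rng(seed)
    pick = start + (rng.random(uniq.size) * counts).astype(int)
    return ordered.iloc[np.sort(pick)].copy()


def merge_bcs_5pt(bcs_5pt: int) -> str:
    """Collapse a 5-point BCS to underweight / ideal / overweight_obese."""
    try:
        key = int(bcs_5pt)
    except (TypeError, ValueError):
        raise RecodeError(f"5-point BCS must be an integer, got {bcs_5pt!r}") from None
    if key != bcs_5pt or key not in BCS3_FROM_5PT:
        raise RecodeError(f"5-point BCS out of range 1..5: {bcs_5pt!r}")
    return BCS3_FROM_5PT[key]


def recode_bcs_column(records: pd.DataFrame, bcs_col: str = "bcs_5pt",
                      out_col: str = "bcs_category") -> pd.DataFrame:
    """Vectorised 5-point -> 3-category recode, added as a new column."""
    values = records[bcs_col]
    bad = ~values.isin(list(BCS3_FROM_5PT))
    if bad.any():
        raise RecodeError(
            f"5-point BCS out of range 1..5 at rows {list(np.flatnonzero(bad))[:5]}"
        )
    out = records.copy()
    out[out_col] = values.map(BCS3_FROM_5PT)
    return out


def assign_tertiles(fms) -> np.ndarray:
    """Split values into low / medium / high thirds by rank.

    The cut points are the values at the equal-split ranks; every record
    tied with a cut-point value falls in the lower group, so group sizes
    differ by at most the number of boundary ties and the assignment is a
    pure function of the values (invariant to input order).  Missing values
    receive no label.  Requires at least 3 non-missing values; all-identical
    values are rejected as degenerate.
    """
    values = np.asarray(fms, dtype=float)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("tertile assignment requires at least 3 non-missing values")
    v = values[ok]
    if np.all(v == v[0]):
        raise ValueError("tertile assignment is degenerate: all values identical")
    b1, b2 = n // 3 + (n % 3 > 0), 2 * (n // 3) + (n % 3)
    v_sorted = np.sort(v)
    t1, t2 = v_sorted[b1 - 1], v_sorted[b2 - 1]
    sub = np.where(v <= t1, "low", np.where(v <= t2, "medium", "high"))
    out = np.full(values.shape, None, dtype=object)
    out[ok] = sub
    return out


def breed_average(table: pd.DataFrame, value_column: str, min_n: int = 10,
                  breed_col: str = "breed") -> pd.DataFrame:
    """Per-breed n / mean / sd of ``value_column``, for breeds with n > min_n.

    The threshold is strict ("more than" ``min_n`` dogs); rows with a
    missing value do not count towards n.
    """
    if breed_col not in table.columns:
        raise SchemaError("breed averaging lacks a required column", missing=[breed_col])
    sub = table[[breed_col, value_column]].dropna(subset=[value_column])
    grouped = sub.groupby(breed_col)[value_column]
    out = grouped.agg(n="count", mean_value="mean", sd_value="std").reset_index()
    out = out.rename(columns={breed_col: "breed"})
    out = out[out["n"] > min_n].reset_index(drop=True)
    return out


def eligible_ehr_breeds(records: pd.DataFrame, min_cell_mean: float = 50.0,
                        breed_col: str = "breed") -> list[str]:
    """Breeds whose mean dog count over the observed sex x age grid is >= threshold."""
    counts = records.groupby([breed_col, "sex", "age_years"]).size()
    means = counts.groupby(level=0).mean()
    return sorted(means.index[means >= min_cell_mean])
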