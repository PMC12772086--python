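"""Scoring of owner-reported eating-behaviour questionnaires.

Converts Likert answers into six factor scores and two weighted composites:

* **Food Motivation Score (FMS)** — how food-driven the dog is, combining
  responsiveness/satiety (7 items), lack of fussiness (3 items) and interest
  in food (3 items): ``FMS = (7*RS + 3*LF + 3*IF) / 13``.
* **Owner Control Score (OCS)** — how tightly the owner manages diet and
  activity, combining owner intervention (4 items), restriction of human food
  (4 items) and exercise taken (5 items): ``OCS = (4*OI + 4*RHF + 5*EX) / 13``.

Each factor score is the sum of its item scores divided by the sum of the
item maxima (every item maximum is 1), so factors and composites live on
[0, 1].  Item scores come from fixed Likert maps: 4-option items score
1 / 0.6667 / 0.3333 / 0, 5-option items score 1 / 0.75 / 0.5 / 0.25 / 0, and
reverse-keyed items allocate the same decimals in the opposite direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, LikertParseError, SchemaError

#: The six behaviour/management factors, in canonical order.
FACTORS = (
    "responsiveness_satiety",
    "lack_fussiness",
    "interest_in_food",
    "owner_intervention",
    "restriction_human_food",
    "exercise_taken",
)

#: Factors entering the Food Motivation Score, with their item-count weights.
FMS_WEIGHTS = {
    "responsiveness_satiety": 7,
    "lack_fussiness": 3,
    "interest_in_food": 3,
}

#: Factors entering the Owner Control Score, with their item-count weights.
OCS_WEIGHTS = {
    "owner_intervention": 4,
    "restriction_human_food": 4,
    "exercise_taken": 5,
}

# Published decimals are used verbatim (0.6667, not 2/3) so that scored
# outputs are bit-compatible with the printed protocol; the reversed tables
# therefore hold 0.3333 for 'mainly true' rather than 1 - 0.6667.
LIKERT_4 = {
    "definitely true": 1.0,
    "mainly true": 0.6667,
    "somewhat true": 0.3333,
    "not at all true": 0.0,
}
LIKERT_4_REVERSED = {
    "definitely true": 0.0,
    "mainly true": 0.3333,
    "somewhat true": 0.6667,
    "not at all true": 1.0,
}
LIKERT_5 = {
    "always": 1.0,
    "often": 0.75,
    "sometimes": 0.5,
    "rarely": 0.25,
    "never": 0.0,
}
LIKERT_5_REVERSED = {label: 1.0 - s for label, s in LIKERT_5.items()}

_TABLES = {
    (4, False): LIKERT_4,
    (4, True): LIKERT_4_REVERSED,
    (5, False): LIKERT_5,
    (5, True): LIKERT_5_REVERSED,
}

#: Labels in descending score order for each scale width (forward keying).
LABELS_DESCENDING = {
    4: ["definitely true", "mainly true", "somewhat true", "not at all true"],
    5: ["always", "often", "sometimes", "rarely", "never"],
}


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item: its column, factor, scale width and keying."""

    item_id: str
    factor: str
    n_options: int
    reversed: bool = False
    column: str = ""

    def __post_init__(self):
        if self.factor not in FACTORS:
            raise ConfigurationError("factor", f"unknown factor {self.factor!r}")
        if self.n_options not in (4, 5):
            raise ConfigurationError("n_options", "must be 4 or 5")
        if not self.column:
            object.__setattr__(self, "column", self.item_id)


def default_items() -> list[ItemDefinition]:
    """The default 26-item key: 13 dog items and 13 owner items.

    Factor sizes follow the published instrument (7/3/3 dog, 4/4/5 owner).
    The per-item factor assignment and reverse keying here are synthetic
    placeholders matching the generator in :mod:`bst.synthetic`; a real
    instrument key can be supplied as YAML via :func:`load_items`.
    """
    layout = [
        ("responsiveness_satiety", 7, 4),
        ("lack_fussiness", 3, 4),
        ("interest_in_food", 3, 4),
        ("owner_intervention", 4, 5),
        ("restriction_human_food", 4, 5),
        ("exercise_taken", 5, 5),
    ]
    # items 8 and 20 are reverse-keyed so that reversal handling is always
    # exercised on both scale widths
    reversed_ids = {"item_08", "item_20"}
    items = []
    idx = 1
    for factor, count, n_options in layout:
        for _ in range(count):
            item_id = f"item_{idx:02d}"
            items.append(
                ItemDefinition(
                    item_id=item_id,
                    factor=factor,
                    n_options=n_options,
                    reversed=item_id in reversed_ids,
                )
            )
            idx += 1
    return items


def load_items(path) -> list[ItemDefinition]:
    """Read an item-definition key from YAML (a list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError("items", "item key must be a YAML list")
    return [
        ItemDefinition(
            item_id=str(entry["item_id"]),
            factor=entry["factor"],
            n_options=int(entry["n_options"]),
            reversed=bool(entry.get("reversed", False)),
            column=str(entry.get("column", "")),
        )
        for entry in raw
    ]


def save_items(items: list[ItemDefinition], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "item_id": it.item_id,
                    "column": it.column,
                    "factor": it.factor,
                    "n_options": it.n_options,
                    "reversed": it.reversed,
                }
                for it in items
            ],
            fh,
            sort_keys=False,
        )


def map_likert(answer_label, n_options: int, reversed: bool = False) -> float:
    """Score one Likert answer label on [0, 1].

    Matching is case-insensitive after trimming.  Missing answers (None,
    NaN or the empty string) return NaN; an unknown label raises
    :class:`~bst.errors.LikertParseError`.
    """
    if answer_label is None:
        return math.nan
    if isinstance(answer_label, float) and math.isnan(answer_label):
        return math.nan
    label = str(answer_label).strip().lower()
    if label in ("", "na"):
        return math.nan
    try:
        table = _TABLES[(n_options, bool(reversed))]
    except KeyError:
        raise ConfigurationError("n_options", "must be 4 or 5") from None
    try:
        return table[label]
    except KeyError:
        raise LikertParseError(answer_label) from None


def score_factor(item_scores) -> tuple[float, bool]:
    """Score one factor: sum of answered items over their summed maxima.

    Items are all scored on [0, 1] so this is the mean over answered items.
    Returns ``(score, flagged)`` where ``flagged`` marks factors with more
    than half their items missing; with every item missing the score is NaN.
    """
    arr = np.asarray(item_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("score_factor requires at least one item")
    n_missing = int(np.isnan(arr).sum())
    n_answered = arr.size - n_missing
    if n_answered == 0:
        return math.nan, True
    score = float(np.nansum(arr) / n_answered)
    return score, n_missing * 2 > arr.size


def compute_fms(rs: float, lf: float, intf: float) -> float:
    """Food Motivation Score: ``(7*rs + 3*lf + 3*intf) / 13``.

    NaN if any factor is missing (all three factors are required).
    """
    if any(math.isnan(v) for v in (rs, lf, intf)):
        return math.nan
    return (7.0 * rs + 3.0 * lf + 3.0 * intf) / 13.0


def compute_ocs(oi: float, rhf: float, ex: float) -> float:
    """Owner Control Score: ``(4*oi + 4*rhf + 5*ex) / 13``."""
    if any(math.isnan(v) for v in (oi, rhf, ex)):
        return math.nan
    return (4.0 * oi + 4.0 * rhf + 5.0 * ex) / 13.0


def score_cohort(raw: pd.DataFrame, items: list[ItemDefinition] | None = None) -> pd.DataFrame:
    """Score a cohort table: one output row per input row.

    Adds the six factor-score columns, ``fms``, ``ocs``, a per-factor
    ``<factor>_flagged`` boolean (more than half the factor's items missing)
    and ``scoring_flagged`` (any factor flagged or composite missing).
    Covariate columns pass through unchanged; flagged rows are kept.
    """
    if items is None:
        items = default_items()
    missing_cols = [it.column for it in items if it.column not in raw.columns]
    if missing_cols:
        raise SchemaError("item columns absent from input table", missing=missing_cols)

    covariate_cols = [c for c in raw.columns if c not in {it.column for it in items}]
    out = raw[covariate_cols].copy()

    # vectorised label -> score per item column
    item_scores: dict[str, np.ndarray] = {}
    for it in items:
        col = raw[it.column]
        normalised = col.map(
            lambda v: v if (v is None or (isinstance(v, float) and math.isnan(v)))
            else str(v).strip().lower()
        )
        table = _TABLES[(it.n_options, it.reversed)]
        scored = normalised.map(lambda v, t=table: _lookup(v, t))
        bad = scored.isna() & normalised.notna() & ~normalised.isin(["", "na"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LikertParseError(raw[it.column].iloc[row], item_id=it.item_id, row=row)
        item_scores[it.item_id] = scored.to_numpy(dtype=float)

    by_factor: dict[str, list[np.ndarray]] = {f: [] for f in FACTORS}
    for it in items:
        by_factor[it.factor].append(item_scores[it.item_id])

    any_flag = np.zeros(len(raw), dtype=bool)
    for factor in FACTORS:
        cols = by_factor[factor]
        if not cols:
            raise SchemaError(f"no items defined for factor '{factor}'")
        mat = np.column_stack(cols)
        n_missing = np.isnan(mat).sum(axis=1)
        n_answered = mat.shape[1] - n_missing
        with np.errstate(invalid="ignore"):
            score = np.where(n_answered > 0, np.nansum(mat, axis=1) / np.maximum(n_answered, 1), np.nan)
        flagged = n_missing * 2 > mat.shape[1]
        out[factor] = score
        out[f"{factor}_flagged"] = flagged
        any_flag |= flagged

    fms_parts = [out[f].to_numpy() for f in FMS_WEIGHTS]
    ocs_parts = [out[f].to_numpy() for f in OCS_WEIGHTS]
    w_fms = np.array(list(FMS_WEIGHTS.values()), dtype=float)
    w_ocs = np.array(list(OCS_WEIGHTS.values()), dtype=float)
    out["fms"] = np.column_stack(fms_parts) @ w_fms / 13.0
    out["ocs"] = np.column_stack(ocs_parts) @ w_ocs / 13.0
    out["scoring_flagged"] = any_flag | out["fms"].isna().to_numpy() | out["ocs"].isna().to_numpy()
    return out


def _lookup(value, table):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if value in ("", "na"):
        return math.nan
    return table.get(value, math.nan)
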