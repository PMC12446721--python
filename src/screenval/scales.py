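"""Questionnaire scale scoring and inter-scale correlation.

Scales are raw sums of three-point Likert items (0/1/2); no t-score or
age/sex norming is applied, matching the convention of analysing raw
checklist values. The default depression scale has 13 items; which items
belong to a scale is configuration, not code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from screenval.synthetic_cohort import CohortTable

MISSING_POLICIES = ("exclude", "prorate")


@dataclass(frozen=True)
class ScaleDefinition:
    """A named, ordered set of item identifiers with its scoring range."""

    name: str
    item_ids: tuple[str, ...]
    min_item_value: int = 0
    max_item_value: int = 2

    def __post_init__(self) -> None:
        if not self.item_ids:
            raise ValueError("a scale needs at least one item")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("scale item ids must be unique")
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def max_score(self) -> int:
        return self.max_item_value * self.n_items


def default_affective_scale() -> ScaleDefinition:
    """The 13-item DSM-oriented depression (affective problems) scale.

    Item membership here is a placeholder mapping onto the simulator's 13
    generated items; on real checklist data the item list is supplied via
    configuration.
    """
    return ScaleDefinition(
        name="dsm_affective_13",
        item_ids=tuple(f"item_{j:02d}" for j in range(1, 14)),
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def score_scale(
    cohort: CohortTable,
    scale: ScaleDefinition,
    reporter: str,
    missing_policy: str = "exclude",
) -> pd.DataFrame:
    """Score a scale for one reporter; returns id / raw_score / n_items_missing.

    Under ``exclude`` (the default) the score is missing if any item is
    missing — the whole-participant omission rule. Under ``prorate`` the
    score is ``round(mean(present) * n_items)`` (half away from zero) when
    at least 50% of items are present, else missing.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}")
    available = cohort.item_columns(reporter)
    if not available and reporter not in cohort.reporters():
        raise KeyError(f"unknown reporter {reporter!r}")
    cols = []
    for iid in scale.item_ids:
        col = f"{reporter}.{iid}"
        if col not in cohort.data.columns:
            raise KeyError(f"unknown item id {iid!r} for reporter {reporter!r}")
        cols.append(col)

    block = cohort.data[cols]
    n_missing = block.isna().sum(axis=1).to_numpy()
    sums = block.sum(axis=1, skipna=True).to_numpy(dtype=float)
    n_present = scale.n_items - n_missing

    score = np.full(len(block), np.nan)
    if missing_policy == "exclude":
        complete = n_missing == 0
        score[complete] = sums[complete]
    else:
        enough = n_present >= 0.5 * scale.n_items
        with np.errstate(invalid="ignore", divide="ignore"):
            prorated = _round_half_away(sums / np.maximum(n_present, 1) * scale.n_items)
        score[enough] = prorated[enough]

    return pd.DataFrame(
        {
            "id": cohort.data["id"].to_numpy(),
            "raw_score": pd.array(
                [int(s) if not math.isnan(s) else pd.NA for s in score], dtype="Int64"
            ),
            "n_items_missing": n_missing.astype(int),
        }
    )


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def correlate_scores(a: pd.DataFrame, b: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between two score tables over pairwise-complete ids."""
    merged = a.merge(b, on="id", suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["raw_score_a", "raw_score_b"])
    if len(merged) < 3:
        raise ValueError(
            f"need at least 3 participants with both scores, got {len(merged)}"
        )
    x = merged["raw_score_a"].to_numpy(dtype=float)
    y = merged["raw_score_b"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a score vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(merged))


def write_scores(scores: pd.DataFrame, destination, sep: str = ",") -> None:
    scores[["id", "raw_score"]].to_csv(destination, sep=sep, index=False, na_rep="NA")


def scale_from_mapping(name: str, item_ids: list[str]) -> ScaleDefinition:
    """Build a scale from a configuration mapping entry."""
    return ScaleDefinition(name=name, item_ids=tuple(item_ids))
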