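"""Case-control contrast construction and prevalence balancing.

Three contrasts, each defined on one reporter's diagnosis flags:

- **sensitivity** — depressed vs. everyone else (other diagnoses and
  healthy participants alike);
- **specificity** — depressed (comorbidity allowed) vs. participants
  carrying at least one non-depression diagnosis and no depression;
- **strict_specificity** — depressed with no comorbid flag vs. the same
  negatives as specificity.

Controls are then subsampled (uniformly, seeded, without replacement) so
that positives make up a target fraction of the analysis sample — 10% by
default, a typical community depression rate. When the control pool is
too small the whole pool is kept and a ratio-not-met marker is set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from screenval.scales import ScaleDefinition
from screenval.synthetic_cohort import CohortTable

CONTRAST_KINDS = ("sensitivity", "specificity", "strict_specificity")
DEFAULT_TARGET_RATIO = 0.10


class ContrastUnconstructibleError(ValueError):
    """Raised when a contrast has an empty positive or negative side."""

    def __init__(self, kind: str, reporter: str, empty_side: str):
        self.kind = kind
        self.reporter = reporter
        self.empty_side = empty_side
        super().__init__(
            f"contrast unconstructible: {kind!r} on reporter {reporter!r} has no {empty_side}"
        )


@dataclass(frozen=True)
class ContrastSample:
    """Labelled case/control id sets for one contrast."""

    kind: str
    reporter: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    target_ratio: float | None = None
    seed: int | None = None
    balanced: bool = False
    ratio_met: bool | None = None

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives must be disjoint")
        if not self.positives:
            raise ContrastUnconstructibleError(self.kind, self.reporter, "positives")
        if not self.negatives:
            raise ContrastUnconstructibleError(self.kind, self.reporter, "negatives")

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def n_negatives(self) -> int:
        return len(self.negatives)

    @property
    def positive_fraction(self) -> float:
        return self.n_positives / (self.n_positives + self.n_negatives)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (id, label) with cases labelled 1."""
        ids = list(self.positives) + list(self.negatives)
        labels = [1] * self.n_positives + [0] * self.n_negatives
        return pd.DataFrame({"id": ids, "label": labels})


def filter_age(cohort: CohortTable, bounds: tuple[int, int]) -> CohortTable:
    """Keep participants with age inside inclusive integer bounds."""
    lo, hi = bounds
    if lo > hi:
        raise ValueError("age bounds must be ordered")
    mask = (cohort.data["age"] >= lo) & (cohort.data["age"] <= hi)
    return CohortTable(cohort.data.loc[mask.fillna(False)].reset_index(drop=True))


def exclude_incomplete(
    cohort: CohortTable,
    required_reporters: list[str] | tuple[str, ...],
    required_scale: ScaleDefinition,
    scale_reporter: str = "parent",
) -> CohortTable:
    """Drop participants with any missing required diagnosis or scale item.

    Retains exactly the participants that have (a) non-missing diagnosis
    flags for every required reporter and (b) a scorable scale: every item
    of ``required_scale`` present for ``scale_reporter``.
    """
    df = cohort.data
    mask = pd.Series(True, index=df.index)
    for reporter in required_reporters:
        cols = cohort.dx_columns(reporter)
        if not cols:
            raise KeyError(f"no diagnosis columns for reporter {reporter!r}")
        mask &= df[cols].notna().all(axis=1)
    item_cols = [f"{scale_reporter}.{iid}" for iid in required_scale.item_ids]
    for col in item_cols:
        if col not in df.columns:
            raise KeyError(f"scale item column {col!r} absent from cohort")
    mask &= df[item_cols].notna().all(axis=1)
    return CohortTable(df.loc[mask].reset_index(drop=True))


def _flags(cohort: CohortTable, reporter: str) -> tuple[pd.Series, pd.Series]:
    """(depression flag, any-other-diagnosis flag) for one reporter."""
    dep_col = f"{reporter}.dx_depression"
    if dep_col not in cohort.data.columns:
        raise KeyError(f"no depression diagnosis column for reporter {reporter!r}")
    dep = cohort.data[dep_col] == 1
    other_cols = [c for c in cohort.dx_columns(reporter) if c != dep_col]
    if other_cols:
        other = (cohort.data[other_cols] == 1).any(axis=1)
    else:
        other = pd.Series(False, index=cohort.data.index)
    return dep, other


def build_contrast(cohort: CohortTable, kind: str, reporter: str) -> ContrastSample:
    """Construct the unbalanced case/control sets for one contrast kind."""
    if kind not in CONTRAST_KINDS:
        raise ValueError(f"unknown contrast kind {kind!r}; choose from {CONTRAST_KINDS}")
    dep, other = _flags(cohort, reporter)
    ids = cohort.data["id"]

    if kind == "sensitivity":
        pos_mask = dep
        neg_mask = ~dep
    elif kind == "specificity":
        pos_mask = dep
        neg_mask = ~dep & other
    else:  # strict_specificity: any non-depression flag disqualifies a case
        pos_mask = dep & ~other
        neg_mask = ~dep & other

    positives = tuple(ids[pos_mask])
    negatives = tuple(ids[neg_mask])
    if not positives:
        raise ContrastUnconstructibleError(kind, reporter, "positives")
    if not negatives:
        raise ContrastUnconstructibleError(kind, reporter, "negatives")
    return ContrastSample(kind=kind, reporter=reporter, positives=positives, negatives=negatives)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def balance_to_ratio(
    sample: ContrastSample,
    target_ratio: float = DEFAULT_TARGET_RATIO,
    seed: int = 0,
) -> ContrastSample:
    """Subsample controls so positives form ``target_ratio`` of the sample.

    Keeps all positives and draws ``round(n_pos * (1 - r) / r)`` controls
    uniformly without replacement. If the pool is smaller, every control
    is kept and ``ratio_met`` is set to False (all-controls fallback).
    """
    if not 0.0 < target_ratio < 1.0:
        raise ValueError(f"target_ratio must lie strictly in (0, 1), got {target_ratio}")
    if sample.balanced:
        raise ValueError("sample is already balanced")
    n_controls = _round_half_away(sample.n_positives * (1.0 - target_ratio) / target_ratio)
    pool = sorted(sample.negatives)
    if n_controls >= len(pool):
        chosen = tuple(pool)
        ratio_met = n_controls == len(pool)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n_controls, replace=False)
        chosen = tuple(pool[i] for i in sorted(idx))
        ratio_met = True
    return replace(
        sample,
        negatives=chosen,
        target_ratio=target_ratio,
        seed=seed,
        balanced=True,
        ratio_met=ratio_met,
    )
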