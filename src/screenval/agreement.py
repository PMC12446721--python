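"""Cross-informant diagnostic agreement: 2x2 tables and Cohen's kappa.

Parents, children and clinicians frequently disagree about the same
child's diagnosis; in community samples the concordant-positive cell of a
parent x child depression table is typically the smallest. This module
produces those tables and the chance-corrected agreement statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-tabulation of two raters' binary diagnoses.

    Cell names follow (rater A, rater B): ``pos_pos`` is the concordant
    positive cell.
    """

    pos_pos: int
    pos_neg: int
    neg_pos: int
    neg_neg: int
    rater_a: str = "A"
    rater_b: str = "B"

    def __post_init__(self) -> None:
        if min(self.pos_pos, self.pos_neg, self.neg_pos, self.neg_neg) < 0:
            raise ValueError("agreement counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.pos_pos + self.pos_neg + self.neg_pos + self.neg_neg

    def transpose(self) -> "AgreementTable":
        return AgreementTable(
            pos_pos=self.pos_pos,
            pos_neg=self.neg_pos,
            neg_pos=self.pos_neg,
            neg_neg=self.neg_neg,
            rater_a=self.rater_b,
            rater_b=self.rater_a,
        )

    def to_frame(self) -> pd.DataFrame:
        """Rows = rater A +/-, columns = rater B +/-."""
        return pd.DataFrame(
            [[self.pos_pos, self.pos_neg], [self.neg_pos, self.neg_neg]],
            index=[f"{self.rater_a} +", f"{self.rater_a} -"],
            columns=[f"{self.rater_b} +", f"{self.rater_b} -"],
        )


def cross_tabulate(
    dx_a,
    dx_b,
    rater_a: str = "A",
    rater_b: str = "B",
) -> AgreementTable:
    """Exact 2x2 counts between two equal-length binary diagnosis vectors.

    Participants with a missing rating on either side are dropped
    pairwise before counting.
    """
    a = pd.Series(dx_a)
    b = pd.Series(dx_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    keep = a.notna().to_numpy() & b.notna().to_numpy()
    av = a[keep].to_numpy(dtype=int)
    bv = b[keep].to_numpy(dtype=int)
    if not (np.isin(av, (0, 1)).all() and np.isin(bv, (0, 1)).all()):
        raise ValueError("diagnosis vectors must be binary 0/1")
    return AgreementTable(
        pos_pos=int(np.sum((av == 1) & (bv == 1))),
        pos_neg=int(np.sum((av == 1) & (bv == 0))),
        neg_pos=int(np.sum((av == 0) & (bv == 1))),
        neg_neg=int(np.sum((av == 0) & (bv == 0))),
        rater_a=rater_a,
        rater_b=rater_b,
    )


def cohen_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Returns NaN (the undefined marker) when expected agreement p_e = 1,
    i.e. both raters are constant.
    """
    n = table.total
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = (table.pos_pos + table.neg_neg) / n
    a_pos = (table.pos_pos + table.pos_neg) / n
    b_pos = (table.pos_pos + table.neg_pos) / n
    p_e = a_pos * b_pos + (1.0 - a_pos) * (1.0 - b_pos)
    if math.isclose(p_e, 1.0, abs_tol=1e-15):
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)
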