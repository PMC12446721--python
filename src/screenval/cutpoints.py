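"""Exploratory optimal-cutoff selection and confusion-matrix reporting.

A cutoff ``t`` classifies ``score >= t`` as predicted positive. Candidate
cutoffs are the midpoints between adjacent distinct scores plus the two
degenerate rules (-inf: everyone positive; +inf: everyone negative), so
the scan covers every achievable confusion matrix exactly once.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

CRITERIA = ("youden", "closest_topleft")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 classification counts at one cutoff, with derived rates.

    Rates with an empty denominator (e.g. PPV when nothing is predicted
    positive) are NaN.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_positives if self.n_positives else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / self.n_negatives if self.n_negatives else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else math.nan

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def render(self) -> str:
        """2x2 block with labelled margins."""
        buf = io.StringIO()
        buf.write(f"cutoff\t{self.cutoff}\n")
        buf.write("\ttrue+\ttrue-\ttotal\n")
        buf.write(f"pred+\t{self.tp}\t{self.fp}\t{self.tp + self.fp}\n")
        buf.write(f"pred-\t{self.fn}\t{self.tn}\t{self.fn + self.tn}\n")
        buf.write(f"total\t{self.n_positives}\t{self.n_negatives}\t{self.n_positives + self.n_negatives}\n")
        return buf.getvalue()


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    criterion: str
    criterion_value: float
    tied: bool
    confusion: ConfusionMatrix


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def confusion_at(scores, labels, cutoff: float) -> ConfusionMatrix:
    """Confusion counts at one cutoff under the score >= cutoff rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, cutoff=float(cutoff))


def candidate_cutoffs(scores) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus -inf and +inf."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.r_[-np.inf, mids, np.inf]


def optimal_cutoff(scores, labels, criterion: str = "youden") -> CutoffResult:
    """Scan all candidate cutoffs and return the criterion-optimal one.

    Criteria: ``youden`` maximises J = sensitivity + specificity - 1;
    ``closest_topleft`` minimises the Euclidean distance of the ROC point
    to (FPR, TPR) = (0, 1). Ties on the criterion are broken toward
    higher specificity (fewer false positives); if every candidate is
    tied — an uninformative score — the degenerate all-positive cutoff is
    returned with the tie flag set.
    """
    scores, labels = _validate(scores, labels)
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    cands = candidate_cutoffs(scores)
    mats = [confusion_at(scores, labels, c) for c in cands]
    if criterion == "youden":
        vals = np.array([m.youden_j for m in mats])
    else:
        vals = -np.array(
            [math.hypot(1.0 - m.specificity, 1.0 - m.sensitivity) for m in mats]
        )
    best = vals.max()
    tied_idx = np.nonzero(np.isclose(vals, best, rtol=0, atol=1e-12))[0]
    tied = len(tied_idx) > 1
    if len(tied_idx) == len(cands):
        # completely uninformative scan: report the all-positive rule
        pick = 0
    else:
        spec = np.array([mats[i].specificity for i in tied_idx])
        pick = int(tied_idx[int(np.argmax(spec))])
    m = mats[pick]
    value = m.youden_j if criterion == "youden" else float(vals[pick])
    return CutoffResult(
        cutoff=float(cands[pick]),
        criterion=criterion,
        criterion_value=float(value),
        tied=tied,
        confusion=m,
    )
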