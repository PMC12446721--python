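"""AUCROC estimation and bootstrap inference against a fixed threshold.

The AUCROC is computed with the tie-aware (Mann-Whitney) convention:
``P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg)``, which
equals the trapezoidal area under the tie-aware ROC curve. Ties matter
here because integer scale scores guarantee them.

Inference follows the bootstrap-count recipe: the AUCROC is recomputed on
each of ``n_boot`` resamples (1000 by default) and the one-sided p-value
for H0 "performance below threshold" is the number of bootstrap AUCROCs
above the threshold divided by ``n_boot + 1`` (the +1 standing for the
original arrangement of the data, so 1001 at the default). A zero count
is reported as a floor, "<1/(n_boot+1)" — rendered "<0.001" at 1000
iterations. Two-sided p-values double the smaller tail share. Confidence
intervals are percentile intervals with the linear-interpolation quantile
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

DEFAULT_THRESHOLD = 0.8
DEFAULT_N_BOOT = 1000
DEFAULT_CI_LEVEL = 0.95


def _validate_sample(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """Tie-aware AUCROC via the Mann-Whitney rank statistic.

    Equals the probability that a randomly chosen case outscores a
    randomly chosen control, with half credit for ties.
    """
    scores, labels = _validate_sample(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_from_arrays(scores: np.ndarray, labels: np.ndarray) -> float:
    # internal fast path: assumes validated input with both classes
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class RocCurve:
    """Tie-aware ROC curve: one point per distinct threshold plus (0,0)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.fpr, self.tpr):
            if np.any(np.diff(arr) < 0):
                raise ValueError("ROC coordinates must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_points(scores, labels) -> RocCurve:
    """ROC points over all distinct score thresholds (rule: score >= t)."""
    scores, labels = _validate_sample(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # last index of each run of equal scores = counts at threshold "score >= s[i]"
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


@dataclass
class BootstrapAuc:
    """Bootstrap AUCROC distribution plus resampling bookkeeping."""

    values: np.ndarray
    scheme: str
    seed: int
    n_single_class_redraws: int = 0

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.values)


def bootstrap_auc(
    scores,
    labels,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    scheme: str = "stratified",
) -> BootstrapAuc:
    """Bootstrap distribution of the AUCROC.

    ``stratified`` (default) resamples cases and controls separately with
    replacement, preserving class counts — at a 10% positive ratio with
    few cases, joint resampling can produce single-class resamples.
    ``simple`` resamples rows jointly; single-class resamples are skipped
    and redrawn, with the number of redraws counted and reported.
    """
    scores, labels = _validate_sample(scores, labels)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if scheme not in ("stratified", "simple"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n = scores.size
    values = np.empty(n_boot)
    redraws = 0
    if scheme == "stratified":
        pos_idx = np.nonzero(labels == 1)[0]
        neg_idx = np.nonzero(labels == 0)[0]
        for b in range(n_boot):
            take = np.r_[
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
            values[b] = _auc_from_arrays(scores[take], labels[take])
    else:
        for b in range(n_boot):
            while True:
                take = rng.integers(0, n, size=n)
                sub = labels[take]
                if sub.min() != sub.max():
                    break
                redraws += 1
            values[b] = _auc_from_arrays(scores[take], sub)
    return BootstrapAuc(values=values, scheme=scheme, seed=seed, n_single_class_redraws=redraws)


@dataclass(frozen=True)
class PValue:
    """A bootstrap-count p-value with an explicit reporting floor.

    ``value`` is the numeric p; ``at_floor`` marks the zero-count case
    where only the floor ``k/(n_boot+1)`` can be reported (k = 1 one-sided,
    k = 2 two-sided) and the true p is known only to be below it.
    """

    value: float
    at_floor: bool
    denominator: int

    def __str__(self) -> str:
        return f"<{self.value:.3f}" if self.at_floor else f"{self.value:.3f}"

    def __float__(self) -> float:
        return self.value


def p_threshold_one_sided(boot, threshold: float, direction: str = "below") -> PValue:
    """One-sided bootstrap-count p-value against a fixed threshold.

    ``direction='below'`` tests H0 "true performance is below threshold":
    p = #{bootstrap values above threshold} / (n_boot + 1). A small p
    means almost no bootstrap AUCROC crossed the threshold, i.e. evidence
    that performance is below it. ``direction='above'`` mirrors this with
    the count of values below the threshold.
    """
    boot = np.asarray(boot, dtype=float)
    if boot.size == 0:
        raise ValueError("empty bootstrap vector")
    if direction not in ("below", "above"):
        raise ValueError(f"unknown direction {direction!r}")
    denom = boot.size + 1
    count = int((boot > threshold).sum()) if direction == "below" else int((boot < threshold).sum())
    if count == 0:
        return PValue(value=1.0 / denom, at_floor=True, denominator=denom)
    return PValue(value=count / denom, at_floor=False, denominator=denom)


def p_threshold_two_sided(boot, threshold: float) -> PValue:
    """Two-sided p: twice the smaller tail share, same (n_boot+1) denominator."""
    boot = np.asarray(boot, dtype=float)
    if boot.size == 0:
        raise ValueError("empty bootstrap vector")
    denom = boot.size + 1
    n_le = int((boot <= threshold).sum())
    n_ge = int((boot >= threshold).sum())
    smaller = min(n_le, n_ge)
    if smaller == 0:
        return PValue(value=min(1.0, 2.0 / denom), at_floor=True, denominator=denom)
    return PValue(value=min(1.0, 2.0 * smaller / denom), at_floor=False, denominator=denom)


def bootstrap_ci(boot, level: float = DEFAULT_CI_LEVEL) -> tuple[float, float]:
    """Percentile interval (linear-interpolation quantiles)."""
    boot = np.asarray(boot, dtype=float)
    if boot.size == 0:
        raise ValueError("empty bootstrap vector")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(boot, [alpha, 1.0 - alpha], method="linear")
    return float(low), float(high)


@dataclass
class RocResult:
    """One validation row: AUCROC, CI, and threshold-test p-values."""

    auc: float
    n_positives: int
    n_negatives: int
    threshold_tested: float
    ci_level: float
    ci: tuple[float, float]
    p_one_sided: PValue
    p_two_sided: PValue
    n_boot: int
    seed: int
    scheme: str = "stratified"
    boot: BootstrapAuc | None = field(default=None, repr=False)


def roc_test(
    scores,
    labels,
    threshold: float = DEFAULT_THRESHOLD,
    n_boot: int = DEFAULT_N_BOOT,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int = 0,
    scheme: str = "stratified",
    keep_boot: bool = False,
) -> RocResult:
    """Point AUCROC plus bootstrap CI and one-/two-sided threshold tests."""
    scores, labels = _validate_sample(scores, labels)
    point = auc(scores, labels)
    boot = bootstrap_auc(scores, labels, n_boot=n_boot, seed=seed, scheme=scheme)
    return RocResult(
        auc=point,
        n_positives=int(labels.sum()),
        n_negatives=int(labels.size - labels.sum()),
        threshold_tested=threshold,
        ci_level=ci_level,
        ci=bootstrap_ci(boot, level=ci_level),
        p_one_sided=p_threshold_one_sided(boot, threshold, direction="below"),
        p_two_sided=p_threshold_two_sided(boot, threshold),
        n_boot=n_boot,
        seed=seed,
        scheme=scheme,
        boot=boot if keep_boot else None,
    )
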