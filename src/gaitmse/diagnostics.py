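"""Diagnostic-accuracy evaluation of a scalar feature against a binary label.

Given one score per subject (e.g. an entropy value) and patient/control
labels, this module computes:

* ROC area (AUC) as the Mann–Whitney pair statistic, with a DeLong 95%
  confidence interval and a "sufficient discriminative ability" flag at
  AUC >= 0.70;
* confusion counts, sensitivity/specificity, Youden index and F1 at any
  cutoff;
* positive/negative likelihood ratios, Fagan post-test probabilities at an
  arbitrary pretest prevalence, and the diagnostic odds ratio;
* optimal-cutoff selection maximising sensitivity+specificity / Youden / F1,
  with disagreements resolved by the largest PTP+ − PTP− difference.

Cutoffs use a ">= cutoff is positive" convention (or "<=" when lower scores
indicate disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "LabeledScores",
    "RocResult",
    "CutoffReport",
    "roc_auc",
    "cutoff_report",
    "fagan_posttest",
    "select_ocp",
    "confusion_rates",
]

#: AUC threshold for "sufficient overall discriminative ability".
DEFAULT_AUC_THRESHOLD = 0.70


@dataclass(frozen=True)
class LabeledScores:
    """Per-subject scores with binary labels (1 = patient, 0 = control)."""

    scores: np.ndarray
    labels: np.ndarray
    positivity_direction: str = "higher_is_positive"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be 1-D and equal length")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not (np.any(y == 1) and np.any(y == 0)):
            raise ValueError("both classes must be non-empty")
        if self.positivity_direction not in (
            "higher_is_positive", "lower_is_positive",
        ):
            raise ValueError("unknown positivity_direction")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    @property
    def oriented(self) -> np.ndarray:
        """Scores with sign flipped so that higher always means 'positive'."""
        if self.positivity_direction == "higher_is_positive":
            return self.scores
        return -self.scores

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.labels.size


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    sufficient: bool


@dataclass(frozen=True)
class CutoffReport:
    """All diagnostic-accuracy quantities at one candidate cutoff.

    ``dor`` is the exact cross-product ratio, +inf when a denominator cell
    is empty; in that case ``dor_haldane`` carries the finite estimate after
    adding 0.5 to every cell (Haldane–Anscombe correction) and ``zero_cell``
    flags the report.  Likelihood ratios and post-test probabilities always
    use the exact formulas with 0/+inf endpoints.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    youden: float
    f1: float
    lr_pos: float
    lr_neg: float
    ptp_pos: float
    ptp_neg: float
    ptp_diff: float
    dor: float
    prevalence_used: float
    zero_cell: bool = False
    dor_haldane: float = math.nan


def _auc_mann_whitney(oriented: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-aware Mann–Whitney pair statistic via midranks."""
    ranks = stats.rankdata(oriented)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _delong_variance(oriented: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC from midrank placement components."""
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # Placement of each positive among the negatives and vice versa.
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    data: LabeledScores, auc_threshold: float = DEFAULT_AUC_THRESHOLD
) -> RocResult:
    """ROC area with DeLong 95% CI.

    The AUC equals the probability that a randomly drawn patient scores
    more toward the positive direction than a randomly drawn control, ties
    counting one half.
    """
    oriented = data.oriented
    auc = _auc_mann_whitney(oriented, data.labels)
    var = _delong_variance(oriented, data.labels)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci_low = max(0.0, auc - half)
    ci_high = min(1.0, auc + half)
    return RocResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high,
        n_pos=data.n_pos, n_neg=data.n_neg,
        sufficient=bool(auc >= auc_threshold),
    )


def _ptp_from_lr(lr: float, prevalence: float) -> float:
    """Fagan relation: post-test probability from a likelihood ratio."""
    if math.isnan(lr):
        return math.nan
    if math.isinf(lr):
        return 1.0
    odds = prevalence / (1.0 - prevalence)
    post_odds = odds * lr
    return post_odds / (1.0 + post_odds)


def fagan_posttest(
    sens: float, spec: float, prevalence: float
) -> Tuple[float, float]:
    """Post-test probabilities after a positive and a negative test result.

    Pretest odds o = prev/(1−prev) are multiplied by LR+ = sens/(1−spec)
    (or LR− = (1−sens)/spec) and converted back to a probability.  A perfect
    rule-in test (spec = 1, sens > 0) gives PTP+ = 1; a perfect rule-out
    test (sens = 1) gives PTP− = 0.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    if spec == 1.0:
        lr_pos = math.inf if sens > 0 else math.nan
    else:
        lr_pos = sens / (1.0 - spec)
    if sens == 1.0:
        lr_neg = 0.0
    elif spec == 0.0:
        lr_neg = math.inf
    else:
        lr_neg = (1.0 - sens) / spec
    return _ptp_from_lr(lr_pos, prevalence), _ptp_from_lr(lr_neg, prevalence)


def cutoff_report(
    data: LabeledScores, cutoff: float, prevalence: float | None = None
) -> CutoffReport:
    """Full diagnostic-accuracy report at one cutoff.

    A subject is called positive when its score is >= ``cutoff`` (or <=
    when lower scores indicate disease).  ``prevalence`` defaults to the
    sample prevalence.
    """
    if prevalence is None:
        prevalence = data.prevalence
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    oriented = data.oriented
    oriented_cutoff = (
        cutoff if data.positivity_direction == "higher_is_positive" else -cutoff
    )
    called_pos = oriented >= oriented_cutoff
    y = data.labels
    tp = int(np.sum(called_pos & (y == 1)))
    fn = int(np.sum(~called_pos & (y == 1)))
    fp = int(np.sum(called_pos & (y == 0)))
    tn = int(np.sum(~called_pos & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    youden = sens + spec - 1.0
    denom_f1 = 2 * tp + fp + fn
    f1 = 2 * tp / denom_f1 if denom_f1 > 0 else 0.0

    if spec == 1.0:
        lr_pos = math.inf if sens > 0 else math.nan
    else:
        lr_pos = sens / (1.0 - spec)
    if sens == 1.0:
        lr_neg = 0.0
    elif spec == 0.0:
        lr_neg = math.inf
    else:
        lr_neg = (1.0 - sens) / spec
    ptp_pos, ptp_neg = fagan_posttest(sens, spec, prevalence)

    zero_cell = min(tp, fp, tn, fn) == 0
    if fp * fn > 0:
        dor = (tp * tn) / (fp * fn)
    else:
        dor = math.inf if tp * tn > 0 else math.nan
    dor_haldane = math.nan
    if zero_cell:
        dor_haldane = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))

    return CutoffReport(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sens=sens, spec=spec, youden=youden, f1=f1,
        lr_pos=lr_pos, lr_neg=lr_neg,
        ptp_pos=ptp_pos, ptp_neg=ptp_neg,
        ptp_diff=ptp_pos - ptp_neg,
        dor=dor, prevalence_used=float(prevalence),
        zero_cell=zero_cell, dor_haldane=dor_haldane,
    )


def candidate_cutoffs(data: LabeledScores) -> np.ndarray:
    """Midpoints between consecutive distinct scores plus sentinels beyond
    the observed range (everyone positive / everyone negative)."""
    distinct = np.unique(data.scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = distinct[-1] - distinct[0] if distinct.size > 1 else 1.0
    lo = distinct[0] - max(span, 1.0)
    hi = distinct[-1] + max(span, 1.0)
    return np.concatenate([[lo], mids, [hi]])


def select_ocp(
    data: LabeledScores, prevalence: float | None = None
) -> CutoffReport:
    """Optimal cutoff point over the exhaustive candidate sweep.

    Maximisers of sensitivity+specificity, of the Youden index and of F1
    are determined; when they agree on a common cutoff that report is
    returned.  When the criteria disagree, the candidate (among the
    maximisers) with the greatest PTP+ − PTP− difference wins; remaining
    ties go to the higher specificity, then to the lower cutoff value.
    """
    reports = [cutoff_report(data, c, prevalence) for c in candidate_cutoffs(data)]
    eps = 1e-12
    max_youden = max(r.youden for r in reports)
    max_f1 = max(r.f1 for r in reports)
    # sens+spec and Youden rank cutoffs identically (offset by 1).
    youden_set = [r for r in reports if r.youden >= max_youden - eps]
    f1_set = [r for r in reports if r.f1 >= max_f1 - eps]
    common = [r for r in youden_set if r.f1 >= max_f1 - eps]
    pool = common if common else youden_set + [r for r in f1_set if r not in youden_set]

    def preference(r: CutoffReport):
        ptp_diff = r.ptp_diff if not math.isnan(r.ptp_diff) else -math.inf
        return (ptp_diff, r.spec, -r.cutoff)

    return max(pool, key=preference)


def confusion_rates(report: CutoffReport) -> Tuple[float, float, float, float]:
    """(TPR, TNR, FPR, FNR) of a cutoff report."""
    return report.sens, report.spec, 1.0 - report.spec, 1.0 - report.sens
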