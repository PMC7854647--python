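"""ROC construction over patient scores and operating-cutoff selection.

Low scores (sparse lymphocytic infiltrate) predict death from melanoma, so
the ROC is oriented as ``score < threshold`` => predicted died.  Candidate
thresholds are the midpoints between consecutive sorted unique scores plus
-inf/+inf sentinels, so the chosen cutoff never coincides with an observed
score and boundary classification on the training set is unambiguous.

The selection criterion is Youden's J = sensitivity + specificity - 1 by
default (the standard reading of "most accurately distinguishing"); raw
accuracy and closest-to-(0,1) are available so the cutoff's sensitivity to
the criterion can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["RocResult", "roc_curve", "select_cutoff"]


@dataclass(frozen=True)
class RocResult:
    """Sensitivity/specificity sweep with the Youden-optimal cutoff.

    ``thresholds`` is ascending; at threshold t a patient is predicted to
    die of melanoma iff their score is strictly below t.  ``auc`` is the
    trapezoid area over (1 - specificity, sensitivity), which equals the
    probability that a random decedent scores below a random survivor
    (ties counted half).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_cutoff: float
    n_pos: int
    n_neg: int

    @property
    def youden_j(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_curve(scores, died) -> RocResult:
    """ROC of per-patient scores against the died-of-melanoma label.

    Parameters
    ----------
    scores : per-patient ADTA values.
    died : binary labels, 1 = died of melanoma.

    Raises
    ------
    ValueError
        If only one label class is present, or fewer than two distinct
        scores ("degenerate ROC").
    """
    scores = np.asarray(scores, dtype=float)
    died = np.asarray(died, dtype=int)
    if scores.shape != died.shape or scores.ndim != 1:
        raise ValueError("scores and died must be 1-d arrays of equal length")
    if not (np.any(died == 1) and np.any(died == 0)):
        raise ValueError("degenerate ROC: both label classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("degenerate ROC: need at least 2 distinct scores")

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    n_pos = int((died == 1).sum())
    n_neg = int((died == 0).sum())
    pred = scores[None, :] < thresholds[:, None]  # (t, n): predicted died
    sens = (pred & (died == 1)).sum(axis=1) / n_pos
    spec = (~pred & (died == 0)).sum(axis=1) / n_neg

    # trapezoid over the ROC polyline; thresholds ascend so FPR ascends too
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    chosen = _argmax_criterion(thresholds, sens, spec, n_pos, n_neg, "youden")
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        chosen_cutoff=float(thresholds[chosen]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


Criterion = Literal["youden", "accuracy", "closest_topleft"]


def _argmax_criterion(
    thresholds: np.ndarray,
    sens: np.ndarray,
    spec: np.ndarray,
    n_pos: int,
    n_neg: int,
    criterion: Criterion,
) -> int:
    if criterion == "youden":
        value = sens + spec - 1.0
    elif criterion == "accuracy":
        value = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    elif criterion == "closest_topleft":
        value = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    # ties broken toward the smaller threshold: fewer patients called
    # high-risk.  argmax returns the first maximum on the ascending grid.
    return int(np.argmax(value))


def select_cutoff(roc: RocResult, criterion: Criterion = "youden") -> float:
    """The operating cutoff: candidate threshold maximizing the criterion.

    The -inf sentinel (call nobody high-risk) wins only when no finite
    candidate beats J = 0, i.e. the scores carry no usable signal.
    """
    idx = _argmax_criterion(
        roc.thresholds, roc.sensitivity, roc.specificity,
        roc.n_pos, roc.n_neg, criterion,
    )
    return float(roc.thresholds[idx])
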