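"""ROC curves and AUC, pooled and stratified by family.

AUC is the Mann–Whitney probability that a randomly chosen positive scores
above a randomly chosen negative, with ties counted one half — equivalently
the trapezoidal area under the tie-grouped ROC curve.  Values above 0.70 are
conventionally regarded as clinically relevant classifiers and are flagged
as such in reports (an annotation, not a gate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from mifhh.exceptions import UndefinedStatisticError

logger = logging.getLogger(__name__)

#: AUC above which a classifier is conventionally deemed clinically relevant
CLINICAL_AUC_THRESHOLD = 0.70


@dataclass
class RocCurve:
    """Tie-grouped ROC curve with its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def clinically_relevant(self) -> bool:
        return self.auc > CLINICAL_AUC_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and Mann–Whitney AUC for binary labels.

    Requires at least one positive and one negative label; single-class
    input raises :class:`UndefinedStatisticError`.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise UndefinedStatisticError(
            "AUC undefined: labels contain a single class"
        )
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def family_stratified_roc(
    scores, labels, family_ids
) -> tuple[dict[str, RocCurve], RocCurve]:
    """Per-family ROC curves plus the pooled curve.

    Families whose labels are single-class (all affected or all unaffected)
    cannot support an ROC and are skipped with a log entry; the pooled curve
    over all rows is always returned.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    family_ids = np.asarray(family_ids)
    if not (scores.shape == labels.shape == family_ids.shape):
        raise ValueError("scores, labels and family_ids must have equal length")
    per_family: dict[str, RocCurve] = {}
    for fam in pd.unique(family_ids):
        mask = family_ids == fam
        try:
            per_family[str(fam)] = roc_auc(scores[mask], labels[mask])
        except UndefinedStatisticError:
            logger.info("family %s skipped: single-class labels", fam)
    pooled = roc_auc(scores, labels)
    return per_family, pooled
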