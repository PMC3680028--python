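"""Scoring predicted complexes against a reference catalog.

Implements the standard complex-level metrics: Jaccard match score with a
threshold alpha for complex-level recall/precision/F1; the clustering-wise
sensitivity (Sn), positive predictive value (PPV) and their geometric mean
(Acc) from the reference x prediction confusion matrix; and the maximum
matching ratio (MMR), the total Jaccard weight of a maximum-weight
one-to-one reference-prediction assignment divided by the number of
reference complexes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from pewcc.ppi_graph import ComplexSet

logger = logging.getLogger("pewcc")


@dataclass
class ConfusionMatrix:
    """t[i, j] = number of proteins shared by reference i and prediction j."""

    t: np.ndarray
    row_sizes: np.ndarray  # n_i = size of reference complex i


@dataclass
class EvaluationReport:
    alpha: float
    matched_ref: int
    matched_pred: int
    rec: float
    prec: float
    f1: float
    sn: float
    ppv: float
    acc: float
    mmr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "matched_ref": self.matched_ref,
            "matched_pred": self.matched_pred,
            "rec": self.rec,
            "prec": self.prec,
            "f1": self.f1,
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
            "mmr": self.mmr,
        }


def match_score(k: frozenset[str] | set[str], r: frozenset[str] | set[str]) -> float:
    """Jaccard index |K n R| / |K u R| between two complexes."""
    if not k or not r:
        raise ValueError("match score undefined for empty complexes")
    return len(set(k) & set(r)) / len(set(k) | set(r))


def recall_precision(
    refs: ComplexSet,
    preds: ComplexSet,
    alpha: float = 0.25,
) -> tuple[float, float, float, int, int]:
    """Complex-level recall, precision and F1 at match threshold ``alpha``.

    A reference counts as matched when some prediction reaches Jaccard
    >= alpha against it, and vice versa.  Returns
    (rec, prec, f1, matched_ref, matched_pred); empty catalogs make the
    corresponding metric 0 by convention.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if len(refs) == 0 or len(preds) == 0:
        logger.warning("empty catalog: recall/precision fall back to 0")
    matched_ref = sum(
        1 for r in refs if any(match_score(k, r) >= alpha for k in preds)
    )
    matched_pred = sum(
        1 for k in preds if any(match_score(k, r) >= alpha for r in refs)
    )
    rec = matched_ref / len(refs) if len(refs) else 0.0
    prec = matched_pred / len(preds) if len(preds) else 0.0
    f1 = (2.0 * prec * rec / (prec + rec)) if (prec + rec) > 0 else 0.0
    return rec, prec, f1, matched_ref, matched_pred


def confusion(refs: ComplexSet, preds: ComplexSet) -> ConfusionMatrix:
    """Exact intersection counts between every reference and prediction."""
    t = np.zeros((len(refs), len(preds)), dtype=np.int64)
    for i, r in enumerate(refs):
        for j, k in enumerate(preds):
            t[i, j] = len(r & k)
    return ConfusionMatrix(t=t, row_sizes=np.array([len(r) for r in refs], dtype=np.int64))


def sn_ppv_acc(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, PPV and their geometric mean.

    Sn = sum_i max_j t_ij / sum_i n_i;  PPV = sum_j max_i t_ij / sum_ij t_ij;
    Acc = sqrt(Sn * PPV).  A prediction overlapping no reference contributes
    0 to both PPV sums; if nothing overlaps at all, PPV and Acc are 0.
    """
    if cm.t.size == 0:
        raise ValueError("confusion matrix must have at least one row and column")
    sn = float(cm.t.max(axis=1).sum() / cm.row_sizes.sum())
    total = cm.t.sum()
    if total == 0:
        logger.warning("no reference/prediction overlap at all: PPV = Acc = 0")
        return sn, 0.0, 0.0
    ppv = float(cm.t.max(axis=0).sum() / total)
    return sn, ppv, math.sqrt(sn * ppv)


def mmr(refs: ComplexSet, preds: ComplexSet) -> float:
    """Maximum matching ratio.

    Builds the complete bipartite graph refs x preds weighted by Jaccard
    match score, finds a maximum-total-weight one-to-one assignment, and
    divides the matched weight by the number of reference complexes.
    Zero-weight pairs contribute nothing, so whether they are formally
    "matched" is immaterial.
    """
    if len(refs) == 0:
        raise ValueError("MMR undefined without reference complexes")
    if len(preds) == 0:
        return 0.0
    weights = np.array([[match_score(k, r) for k in preds] for r in refs])
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return float(weights[rows, cols].sum() / len(refs))


def evaluate(refs: ComplexSet, preds: ComplexSet, alpha: float = 0.25) -> EvaluationReport:
    """All metrics in one report: Rec/Prec/F1 at ``alpha``, Sn/PPV/Acc, MMR."""
    rec, prec, f1, matched_ref, matched_pred = recall_precision(refs, preds, alpha)
    if len(refs) and len(preds):
        sn, ppv, acc = sn_ppv_acc(confusion(refs, preds))
        ratio = mmr(refs, preds)
    else:
        sn = ppv = acc = ratio = 0.0
    return EvaluationReport(
        alpha=alpha,
        matched_ref=matched_ref,
        matched_pred=matched_pred,
        rec=rec,
        prec=prec,
        f1=f1,
        sn=sn,
        ppv=ppv,
        acc=acc,
        mmr=ratio,
    )
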