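"""Alignment-quality metrics: agreement/reliability, confidence-stratified
accuracy, triplet consistency, and ROC/PRC classifier evaluation.

These metrics compare a produced pairwise alignment against a reference
(gold-standard or profile-based) alignment, measure the self-consistency of
three alignments over a protein triplet, and score how well a similarity
score separates homologous from non-homologous pairs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn import metrics as _skm

from .types import Alignment

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ReferenceAlignment:
    """A reference pairwise alignment, optionally with per-position
    confidence digits (0-9, profile-alignment style)."""

    pairs: Alignment
    confidence: np.ndarray | None = None

    def __post_init__(self):
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=int)
            if len(self.confidence) != len(self.pairs):
                raise ValueError("confidence length must equal the number of "
                                 "aligned pairs")


@dataclasses.dataclass
class EvalResult:
    n_correct: int
    agreement: float
    reliability: float
    l_ref: int
    l_ali: int


@dataclasses.dataclass
class TripletResult:
    n_consist: int
    al: int
    cov: float
    rate: float


@dataclasses.dataclass
class ClassifierEval:
    auc: float
    auprc: float
    roc_points: np.ndarray   # (k, 2): FPrate, Recall
    prc_points: np.ndarray   # (k, 2): Recall, Precision


def agreement_reliability(test: Alignment,
                          ref: ReferenceAlignment) -> EvalResult:
    """Agreement = Nc/L_ref and reliability = Nc/L_ali, with Nc the number
    of exactly-matching aligned pairs.  Gap positions carry no pairs and are
    thereby excluded.  Empty alignments give 0 with a warning."""
    ref_set = set(map(tuple, ref.pairs.pairs.tolist()))
    test_set = set(map(tuple, test.pairs.tolist()))
    n_c = len(ref_set & test_set)
    l_ref = len(ref_set)
    l_ali = len(test_set)
    if l_ref == 0 or l_ali == 0:
        logger.warning("empty alignment in evaluation; metrics set to 0")
    return EvalResult(
        n_correct=n_c,
        agreement=n_c / l_ref if l_ref else 0.0,
        reliability=n_c / l_ali if l_ali else 0.0,
        l_ref=l_ref,
        l_ali=l_ali,
    )


def aq(test: Alignment, ref: ReferenceAlignment, x: int) -> float | None:
    """AQ(x): fraction of reference positions with confidence >= x that the
    test alignment recovers exactly.  None when no reference position meets
    the threshold."""
    if ref.confidence is None:
        raise ValueError("reference has no confidence values; "
                         "use agreement_reliability instead")
    keep = ref.confidence >= x
    n = int(keep.sum())
    if n == 0:
        return None
    test_set = set(map(tuple, test.pairs.tolist()))
    cr = sum(1 for p in ref.pairs.pairs[keep].tolist() if tuple(p) in test_set)
    return cr / n


def aq_profile(test: Alignment, ref: ReferenceAlignment,
               thresholds=range(10)) -> dict[int, float | None]:
    return {x: aq(test, ref, x) for x in thresholds}


def triplet_consistency(aln_ab: Alignment, aln_bc: Alignment,
                        aln_ca: Alignment, n_a: int, n_b: int,
                        n_c: int) -> TripletResult:
    """Consistency of three pairwise alignments over proteins A, B, C.

    A position i of A is *commonly aligned* (counted in AL) when its A-B
    partner j is aligned in B-C and i itself is aligned in C-A; it is
    *consistent* when additionally the cycle closes: the C-A alignment maps
    the B-C partner k back to i.  Cov normalises by the smallest protein,
    Rate by AL.
    """
    ab = {int(ia): int(ib) for ia, ib in aln_ab.pairs}
    bc = {int(ib): int(ic) for ib, ic in aln_bc.pairs}
    ca = {int(ic): int(ia) for ic, ia in aln_ca.pairs}
    a_in_ca = set(ca.values())
    al = 0
    n_consist = 0
    for i, j in ab.items():
        k = bc.get(j)
        if k is None:
            continue
        if i in a_in_ca:
            al += 1
        if ca.get(k) == i:
            n_consist += 1
    if al == 0:
        logger.warning("no commonly aligned positions; Rate set to 0")
    return TripletResult(
        n_consist=n_consist,
        al=al,
        cov=n_consist / min(n_a, n_b, n_c),
        rate=n_consist / al if al else 0.0,
    )


def roc_prc(scores, labels) -> ClassifierEval:
    """ROC and precision-recall evaluation of a similarity score.

    ``labels`` are truthy for positive (same-class) pairs.  AUC is the
    trapezoidal area under (FPrate, Recall); AUPRC is the step-wise
    (right-continuous) area under (Recall, Precision).  Tied scores share a
    threshold.  Requires at least one positive and one negative.
    """
    y = np.asarray([bool(v) for v in labels])
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    return ClassifierEval(
        auc=float(_skm.auc(fpr, tpr)),
        auprc=float(_skm.average_precision_score(y, s)),
        roc_points=np.column_stack([fpr, tpr]),
        prc_points=np.column_stack([recall, precision])[::-1],
    )
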