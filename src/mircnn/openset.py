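"""Open-set rejection on the maximum softmax probability.

An in-distribution query typically concentrates softmax mass on one
family while out-of-distribution inputs (other ncRNAs, unseen families)
spread it, so thresholding the maximum softmax value rejects them. The
threshold is chosen from score distributions by ROC analysis, either at a
target false-positive rate or by maximizing the F-score of the accept
decision. "Positive" throughout means the in-distribution accept:
FPR = FP/(FP+TN) is the fraction of decoys accepted, TPR = TP/(TP+FN)
the fraction of genuine members accepted; a score >= threshold accepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .training import DEFAULT_SOFTMAX_THRESHOLD, TrainedClassifier

REJECTED_LABEL = "rejected"


@dataclass(frozen=True)
class ScoredPrediction:
    seq_id: str
    family: str
    max_prob: float
    accepted: bool = True


@dataclass
class RocCurve:
    """Accept/reject ROC: thresholds descending, (fpr, tpr) non-decreasing."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def max_softmax_scores(
    classifier: TrainedClassifier,
    X: np.ndarray,
    seq_ids: list[str] | None = None,
) -> list[ScoredPrediction]:
    """Thresholdless scores: max softmax value and argmax family per input."""
    probs = classifier.predict_proba(X)
    families = classifier.families
    ids = seq_ids or [f"seq{i}" for i in range(len(probs))]
    return [
        ScoredPrediction(sid, families[int(p.argmax())], float(p.max()))
        for sid, p in zip(ids, probs)
    ]


def roc(pos_scores, neg_scores) -> RocCurve:
    """ROC of the accept decision over all distinct scores as thresholds.

    Thresholds sweep from a sentinel above every score (reject all,
    (0,0)) down to a sentinel below (accept all, (1,1)); AUC by the
    trapezoid rule, which splits ties evenly.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    scores = np.unique(np.concatenate([pos, neg]))[::-1]
    hi = scores[0] + 1.0
    lo = scores[-1] - 1.0
    thresholds = np.concatenate([[hi], scores, [lo]])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc)


def choose_threshold(
    curve: RocCurve,
    target_fpr: float | None = None,
    max_fscore: tuple[int, int] | None = None,
) -> float:
    """Pick an operating threshold from an ROC curve.

    ``target_fpr`` — the smallest threshold with FPR <= target (i.e. the
    most permissive acceptable point); if only the reject-all sentinel
    qualifies, it is returned with a warning. ``max_fscore=(n_pos,
    n_neg)`` — the threshold maximizing the F-score of the accept
    decision, ties resolved toward the larger threshold.
    """
    if (target_fpr is None) == (max_fscore is None):
        raise ValueError("pass exactly one of target_fpr or max_fscore")
    if target_fpr is not None:
        ok = np.flatnonzero(curve.fpr <= target_fpr)
        if ok.size == 0:
            raise ValueError("even the reject-all threshold exceeds the target FPR")
        idx = int(ok[-1])  # thresholds descend: last qualifying = smallest threshold
        if idx == 0 and curve.tpr[0] == 0.0:
            warnings.warn(
                "only the degenerate reject-all threshold meets the FPR target",
                stacklevel=2,
            )
        return float(curve.thresholds[idx])
    n_pos, n_neg = max_fscore
    best_t, best_f = None, -1.0
    for t, fp_rate, tp_rate in zip(curve.thresholds, curve.fpr, curve.tpr):
        tp = tp_rate * n_pos
        fp = fp_rate * n_neg
        fn = n_pos - tp
        denom = 2 * tp + fp + fn
        f = 2 * tp / denom if denom > 0 else 0.0
        if f > best_f:  # thresholds descend, so strict > keeps the larger tie
            best_f, best_t = f, float(t)
    return best_t


def predict_with_rejection(
    classifier: TrainedClassifier,
    X: np.ndarray,
    threshold: float | None = None,
    seq_ids: list[str] | None = None,
) -> list[ScoredPrediction]:
    """Classify with rejection: max_prob < threshold -> the reserved
    ``rejected`` label; accept at equality."""
    if threshold is None:
        threshold = classifier.rejection_threshold
    if not (0.0 <= threshold <= 1.0 + 1e-12):
        raise ValueError("threshold must be in [0, 1]")
    out = []
    for sp in max_softmax_scores(classifier, X, seq_ids):
        accepted = sp.max_prob >= threshold
        out.append(
            ScoredPrediction(
                sp.seq_id, sp.family if accepted else REJECTED_LABEL,
                sp.max_prob, accepted,
            )
        )
    return out


def write_scores_tsv(preds: list[ScoredPrediction], path) -> None:
    with open(path, "w") as fh:
        for p in preds:
            fh.write(f"{p.seq_id}\t{p.family}\t{p.max_prob:.6f}\t{int(p.accepted)}\n")


def write_roc_tsv(curve: RocCurve, path) -> None:
    with open(path, "w") as fh:
        for t, f, s in zip(curve.thresholds, curve.fpr, curve.tpr):
            fh.write(f"{t:.6f}\t{f:.6f}\t{s:.6f}\n")
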