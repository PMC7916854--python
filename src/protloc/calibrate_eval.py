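"""Per-class threshold calibration and the multi-label evaluation suite.

Calibration scans, independently per class, all confidence cutoffs on a
0.01 grid and keeps the one maximizing the dice coefficient
2TP/(2TP+FP+FN) of the binarized predictions against the training
labels (ties break to the smallest cutoff).  The evaluation suite
computes:

* a 13x13 multi-label confusion matrix — a correctly found label counts
  on the diagonal; a missed true label "gets a hit" from every predicted
  false positive of the same sample; rows are normalized by the number
  of samples carrying the true class;
* the unweighted mean of the normalized diagonal (class-average
  accuracy) and the unweighted mean of per-class dice;
* accuracy stratified by the number of simultaneous localizations
  (1-4), where "correct" is by default an exact set match;
* the class co-occurrence matrix (row-conditional fractions);
* dice stratified by cell-line group, with minority groups pooled into
  an "other" group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classes import CLASS_CODES, N_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "ConfusionMatrix",
    "EvalReport",
    "dice_for_class",
    "calibrate_thresholds",
    "apply_thresholds",
    "multilabel_confusion",
    "mean_diag_accuracy",
    "per_class_dice",
    "accuracy_by_multiloc",
    "cooccurrence_matrix",
    "groupwise_dice",
    "evaluate",
    "THRESHOLD_GRID",
]

THRESHOLD_GRID = np.round(np.arange(0, 101) * 0.01, 2)


@dataclass
class ThresholdSet:
    """Per-class confidence cutoffs on the 0.01 grid."""

    thresholds: np.ndarray

    def validate(self) -> None:
        t = np.asarray(self.thresholds)
        if t.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} thresholds")
        if not np.allclose(np.round(t * 100), t * 100):
            raise ValueError("thresholds must lie on the 0.01 grid")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray       # (13, 13) int
    row_totals: np.ndarray   # (13,) samples containing the true class

    @property
    def normalized(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.row_totals[:, None] > 0,
                self.counts / self.row_totals[:, None],
                np.nan,
            )


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    per_class_dice: np.ndarray
    mean_diag_accuracy: float
    mean_dice: float
    by_multiloc: dict[int, dict]
    cooccurrence: np.ndarray
    by_group_dice: dict[str, float] | None = None
    thresholds: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "class_order": list(CLASS_CODES),
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_normalized": np.nan_to_num(self.confusion.normalized, nan=-1.0).tolist(),
            "row_totals": self.confusion.row_totals.tolist(),
            "per_class_dice": self.per_class_dice.tolist(),
            "mean_diag_accuracy": self.mean_diag_accuracy,
            "mean_dice": self.mean_dice,
            "by_multiloc": {
                str(k): v for k, v in self.by_multiloc.items()
            },
            "cooccurrence": self.cooccurrence.tolist(),
            "by_group_dice": self.by_group_dice,
            "thresholds": None if self.thresholds is None else self.thresholds.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def dice_for_class(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN) over sample-level presence calls.

    Returns 0 when the denominator is 0 (class never present and never
    predicted), the conservative convention for rare classes.
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    denom = 2 * tp + fp + fn
    return 2.0 * tp / denom if denom else 0.0


def calibrate_thresholds(
    confidences: np.ndarray, truths: np.ndarray, grid_step: float = 0.01
) -> ThresholdSet:
    """Per-class exhaustive scan of the threshold grid, maximizing dice.

    A class is called present when confidence >= threshold.  Ties break
    to the smallest grid value.
    """
    conf = np.asarray(confidences, dtype=float)
    truth = np.asarray(truths).astype(bool)
    if conf.ndim != 2 or conf.shape != truth.shape:
        raise ValueError("confidences and truths must be matching (n, 13) arrays")
    if conf.shape[0] < 1:
        raise ValueError("need at least one sample")
    grid = np.round(np.arange(0, int(round(1 / grid_step)) + 1) * grid_step, 10)
    thresholds = np.zeros(conf.shape[1])
    for c in range(conf.shape[1]):
        pred = conf[:, c][:, None] >= grid[None, :]          # (n, grid)
        tp = (pred & truth[:, c][:, None]).sum(axis=0)
        fp = (pred & ~truth[:, c][:, None]).sum(axis=0)
        fn = (~pred & truth[:, c][:, None]).sum(axis=0)
        denom = 2 * tp + fp + fn
        dice = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
        thresholds[c] = grid[int(np.argmax(dice))]           # first max = smallest
    return ThresholdSet(thresholds)


def apply_thresholds(confidences: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Binary (n, 13) presence calls: present iff confidence >= threshold."""
    t = np.asarray(thresholds.thresholds)
    return (np.asarray(confidences) >= t[None, :]).astype(np.int8)


def _as_sets(label_matrix_or_sets) -> list[frozenset[int]]:
    """Accept either a binary (n, 13) matrix or a list of index/code sets."""
    out: list[frozenset[int]] = []
    if isinstance(label_matrix_or_sets, np.ndarray) and label_matrix_or_sets.ndim == 2:
        for row in label_matrix_or_sets:
            out.append(frozenset(int(i) for i in np.flatnonzero(row)))
        return out
    for entry in label_matrix_or_sets:
        s = set()
        for item in entry:
            if isinstance(item, (int, np.integer)):
                s.add(int(item))
            else:
                s.add(CLASS_CODES.index(item))
        out.append(frozenset(s))
    return out


def multilabel_confusion(true_sets, predicted_sets) -> ConfusionMatrix:
    """Multi-label confusion matrix with the missed-label attribution rule.

    Per sample with true set T and predicted set P: every c in T∩P adds
    one diagonal count at (c, c); every missed label c in T\\P receives
    one off-diagonal count at (c, c') for each false positive c' in P\\T.
    Row totals count samples containing the true class.
    """
    T = _as_sets(true_sets)
    P = _as_sets(predicted_sets)
    if len(T) != len(P):
        raise ValueError("true and predicted lists differ in length")
    if len(T) == 0:
        raise ValueError("empty sample list")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    row_totals = np.zeros(N_CLASSES, dtype=int)
    for t, p in zip(T, P):
        for c in t:
            row_totals[c] += 1
        for c in t & p:
            counts[c, c] += 1
        for c in t - p:
            for fp in p - t:
                counts[c, fp] += 1
    return ConfusionMatrix(counts, row_totals)


def mean_diag_accuracy(confusion: ConfusionMatrix) -> float:
    """Unweighted mean of the normalized diagonal over represented classes.

    Classes absent from the truth (row total 0) are excluded with a
    logged warning.
    """
    included = confusion.row_totals > 0
    if not included.any():
        raise ValueError("no class is represented in the truth")
    if not included.all():
        missing = [CLASS_CODES[i] for i in np.flatnonzero(~included)]
        logger.warning("classes absent from truth excluded from mean: %s", missing)
    diag = np.diag(confusion.counts)[included] / confusion.row_totals[included]
    return float(diag.mean())


def per_class_dice(predicted: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Dice per class over binary (n, 13) prediction/truth matrices."""
    predicted = np.asarray(predicted)
    truths = np.asarray(truths)
    return np.array(
        [dice_for_class(predicted[:, c], truths[:, c]) for c in range(truths.shape[1])]
    )


def accuracy_by_multiloc(
    true_sets, predicted_sets, rule: str = "exact"
) -> dict[int, dict]:
    """Correct fraction stratified by localization count k = 1..4.

    ``rule='exact'``: correct iff the predicted set equals the true set.
    ``rule='all_found'``: correct iff every true label was predicted
    (false positives allowed).  Strata with no samples report NaN.
    """
    if rule not in ("exact", "all_found"):
        raise ValueError("rule must be 'exact' or 'all_found'")
    T = _as_sets(true_sets)
    P = _as_sets(predicted_sets)
    out: dict[int, dict] = {}
    for k in (1, 2, 3, 4):
        members = [(t, p) for t, p in zip(T, P) if len(t) == k]
        if not members:
            out[k] = {"n": 0, "correct_fraction": float("nan")}
            continue
        if rule == "exact":
            good = sum(1 for t, p in members if t == p)
        else:
            good = sum(1 for t, p in members if t <= p)
        out[k] = {"n": len(members), "correct_fraction": good / len(members)}
    return out


def cooccurrence_matrix(true_sets) -> np.ndarray:
    """Entry (r, c) = fraction of samples with class r that also carry c."""
    T = _as_sets(true_sets)
    if len(T) == 0:
        raise ValueError("empty sample list")
    both = np.zeros((N_CLASSES, N_CLASSES))
    totals = np.zeros(N_CLASSES)
    for t in T:
        for r in t:
            totals[r] += 1
            for c in t:
                both[r, c] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals[:, None] > 0, both / totals[:, None], 0.0)


def groupwise_dice(
    confidences: np.ndarray,
    truths: np.ndarray,
    thresholds: ThresholdSet,
    group_tags: list[str],
    major_groups: list[str] | None = None,
) -> dict[str, float]:
    """Unweighted mean dice per cell-line group.

    ``major_groups`` (default: every tag covering >= 10% of samples)
    are reported individually; all remaining samples pool into "other".
    Classes absent from a group's truth are excluded from that group's
    mean.
    """
    tags = np.asarray(group_tags)
    if len(tags) != len(truths):
        raise ValueError("group tags must align with samples")
    pred = apply_thresholds(confidences, thresholds)
    truths = np.asarray(truths)
    if major_groups is None:
        uniq, counts = np.unique(tags, return_counts=True)
        major_groups = [str(u) for u, c in zip(uniq, counts) if c / len(tags) >= 0.10]
    out: dict[str, float] = {}
    groups = {g: tags == g for g in major_groups}
    pooled = ~np.logical_or.reduce(list(groups.values())) if groups else np.ones(len(tags), bool)
    if pooled.any():
        groups["other"] = pooled
    for name, mask in groups.items():
        d = per_class_dice(pred[mask], truths[mask])
        present = truths[mask].sum(axis=0) > 0
        out[name] = float(d[present].mean()) if present.any() else float("nan")
    return out


def evaluate(
    confidences: np.ndarray,
    truths: np.ndarray,
    thresholds: ThresholdSet,
    group_tags: list[str] | None = None,
    multiloc_rule: str = "exact",
) -> EvalReport:
    """Full evaluation of thresholded confidences against multi-label truth."""
    truths = np.asarray(truths)
    pred = apply_thresholds(confidences, thresholds)
    confusion = multilabel_confusion(truths, pred)
    dice = per_class_dice(pred, truths)
    present = truths.sum(axis=0) > 0
    report = EvalReport(
        confusion=confusion,
        per_class_dice=dice,
        mean_diag_accuracy=mean_diag_accuracy(confusion),
        mean_dice=float(dice[present].mean()),
        by_multiloc=accuracy_by_multiloc(truths, pred, rule=multiloc_rule),
        cooccurrence=cooccurrence_matrix(truths),
        by_group_dice=None
        if group_tags is None
        else groupwise_dice(confidences, truths, thresholds, group_tags),
        thresholds=np.asarray(thresholds.thresholds),
    )
    return report
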