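"""Pixel-level evaluation: fixed-threshold binarisation, confusion counts,
accuracy / Dice / sensitivity / specificity, and ROC AUC.

Vessel pixels are the positive class.  The evaluation domain defaults to
the whole (cropped) image; pass a field-of-view mask to restrict counting
to retinal content.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    acc: float
    dsc: float
    se: float
    sp: float
    auc: float | None = None
    threshold: float = 0.5
    domain: str = "full"
    degenerate: bool = False
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: pixels strictly exceeding the threshold become 1."""
    return (np.asarray(prob) > threshold).astype(np.uint8)


def confusion(pred: np.ndarray, truth: np.ndarray,
              domain: np.ndarray | None = None) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if domain is not None:
        sel = np.asarray(domain).astype(bool)
        if sel.shape != pred.shape:
            raise ValueError("domain mask dims differ from prediction dims")
        pred, truth = pred[sel], truth[sel]
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(c: ConfusionCounts, threshold: float = 0.5,
                    domain: str = "full") -> MetricsReport:
    """Acc / DSC / Se / Sp from confusion counts.

    Undefined ratios (zero denominator) are reported as 0 with the
    ``degenerate`` flag set.
    """
    if c.n == 0:
        return MetricsReport(0.0, 0.0, 0.0, 0.0, None, threshold, domain,
                             degenerate=True, counts=c)
    acc = (c.tp + c.tn) / c.n
    dsc, d1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    se, d2 = _ratio(c.tp, c.tp + c.fn)
    sp, d3 = _ratio(c.tn, c.tn + c.fp)
    return MetricsReport(acc, dsc, se, sp, None, threshold, domain,
                         degenerate=d1 or d2 or d3, counts=c)


def roc_auc(prob: np.ndarray, truth: np.ndarray,
            domain: np.ndarray | None = None) -> float:
    """Area under the ROC curve over all score thresholds.

    Equals the rank statistic: the probability that a random vessel pixel
    outscores a random background pixel, ties counted one half.  Raises if
    the truth contains a single class (AUC undefined).
    """
    scores = np.asarray(prob, dtype=np.float64).ravel()
    labels = np.asarray(truth).astype(bool).ravel()
    if domain is not None:
        sel = np.asarray(domain).astype(bool).ravel()
        scores, labels = scores[sel], labels[sel]
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: ground truth contains a single class")
    return float(roc_auc_score(labels, scores))


def evaluate_probability_map(prob: np.ndarray, truth: np.ndarray,
                             threshold: float = 0.5,
                             domain: np.ndarray | None = None) -> MetricsReport:
    """Threshold a probability map and report all five metrics."""
    c = confusion(binarize(prob, threshold), truth, domain)
    report = compute_metrics(c, threshold,
                             "fov" if domain is not None else "full")
    truth_arr = np.asarray(truth).astype(bool)
    sel = truth_arr if domain is None else truth_arr[np.asarray(domain).astype(bool)]
    if sel.any() and not sel.all():
        report.auc = roc_auc(prob, truth, domain)
    return report
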