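"""Multi-label evaluation metrics.

Overall metrics over observed/predicted label *sets* (per sample, then
averaged):

* aiming      — |L ∩ L*| / |L*|   (precision-like)
* coverage    — |L ∩ L*| / |L|    (recall-like)
* accuracy    — |L ∩ L*| / |L ∪ L*|  (Jaccard)
* absolute true  — 1 if L == L* else 0
* absolute false — (|L ∪ L*| - |L ∩ L*|) / M

Empty-set conventions: a ratio whose denominator set is empty contributes
1 when both sets are empty (the sets are identical) and 0 when only the
denominator set is empty.  Absolute true counts two empty sets as a match.
These conventions reproduce, and are pinned down by, the published
five-metric evaluation of the histone H2B type 1-K test protein (Q16778).

Per-label metrics are the usual binary confusion rates plus ROC / PR areas
computed from the continuous kernel scores.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .segments import PTM_TYPES

LabelSetPair = tuple[frozenset, frozenset]


@dataclass
class MetricsReport:
    """The five overall multi-label measurements."""

    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    n: int
    m: int = len(PTM_TYPES)

    def to_dict(self) -> dict:
        return asdict(self)

    def round(self, ndigits: int = 4) -> "MetricsReport":
        return MetricsReport(
            *(round(getattr(self, f), ndigits)
              for f in ("aiming", "coverage", "accuracy", "absolute_true",
                        "absolute_false")),
            n=self.n, m=self.m,
        )


def _ratio(num: int, den: int, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def overall_metrics(
    pairs: Iterable[tuple[Iterable, Iterable]], m: int = len(PTM_TYPES)
) -> MetricsReport:
    """Compute the five overall metrics from (observed, predicted) set pairs."""
    pairs = [(frozenset(obs), frozenset(pred)) for obs, pred in pairs]
    if not pairs:
        raise ValueError("empty pair list")
    aim = cov = acc = atrue = afalse = 0.0
    for obs, pred in pairs:
        inter = len(obs & pred)
        union = len(obs | pred)
        both_empty = union == 0
        aim += _ratio(inter, len(pred), both_empty)
        cov += _ratio(inter, len(obs), both_empty)
        acc += _ratio(inter, union, both_empty)
        atrue += 1.0 if obs == pred else 0.0
        afalse += (union - inter) / m
    n = len(pairs)
    return MetricsReport(aim / n, cov / n, acc / n, atrue / n, afalse / n, n=n, m=m)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def per_label_metrics(
    truths: np.ndarray,
    predictions: np.ndarray,
    scores: np.ndarray | None = None,
    labels: Sequence[str] = PTM_TYPES,
) -> pd.DataFrame:
    """Binary confusion metrics (and score-based AUROC / AUPR) per label.

    ``truths`` and ``predictions`` are ``(n, 4)`` +/-1 matrices; ``scores``
    holds the continuous per-label scores used for the ROC and PR areas
    (NaN when a label has a single class in ``truths``).  Precision and F1
    fall back to 0 when their denominators are 0.
    """
    truths = np.asarray(truths)
    predictions = np.asarray(predictions)
    if truths.shape != predictions.shape:
        raise ValueError("shape mismatch between truths and predictions")
    if scores is not None and np.asarray(scores).shape != truths.shape:
        raise ValueError("shape mismatch between truths and scores")
    rows = []
    for v, name in enumerate(labels):
        t = truths[:, v] > 0
        p = predictions[:, v] > 0
        tp = int(np.sum(t & p))
        tn = int(np.sum(~t & ~p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        sn = _safe_div(tp, tp + fn)
        sp = _safe_div(tn, tn + fp)
        accuracy = _safe_div(tp + tn, tp + tn + fp + fn)
        precision = _safe_div(tp, tp + fp)
        f1 = _safe_div(2 * sn * precision, sn + precision)
        auroc = aupr = float("nan")
        if scores is not None and 0 < t.sum() < len(t):
            auroc = roc_auc_score(t, np.asarray(scores)[:, v])
            aupr = average_precision_score(t, np.asarray(scores)[:, v])
        rows.append(
            {"label": name, "TP": tp, "TN": tn, "FP": fp, "FN": fn,
             "SN": sn, "SP": sp, "ACC": accuracy, "precision": precision,
             "F1": f1, "AUROC": auroc, "AUPR": aupr}
        )
    return pd.DataFrame(rows).set_index("label")
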