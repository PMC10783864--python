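"""Multi-label Gaussian kernel regression engines.

The score of label ``v`` for a query ``q`` is the kernel-weighted mean of
the +/-1 training labels,

    S_v = Σ_i l_i^v exp(-d_i(v) / (2 θ²)) / Σ_i exp(-d_i(v) / (2 θ²)),

so ``S_v`` always lies in [-1, 1] and ``S_v >= 0`` predicts the label.
Two engines differ only in the distance ``d_i(v)``:

* ``gkpr`` (masked; the default): squared Euclidean distance restricted to
  the ``v``-th slot of every di-residue block — each label is scored only
  on the features that carry its own proportions.
* ``gkr`` (baseline): full squared Euclidean distance for every label.

Because the features are label-conditional, a small kernel width sharpens
the weighting toward the nearest training segments; θ = 1/6 is the default.
Exponents are shifted by the per-query minimal distance before
exponentiation — the score is a ratio, so the shift is exact — which keeps
``exp`` away from underflow at small θ.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import BLOCK, CountTable, DiresidueEncoder, encode_dataset
from .segments import Dataset

THETA_DEFAULT = 1.0 / 6.0

#: Kernel widths examined when tuning θ.
THETA_GRID = (1 / 2, 1 / 4, 1 / 6, 1 / 8, 1 / 16, 1 / 32)

MODEL_FORMAT = "lysptm-model"
MODEL_VERSION = 1


def masked_sq_distance(x: np.ndarray, y: np.ndarray, v: int) -> float:
    """Squared distance restricted to label ``v``'s feature slots.

    ``v`` is 1-based (1..4).  With features laid out in blocks of four,
    label ``v`` owns columns ``v-1, v-1+4, v-1+8, ...``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if not 1 <= v <= BLOCK:
        raise ValueError(f"label index {v} outside 1..{BLOCK}")
    diff = x[v - 1 :: BLOCK] - y[v - 1 :: BLOCK]
    return float(diff @ diff)


def _label_scores(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    theta: float,
    engine: str,
) -> np.ndarray:
    """Vectorized scores for a query batch; rows queries, columns labels."""
    if train_features.shape[0] == 0:
        raise ValueError("empty model")
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    inv = 1.0 / (2.0 * theta * theta)
    scores = np.empty((queries.shape[0], BLOCK))
    if engine == "gkr":
        d_full = cdist(queries, train_features, "sqeuclidean")
    for v in range(BLOCK):
        if engine == "gkpr":
            d = cdist(queries[:, v::BLOCK], train_features[:, v::BLOCK], "sqeuclidean")
        elif engine == "gkr":
            d = d_full
        else:
            raise ValueError(f"unknown engine {engine!r}")
        w = np.exp(-(d - d.min(axis=1, keepdims=True)) * inv)
        scores[:, v] = (w @ train_labels[:, v]) / w.sum(axis=1)
    return scores


def predict_labels(scores: np.ndarray) -> np.ndarray:
    """Threshold scores at zero; a tie at exactly 0 predicts the label."""
    return np.where(np.asarray(scores) >= 0, 1, -1).astype(np.int8)


class MultiLabelKernelClassifier(ClassifierMixin, BaseEstimator):
    """Multi-label lysine PTM classifier over peptide segments.

    Fits the di-residue count table on the training segments, encodes them,
    and scores queries by per-label (masked) Gaussian kernel regression.

    Parameters
    ----------
    theta : float
        Kernel width θ (> 0).
    engine : {"gkpr", "gkr"}
        Masked per-label distances, or the unmasked full-distance baseline.
    half_width : int or None
        Window half width; inferred from the training segments when None.

    Attributes
    ----------
    encoder_ : DiresidueEncoder
        Fitted feature encoder (owns the count table).
    train_features_ : ndarray of shape (a, 8 (L - 1))
    train_labels_ : ndarray of shape (a, 4), entries +/-1

    Examples
    --------
    >>> segs = ["AAKAA", "CCKCC"]
    >>> y = [[1, -1, -1, -1], [-1, -1, -1, 1]]
    >>> clf = MultiLabelKernelClassifier().fit(segs, y)
    >>> clf.predict(["AAKAA"])[0].tolist()
    [1, -1, -1, -1]
    """

    def __init__(
        self,
        theta: float = THETA_DEFAULT,
        engine: str = "gkpr",
        half_width: int | None = None,
    ):
        self.theta = theta
        self.engine = engine
        self.half_width = half_width

    def _validate_params(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if self.engine not in ("gkpr", "gkr"):
            raise ValueError(f"unknown engine {self.engine!r}")

    def fit(self, X: Sequence[str] | Dataset, y: np.ndarray | None = None):
        """Fit on segments ``X`` and an ``(n, 4)`` +/-1 label matrix ``y``.

        ``X`` may be a :class:`~lysptm.segments.Dataset`, in which case its
        labels are used and ``y`` may be omitted.
        """
        self._validate_params()
        if isinstance(X, Dataset):
            segments, y = X.segments, X.labels
        else:
            segments = list(X)
            if y is None:
                raise ValueError("y is required when X is not a Dataset")
        y = np.asarray(y)
        if len(segments) == 0:
            raise ValueError("empty training set")
        if not np.all(np.abs(y) == 1):
            raise ValueError("labels must be +/-1")
        self.encoder_ = DiresidueEncoder(self.half_width).fit(segments, y)
        self.half_width_ = self.encoder_.count_table_.half_width
        self.train_features_ = self.encoder_.transform(segments)
        self.train_labels_ = y.astype(np.int8)
        return self

    def _encode(self, X: Sequence[str] | Dataset | np.ndarray) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.dtype != object and X.ndim == 2:
            return X  # already encoded
        return self.encoder_.transform(X)

    def decision_function(self, X) -> np.ndarray:
        """Per-label scores ``S_v`` in [-1, 1]; shape (n, 4)."""
        check_is_fitted(self, "train_features_")
        return _label_scores(
            self.train_features_, self.train_labels_, self._encode(X),
            self.theta, self.engine,
        )

    def predict(self, X) -> np.ndarray:
        """Predicted +/-1 label matrix of shape (n, 4)."""
        return predict_labels(self.decision_function(X))

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "train_features_")
        return json.dumps(
            {
                "format": MODEL_FORMAT,
                "version": MODEL_VERSION,
                "params": {"theta": self.theta, "engine": self.engine,
                           "half_width": self.half_width_},
                "count_table": json.loads(self.encoder_.count_table_.to_json()),
                "train_features": self.train_features_.tolist(),
                "train_labels": self.train_labels_.tolist(),
            }
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "MultiLabelKernelClassifier":
        payload = json.loads(text)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError("not a model document")
        params = payload["params"]
        model = cls(theta=params["theta"], engine=params["engine"],
                    half_width=params["half_width"])
        table = CountTable.from_json(json.dumps(payload["count_table"]))
        model.encoder_ = DiresidueEncoder(table.half_width)
        model.encoder_.count_table_ = table
        model.encoder_.n_features_out_ = table.n_features()
        model.half_width_ = table.half_width
        model.train_features_ = np.asarray(payload["train_features"], dtype=float)
        model.train_labels_ = np.asarray(payload["train_labels"], dtype=np.int8)
        return model

    @classmethod
    def load(cls, path: str | Path) -> "MultiLabelKernelClassifier":
        return cls.from_json(Path(path).read_text())


def score_labels(model: MultiLabelKernelClassifier, query) -> np.ndarray:
    """Score a single query segment (or feature vector); returns 4 scores."""
    return model.decision_function([query] if isinstance(query, str) else
                                   np.atleast_2d(query))[0]
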