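"""Location-fixed di-residue distribution features.

For every adjacent residue pair ``αβ`` at window positions ``(i, i + 1)``
(excluding the two pairs touching the center lysine) the training set
yields a count ``N(αβ(i, i+1))`` of segments carrying that pair at that
exact location, plus four restricted counts over the segments annotated
with each PTM type.  The ratios

    ρ_type = N_type / N

form a 4-vector per pair; concatenating the 4-vectors of a segment's
``2 (L - 1)`` pairs in ascending position order gives its ``8 (L - 1)``
feature vector.  Every feature lies in [0, 1] and mixes sequence context
with training-label information, so the table must be refitted on the
training split of every fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .segments import PTM_TYPES, Dataset, enumerate_diresidues, validate_segment

#: Number of features emitted per di-residue block.
BLOCK = len(PTM_TYPES)

SERIAL_FORMAT = "lysptm-count-table"
SERIAL_VERSION = 1

DiresidueKey = tuple[int, str]


@dataclass
class CountTable:
    """Fitted di-residue counts.

    ``counts`` maps ``(start_position, pair)`` to a length-5 integer array
    ``[N, N_acetylation, N_crotonylation, N_methylation, N_succinylation]``.
    Keys never observed in training are absent (count zero).
    """

    half_width: int
    n_train: int
    counts: dict[DiresidueKey, np.ndarray] = field(default_factory=dict)

    def n_features(self) -> int:
        return 2 * BLOCK * (self.half_width - 1)

    def to_json(self) -> str:
        payload = {
            "format": SERIAL_FORMAT,
            "version": SERIAL_VERSION,
            "half_width": self.half_width,
            "n_train": self.n_train,
            "counts": {f"{i}:{pair}": [int(c) for c in v]
                       for (i, pair), v in sorted(self.counts.items())},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CountTable":
        payload = json.loads(text)
        if payload.get("format") != SERIAL_FORMAT:
            raise ValueError("not a count-table document")
        counts: dict[DiresidueKey, np.ndarray] = {}
        for key, vals in payload["counts"].items():
            pos, pair = key.split(":")
            counts[(int(pos), pair)] = np.asarray(vals, dtype=np.int64)
        return cls(payload["half_width"], payload["n_train"], counts)


def fit_count_table(
    training: Dataset | Sequence[str],
    labels: np.ndarray | None = None,
    half_width: int | None = None,
) -> CountTable:
    """Count location-fixed di-residues over a training set.

    Accepts either a :class:`Dataset` or a sequence of segment strings plus
    an ``(n, 4)`` +/-1 label matrix.  Multi-labeled segments contribute to
    every active type's count; "other" segments contribute to totals only.
    """
    if isinstance(training, Dataset):
        segments, labels, half_width = training.segments, training.labels, training.half_width
    else:
        segments = list(training)
        if labels is None:
            raise ValueError("labels required when passing raw segments")
        if half_width is None:
            half_width = len(segments[0]) // 2 if segments else None
    if not segments:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    counts: dict[DiresidueKey, np.ndarray] = {}
    for seg, lab in zip(segments, labels):
        active = lab > 0
        for key in enumerate_diresidues(seg, half_width):
            row = counts.get(key)
            if row is None:
                row = counts[key] = np.zeros(1 + BLOCK, dtype=np.int64)
            row[0] += 1
            row[1:][active] += 1
    return CountTable(half_width, len(segments), counts)


def encode_diresidue(table: CountTable, key: DiresidueKey) -> np.ndarray:
    """The ρ 4-vector of one location-fixed pair.

    Unseen keys (``N = 0``) encode as the zero vector: no training evidence
    supports any type.
    """
    row = table.counts.get(key)
    if row is None or row[0] == 0:
        return np.zeros(BLOCK)
    return row[1:] / row[0]


def encode_segment(table: CountTable, segment: str) -> np.ndarray:
    """Concatenate the ρ-vectors of a segment's pairs in ascending position order."""
    seg = validate_segment(segment, table.half_width)
    return np.concatenate(
        [encode_diresidue(table, key) for key in enumerate_diresidues(seg, table.half_width)]
    )


def encode_dataset(table: CountTable, data: Dataset | Iterable[str]) -> np.ndarray:
    """Row-wise :func:`encode_segment`, preserving record order."""
    segments = data.segments if isinstance(data, Dataset) else list(data)
    if not segments:
        return np.empty((0, table.n_features()))
    return np.vstack([encode_segment(table, s) for s in segments])


class DiresidueEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the distribution features.

    Parameters
    ----------
    half_width : int or None
        Window half width ``L``; inferred from the first training segment
        when None.

    Attributes
    ----------
    count_table_ : CountTable
        Counts fitted on the training segments and labels.
    n_features_out_ : int
        ``8 (L - 1)``.

    Notes
    -----
    ``fit`` is supervised: it needs the +/-1 label matrix, because the
    features are label-conditional proportions.  Use inside a fold-aware
    pipeline so held-out segments are encoded with a table they did not
    contribute to.
    """

    def __init__(self, half_width: int | None = None):
        self.half_width = half_width

    def fit(self, X: Sequence[str], y: np.ndarray) -> "DiresidueEncoder":
        segments = X.segments if isinstance(X, Dataset) else list(X)
        if isinstance(X, Dataset):
            y = X.labels
        self.count_table_ = fit_count_table(segments, np.asarray(y), self.half_width)
        self.n_features_out_ = self.count_table_.n_features()
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "count_table_")
        return encode_dataset(self.count_table_, X)
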