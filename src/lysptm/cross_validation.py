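"""Cross-validation drivers with per-fold feature refitting.

Two fold constructions:

* ``general`` — records are shuffled and split into folds of as equal size
  as possible.  Windows from the same protein may land on both sides of a
  split, which flatters the estimate when proteins contribute many sites.
* ``strict`` — *proteins* are shuffled and split, and every record follows
  its protein, so no sequence contributes to both training and testing.

In every fold the count table and model are fitted on the training folds
only and the held-out fold is encoded with that table; the features are
label-conditional, so refitting inside the fold is what keeps the
evaluation honest.  The five overall metrics are averaged over folds;
per-label confusion metrics and ROC / PR areas are computed on the pooled
out-of-fold predictions and scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import THETA_DEFAULT, MultiLabelKernelClassifier
from .metrics import MetricsReport, overall_metrics, per_label_metrics
from .segments import Dataset, labels_to_sets, load_fasta_plus_sites


@dataclass
class CVConfig:
    """Cross-validation settings."""

    folds: int = 5
    mode: str = "general"  # or "strict"
    seed: int = 0
    exclude_unlabeled: bool = False
    theta: float = THETA_DEFAULT
    engine: str = "gkpr"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.mode not in ("general", "strict"):
            raise ValueError(f"unknown CV mode {self.mode!r}")


@dataclass
class CVResult:
    """Outcome of one cross-validated run."""

    overall: MetricsReport                 # mean of per-fold overall metrics
    per_fold: list[MetricsReport]
    per_label: pd.DataFrame                # pooled out-of-fold
    predictions: np.ndarray                # (n, 4) +/-1, dataset order
    scores: np.ndarray                     # (n, 4), dataset order
    fold_of: np.ndarray                    # fold index per record


def _chunk_sizes(n: int, k: int) -> list[int]:
    # as equal as possible; remainder spread over the first folds
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def make_folds(data: Dataset, config: CVConfig) -> list[np.ndarray]:
    """Record indices of each test fold, per the configured mode and seed."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "general":
        n = len(data)
        if config.folds > n:
            raise ValueError("more folds than records")
        perm = rng.permutation(n)
        out, start = [], 0
        for size in _chunk_sizes(n, config.folds):
            out.append(np.sort(perm[start : start + size]))
            start += size
        return out
    # strict: partition proteins (balanced by protein count), records follow
    proteins = list(dict.fromkeys(data.protein_ids))
    if config.folds > len(proteins):
        raise ValueError("more folds than proteins")
    perm = rng.permutation(len(proteins))
    by_protein: dict[str, list[int]] = {}
    for idx, pid in enumerate(data.protein_ids):
        by_protein.setdefault(pid, []).append(idx)
    out, start = [], 0
    for size in _chunk_sizes(len(proteins), config.folds):
        fold_pids = [proteins[i] for i in perm[start : start + size]]
        start += size
        idx = np.sort(np.concatenate([np.asarray(by_protein[p]) for p in fold_pids]))
        out.append(idx)
    return out


def run_cv(data: Dataset, config: CVConfig) -> CVResult:
    """Cross-validate the kernel classifier on ``data``."""
    if config.exclude_unlabeled:
        keep = np.flatnonzero((data.labels > 0).any(axis=1))
        data = data.subset(keep)
    n = len(data)
    folds = make_folds(data, config)
    scores = np.full((n, 4), np.nan)
    predictions = np.zeros((n, 4), dtype=np.int8)
    fold_of = np.full(n, -1, dtype=int)
    per_fold: list[MetricsReport] = []
    for f, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train = data.subset(np.flatnonzero(mask))
        test = data.subset(test_idx)
        model = MultiLabelKernelClassifier(theta=config.theta, engine=config.engine)
        model.fit(train)
        s = model.decision_function(test)
        p = np.where(s >= 0, 1, -1).astype(np.int8)
        scores[test_idx] = s
        predictions[test_idx] = p
        fold_of[test_idx] = f
        per_fold.append(
            overall_metrics(zip(labels_to_sets(test.labels), labels_to_sets(p)))
        )
    k = len(per_fold)
    mean = MetricsReport(
        *(float(np.mean([getattr(r, f) for r in per_fold]))
          for f in ("aiming", "coverage", "accuracy", "absolute_true",
                    "absolute_false")),
        n=n,
    )
    per_label = per_label_metrics(data.labels, predictions, scores)
    return CVResult(mean, per_fold, per_label, predictions, scores, fold_of)


def sweep(
    source: Dataset | tuple[str, str],
    thetas: Sequence[float] | None = None,
    half_widths: Sequence[int] | None = None,
    config: CVConfig | None = None,
) -> pd.DataFrame:
    """Grid-evaluate θ and/or window size by cross-validation.

    ``source`` is a :class:`Dataset` (window sizes may only shrink its
    windows) or a ``(fasta_path, sites_path)`` pair, in which case segments
    are re-extracted from the sequences for every window size.
    """
    config = config or CVConfig()
    thetas = list(thetas) if thetas is not None else [config.theta]
    rows = []
    if half_widths is None:
        datasets = [(source.half_width, source)] if isinstance(source, Dataset) else None
        if datasets is None:
            raise ValueError("half_widths required with a (fasta, sites) source")
    elif isinstance(source, Dataset):
        datasets = [(L, source.with_half_width(L)) for L in half_widths]
    else:
        fasta, sites = source
        datasets = [(L, load_fasta_plus_sites(fasta, sites, L)) for L in half_widths]
    for L, data in datasets:
        for theta in thetas:
            res = run_cv(data, replace(config, theta=theta))
            rows.append({"theta": theta, "half_width": L, "n": res.overall.n,
                         **{k: getattr(res.overall, k)
                            for k in ("aiming", "coverage", "accuracy",
                                      "absolute_true", "absolute_false")}})
    return pd.DataFrame(rows)
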