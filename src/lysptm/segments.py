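"""Lysine-centered peptide segments and dataset I/O.

A *peptide segment* is a window of ``2L + 1`` residues centered on a lysine
(K), with signed positions ``-L .. -1, 0, 1 .. L`` and the lysine at
position 0.  Windows that run past a protein terminus are padded by
repeating the terminal residue.  Each segment carries a four-entry
+/-1 label vector over the PTM types (acetylation, crotonylation,
methylation, succinylation); the all-negative vector is the "other"
class of unannotated lysines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The four PTM labels, in canonical order.
PTM_TYPES = ("acetylation", "crotonylation", "methylation", "succinylation")

#: Canonical 20-letter amino-acid alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol that every non-standard residue letter is mapped to.
UNKNOWN_RESIDUE = "X"

# Ambiguity / rare codes collapsed onto the unknown symbol.  They take part
# in di-residue counting like any other letter.
_NONSTANDARD = set("BJOUZX*")

_VALID = set(AMINO_ACIDS) | _NONSTANDARD


def normalize_residues(residues: str) -> str:
    """Uppercase and map non-standard residue letters to ``X``.

    Raises ``ValueError`` for characters outside the accepted alphabet.
    """
    out = []
    for ch in residues.upper():
        if ch in _NONSTANDARD:
            out.append(UNKNOWN_RESIDUE)
        elif ch in _VALID:
            out.append(ch)
        else:
            raise ValueError(f"unknown residue letter {ch!r}")
    return "".join(out)


def extract_peptide_segment(sequence: str, position: int, half_width: int) -> str:
    """Extract the ``2L + 1`` window centered on a lysine.

    Parameters
    ----------
    sequence : str
        Full protein sequence.
    position : int
        1-based index of the center lysine in ``sequence``.
    half_width : int
        Number of residues taken on each side of the center (``L``).

    Returns
    -------
    str
        Window of length ``2 * half_width + 1``.  When fewer than ``L``
        residues exist upstream (downstream), the missing slots are filled
        by repeating the first (last) residue of the sequence.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    n = len(sequence)
    if not 1 <= position <= n:
        raise IndexError(f"position {position} outside sequence of length {n}")
    if sequence[position - 1].upper() != "K":
        raise ValueError(
            f"residue at position {position} is {sequence[position - 1]!r}, not 'K'"
        )
    center = position - 1
    left = sequence[max(0, center - half_width) : center]
    right = sequence[center + 1 : center + 1 + half_width]
    pad_left = sequence[0] * (half_width - len(left))
    pad_right = sequence[-1] * (half_width - len(right))
    return normalize_residues(pad_left + left + "K" + right + pad_right)


def validate_segment(segment: str, half_width: int) -> str:
    """Check segment length / center-K invariants; return the normalized string."""
    seg = normalize_residues(segment)
    if len(seg) != 2 * half_width + 1:
        raise ValueError(
            f"segment length {len(seg)} != 2*{half_width}+1 = {2 * half_width + 1}"
        )
    if seg[half_width] != "K":
        raise ValueError(f"center residue of {segment!r} is not 'K'")
    return seg


def enumerate_diresidues(segment: str, half_width: int | None = None) -> list[tuple[int, str]]:
    """List the location-fixed di-residues of a segment.

    Returns the ``2 (L - 1)`` keys ``(i, pair)`` for adjacent positions
    ``(i, i + 1)`` with ``i`` in ``{-L .. -2} ∪ {1 .. L - 1}`` in ascending
    ``i`` order.  The two pairs touching the center lysine, ``(-1, 0)`` and
    ``(0, 1)``, are excluded.
    """
    if half_width is None:
        if len(segment) % 2 == 0:
            raise ValueError("segment length must be odd")
        half_width = len(segment) // 2
    L = half_width
    seg = validate_segment(segment, L)
    keys: list[tuple[int, str]] = []
    for i in range(-L, L):
        if i in (-1, 0):
            continue
        idx = i + L
        keys.append((i, seg[idx : idx + 2]))
    return keys


def labels_to_vector(names: Iterable[str]) -> np.ndarray:
    """Map a collection of PTM type names to a +/-1 vector of length 4."""
    vec = -np.ones(len(PTM_TYPES), dtype=np.int8)
    for name in names:
        name = name.strip()
        if not name:
            continue
        try:
            vec[PTM_TYPES.index(name)] = 1
        except ValueError:
            raise ValueError(f"unknown PTM label {name!r}") from None
    return vec


def vector_to_labels(vec: Sequence[int]) -> list[str]:
    """Inverse of :func:`labels_to_vector`."""
    return [t for t, v in zip(PTM_TYPES, vec) if v > 0]


def labels_to_sets(labels: np.ndarray) -> list[frozenset[str]]:
    """Convert an ``(n, 4)`` +/-1 matrix to per-row label sets."""
    return [frozenset(vector_to_labels(row)) for row in np.asarray(labels)]


@dataclass
class Dataset:
    """An ordered collection of labeled lysine-centered peptide segments.

    Attributes
    ----------
    protein_ids : list of str
        Source accession of each record.
    positions : ndarray of int
        1-based lysine position of each record in its protein.
    segments : list of str
        Fixed-length windows, all sharing ``half_width``.
    labels : ndarray of shape (n, 4)
        +/-1 annotations in the canonical type order.
    half_width : int
        Shared window half width ``L``.
    """

    protein_ids: list[str]
    positions: np.ndarray
    segments: list[str]
    labels: np.ndarray
    half_width: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n = len(self.segments)
        if not (len(self.protein_ids) == len(self.positions) == n == self.labels.shape[0]):
            raise ValueError("field lengths disagree")
        if n and self.labels.shape[1] != len(PTM_TYPES):
            raise ValueError("labels must have 4 columns")
        if not np.all(np.abs(self.labels) == 1):
            raise ValueError("labels must be +/-1")
        self.segments = [validate_segment(s, self.half_width) for s in self.segments]

    def __len__(self) -> int:
        return len(self.segments)

    def subset(self, index: Sequence[int]) -> "Dataset":
        index = np.asarray(index, dtype=int)
        return Dataset(
            [self.protein_ids[i] for i in index],
            self.positions[index],
            [self.segments[i] for i in index],
            self.labels[index],
            self.half_width,
        )

    def label_sets(self) -> list[frozenset[str]]:
        return labels_to_sets(self.labels)

    def with_half_width(self, half_width: int) -> "Dataset":
        """Trim every window to a smaller half width.

        Valid because terminal padding repeats the terminal residue, so the
        central ``2L' + 1`` slice of a window equals direct extraction at
        ``L'``.
        """
        if half_width > self.half_width:
            raise ValueError("can only shrink windows; re-extract from FASTA to grow")
        off = self.half_width - half_width
        segs = [s[off : len(s) - off] for s in self.segments]
        return Dataset(list(self.protein_ids), self.positions.copy(), segs,
                       self.labels.copy(), half_width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "position": self.positions,
                "segment": self.segments,
                "labels": [",".join(vector_to_labels(v)) for v in self.labels],
            }
        )


def _check_duplicates(protein_ids: Sequence[str], positions: Sequence[int]) -> None:
    seen: set[tuple[str, int]] = set()
    for pid, pos in zip(protein_ids, positions):
        key = (pid, int(pos))
        if key in seen:
            raise ValueError(f"duplicate site {key}")
        seen.add(key)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_segments_tsv(path: str | Path, half_width: int | None = None) -> Dataset:
    """Load the canonical tab-separated segment table.

    Columns: ``protein_id``, ``position``, ``segment``, ``labels`` (a
    comma-separated subset of the four type names; empty = unannotated).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str}, keep_default_na=False)
    required = ["protein_id", "position", "segment", "labels"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"segments_tsv missing columns {missing}")
    segments = [str(s) for s in df["segment"]]
    if not segments:
        raise ValueError("empty dataset")
    if half_width is None:
        if len(segments[0]) % 2 == 0:
            raise ValueError("segment length must be odd")
        half_width = len(segments[0]) // 2
    labels = np.array([labels_to_vector(str(s).split(",")) for s in df["labels"]])
    _check_duplicates(df["protein_id"], df["position"])
    return Dataset(list(df["protein_id"]), df["position"].to_numpy(), segments,
                   labels, half_width)


def load_fasta_plus_sites(
    fasta_path: str | Path, sites_path: str | Path, half_width: int
) -> Dataset:
    """Build a dataset from a FASTA and a site table.

    The site table is tab-separated with columns ``protein_id``,
    ``position`` (1-based lysine position) and ``labels``.
    """
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(sites_path, sep="\t", dtype={"protein_id": str}, keep_default_na=False)
    required = ["protein_id", "position", "labels"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns {missing}")
    _check_duplicates(df["protein_id"], df["position"])
    segments, labels = [], []
    for _, row in df.iterrows():
        pid = row["protein_id"]
        if pid not in seqs:
            raise KeyError(f"protein {pid!r} absent from FASTA")
        segments.append(extract_peptide_segment(seqs[pid], int(row["position"]), half_width))
        labels.append(labels_to_vector(str(row["labels"]).split(",")))
    if not segments:
        raise ValueError("empty dataset")
    return Dataset(list(df["protein_id"]), df["position"].to_numpy(), segments,
                   np.array(labels), half_width)


def load_dataset(
    path: str | Path,
    format: str = "segments_tsv",
    half_width: int | None = None,
    sites: str | Path | None = None,
) -> Dataset:
    """Load a dataset in one of the supported dialects.

    ``format="segments_tsv"`` reads the canonical table at ``path``;
    ``format="fasta_plus_sites"`` reads sequences from ``path`` and the
    site table from ``sites`` and extracts windows at ``half_width``.
    """
    if format == "segments_tsv":
        return load_segments_tsv(path, half_width)
    if format == "fasta_plus_sites":
        if sites is None:
            raise ValueError("fasta_plus_sites requires a sites= table path")
        if half_width is None:
            raise ValueError("fasta_plus_sites requires half_width")
        return load_fasta_plus_sites(path, sites, half_width)
    raise ValueError(f"unknown format {format!r}")


def save_segments_tsv(dataset: Dataset, path: str | Path | io.TextIOBase) -> None:
    """Write a dataset as the canonical segments table."""
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def save_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write an id -> sequence mapping as FASTA."""
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
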