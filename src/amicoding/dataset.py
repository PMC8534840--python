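"""Fixed-length labeled sampling from parent sequences and CV splitting.

Datasets mirror the benchmark construction used throughout this package:
up to ``n_per_class`` (default 2000) non-overlapping windows of constant
length are drawn from each parent sequence, labeled by their source parent
(1 = coding, 0 = noncoding).  Non-overlap is guaranteed by partitioning a
parent into ``floor(L / length)`` consecutive disjoint windows and sampling
windows without replacement, which also makes the attainable count exact:
when the parent is too short for the request, the class simply shrinks to
capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .sequence_io import ParentSequences, read_fasta, write_fasta

__all__ = [
    "Window",
    "LabeledDataset",
    "DatasetError",
    "LENGTH_GRID",
    "sample_nonoverlapping",
    "build_dataset",
    "kfold_split",
    "write_dataset_fasta",
    "read_dataset_fasta",
]

#: Sequence-length sweep covering 25 bp through 12,800 bp.
LENGTH_GRID = (25, 50, 100, 200, 400, 800, 1600, 3200, 6400, 12800)


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class Window:
    """A sampled window: 0-based start offset in its parent, and its sequence."""

    start: int
    seq: str


@dataclass
class LabeledDataset:
    """Fixed-length sequences with binary labels (1 = coding, 0 = noncoding)."""

    sequences: list[str]
    labels: np.ndarray
    starts: np.ndarray  # 0-based window starts within the source parent
    seq_length: int
    species_id: str = ""
    seed: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.starts = np.asarray(self.starts, dtype=int)
        if not (len(self.sequences) == self.labels.size == self.starts.size):
            raise DatasetError("sequences, labels and starts must align")

    def __len__(self) -> int:
        return len(self.sequences)

    def class_counts(self) -> tuple[int, int]:
        """(coding, noncoding) sample counts."""
        n1 = int(self.labels.sum())
        return n1, int(self.labels.size - n1)


def sample_nonoverlapping(
    parent: str, length: int, n: int, seed: int | np.random.Generator = 0
) -> list[Window]:
    """Draw up to ``n`` non-overlapping windows of ``length`` bases.

    The parent is partitioned into ``floor(L / length)`` consecutive
    disjoint windows; ``min(n, capacity)`` of them are chosen uniformly
    without replacement.  Deterministic given the seed.
    """
    if length < 1 or n < 1:
        raise DatasetError("length and n must be >= 1")
    capacity = len(parent) // length
    if capacity == 0:
        raise DatasetError(
            f"parent-too-short: length {len(parent)} cannot fit a {length}-base window"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chosen = rng.choice(capacity, size=min(n, capacity), replace=False)
    return [Window(int(i) * length, parent[i * length : (i + 1) * length]) for i in chosen]


def build_dataset(
    parents: ParentSequences,
    length: int,
    n_per_class: int = 2000,
    seed: int = 0,
) -> LabeledDataset:
    """Sample both parents independently and label windows by source."""
    ss = np.random.SeedSequence(seed).spawn(2)
    coding = sample_nonoverlapping(
        parents.coding, length, n_per_class, np.random.default_rng(ss[0])
    )
    noncoding = sample_nonoverlapping(
        parents.noncoding, length, n_per_class, np.random.default_rng(ss[1])
    )
    if not coding or not noncoding:
        raise DatasetError("empty class after sampling")
    sequences = [w.seq for w in coding] + [w.seq for w in noncoding]
    labels = np.concatenate([np.ones(len(coding), int), np.zeros(len(noncoding), int)])
    starts = np.array([w.start for w in coding] + [w.start for w in noncoding])
    return LabeledDataset(sequences, labels, starts, length, parents.species_id, seed)


def kfold_split(
    dataset: LabeledDataset | np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of dataset indices, deterministic in ``seed``."""
    labels = dataset.labels if isinstance(dataset, LabeledDataset) else np.asarray(dataset)
    counts = np.bincount(labels)
    if (counts[counts > 0] < k).any():
        raise DatasetError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    return [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(labels.size), labels)
    ]


# ---------------------------------------------------------------------------
# serialization: FASTA with labels in headers plus a TSV manifest


def write_dataset_fasta(path, dataset: LabeledDataset) -> None:
    names = []
    for i, (lab, start) in enumerate(zip(dataset.labels, dataset.starts)):
        cls = "coding" if lab == 1 else "noncoding"
        names.append(f"{cls}_{i}_{start}")
    write_fasta(path, zip(names, dataset.sequences))
    manifest = Path(path).with_suffix(".manifest.tsv")
    with manifest.open("w") as fh:
        fh.write("index\tlabel\tstart\tlength\tspecies\tseed\n")
        for i, (lab, start) in enumerate(zip(dataset.labels, dataset.starts)):
            fh.write(
                f"{i}\t{lab}\t{start}\t{dataset.seq_length}\t"
                f"{dataset.species_id}\t{dataset.seed}\n"
            )


def read_dataset_fasta(path, species_id: str = "", seed: int = 0) -> LabeledDataset:
    records = read_fasta(path)
    sequences, labels, starts = [], [], []
    for name, seq in records.items():
        cls, _idx, start = name.rsplit("_", 2)
        labels.append(1 if cls == "coding" else 0)
        starts.append(int(start))
        sequences.append(seq)
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise DatasetError("dataset FASTA contains mixed sequence lengths")
    return LabeledDataset(
        sequences, np.array(labels), np.array(starts), lengths.pop(), species_id, seed
    )
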