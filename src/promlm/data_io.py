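"""Sequence-dataset and feature-table I/O.

Datasets are flat collections of labeled DNA sequences organised in two
classification layers: layer 1 separates promoters from non-promoters,
layer 2 separates strong from weak promoters (layer 2 contains only the
positive half of layer 1, relabeled).  Feature tables are dense
samples x features matrices with a binary label column, written as TSV.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio import SeqIO

LAYER1 = "layer1"
LAYER2 = "layer2"

#: admissible class labels per layer; the first entry is the positive class
LAYER_CLASSES: dict[str, tuple[str, str]] = {
    LAYER1: ("promoter", "non-promoter"),
    LAYER2: ("strong", "weak"),
}

VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


@dataclass
class SequenceRecord:
    """One DNA sequence with an optional binary class label.

    ``bases`` is stored uppercase and restricted to the alphabet
    {A, C, G, T, N}; anything else is rejected rather than silently
    remapped.
    """

    id: str
    bases: str
    label: str | None = None
    layer: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.bases = self.bases.upper()
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal character(s) "
                f"{', '.join(sorted(bad))} (alphabet is A/C/G/T/N)"
            )
        if self.layer is not None:
            if self.layer not in LAYER_CLASSES:
                raise ValueError(f"unknown layer {self.layer!r}")
            if self.label is not None and self.label not in LAYER_CLASSES[self.layer]:
                raise ValueError(
                    f"record {self.id!r}: label {self.label!r} not admissible "
                    f"for {self.layer} {LAYER_CLASSES[self.layer]}"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Dataset:
    """Ordered collection of :class:`SequenceRecord` for one layer."""

    records: list[SequenceRecord] = field(default_factory=list)
    layer: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records if r.label is not None))

    @property
    def positive_class(self) -> str:
        if self.layer is None:
            raise ValueError("dataset has no layer; labels are undefined")
        return LAYER_CLASSES[self.layer][0]

    def labels(self) -> np.ndarray:
        """Binary label vector (1 = positive class of the layer)."""
        pos = self.positive_class
        out = np.empty(len(self.records), dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.label is None:
                raise ValueError(f"record {r.id!r} is unlabeled")
            out[i] = 1 if r.label == pos else 0
        return out

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


# ---------------------------------------------------------------------------
# FASTA / plain-text sequence input
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dataset:
    """Parse a FASTA file into an unlabeled :class:`Dataset`.

    Multi-line sequence bodies are joined; bases are uppercased.  A small
    validating parser is used so that errors can name the offending line
    (sequence data before the first header) or record (illegal character).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        records.append(SequenceRecord(id=header, bases="".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else line[1:]
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
    flush()
    return Dataset(records=records, layer=None)


def read_sequences(path: str | Path) -> Dataset:
    """Read FASTA or one-sequence-per-line text (sniffed from the first line)."""
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    if first.startswith(">"):
        return read_fasta(path)
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line:
                records.append(SequenceRecord(id=f"{path.stem}_{lineno}", bases=line))
    return Dataset(records=records, layer=None)


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.bases), id=r.id, description="")
        for r in dataset.records
    ]
    SeqIO.write(bio, str(path), "fasta")


def load_benchmark(
    positives: str | Path,
    negatives: str | Path,
    layer: str = LAYER1,
    seed: int | None = None,
) -> Dataset:
    """Assemble a two-class dataset from a positives file and a negatives file.

    Labels are assigned by source file (first/second admissible class of the
    layer).  Record order is positives-then-negatives as read; the dataset is
    shuffled only when an explicit ``seed`` is given.  Duplicate ids across
    the two files are warned about and suffixed.
    """
    if layer not in LAYER_CLASSES:
        raise ValueError(f"unknown layer {layer!r}")
    pos_label, neg_label = LAYER_CLASSES[layer]
    pos = read_sequences(positives)
    neg = read_sequences(negatives)
    if len(pos) == 0:
        raise ValueError(f"positive class file {positives} contains no sequences")
    if len(neg) == 0:
        raise ValueError(f"negative class file {negatives} contains no sequences")

    seen = {r.id for r in pos.records}
    dupes = [r.id for r in neg.records if r.id in seen]
    if dupes:
        warnings.warn(
            f"{len(dupes)} duplicate id(s) across class files; suffixing", UserWarning
        )
    records = [
        SequenceRecord(r.id, r.bases, label=pos_label, layer=layer)
        for r in pos.records
    ]
    for r in neg.records:
        rid = r.id + "_neg" if r.id in seen else r.id
        records.append(SequenceRecord(rid, r.bases, label=neg_label, layer=layer))

    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
    return Dataset(records=records, layer=layer)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Dense samples x features matrix with ids, names and binary labels."""

    sample_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n, p = self.matrix.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length != row count")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length != column count")
        if self.labels.shape != (n,):
            raise ValueError("labels length != row count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select(self, mask_or_indices) -> "FeatureTable":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            sample_ids=self.sample_ids,
            matrix=self.matrix[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=self.labels,
        )

    def subset_rows(self, rows) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            matrix=self.matrix[rows],
            feature_names=self.feature_names,
            labels=self.labels[rows],
        )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a TSV: header of feature names, first column id, last column label.

    Values are printed at full repr precision so a read-back reproduces the
    matrix bit-for-bit.
    """
    df = pd.DataFrame(table.matrix, columns=table.feature_names)
    df.insert(0, "sample_id", table.sample_ids)
    df["label"] = table.labels
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "sample_id" or df.columns[-1] != "label":
        raise ValueError("feature table must have 'sample_id' first and 'label' last")
    names = list(df.columns[1:-1])
    return FeatureTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        matrix=df[names].to_numpy(dtype=float),
        feature_names=names,
        labels=df["label"].to_numpy(dtype=np.int64),
    )


def write_manifest(path: str | Path, **fields) -> None:
    """JSON run manifest (paths, seeds, class counts, config)."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
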