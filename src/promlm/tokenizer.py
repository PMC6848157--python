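"""k-mer sentence tokenization.

A DNA sequence of length L is read as a "sentence" whose words are the
L - n + 1 overlapping k-mers of length n (stride 1, single strand, left to
right).  Each word length n in 1..10 defines one n-gram *level*; the ten
levels give ten distinct tokenizations of the same sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .data_io import Dataset, SequenceRecord

MAX_LEVEL = 10


@dataclass(frozen=True)
class NGramLevel:
    """Word length of one tokenization level; bounded to the extracted range 1..10."""

    n: int

    def __post_init__(self) -> None:
        if not 1 <= self.n <= MAX_LEVEL:
            raise ValueError(f"n-gram level must be in [1, {MAX_LEVEL}], got {self.n}")


@dataclass(frozen=True)
class Sentence:
    words: tuple[str, ...]
    source_id: str
    level: NGramLevel

    def __len__(self) -> int:
        return len(self.words)


def tokenize(record: SequenceRecord, level: NGramLevel | int) -> Sentence:
    """Slide a length-n window at stride 1 over the sequence.

    Word count is exactly L - n + 1; uppercase is preserved (records store
    uppercase already).
    """
    if isinstance(level, int):
        level = NGramLevel(level)
    n = level.n
    L = len(record.bases)
    if L < n:
        raise ValueError(
            f"record {record.id!r} (length {L}) shorter than n-gram level {n}"
        )
    words = tuple(record.bases[i:i + n] for i in range(L - n + 1))
    return Sentence(words=words, source_id=record.id, level=level)


def corpus_sentences(dataset: Dataset, level: NGramLevel | int) -> list[Sentence]:
    """One sentence per record, in dataset order."""
    if isinstance(level, int):
        level = NGramLevel(level)
    out = []
    for r in dataset.records:
        try:
            out.append(tokenize(r, level))
        except ValueError as e:
            raise ValueError(f"while tokenizing dataset at level {level.n}: {e}") from e
    return out


def write_sentences(sentences: list[Sentence], path: str | Path) -> None:
    """Export as a text corpus: one sentence per line, words space-separated."""
    with open(path, "w") as fh:
        for s in sentences:
            fh.write(" ".join(s.words))
            fh.write("\n")
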