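"""Subword-aware k-mer embeddings.

Each k-mer word w is represented by the bag of character n-grams of the
boundary-wrapped word "<w>" (sizes minn..maxn) plus the distinct whole-word
token "<w>" itself.  A word scores a context c as

    s(w, c) = sum over g in G_w of  z_g . v_c

where z_g are gram vectors and v_c context vectors.  Three training
objectives are provided: ``supervised`` (a text-classifier head over the
averaged sentence representation — the tuned setting), and the unsupervised
``skipgram`` / ``cbow`` objectives with full-softmax or negative-sampling
loss.  The gram dictionary is exact (no hash buckets): the ACGT gram space
is small enough that collisions are avoidable, which keeps training
bit-reproducible under a fixed seed.

A sequence vector is the unweighted mean over words of each word's
representation (itself the mean of its gram vectors), giving one
``dim``-length vector per sequence and per level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .tokenizer import NGramLevel, Sentence

BOUNDARY_LEFT = "<"
BOUNDARY_RIGHT = ">"

LOSSES = ("ns", "hs", "softmax")
OBJECTIVES = ("supervised", "skipgram", "cbow")


@dataclass
class EmbeddingConfig:
    """Training hyperparameters; defaults are the tuned optimum."""

    dim: int = 100
    lr: float = 0.1
    ws: int = 5
    epoch: int = 100
    loss: str = "softmax"
    objective: str = "supervised"
    minn: int = 3
    maxn: int = 6
    neg: int = 5          # negatives per positive pair (loss="ns")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 1 <= self.minn <= self.maxn:
            raise ValueError(f"require 1 <= minn <= maxn, got {self.minn}, {self.maxn}")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epoch < 1:
            raise ValueError("epoch must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")


def char_ngrams(word: str, minn: int = 3, maxn: int = 6) -> frozenset[str]:
    """Character n-grams of the boundary-wrapped word, plus the whole-word token.

    The whole-word token of "TGA" (i.e. "<TGA>") is distinct from the
    interior tri-gram "TGA" extracted from a longer word.  When the wrapped
    word is itself no longer than ``maxn`` the whole-word token coincides
    with one of the enumerated grams and appears once.
    """
    if not word:
        raise ValueError("word must be non-empty")
    if minn > maxn:
        raise ValueError(f"minn ({minn}) > maxn ({maxn})")
    wrapped = BOUNDARY_LEFT + word + BOUNDARY_RIGHT
    grams = {wrapped}
    for size in range(minn, maxn + 1):
        if size > len(wrapped):
            break
        if size == len(wrapped):
            # the full wrapped word is the whole-word token, already included
            continue
        for i in range(len(wrapped) - size + 1):
            grams.add(wrapped[i:i + size])
    return frozenset(grams)


def whole_word_token(word: str) -> str:
    return BOUNDARY_LEFT + word + BOUNDARY_RIGHT


class EmbeddingModel:
    """Trained per-level gram and context vector tables."""

    def __init__(self, level: NGramLevel, config: EmbeddingConfig,
                 gram_ids: dict[str, int], Z: np.ndarray,
                 context_ids: dict[str, int], V: np.ndarray) -> None:
        self.level = level
        self.config = config
        self.gram_ids = gram_ids
        self.Z = Z
        self.context_ids = context_ids
        self.V = V
        if Z.shape != (len(gram_ids), config.dim):
            raise ValueError("gram vector table shape mismatch")
        if V.shape != (len(context_ids), config.dim):
            raise ValueError("context vector table shape mismatch")
        self._word_rep_cache: dict[str, np.ndarray | None] = {}

    # -- Eq.-style accessors -------------------------------------------------
    @property
    def n_grams(self) -> int:
        """G: total number of gram tokens in the dictionary."""
        return len(self.gram_ids)

    def gram_vector(self, token: str) -> np.ndarray | None:
        i = self.gram_ids.get(token)
        return None if i is None else self.Z[i]

    @property
    def gram_vectors(self) -> dict[str, np.ndarray]:
        return {g: self.Z[i] for g, i in self.gram_ids.items()}

    @property
    def context_vectors(self) -> dict[str, np.ndarray]:
        return {c: self.V[i] for c, i in self.context_ids.items()}

    def known_gram_indices(self, word: str) -> np.ndarray:
        """Indices of the model-known grams of G_w (whole-word token included)."""
        grams = char_ngrams(word, self.config.minn, self.config.maxn)
        idx = [self.gram_ids[g] for g in sorted(grams) if g in self.gram_ids]
        return np.asarray(idx, dtype=np.int64)

    def word_vector(self, word: str) -> np.ndarray | None:
        """Mean of the word's known gram vectors; None if no gram is known."""
        rep = self._word_rep_cache.get(word, "miss")
        if not isinstance(rep, str):
            return rep
        idx = self.known_gram_indices(word)
        rep = None if idx.size == 0 else self.Z[idx].mean(axis=0)
        self._word_rep_cache[word] = rep
        return rep

    def predict_proba(self, sentence: Sentence) -> np.ndarray:
        """Class probabilities for a sentence (supervised models only)."""
        if self.config.objective != "supervised":
            raise ValueError("predict_proba requires a supervised model")
        h = sequence_vector(sentence, self)
        logits = self.V @ h
        e = np.exp(logits - logits.max())
        return e / e.sum()


def score(w: str, c: str, model: EmbeddingModel) -> float:
    """s(w, c) = sum over g in G_w of z_g . v_c (unknown grams contribute 0)."""
    ci = model.context_ids.get(c)
    if ci is None:
        return 0.0
    idx = model.known_gram_indices(w)
    if idx.size == 0:
        return 0.0
    return float(model.Z[idx].sum(axis=0) @ model.V[ci])


def sequence_vector(sentence: Sentence, model: EmbeddingModel) -> np.ndarray:
    """Mean over words of each word's (gram-mean) representation.

    Words none of whose grams are known are skipped; a sentence with no
    known grams at all yields a zero vector with a warning.
    """
    if len(sentence.words) == 0:
        raise ValueError(f"sentence {sentence.source_id!r} is empty")
    reps = [r for r in (model.word_vector(w) for w in sentence.words)
            if r is not None]
    if not reps:
        warnings.warn(
            f"sentence {sentence.source_id!r}: no model-known grams; zero vector",
            UserWarning,
        )
        return np.zeros(model.config.dim)
    return np.mean(reps, axis=0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _build_vocab(sentences: list[Sentence], config: EmbeddingConfig):
    words: dict[str, int] = {}
    for s in sentences:
        for w in s.words:
            words[w] = words.get(w, 0) + 1
    word_list = sorted(words)
    gram_set: set[str] = set()
    for w in word_list:
        gram_set |= char_ngrams(w, config.minn, config.maxn)
    gram_ids = {g: i for i, g in enumerate(sorted(gram_set))}
    counts = np.array([words[w] for w in word_list], dtype=float)
    return word_list, counts, gram_ids


def _word_gram_index(word_list, gram_ids, config):
    return {
        w: np.array(sorted(gram_ids[g]
                           for g in char_ngrams(w, config.minn, config.maxn)),
                    dtype=np.int64)
        for w in word_list
    }


def _softmax_vec(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def train_embedding(
    sentences: list[Sentence],
    labels: np.ndarray | None = None,
    config: EmbeddingConfig | None = None,
) -> EmbeddingModel:
    """Train a per-level embedding model on a sentence corpus.

    ``labels`` (binary, one per sentence) are required iff the objective is
    ``supervised``.  Training is deterministic given ``config.seed``.
    """
    config = config or EmbeddingConfig()
    if not sentences:
        raise ValueError("empty corpus")
    level = sentences[0].level
    if config.loss == "hs":
        raise ValueError("hierarchical softmax ('hs') is not supported; "
                         "use 'softmax' or 'ns'")
    if config.objective == "supervised":
        if labels is None:
            raise ValueError("supervised objective requires labels")
        labels = np.asarray(labels, dtype=np.int64)
        if labels.shape != (len(sentences),):
            raise ValueError("labels length must equal number of sentences")
        if len(np.unique(labels)) < 2:
            raise ValueError("supervised objective requires both classes")
        return _train_supervised(sentences, labels, config, level)
    return _train_unsupervised(sentences, config, level)


def _init_tables(rng, n_grams, n_ctx, dim):
    Z = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_grams, dim))
    V = np.zeros((n_ctx, dim))
    return Z, V


def _train_supervised(sentences, labels, config, level) -> EmbeddingModel:
    word_list, _, gram_ids = _build_vocab(sentences, config)
    gram_idx = _word_gram_index(word_list, gram_ids, config)
    rng = np.random.default_rng(config.seed)

    # per-sentence unique gram indices and mean weights:
    # word w contributes 1/(n_words * |G_w|) to each of its grams
    sent_idx: list[np.ndarray] = []
    sent_wgt: list[np.ndarray] = []
    for s in sentences:
        acc: dict[int, float] = {}
        nw = len(s.words)
        for w in s.words:
            gi = gram_idx[w]
            share = 1.0 / (nw * gi.size)
            for g in gi:
                acc[g] = acc.get(g, 0.0) + share
        items = sorted(acc.items())
        sent_idx.append(np.fromiter((k for k, _ in items), dtype=np.int64,
                                    count=len(items)))
        sent_wgt.append(np.fromiter((v for _, v in items), dtype=float,
                                    count=len(items)))

    classes = sorted(str(c) for c in np.unique(labels))
    context_ids = {c: i for i, c in enumerate(classes)}
    y_rows = np.array([context_ids[str(y)] for y in labels])

    Z, V = _init_tables(rng, len(gram_ids), len(classes), config.dim)
    n = len(sentences)
    history: list[float] = []
    # Adagrad: per-parameter adaptive steps keep lr meaningful regardless of
    # the (tiny) scale of the averaged sentence representation
    acc_z = np.full_like(Z, 1e-8)
    acc_v = np.full_like(V, 1e-8)
    for _ in range(config.epoch):
        for si in rng.permutation(n):
            idx, wgt = sent_idx[si], sent_wgt[si]
            h = wgt @ Z[idx]
            p = _softmax_vec(V @ h)
            g = p.copy()
            g[y_rows[si]] -= 1.0
            dh = V.T @ g
            dV = np.outer(g, h)
            acc_v += dV * dV
            V -= config.lr * dV / np.sqrt(acc_v)
            dZ = np.outer(wgt, dh)
            acc_z[idx] += dZ * dZ
            Z[idx] -= config.lr * dZ / np.sqrt(acc_z[idx])
        # full-corpus loss at epoch end (tracked for convergence diagnostics)
        loss = 0.0
        for si in range(n):
            h = sent_wgt[si] @ Z[sent_idx[si]]
            p = _softmax_vec(V @ h)
            loss -= np.log(max(p[y_rows[si]], 1e-300))
        history.append(loss / n)

    model = EmbeddingModel(level, config, gram_ids, Z, context_ids, V)
    model.loss_history = history
    return model


def _train_unsupervised(sentences, config, level) -> EmbeddingModel:
    word_list, counts, gram_ids = _build_vocab(sentences, config)
    gram_idx = _word_gram_index(word_list, gram_ids, config)
    word_ids = {w: i for i, w in enumerate(word_list)}
    rng = np.random.default_rng(config.seed)

    context_ids = {w: i for i, w in enumerate(word_list)}
    Z, V = _init_tables(rng, len(gram_ids), len(word_list), config.dim)
    noise = counts ** 0.75
    noise /= noise.sum()

    seqs = [np.array([word_ids[w] for w in s.words]) for s in sentences]
    n_tokens = sum(len(q) for q in seqs)
    total = config.epoch * n_tokens
    t = 0
    history: list[float] = []

    def word_rep(wi: int) -> tuple[np.ndarray, np.ndarray]:
        gi = gram_idx[word_list[wi]]
        return gi, Z[gi].mean(axis=0)

    for _ in range(config.epoch):
        epoch_loss, updates = 0.0, 0
        for si in rng.permutation(len(seqs)):
            q = seqs[si]
            for pos in range(len(q)):
                lo, hi = max(0, pos - config.ws), min(len(q), pos + config.ws + 1)
                ctx = [q[j] for j in range(lo, hi) if j != pos]
                if not ctx:
                    t += 1
                    continue
                lr_t = config.lr * (1.0 - t / total)
                if config.objective == "skipgram":
                    gi, h = word_rep(q[pos])
                    targets = ctx
                else:  # cbow: predict center from averaged context reps
                    parts = [word_rep(c) for c in ctx]
                    h = np.mean([p[1] for p in parts], axis=0)
                    gi = None
                    targets = [q[pos]]
                for tgt in targets:
                    if config.loss == "softmax":
                        p = _softmax_vec(V @ h)
                        epoch_loss -= np.log(max(p[tgt], 1e-300))
                        g = p
                        g[tgt] -= 1.0
                        dh = V.T @ g
                        V -= lr_t * np.outer(g, h)
                    else:  # negative sampling
                        negs = rng.choice(len(word_list), size=config.neg, p=noise)
                        rows = np.concatenate(([tgt], negs))
                        sgn = np.zeros(rows.size)
                        sgn[0] = 1.0
                        act = 1.0 / (1.0 + np.exp(-(V[rows] @ h)))
                        epoch_loss -= (np.log(max(act[0], 1e-300))
                                       + np.log(np.maximum(1 - act[1:], 1e-300)).sum())
                        g = act - sgn
                        dh = g @ V[rows]
                        V[rows] -= lr_t * np.outer(g, h)
                    if config.objective == "skipgram":
                        Z[gi] -= lr_t * dh / gi.size
                    else:
                        for pgi, _ in parts:
                            Z[pgi] -= lr_t * dh / (pgi.size * len(parts))
                    updates += 1
                t += 1
        history.append(epoch_loss / max(updates, 1))

    model = EmbeddingModel(level, config, gram_ids, Z, context_ids, V)
    model.loss_history = history
    return model


# ---------------------------------------------------------------------------
# Persistence: plain-text vector tables + JSON config header
# ---------------------------------------------------------------------------

def save_model(model: EmbeddingModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = {
            "level": model.level.n,
            "config": asdict(model.config),
            "n_grams": model.n_grams,
            "n_contexts": len(model.context_ids),
        }
        fh.write(json.dumps(header) + "\n")
        for g, i in sorted(model.gram_ids.items(), key=lambda kv: kv[1]):
            fh.write("g\t" + g + "\t"
                     + " ".join(repr(float(x)) for x in model.Z[i]) + "\n")
        for c, i in sorted(model.context_ids.items(), key=lambda kv: kv[1]):
            fh.write("c\t" + c + "\t"
                     + " ".join(repr(float(x)) for x in model.V[i]) + "\n")


def load_model(path: str | Path) -> EmbeddingModel:
    with open(path) as fh:
        header = json.loads(fh.readline())
        config = EmbeddingConfig(**header["config"])
        gram_ids: dict[str, int] = {}
        context_ids: dict[str, int] = {}
        Z = np.empty((header["n_grams"], config.dim))
        V = np.empty((header["n_contexts"], config.dim))
        for line in fh:
            kind, token, vals = line.rstrip("\n").split("\t")
            vec = np.fromiter(map(float, vals.split()), dtype=float)
            if kind == "g":
                gram_ids[token] = len(gram_ids)
                Z[gram_ids[token]] = vec
            else:
                context_ids[token] = len(context_ids)
                V[context_ids[token]] = vec
    return EmbeddingModel(NGramLevel(header["level"]), config, gram_ids, Z,
                          context_ids, V)
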