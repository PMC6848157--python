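"""Combined multi-level representations and MRMD feature ranking.

Per-level sequence vectors (one ``dim``-length vector per sequence per
n-gram level) are block-concatenated in ascending level order into a single
combined vector — 10 levels x 100 dimensions = 1,000 features at defaults.
Features can then be ranked by Maximum-Relevance-Maximum-Distance (MRMD):
relevance is the absolute Pearson correlation of a (standardized) feature
with the 0/1 label vector; distance is the mean of three inter-feature
dissimilarity components (Euclidean, cosine and Tanimoto distance), each
min-max scaled to [0, 1] across features before averaging.  Total scores
are normalized so the top-ranked feature scores exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import FeatureTable
from .embedding import EmbeddingModel, sequence_vector
from .tokenizer import Sentence

DEFAULT_LEVELS: tuple[int, ...] = tuple(range(1, 11))


@dataclass
class CombinedFeatureVector:
    """Level-ordered concatenation with a recorded block layout."""

    values: np.ndarray
    layout: list[tuple[int, int, int]]  # (level, offset, dim)

    def block(self, level: int) -> np.ndarray:
        for lv, off, dim in self.layout:
            if lv == level:
                return self.values[off:off + dim]
        raise KeyError(f"level {level} not in layout")


def combine(per_level: dict[int, np.ndarray],
            levels: tuple[int, ...] = DEFAULT_LEVELS) -> CombinedFeatureVector:
    """Concatenate per-level vectors in ascending level order.

    All configured levels must be present and share one dimension.
    """
    missing = [lv for lv in levels if lv not in per_level]
    if missing:
        raise ValueError(f"missing level(s): {missing}")
    dims = {lv: np.asarray(per_level[lv]).shape[0] for lv in levels}
    if len(set(dims.values())) > 1:
        raise ValueError(f"inconsistent per-level dims: {dims}")
    blocks, layout, off = [], [], 0
    for lv in sorted(levels):
        v = np.asarray(per_level[lv], dtype=float)
        blocks.append(v)
        layout.append((lv, off, v.shape[0]))
        off += v.shape[0]
    return CombinedFeatureVector(values=np.concatenate(blocks), layout=layout)


def combined_table(
    per_level_sentences: dict[int, list[Sentence]],
    models: dict[int, EmbeddingModel],
    labels: np.ndarray,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> FeatureTable:
    """Featurize a corpus: sequence vectors per level, combined per sample."""
    missing = [lv for lv in levels if lv not in models or lv not in per_level_sentences]
    if missing:
        raise ValueError(f"missing level(s): {missing}")
    n = len(per_level_sentences[levels[0]])
    rows = []
    for i in range(n):
        per_level = {
            lv: sequence_vector(per_level_sentences[lv][i], models[lv])
            for lv in levels
        }
        rows.append(combine(per_level, levels).values)
    sample_ids = [s.source_id for s in per_level_sentences[levels[0]]]
    names = [f"l{lv}_{j:03d}" for lv in sorted(levels)
             for j in range(models[lv].config.dim)]
    return FeatureTable(sample_ids=sample_ids, matrix=np.vstack(rows),
                        feature_names=names, labels=np.asarray(labels))


# ---------------------------------------------------------------------------
# MRMD
# ---------------------------------------------------------------------------

@dataclass
class MrmdRanking:
    feature_names: list[str]
    relevance: np.ndarray   # MR_i >= 0
    distance: np.ndarray    # MD_i >= 0
    scores: np.ndarray      # (MR_i + MD_i) / max, top feature == 1.0
    order: np.ndarray       # feature indices, score descending, ties by index
    normalizer: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature_name": self.feature_names,
            "MR": self.relevance,
            "MD": self.distance,
            "score": self.scores,
        })
        rank = np.empty(len(self.order), dtype=int)
        rank[self.order] = np.arange(1, len(self.order) + 1)
        df["rank"] = rank
        return df.sort_values("rank").reset_index(drop=True)


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def mrmd_rank(table: FeatureTable, standardize: bool = True) -> MrmdRanking:
    """Rank features by relevance to the label plus distance to other features."""
    X = table.matrix
    y = table.labels.astype(float)
    n, p = X.shape
    if p < 2:
        raise ValueError("MRMD requires at least 2 features")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("MRMD requires both classes present")

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    # relevance: |Pearson r| between feature and label; 0 for constant features
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    relevance = np.abs(np.where(sx > 0, r, 0.0))

    # distance: mean pairwise dissimilarity of feature columns, three ways
    G = X.T @ X                      # gram matrix of feature columns
    sq = np.diag(G)
    eu2 = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
    eu = np.sqrt(eu2)
    norms = np.sqrt(sq)
    denom_cos = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_sim = np.where(denom_cos > 0, G / denom_cos, 0.0)
        denom_tan = sq[:, None] + sq[None, :] - G
        tan_sim = np.where(denom_tan != 0, G / denom_tan, 0.0)
    mean_off = lambda D: (D.sum(axis=1) - np.diag(D)) / (p - 1)
    ed = mean_off(eu)
    cd = mean_off(1.0 - cos_sim)
    td = mean_off(1.0 - tan_sim)
    distance = (_minmax(ed) + _minmax(cd) + _minmax(td)) / 3.0

    total = relevance + distance
    normalizer = float(total.max())
    scores = total / normalizer if normalizer > 0 else total
    # descending score, ties broken by ascending feature index
    order = np.lexsort((np.arange(p), -scores))
    return MrmdRanking(
        feature_names=list(table.feature_names),
        relevance=relevance, distance=distance, scores=scores,
        order=order, normalizer=normalizer,
    )


def sweep_select(
    table: FeatureTable,
    ranking: MrmdRanking,
    classifier_factory,
    k_grid: list[int] | None = None,
    cv=None,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the top-k feature count maximizing CV accuracy (ties -> smallest k).

    ``classifier_factory()`` must return an estimator with fit/predict.
    ``cv`` is a FoldPlan (from :mod:`promlm.evaluation`) or None for a
    default stratified 5-fold plan.
    """
    from .evaluation import make_folds

    p = table.n_features
    if k_grid is None:
        k_grid = list(range(5, p + 1, 5)) or [p]
    if not k_grid:
        raise ValueError("empty k_grid")
    for k in k_grid:
        if not 1 <= k <= p:
            raise ValueError(f"k={k} outside [1, {p}]")
    k_grid = sorted(k_grid)  # ascending grid so argmax ties pick the smallest k
    plan = cv if cv is not None else make_folds(table.labels, seed=seed)

    accs = []
    for k in k_grid:
        keep = np.sort(ranking.order[:k])
        X, y = table.matrix[:, keep], table.labels
        fold_accs = []
        for f in range(plan.n_folds):
            tr, va = plan.assignments != f, plan.assignments == f
            clf = classifier_factory()
            clf.fit(X[tr], y[tr])
            fold_accs.append(float(np.mean(clf.predict(X[va]) == y[va])))
        accs.append(np.mean(fold_accs))
    best = int(np.argmax(accs))  # argmax takes first max -> smallest k on ties
    best_k = k_grid[best]
    mask = np.zeros(p, dtype=bool)
    mask[ranking.order[:best_k]] = True
    return best_k, mask
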