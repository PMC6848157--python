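"""End-to-end classifier: tokenize -> embed per level -> combine -> classify.

``PromoterClassifier`` wires the stages into one fit/predict object usable
inside the CV harness.  By default every trainable stage (embeddings, the
feature scaler, optional MRMD selection, the classifier) is fit on the
training fold only.  In *paper mode* the per-level embeddings are fit once
on the full dataset and shared across folds, reproducing the protocol in
which a single language model feeds all cross-validation splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import Dataset, FeatureTable, SequenceRecord
from .embedding import EmbeddingConfig, EmbeddingModel, sequence_vector, train_embedding
from .features import DEFAULT_LEVELS, MrmdRanking, mrmd_rank, sweep_select
from .models import CnnConfig, Conv1DNet, KnnModel, build_cnn
from .tokenizer import NGramLevel, tokenize


@dataclass
class PipelineConfig:
    levels: tuple[int, ...] = DEFAULT_LEVELS
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    cnn: CnnConfig | None = None          # input_dim filled in at fit time
    cnn_epochs: int = 100                 # used when cnn is None
    model: str = "cnn"                    # "cnn" | "knn"
    knn_k: int = 10
    select_k: int | None = None           # fixed top-k MRMD cut, None = off
    paper_mode: bool = False
    seed: int = 0


def fit_embeddings(records: list[SequenceRecord], labels: np.ndarray,
                   config: PipelineConfig) -> dict[int, EmbeddingModel]:
    """Train one embedding model per n-gram level."""
    models = {}
    for lv in config.levels:
        sents = [tokenize(r, NGramLevel(lv)) for r in records]
        econf = replace(config.embedding, seed=config.embedding.seed + lv)
        lab = labels if econf.objective == "supervised" else None
        models[lv] = train_embedding(sents, lab, econf)
    return models


def featurize_records(records: list[SequenceRecord],
                      models: dict[int, EmbeddingModel],
                      levels: tuple[int, ...]) -> np.ndarray:
    """Stack combined per-level sequence vectors for a list of records."""
    rows = []
    for r in records:
        parts = [sequence_vector(tokenize(r, NGramLevel(lv)), models[lv])
                 for lv in sorted(levels)]
        rows.append(np.concatenate(parts))
    return np.vstack(rows)


class PromoterClassifier:
    """Fit/predict over raw sequence records.

    Pass ``shared_embeddings`` (from :func:`fit_embeddings` on the full
    dataset) to run in paper mode; otherwise embeddings are trained inside
    ``fit`` on the given records only.
    """

    def __init__(self, config: PipelineConfig | None = None,
                 shared_embeddings: dict[int, EmbeddingModel] | None = None):
        self.config = config or PipelineConfig()
        self.shared_embeddings = shared_embeddings
        self.embeddings_: dict[int, EmbeddingModel] | None = shared_embeddings
        self.classifier_ = None
        self.mask_: np.ndarray | None = None
        self.ranking_: MrmdRanking | None = None
        self._mu = None
        self._sd = None

    def fit(self, records: list[SequenceRecord], y) -> "PromoterClassifier":
        y = np.asarray(y, dtype=np.int64)
        cfg = self.config
        if self.shared_embeddings is None:
            self.embeddings_ = fit_embeddings(records, y, cfg)
        X = featurize_records(records, self.embeddings_, cfg.levels)

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd == 0, 1.0, sd)
        Xs = (X - self._mu) / self._sd

        if cfg.select_k is not None:
            table = FeatureTable(
                sample_ids=[r.id for r in records], matrix=Xs,
                feature_names=[f"f{i}" for i in range(Xs.shape[1])], labels=y)
            self.ranking_ = mrmd_rank(table, standardize=False)
            mask = np.zeros(Xs.shape[1], dtype=bool)
            mask[self.ranking_.order[:cfg.select_k]] = True
            self.mask_ = mask
            Xs = Xs[:, mask]
        else:
            self.mask_ = None

        if cfg.model == "cnn":
            cnn_cfg = cfg.cnn or CnnConfig(input_dim=Xs.shape[1],
                                           epochs=cfg.cnn_epochs, seed=cfg.seed)
            if cnn_cfg.input_dim != Xs.shape[1]:
                cnn_cfg = replace(cnn_cfg, input_dim=Xs.shape[1])
            self.classifier_ = build_cnn(cnn_cfg).fit(Xs, y)
        elif cfg.model == "knn":
            self.classifier_ = KnnModel(k=cfg.knn_k).fit(Xs, y)
        else:
            raise ValueError(f"unknown model {cfg.model!r}")
        return self

    def _transform(self, records) -> np.ndarray:
        if self.embeddings_ is None:
            raise RuntimeError("pipeline is not fitted")
        X = featurize_records(records, self.embeddings_, self.config.levels)
        Xs = (X - self._mu) / self._sd
        if self.mask_ is not None:
            Xs = Xs[:, self.mask_]
        return Xs

    def predict_proba(self, records) -> np.ndarray:
        return self.classifier_.predict_proba(self._transform(records))

    def predict(self, records) -> np.ndarray:
        p = self.predict_proba(records)
        return np.where(p[:, 1] >= p[:, 0], 1, 0)

    def decision_scores(self, records) -> np.ndarray:
        return self.predict_proba(records)[:, 1]


def two_layer_predict(layer1: PromoterClassifier, layer2: PromoterClassifier,
                      records: list[SequenceRecord]) -> list[str]:
    """Cascade: layer-1 negatives -> 'non-promoter'; positives -> strong/weak."""
    if not records:
        return []
    calls1 = layer1.predict(records)
    out = ["non-promoter"] * len(records)
    pos_idx = np.flatnonzero(calls1 == 1)
    if pos_idx.size:
        sub = [records[i] for i in pos_idx]
        calls2 = layer2.predict(sub)
        for j, i in enumerate(pos_idx):
            out[i] = "strong" if calls2[j] == 1 else "weak"
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_pipeline(clf: PromoterClassifier, outdir) -> None:
    """Persist a fitted pipeline: embeddings as text tables, arrays as npz."""
    import json
    from pathlib import Path

    from .embedding import save_model
    from .models import Conv1DNet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if clf.embeddings_ is None or clf.classifier_ is None:
        raise RuntimeError("pipeline is not fitted")
    cfg = clf.config
    meta = {
        "levels": list(cfg.levels),
        "model": cfg.model,
        "knn_k": cfg.knn_k,
        "select_k": cfg.select_k,
        "paper_mode": cfg.paper_mode,
        "seed": cfg.seed,
        "embedding": {k: getattr(cfg.embedding, k)
                      for k in ("dim", "lr", "ws", "epoch", "loss", "objective",
                                "minn", "maxn", "neg", "seed")},
        "mask": None if clf.mask_ is None else clf.mask_.astype(int).tolist(),
    }
    if cfg.model == "cnn":
        meta["cnn"] = {k: getattr(clf.classifier_.config, k)
                       for k in ("input_dim", "n_filters", "kernel", "pool",
                                 "pool_stride", "dropout", "weight_max_norm",
                                 "batch_size", "epochs", "lr", "rho", "eps",
                                 "output_units", "seed")}
    with open(outdir / "pipeline.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    for lv, m in clf.embeddings_.items():
        save_model(m, outdir / f"embedding_l{lv}.txt")
    arrays = {"mu": clf._mu, "sd": clf._sd}
    if isinstance(clf.classifier_, Conv1DNet):
        arrays.update(W=clf.classifier_.W, b=clf.classifier_.b,
                      Wd=clf.classifier_.Wd, bd=clf.classifier_.bd)
    else:  # kNN keeps its (standardized, selected) training set
        arrays.update(knn_X=clf.classifier_.X_, knn_y=clf.classifier_.y_)
    np.savez(outdir / "arrays.npz", **arrays)


def load_pipeline(outdir) -> PromoterClassifier:
    import json
    from pathlib import Path

    from .embedding import load_model
    from .models import CnnConfig, KnnModel, build_cnn

    outdir = Path(outdir)
    with open(outdir / "pipeline.json") as fh:
        meta = json.load(fh)
    emb_cfg = EmbeddingConfig(**meta["embedding"])
    cfg = PipelineConfig(levels=tuple(meta["levels"]), embedding=emb_cfg,
                         model=meta["model"], knn_k=meta["knn_k"],
                         select_k=meta["select_k"],
                         paper_mode=meta["paper_mode"], seed=meta["seed"])
    clf = PromoterClassifier(cfg)
    clf.embeddings_ = {lv: load_model(outdir / f"embedding_l{lv}.txt")
                       for lv in cfg.levels}
    data = np.load(outdir / "arrays.npz")
    clf._mu, clf._sd = data["mu"], data["sd"]
    clf.mask_ = (None if meta["mask"] is None
                 else np.asarray(meta["mask"], dtype=bool))
    if cfg.model == "cnn":
        net = build_cnn(CnnConfig(**meta["cnn"]))
        net.W, net.b = data["W"], data["b"]
        net.Wd, net.bd = data["Wd"], data["bd"]
        clf.classifier_ = net
    else:
        clf.classifier_ = KnnModel(k=cfg.knn_k).fit(data["knn_X"], data["knn_y"])
    return clf
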