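"""Experiment orchestration: the feature × extractor × classifier grid,
screening bundles for virtual-screening runs, and a t-SNE diagnostic.

Every grid cell runs on one shared train/test split; results land in a
report table shaped Feature / Extractor / Classifier / Accuracy /
Precision / Recall / F1, and a manifest records every seed and
configuration so the full table can be reproduced bitwise from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import mol2vec as m2v
from .classify import ClassifierSpec, evaluate, fit_predict, make_classifier
from .data import Dataset, SplitSpec, split_dataset
from .encoding import TokenMatrix, encode_matrix
from .extractors import (
    ExtractorConfig,
    NEURAL_KINDS,
    SELECTOR_KINDS,
    TrainedExtractor,
    build_neural,
    fit as fit_extractor,
    fit_selector,
    identity_extractor,
)
from .fingerprints import fingerprint_matrix

__all__ = [
    "ExperimentGrid",
    "run_grid",
    "run_grid_from_manifest",
    "ScreeningBundle",
    "fit_bundle",
    "tsne_diagnostic",
]

FEATURE_NAMES = ("rdkfp", "morganfp", "mol2vec")


@dataclass(frozen=True)
class ExperimentGrid:
    """One experiment: features × extractors × classifiers on a shared split.

    Neural training lengths default to the reference schedule — 15 epochs
    on fingerprint tokens, 100 epochs / batch 50 on molecule vectors.
    """

    features: tuple[str, ...] = ("morganfp",)
    extractors: tuple[str, ...] = ("none",)
    classifiers: tuple[str, ...] = ("svm",)
    split: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 0
    nbits: int = 2048
    mol2vec_dim: int = 100
    mol2vec_radius: int = 1
    mol2vec_epochs: int = 5
    epochs_tokens: int = 15
    epochs_vector: int = 100
    batch_size: int = 50
    learning_rate: float = 0.00025

    def __post_init__(self) -> None:
        for f in self.features:
            if f not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {f!r}")
        for e in self.extractors:
            if e not in ("none",) + SELECTOR_KINDS + NEURAL_KINDS:
                raise ValueError(f"unknown extractor {e!r}")
        for c in self.classifiers:
            if c not in ("lr", "knn", "rf", "dt", "svm", "neural_head"):
                raise ValueError(f"unknown classifier {c!r}")
        if not (self.features and self.extractors and self.classifiers):
            raise ValueError("grid must name at least one feature, extractor and classifier")


def _split_hash(test: Dataset) -> str:
    lines = sorted(f"{r.id}\t{r.smiles}" for r in test)
    return hashlib.md5("\n".join(lines).encode()).hexdigest()[:16]


def _featurize(grid: ExperimentGrid, feature: str, train: Dataset, test: Dataset):
    """Raw train/test feature matrices plus token matrices for fingerprints."""
    if feature == "mol2vec":
        corpus = m2v.corpus(train.smiles, radius=grid.mol2vec_radius)
        table = m2v.train_embeddings(
            corpus, dim=grid.mol2vec_dim, epochs=grid.mol2vec_epochs, seed=grid.seed
        )
        xtr = m2v.embed_molecules(train.smiles, table, radius=grid.mol2vec_radius)
        xte = (
            m2v.embed_molecules(test.smiles, table, radius=grid.mol2vec_radius)
            if len(test)
            else np.zeros((0, grid.mol2vec_dim))
        )
        return {"raw_train": xtr, "raw_test": xte, "table": table, "input_kind": "vector"}
    kind = "morgan" if feature == "morganfp" else "topological"
    ftr = fingerprint_matrix(train.smiles, kind=kind, nbits=grid.nbits)
    fte = fingerprint_matrix(test.smiles, kind=kind, nbits=grid.nbits)
    tok_tr = encode_matrix(ftr)  # freezes l_pad on the training set
    tok_te = (
        encode_matrix(fte, l_pad=tok_tr.l_pad)
        if len(fte)
        else TokenMatrix(rows=np.zeros((0, tok_tr.l_pad), dtype=np.int64), l_pad=tok_tr.l_pad, nbits=grid.nbits)
    )
    return {
        "raw_train": ftr.astype(float),
        "raw_test": fte.astype(float),
        "tokens_train": tok_tr,
        "tokens_test": tok_te,
        "input_kind": "tokens",
    }


def _extractor_config(grid: ExperimentGrid, kind: str, input_kind: str) -> ExtractorConfig:
    epochs = grid.epochs_tokens if input_kind == "tokens" else grid.epochs_vector
    return ExtractorConfig(
        kind=kind,
        epochs=epochs,
        batch_size=grid.batch_size,
        learning_rate=grid.learning_rate,
        seed=grid.seed,
    )


def _fit_cell_extractor(grid: ExperimentGrid, kind: str, feats: dict, y_train: np.ndarray) -> TrainedExtractor:
    if kind == "none":
        return identity_extractor(feats["raw_train"].shape[1])
    if kind in SELECTOR_KINDS:
        cfg = _extractor_config(grid, kind, "matrix")
        return fit_selector(kind, feats["raw_train"], y_train, cfg)
    cfg = _extractor_config(grid, kind, feats["input_kind"])
    if feats["input_kind"] == "tokens":
        tok = feats["tokens_train"]
        model = build_neural(cfg, "tokens", l_pad=tok.l_pad, vocab_size=tok.vocabulary_size)
        return fit_extractor(model, tok, y_train, cfg)
    model = build_neural(cfg, "vector", input_dim=feats["raw_train"].shape[1])
    return fit_extractor(model, feats["raw_train"], y_train, cfg)


def _cell_inputs(feats: dict, extractor_kind: str):
    if extractor_kind in NEURAL_KINDS and feats["input_kind"] == "tokens":
        return feats["tokens_train"], feats["tokens_test"]
    return feats["raw_train"], feats["raw_test"]


def run_grid(dataset: Dataset, grid: ExperimentGrid) -> tuple[pd.DataFrame, dict]:
    """Run every (feature, extractor, classifier) cell on one shared split.

    A failing cell is recorded with its error message and the remaining
    cells proceed.  Returns the report table and a manifest sufficient to
    reproduce it bitwise via :func:`run_grid_from_manifest`.
    """
    train, test = split_dataset(dataset, grid.split)
    y_train, y_test = train.labels, test.labels
    rows = []
    for feature in grid.features:
        feats = _featurize(grid, feature, train, test)
        for ext_kind in grid.extractors:
            try:
                trained = _fit_cell_extractor(grid, ext_kind, feats, y_train)
                xin_tr, xin_te = _cell_inputs(feats, ext_kind)
                f_train = trained.extract(xin_tr)
                f_test = trained.extract(xin_te)
            except Exception as err:  # noqa: BLE001 - cell isolation is the contract
                for clf in grid.classifiers:
                    rows.append(_error_row(feature, ext_kind, clf, err))
                continue
            for clf in grid.classifiers:
                try:
                    if clf == "neural_head":
                        if trained.model is None:
                            raise ValueError("neural_head needs a neural extractor")
                        y_pred = (trained.predict_proba(xin_te) >= 0.5).astype(int)
                    else:
                        y_pred = fit_predict(ClassifierSpec(name=clf), f_train, y_train, f_test)
                    rep = evaluate(y_test, y_pred)
                    rows.append(
                        {
                            "feature": feature,
                            "extractor": ext_kind,
                            "classifier": clf,
                            "accuracy": rep.accuracy,
                            "precision": rep.precision,
                            "recall": rep.recall,
                            "f1": rep.f1,
                            "error": "",
                        }
                    )
                except Exception as err:  # noqa: BLE001
                    rows.append(_error_row(feature, ext_kind, clf, err))
    table = pd.DataFrame(rows)
    ok = table["error"] == ""
    table["best_in_feature"] = False
    for feature in grid.features:
        group = table[(table["feature"] == feature) & ok]
        if len(group):
            table.loc[group["f1"].idxmax(), "best_in_feature"] = True
    manifest = {
        "grid": _grid_to_dict(grid),
        "split_hash": _split_hash(test),
        "n_train": len(train),
        "n_test": len(test),
    }
    return table, manifest


def _error_row(feature, ext_kind, clf, err) -> dict:
    return {
        "feature": feature,
        "extractor": ext_kind,
        "classifier": clf,
        "accuracy": math.nan,
        "precision": math.nan,
        "recall": math.nan,
        "f1": math.nan,
        "error": f"{type(err).__name__}: {err}",
    }


def _grid_to_dict(grid: ExperimentGrid) -> dict:
    d = asdict(grid)
    d["split"] = asdict(grid.split)
    return d


def grid_from_dict(d: dict) -> ExperimentGrid:
    d = dict(d)
    split = SplitSpec(**d.pop("split"))
    for key in ("features", "extractors", "classifiers"):
        d[key] = tuple(d[key])
    return ExperimentGrid(split=split, **d)


def run_grid_from_manifest(dataset: Dataset, manifest: dict) -> tuple[pd.DataFrame, dict]:
    """Re-run a grid from its manifest; verifies the split hash matches."""
    grid = grid_from_dict(manifest["grid"])
    table, new_manifest = run_grid(dataset, grid)
    if new_manifest["split_hash"] != manifest["split_hash"]:
        raise ValueError("split hash mismatch: dataset differs from the manifest's run")
    return table, new_manifest


# ---------------------------------------------------------------------------
# screening bundles


@dataclass
class ScreeningBundle:
    """Frozen featurizer + extractor + classifier for streaming prediction."""

    feature: str
    grid: ExperimentGrid
    extractor: TrainedExtractor
    classifier: object | Literal["neural_head"]
    table: m2v.EmbeddingTable | None = None  # mol2vec only

    def _featurize_batch(self, smiles: list[str]):
        if self.feature == "mol2vec":
            raw = m2v.embed_molecules(smiles, self.table, radius=self.grid.mol2vec_radius)
            return raw, raw
        kind = "morgan" if self.feature == "morganfp" else "topological"
        fps = fingerprint_matrix(smiles, kind=kind, nbits=self.grid.nbits)
        if self.extractor.kind in NEURAL_KINDS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # truncation against frozen l_pad
                tokens = encode_matrix(fps, l_pad=self.extractor.l_pad)
            return fps.astype(float), tokens
        return fps.astype(float), fps.astype(float)

    def screen(self, smiles_iter: Iterable[str | tuple[str, str]], batch_size: int = 256) -> pd.DataFrame:
        """Streaming prediction: constant memory in the candidate count.

        Accepts SMILES strings or (id, SMILES) pairs; unparseable SMILES
        are skipped with a warning.  Returns id, smiles, probability and
        predicted label per surviving molecule.
        """
        out_frames = []
        batch_ids: list[str] = []
        batch_smi: list[str] = []
        counter = 0

        def flush():
            if not batch_smi:
                return
            raw, model_in = self._featurize_batch(batch_smi)
            if self.classifier == "neural_head":
                prob = self.extractor.predict_proba(model_in)
            else:
                feats = self.extractor.extract(model_in)
                prob = _classifier_proba(self.classifier, feats)
            out_frames.append(
                pd.DataFrame(
                    {
                        "id": list(batch_ids),
                        "smiles": list(batch_smi),
                        "probability": prob,
                        "label": (prob >= 0.5).astype(int),
                    }
                )
            )
            batch_ids.clear()
            batch_smi.clear()

        for item in smiles_iter:
            rid, smi = item if isinstance(item, tuple) else (f"cand{counter}", item)
            counter += 1
            if Chem.MolFromSmiles(smi) is None:
                warnings.warn(f"unparseable candidate SMILES {smi!r}; skipped")
                continue
            batch_ids.append(rid)
            batch_smi.append(smi)
            if len(batch_smi) >= batch_size:
                flush()
        flush()
        if not out_frames:
            return pd.DataFrame(columns=["id", "smiles", "probability", "label"])
        return pd.concat(out_frames, ignore_index=True)


def _classifier_proba(clf, feats: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(feats)[:, 1]
    # margin classifiers (SVM): squash the decision function
    z = clf.decision_function(feats)
    return 1.0 / (1.0 + np.exp(-z))


def fit_bundle(
    train: Dataset,
    feature: str,
    extractor: str,
    classifier: str,
    grid: ExperimentGrid | None = None,
) -> ScreeningBundle:
    """Train one (feature, extractor, classifier) cell as a screening bundle."""
    grid = replace(
        grid or ExperimentGrid(),
        features=(feature,),
        extractors=(extractor,),
        classifiers=(classifier,),
    )
    feats = _featurize(grid, feature, train, Dataset([]))
    y = train.labels
    trained = _fit_cell_extractor(grid, extractor, feats, y)
    xin_tr, _ = _cell_inputs(feats, extractor)
    if classifier == "neural_head":
        clf: object = "neural_head"
    else:
        clf = make_classifier(ClassifierSpec(name=classifier))
        clf.fit(trained.extract(xin_tr), y)
    return ScreeningBundle(
        feature=feature,
        grid=grid,
        extractor=trained,
        classifier=clf,
        table=feats.get("table"),
    )


def tsne_diagnostic(
    features: np.ndarray, labels: np.ndarray | None = None, seed: int = 0
) -> tuple[np.ndarray, float]:
    """2-D t-SNE embedding plus a silhouette separation score (diagnostic only)."""
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 points, got {n}")
    if np.allclose(features.std(axis=0), 0):
        # all points identical: the embedding is degenerate but well-defined
        coords = np.zeros((n, 2))
        return coords, math.nan
    perplexity = min(30.0, max(2.0, (n - 2) / 3))
    coords = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca").fit_transform(
        features
    )
    score = math.nan
    if labels is not None:
        labels = np.asarray(labels)
        if np.unique(labels).size >= 2:
            try:
                score = float(silhouette_score(coords, labels))
            except ValueError:
                score = math.nan
    return coords, score
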