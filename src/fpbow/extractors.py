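"""Feature extractors: 1D-CNN / LSTM / Bi-LSTM and classical selectors.

The neural extractors consume either padded token matrices (bag-of-words
fingerprint codes, entering through an embedding layer with the pad masked)
or dense molecule vectors (treated as a single-channel sequence so the same
convolutional stack applies).  The architecture follows the reference
configuration: two convolutions with 32 and 16 filters of kernel size 8, a
max-pool of 3, dense layers tapering to the sigmoid output, all hidden
activations ReLU; recurrent extractors use 128 units on fingerprint tokens
and 64 on molecule vectors, at most two stacked layers.  Adam with learning
rate 2.5e-4 and binary cross-entropy are the training defaults.

Classical baselines: PCA keeping 90% variance, LDA (one dimension for a
binary problem) and decision-tree feature selection retaining features with
impurity importance above 0.005.

Features handed to downstream classifiers are the activations of the
penultimate dense layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.tree import DecisionTreeClassifier

from .encoding import TokenMatrix
from .nn import LSTM, Bidirectional, Conv1D, Dense, Embedding, Flatten, MaxPool1D, Network, ReLU

__all__ = [
    "ExtractorConfig",
    "TrainedExtractor",
    "build_neural",
    "fit",
    "extract",
    "fit_selector",
    "LEARNING_RATE_GRID",
    "sweep_learning_rates",
]

NEURAL_KINDS = ("cnn", "lstm", "bilstm")
SELECTOR_KINDS = ("pca", "lda", "dta")
LEARNING_RATE_GRID = (0.0001, 0.00025, 0.0005, 0.001)

MAX_RECURRENT_LAYERS = 2


@dataclass(frozen=True)
class ExtractorConfig:
    """Hyperparameters of one extractor; defaults are the reference settings."""

    kind: Literal["cnn", "lstm", "bilstm", "pca", "lda", "dta", "none"] = "cnn"
    conv_filters: tuple[int, int] = (32, 16)
    kernel_size: int = 8
    pool_size: int = 3
    recurrent_units: int | None = None  # auto: 128 for tokens, 64 for vectors
    recurrent_layers: int = 1
    embedding_dim: int = 64
    dense_sizes: tuple[int, ...] = (128, 32)
    learning_rate: float = 0.00025
    epochs: int = 15
    batch_size: int = 50
    seed: int = 0
    pca_variance: float = 0.9
    dta_importance_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.recurrent_layers > MAX_RECURRENT_LAYERS:
            raise ValueError(
                f"recurrent_layers={self.recurrent_layers} exceeds the maximum of {MAX_RECURRENT_LAYERS}"
            )
        if self.kind == "cnn" and self.recurrent_units is not None:
            raise ValueError("recurrent_units is meaningless for a cnn extractor")


def _auto_units(config: ExtractorConfig, input_kind: str) -> int:
    if config.recurrent_units is not None:
        return config.recurrent_units
    return 128 if input_kind == "tokens" else 64


def build_neural(
    config: ExtractorConfig,
    input_kind: Literal["tokens", "vector"],
    l_pad: int | None = None,
    vocab_size: int | None = None,
    input_dim: int | None = None,
) -> Network:
    """Assemble an untrained network for the given input kind.

    Token input starts with an embedding layer over codes 0..nbits
    (vocabulary nbits + 1, pad code 0 frozen at zero); vector input is
    reshaped to a single-channel sequence.  The head is a sigmoid unit.
    """
    if config.kind not in NEURAL_KINDS:
        raise ValueError(f"not a neural extractor kind: {config.kind!r}")
    rng = np.random.default_rng(config.seed)
    trunk: list = []
    if input_kind == "tokens":
        if l_pad is None or vocab_size is None:
            raise ValueError("token input requires l_pad and vocab_size")
        trunk.append(Embedding(vocab_size, config.embedding_dim, rng))
        seq_len, channels = l_pad, config.embedding_dim
    elif input_kind == "vector":
        if input_dim is None:
            raise ValueError("vector input requires input_dim")
        trunk.append(_AsSequence())
        seq_len, channels = input_dim, 1
    else:
        raise ValueError(f"unknown input kind {input_kind!r}")

    if config.kind == "cnn":
        f1, f2 = config.conv_filters
        k, p = config.kernel_size, config.pool_size
        trunk += [Conv1D(channels, f1, k, rng), ReLU(), Conv1D(f1, f2, k, rng), ReLU()]
        conv_len = seq_len - 2 * (k - 1)
        if conv_len < p:
            raise ValueError(f"input length {seq_len} too short for conv/pool stack")
        trunk += [MaxPool1D(p), Flatten()]
        width = (conv_len // p) * f2
    else:
        units = _auto_units(config, input_kind)
        if config.recurrent_layers == 2:
            if config.kind == "lstm":
                trunk.append(LSTM(channels, units, rng, return_sequences=True))
                trunk.append(LSTM(units, units, rng))
            else:
                trunk.append(Bidirectional(channels, units, rng, return_sequences=True))
                trunk.append(Bidirectional(2 * units, units, rng))
        else:
            cls = LSTM if config.kind == "lstm" else Bidirectional
            trunk.append(cls(channels, units, rng))
        width = units if config.kind == "lstm" else 2 * units

    for size in config.dense_sizes:
        trunk += [Dense(width, size, rng), ReLU()]
        width = size
    head = Dense(width, 1, rng)
    return Network(trunk=trunk, head=head, feature_dim=width)


class _AsSequence:
    """Reshape (N, D) vectors to a (N, D, 1) single-channel sequence."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)[:, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, :, 0]

    def params(self):
        return []


@dataclass
class TrainedExtractor:
    """A fitted extractor: frozen transform + the input spec it expects."""

    kind: str
    config: ExtractorConfig
    output_dim: int
    model: Network | None = None
    transform: object | None = None  # fitted sklearn transform or feature mask
    input_kind: str = "matrix"
    l_pad: int | None = None
    input_dim: int | None = None
    history: dict = field(default_factory=dict)

    def extract(self, x: np.ndarray | TokenMatrix) -> np.ndarray:
        return extract(self, x)

    def predict_proba(self, x: np.ndarray | TokenMatrix) -> np.ndarray:
        """Sigmoid-head output (neural extractors only)."""
        if self.model is None:
            raise ValueError(f"{self.kind} extractor has no neural head")
        return self.model.predict_proba(_conform(self, x))


def _conform(trained: TrainedExtractor, x) -> np.ndarray:
    if isinstance(x, TokenMatrix):
        x = x.rows
    x = np.asarray(x)
    if trained.l_pad is not None and x.shape[1] != trained.l_pad:
        raise ValueError(f"expected rows of length {trained.l_pad}, got {x.shape[1]}")
    if trained.input_dim is not None and x.shape[1] != trained.input_dim:
        raise ValueError(f"expected {trained.input_dim}-dimensional input, got {x.shape[1]}")
    return x


def fit(
    model: Network,
    x: np.ndarray | TokenMatrix,
    y: np.ndarray,
    config: ExtractorConfig,
) -> TrainedExtractor:
    """Train a neural extractor (Adam, binary cross-entropy, seeded)."""
    input_kind = "tokens" if isinstance(x, TokenMatrix) else "vector"
    l_pad = x.l_pad if isinstance(x, TokenMatrix) else None
    input_dim = None if isinstance(x, TokenMatrix) else np.asarray(x).shape[1]
    xr = x.rows if isinstance(x, TokenMatrix) else np.asarray(x, dtype=float)
    model.fit(
        xr,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        seed=config.seed,
    )
    return TrainedExtractor(
        kind=config.kind,
        config=config,
        output_dim=model.feature_dim,
        model=model,
        input_kind=input_kind,
        l_pad=l_pad,
        input_dim=input_dim,
        history=dict(model.history),
    )


def extract(trained: TrainedExtractor, x: np.ndarray | TokenMatrix) -> np.ndarray:
    """Feature matrix for downstream classifiers (deterministic inference)."""
    xr = _conform(trained, x)
    if trained.kind == "none":
        return np.asarray(xr, dtype=float)
    if trained.model is not None:
        out = []
        for lo in range(0, xr.shape[0], 512):
            out.append(trained.model.features(xr[lo : lo + 512]))
        return np.concatenate(out, axis=0)
    if trained.kind == "dta":
        return np.asarray(xr, dtype=float)[:, trained.transform]
    return trained.transform.transform(xr)


def identity_extractor(input_dim: int) -> TrainedExtractor:
    """Pass-through "extractor" so raw features run through the same grid path."""
    return TrainedExtractor(
        kind="none",
        config=ExtractorConfig(kind="none"),
        output_dim=input_dim,
        input_dim=input_dim,
    )


def fit_selector(
    kind: Literal["pca", "lda", "dta"],
    x: np.ndarray,
    y: np.ndarray | None,
    config: ExtractorConfig | None = None,
) -> TrainedExtractor:
    """Fit a classical feature selector.

    PCA keeps the minimal component count explaining at least the
    configured variance fraction (default 0.9) and ignores labels; LDA
    projects binary problems to a single discriminant axis; the decision-
    tree selector keeps exactly the features whose impurity importance
    exceeds the threshold (default 0.005), tree seeded from the config.
    """
    config = config or ExtractorConfig(kind=kind)
    x = np.asarray(x, dtype=float)
    if kind == "pca":
        if np.allclose(x.std(axis=0), 0):
            raise ValueError("PCA is degenerate on constant-column input")
        model = PCA(n_components=config.pca_variance, svd_solver="full").fit(x)
        out_dim = model.n_components_
        transform = model
    elif kind in ("lda", "dta"):
        if y is None:
            raise ValueError(f"{kind} requires labels")
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError(f"{kind} requires both classes in y")
        if kind == "lda":
            model = LinearDiscriminantAnalysis().fit(x, y)
            out_dim = np.unique(y).size - 1
            transform = model
        else:
            tree = DecisionTreeClassifier(random_state=config.seed).fit(x, y)
            mask = np.flatnonzero(tree.feature_importances_ > config.dta_importance_threshold)
            if mask.size == 0:
                raise ValueError("no feature exceeds the importance threshold")
            out_dim = mask.size
            transform = mask
    else:
        raise ValueError(f"unknown selector kind {kind!r}")
    return TrainedExtractor(
        kind=kind,
        config=replace(config, kind=kind),
        output_dim=out_dim,
        transform=transform,
        input_dim=x.shape[1],
    )


def sweep_learning_rates(
    build,
    x,
    y,
    config: ExtractorConfig,
    rates: Sequence[float] = LEARNING_RATE_GRID,
) -> tuple[TrainedExtractor, dict[float, float]]:
    """Train one extractor per learning rate; return the lowest-final-loss one.

    ``build`` is a zero-argument callable returning a fresh untrained
    network (so every rate starts from identical weights for a given seed).
    """
    results: dict[float, float] = {}
    best: TrainedExtractor | None = None
    for rate in rates:
        trained = fit(build(), x, y, replace(config, learning_rate=rate))
        results[rate] = trained.history["loss"][-1] if trained.history["loss"] else float("inf")
        if best is None or results[rate] < results[best.config.learning_rate]:
            best = trained
    return best, results
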