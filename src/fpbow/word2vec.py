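"""Minimal skip-gram word embeddings with negative sampling.

A compact, seeded trainer for corpora of short sentences: each center word
predicts its context words within a dynamically shrunk window; negative
examples are drawn from the unigram distribution raised to 3/4.  Designed
for the desk-scale substructure corpora used in this package, not for
web-scale text.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

__all__ = ["train_skipgram"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    sentences: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    min_count: int = 1,
    negative: int = 5,
    epochs: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train skip-gram/negative-sampling embeddings; returns word → vector.

    Words occurring fewer than ``min_count`` times are dropped from the
    vocabulary.  Fixed seed gives a bitwise-reproducible table (the trainer
    is single-threaded by construction).
    """
    if not sentences:
        raise ValueError("empty corpus")
    counts = Counter(w for s in sentences for w in s)
    vocab = [w for w, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])) if c >= min_count]
    if not vocab:
        raise ValueError(f"no word reaches min_count={min_count}")
    index = {w: i for i, w in enumerate(vocab)}
    encoded = [np.array([index[w] for w in s if w in index], dtype=np.int64) for s in sentences]
    encoded = [s for s in encoded if s.size]

    rng = np.random.default_rng(seed)
    v = len(vocab)
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    neg_p = freq / freq.sum()

    for _ in range(epochs):
        for sent in encoded:
            n = sent.size
            for pos in range(n):
                center = sent[pos]
                b = int(rng.integers(1, window + 1))
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = sent[cpos]
                    targets = np.empty(negative + 1, dtype=np.int64)
                    targets[0] = context
                    targets[1:] = rng.choice(v, size=negative, p=neg_p)
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    h = w_in[center]
                    scores = _sigmoid(w_out[targets] @ h)
                    g = (scores - labels) * lr
                    grad_h = g @ w_out[targets]
                    w_out[targets] -= np.outer(g, h)
                    w_in[center] -= grad_h
    return {w: w_in[i].copy() for w, i in index.items()}
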