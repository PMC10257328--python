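"""Bag-of-words densification of sparse binary fingerprints.

Each fingerprint bit index ``n`` (0-based) is treated as a vocabulary word
with integer code ``n + 1``; a molecule becomes the ascending sequence of
codes of its set bits.  Code 0 is reserved for padding, so an embedding
layer over codes ``0..nbits`` (vocabulary size ``nbits + 1``) can mask the
pad.  Sequences are right-padded to a common length that is frozen on the
training set; longer rows at inference are right-truncated with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fingerprints import FingerprintVector

__all__ = ["TokenSequence", "TokenMatrix", "encode", "decode", "pad"]

PAD_CODE = 0


@dataclass(frozen=True)
class TokenSequence:
    """Ascending integer codes of a fingerprint's set bits."""

    codes: np.ndarray  # 1-D int array, strictly ascending, values >= 1
    nbits: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if codes.size and (codes.min() < 1 or codes.max() > self.nbits):
            raise ValueError(f"codes must lie in [1, {self.nbits}]")
        if codes.size > 1 and not (np.diff(codes) > 0).all():
            raise ValueError("codes must be strictly ascending")
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class TokenMatrix:
    """N right-padded code rows of common length ``l_pad`` (pad code 0)."""

    rows: np.ndarray  # (N, l_pad) int64
    l_pad: int
    nbits: int

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.int64)
        if rows.ndim != 2 or rows.shape[1] != self.l_pad:
            raise ValueError(f"rows must be N x {self.l_pad}")
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return self.rows.shape[0]

    @property
    def vocabulary_size(self) -> int:
        """Embedding vocabulary: codes 0..nbits inclusive."""
        return self.nbits + 1


def encode(fp: FingerprintVector | np.ndarray, nbits: int | None = None) -> TokenSequence:
    """Set bit at index i  →  code i + 1, in ascending index order."""
    if isinstance(fp, FingerprintVector):
        bits, nbits = fp.bits, fp.nbits
    else:
        bits = np.asarray(fp, dtype=np.uint8)
        nbits = nbits if nbits is not None else bits.shape[0]
    return TokenSequence(codes=np.flatnonzero(bits) + 1, nbits=nbits)


def decode(seq: TokenSequence | np.ndarray, nbits: int | None = None) -> np.ndarray:
    """Inverse of :func:`encode`: bit c − 1 set for every code c (pad 0 ignored)."""
    if isinstance(seq, TokenSequence):
        codes, nbits = seq.codes, seq.nbits
    else:
        codes = np.asarray(seq, dtype=np.int64)
        codes = codes[codes != PAD_CODE]
        if nbits is None:
            raise ValueError("nbits required when decoding a raw code array")
    if codes.size and (codes.min() < 1 or codes.max() > nbits):
        raise ValueError(f"codes out of range [1, {nbits}]")
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[codes - 1] = 1
    return bits


def encode_matrix(fps: np.ndarray, l_pad: int | None = None) -> TokenMatrix:
    """Encode an N × nbits binary matrix into a padded token matrix."""
    nbits = fps.shape[1]
    seqs = [TokenSequence(np.flatnonzero(row) + 1, nbits) for row in np.asarray(fps, dtype=np.uint8)]
    return pad(seqs, length=l_pad)


def pad(seqs: Sequence[TokenSequence], length: int | None = None) -> TokenMatrix:
    """Right-pad token sequences to a rectangular matrix.

    ``length=None`` (auto) freezes ``l_pad`` at the longest sequence; with a
    frozen length, longer rows are right-truncated and a warning names how
    many rows lost codes.  A zero-bit molecule yields an all-pad row.
    """
    if not seqs:
        raise ValueError("cannot pad an empty collection of sequences")
    nbits = seqs[0].nbits
    if any(s.nbits != nbits for s in seqs):
        raise ValueError("sequences disagree on nbits")
    l_pad = max(len(s) for s in seqs) if length is None else int(length)
    rows = np.full((len(seqs), l_pad), PAD_CODE, dtype=np.int64)
    truncated = 0
    for i, s in enumerate(seqs):
        codes = s.codes
        if codes.size > l_pad:
            codes = codes[:l_pad]
            truncated += 1
        rows[i, : codes.size] = codes
    if truncated:
        warnings.warn(f"{truncated} row(s) truncated to frozen length {l_pad}")
    return TokenMatrix(rows=rows, l_pad=l_pad, nbits=nbits)
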