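"""Fixed-length binary molecular fingerprints and Tanimoto similarity.

Two fingerprint kinds are supported: the Morgan (circular, ECFP-like)
fingerprint at radius 2 and the RDKit topological (path-based) fingerprint,
both folded to 2048 bits by default.  Fingerprints are computed on the
parsed molecule, so two SMILES spellings of the same structure always give
the same bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = ["FingerprintVector", "morgan_fp", "topological_fp", "fingerprint_matrix", "tanimoto"]

DEFAULT_NBITS = 2048
DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class FingerprintVector:
    """A fixed-length binary fingerprint with its provenance parameters."""

    bits: np.ndarray
    kind: str  # "morgan" or "topological"
    nbits: int
    radius: int | None = None

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.shape[0] != self.nbits:
            raise ValueError(f"expected a length-{self.nbits} bit vector, got shape {bits.shape}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.nbits

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_fp(smiles: str, radius: int = DEFAULT_RADIUS, nbits: int = DEFAULT_NBITS) -> FingerprintVector:
    """Morgan (circular) fingerprint, radius 2 / 2048 bits by default."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bits = gen.GetFingerprintAsNumPy(_mol(smiles))
    return FingerprintVector(bits=bits, kind="morgan", nbits=nbits, radius=radius)


def topological_fp(smiles: str, nbits: int = DEFAULT_NBITS) -> FingerprintVector:
    """RDKit topological (path-based) fingerprint with default path parameters."""
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=nbits)
    bits = gen.GetFingerprintAsNumPy(_mol(smiles))
    return FingerprintVector(bits=bits, kind="topological", nbits=nbits)


def fingerprint_matrix(
    smiles: Sequence[str], kind: str = "morgan", nbits: int = DEFAULT_NBITS, radius: int = DEFAULT_RADIUS
) -> np.ndarray:
    """N × nbits uint8 matrix, row order preserved."""
    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    elif kind == "topological":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=nbits)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    out = np.zeros((len(smiles), nbits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        out[i] = gen.GetFingerprintAsNumPy(_mol(smi))
    return out


def tanimoto(a: FingerprintVector | np.ndarray, b: FingerprintVector | np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b|; 0 when both vectors are all-zero.

    When both arguments are :class:`FingerprintVector` their kinds must
    match — comparing a Morgan to a topological fingerprint is a bug, not a
    similarity of 0.
    """
    if isinstance(a, FingerprintVector) and isinstance(b, FingerprintVector):
        if a.kind != b.kind:
            raise ValueError(f"fingerprint kinds differ: {a.kind} vs {b.kind}")
    av = a.bits if isinstance(a, FingerprintVector) else np.asarray(a, dtype=np.uint8)
    bv = b.bits if isinstance(b, FingerprintVector) else np.asarray(b, dtype=np.uint8)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    inter = int(np.sum(av & bv))
    union = int(np.sum(av | bv))
    return inter / union if union else 0.0
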