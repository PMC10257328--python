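"""Mol2vec-style substructure embeddings.

A molecule is read as a "sentence" whose words are Morgan circular-
substructure identifiers, one per heavy atom per radius 0..R (atom-index
order, radius-minor).  An embedding table maps identifiers to d-dimensional
vectors (default d = 100); a molecule vector is the element-wise sum of its
word vectors, with unknown substructures contributing zero so the sum stays
well-defined on novel chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .word2vec import train_skipgram

__all__ = [
    "SubstructureSentence",
    "EmbeddingTable",
    "sentence",
    "corpus",
    "train_embeddings",
    "embed_molecule",
    "embed_molecules",
]

DEFAULT_RADIUS = 1
DEFAULT_DIM = 100


@dataclass(frozen=True)
class SubstructureSentence:
    """Ordered substructure identifiers of one molecule."""

    words: tuple[str, ...]
    radius: int

    def __len__(self) -> int:
        return len(self.words)


def sentence(smiles: str, radius: int = DEFAULT_RADIUS) -> SubstructureSentence:
    """Morgan-substructure sentence: atoms × radii 0..R, atom-major order.

    An atom whose environment does not extend to some radius r (e.g. a
    lone atom at r = 1) repeats its largest available identifier, so the
    length law ``len == heavy_atoms * (radius + 1)`` always holds.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=out)
    per_atom: dict[int, dict[int, int]] = {a.GetIdx(): {} for a in mol.GetAtoms()}
    for ident, envs in out.GetBitInfoMap().items():
        for atom_idx, r in envs:
            per_atom[atom_idx][r] = ident
    words: list[str] = []
    for atom_idx in sorted(per_atom):
        last = None
        for r in range(radius + 1):
            ident = per_atom[atom_idx].get(r, last)
            words.append(str(ident))
            last = ident
    return SubstructureSentence(words=tuple(words), radius=radius)


def corpus(smiles_list: Iterable[str], radius: int = DEFAULT_RADIUS) -> list[SubstructureSentence]:
    return [sentence(s, radius=radius) for s in smiles_list]


@dataclass
class EmbeddingTable:
    """Word → d-dimensional vector; unknown words map to the zero vector."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {w!r} has shape {v.shape}, expected ({self.dim},)")
            self.vectors[w] = v

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, word: str) -> np.ndarray:
        return self.vectors.get(word, np.zeros(self.dim))

    def save(self, path: str | Path) -> None:
        """Persist in word2vec text format: header line, then word + floats."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for w, v in self.vectors.items():
                fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        lines = Path(path).read_text().splitlines()
        n, dim = map(int, lines[0].split())
        vectors = {}
        for line in lines[1 : n + 1]:
            parts = line.split()
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=float)
        return cls(vectors=vectors, dim=dim)


def train_embeddings(
    sentences: Sequence[SubstructureSentence],
    dim: int = DEFAULT_DIM,
    window: int = 5,
    min_count: int = 1,
    negative: int = 5,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingTable:
    """Train a substructure embedding table on a sentence corpus (seeded)."""
    table = train_skipgram(
        [s.words for s in sentences],
        dim=dim,
        window=window,
        min_count=min_count,
        negative=negative,
        epochs=epochs,
        seed=seed,
    )
    return EmbeddingTable(vectors=table, dim=dim)


def embed_molecule(sent: SubstructureSentence, table: EmbeddingTable) -> np.ndarray:
    """Molecule vector = element-wise sum of its substructure vectors."""
    vec = np.zeros(table.dim)
    for w in sent.words:
        vec += table.get(w)
    return vec


def embed_molecules(
    smiles_list: Sequence[str], table: EmbeddingTable, radius: int = DEFAULT_RADIUS
) -> np.ndarray:
    """N × d matrix of summed substructure vectors, row order preserved."""
    return np.stack([embed_molecule(sentence(s, radius=radius), table) for s in smiles_list])
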