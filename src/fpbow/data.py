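"""Molecule datasets: readers, merging, splitting and similarity filtering.

The unit of every dataset is a :class:`MoleculeRecord` — an id, a SMILES
string, a binary activity label (1 = active, 0 = inactive, ``None`` =
unknown) and a source tag such as the assay the record came from.  A
:class:`Dataset` is an ordered collection of records with unique ids and a
per-source provenance table, emulating the shape of PubChem BioAssay
exports.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .fingerprints import morgan_fp, tanimoto, topological_fp

__all__ = [
    "MoleculeRecord",
    "Dataset",
    "SplitSpec",
    "read_smiles",
    "read_sdf",
    "read_activity_csv",
    "merge_datasets",
    "split_dataset",
    "filter_by_similarity",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with an optional binary activity label."""

    id: str
    smiles: str
    label: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass
class Dataset:
    """Ordered collection of molecule records with unique ids."""

    records: list[MoleculeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i, c in Counter(ids).items() if c > 1})
            raise ValueError(f"duplicate record ids: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return Dataset([self.records[i] for i in idx])
        return self.records[idx]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        """Label vector; unknown labels become -1."""
        return np.array(
            [r.label if r.label is not None else -1 for r in self.records], dtype=int
        )

    @property
    def n_active(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_inactive(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    @property
    def provenance(self) -> pd.DataFrame:
        """Per-source active/inactive/total counts (conservation table)."""
        rows: dict[str, Counter] = {}
        for r in self.records:
            c = rows.setdefault(r.source, Counter())
            c["total"] += 1
            if r.label == 1:
                c["active"] += 1
            elif r.label == 0:
                c["inactive"] += 1
        df = pd.DataFrame(
            [
                {"source": s, "active": c["active"], "inactive": c["inactive"], "total": c["total"]}
                for s, c in rows.items()
            ]
        )
        return df

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles": self.smiles,
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification.

    The test-set size follows the ceiling rule ``ceil(N * test_fraction)``,
    which reproduces a 1334-record test set from 6666 records at fraction
    0.2.  The default split is plain random; ``stratified=True`` allocates
    the test quota across classes by largest remainder.
    """

    test_fraction: float = 0.2
    seed: int = 42
    stratified: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.test_fraction < 1):
            raise ValueError(f"test_fraction must be in [0, 1), got {self.test_fraction}")


def _parse_label(token: str) -> int | None:
    if token in ("1", "0"):
        return int(token)
    return None


def read_smiles(path: str | Path) -> Dataset:
    """Read a whitespace-delimited .smi file: ``SMILES [id] [label]`` per line.

    Unparseable SMILES are skipped with a warning naming the line number.
    Raises if the file contains no valid molecule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        smi = parts[0]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            warnings.warn(f"{path}:{lineno}: unparseable SMILES {smi!r}; skipped")
            continue
        rid = parts[1] if len(parts) > 1 else f"mol{lineno}"
        label = _parse_label(parts[2]) if len(parts) > 2 else None
        records.append(MoleculeRecord(id=rid, smiles=smi, label=label, source=path.stem))
    if not records:
        raise ValueError(f"{path}: zero valid molecules")
    return Dataset(records)


def read_sdf(path: str | Path, label_prop: str | None = None) -> Dataset:
    """Read molecules from an SDF file; ``label_prop`` names a 0/1 property."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"{path}: molecule #{i + 1} unparseable; skipped")
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
        label = None
        if label_prop and mol.HasProp(label_prop):
            label = _parse_label(mol.GetProp(label_prop))
        records.append(
            MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol), label=label, source=path.stem)
        )
    if not records:
        raise ValueError(f"{path}: zero valid molecules")
    return Dataset(records)


DEFAULT_LABEL_MAP = {"active": 1, "inactive": 0}


def read_activity_csv(
    path: str | Path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    label_col: str = "label",
    label_map: Mapping[str, int] | None = None,
    source: str | None = None,
) -> Dataset:
    """Read an activity table (PubChem BioAssay-style CSV export).

    Label tokens are mapped case-insensitively through ``label_map``
    (default Active→1, Inactive→0).  Unknown tokens and duplicate ids are
    errors, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    df = pd.read_csv(path, dtype=str)
    for col in (id_col, smiles_col, label_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    dupes = df[id_col][df[id_col].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate ids: {sorted(dupes)[:10]}")
    src = source if source is not None else path.stem
    records = []
    for _, row in df.iterrows():
        token = str(row[label_col]).strip().lower()
        if token not in label_map:
            raise ValueError(f"{path}: unknown label token {row[label_col]!r}")
        smi = row[smiles_col]
        if Chem.MolFromSmiles(smi) is None:
            warnings.warn(f"{path}: id {row[id_col]!r} has unparseable SMILES; skipped")
            continue
        records.append(
            MoleculeRecord(id=str(row[id_col]), smiles=smi, label=label_map[token], source=src)
        )
    return Dataset(records)


def merge_datasets(datasets: Sequence[Dataset], prefix_ids: bool = True) -> Dataset:
    """Concatenate datasets, preserving per-source provenance.

    With ``prefix_ids`` each record id becomes ``source:id`` so assay-local
    ids cannot collide across sources; a collision after prefixing is an
    error.  Duplicate molecules (same structure in two sources) are kept.
    """
    merged: list[MoleculeRecord] = []
    for ds in datasets:
        for r in ds:
            rid = f"{r.source}:{r.id}" if prefix_ids and r.source else r.id
            merged.append(replace(r, id=rid))
    return Dataset(merged)  # Dataset.__post_init__ rejects collisions


def split_dataset(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Random train/test partition with ``|test| = ceil(N * test_fraction)``.

    The same seed always yields the same member sets.  Stratified mode
    distributes the test quota over classes proportionally (largest
    remainder), keeping the overall ceiling rule.
    """
    n = len(dataset)
    if n < 1:
        raise ValueError("cannot split an empty dataset")
    n_test = math.ceil(n * spec.test_fraction)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        test_idx = set(perm[:n_test].tolist())
    else:
        labels = dataset.labels
        classes = np.unique(labels)
        quotas = {c: n_test * np.sum(labels == c) / n for c in classes}
        base = {c: int(math.floor(q)) for c, q in quotas.items()}
        remainder = n_test - sum(base.values())
        for c in sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True):
            if remainder <= 0:
                break
            base[c] += 1
            remainder -= 1
        test_idx = set()
        for c in classes:
            members = np.flatnonzero(labels == c)
            take = rng.permutation(len(members))[: base[c]]
            test_idx.update(members[take].tolist())
    train = Dataset([r for i, r in enumerate(dataset) if i not in test_idx])
    test = Dataset([r for i, r in enumerate(dataset) if i in test_idx])
    return train, test


def deduplicate(dataset: Dataset) -> Dataset:
    """Drop molecules whose canonical SMILES was already seen (first kept)."""
    seen: set[str] = set()
    kept = []
    for r in dataset:
        canon = Chem.CanonSmiles(r.smiles)
        if canon in seen:
            continue
        seen.add(canon)
        kept.append(r)
    return Dataset(kept)


def filter_by_similarity(
    candidates: Dataset,
    references: Dataset | Iterable[str],
    threshold: float = 0.5,
) -> Dataset:
    """Keep candidates similar to at least one reference on BOTH fingerprints.

    A candidate is retained when its maximum Tanimoto similarity to any
    reference exceeds ``threshold`` under the Morgan (radius 2) fingerprint
    AND under the topological (path-based) fingerprint — the dual-fingerprint
    pre-filter used to narrow a large purchasable library to the chemical
    neighbourhood of known actives.  Candidates are deduplicated by
    canonical SMILES first.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ref_smiles = references.smiles if isinstance(references, Dataset) else list(references)
    if not ref_smiles:
        raise ValueError("empty reference set")
    ref_morgan = [morgan_fp(s) for s in ref_smiles]
    ref_topo = [topological_fp(s) for s in ref_smiles]
    kept = []
    for r in deduplicate(candidates):
        cm, ct = morgan_fp(r.smiles), topological_fp(r.smiles)
        best_m = max(tanimoto(cm, ref) for ref in ref_morgan)
        best_t = max(tanimoto(ct, ref) for ref in ref_topo)
        if best_m > threshold and best_t > threshold:
            kept.append(r)
    return Dataset(kept)
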