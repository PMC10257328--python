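"""Synthetic structure–activity benchmarks with a planted activity rule.

Molecules are assembled from a small fragment grammar (scaffold templates
with substituent slots), which guarantees every generated SMILES parses.
Activity is planted structurally: active molecules carry a marker
substructure (a sulfonamide by default) that no inactive substituent
contains, so with zero label noise a substructure lookup reproduces the
labels exactly and upper-bounds any model run on the fixture.  Observed
labels are the planted indicator XOR independent noise flips, and each
molecule receives a docking-style binding energy drawn from a Gaussian
conditioned on its observed label.

The default energy Gaussians put actives at −9.5 ± 0.5 kcal/mol and
inactives at −7.5 ± 0.5, placing the Bayes-optimal energy cut at −8.5 —
an engineering choice that makes threshold-recovery behaviour easy to
reason about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .consistency import DockingRecord
from .data import Dataset, MoleculeRecord, merge_datasets

__all__ = ["SyntheticConfig", "generate", "make_imbalanced_pair", "planted_indicator"]

# Scaffold templates with {a}/{b} substituent slots; all slots are
# parenthesized branches on ring or chain carbons, so any branch SMILES
# from the fragment lists below yields a valid molecule.
SCAFFOLDS = (
    "c1ccc({a})cc1",
    "c1ccc({a})c({b})c1",
    "c1ccnc({a})c1",
    "c1cc({b})ccc1{a}",
    "C1CCC({a})CC1",
    "c1ccc2c(c1)cc({a})cc2",
    "O=C({a})c1ccc({b})cc1",
    "c1csc({a})c1",
)

# Sulfur-free substituents, so none collides with the default planted marker.
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)NC", "CO", "CN", "C(F)(F)F",
    "c1ccccc1", "C1CC1", "OC(C)C",
)

DEFAULT_PLANTED = "S(=O)(=O)N"  # attached as a branch => aryl/alkyl sulfonamide


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated dataset."""

    n_molecules: int = 1000
    active_fraction: float = 0.2
    planted_substructure: str = DEFAULT_PLANTED
    label_noise: float = 0.0
    energy_means: tuple[float, float] = (-9.5, -7.5)  # (active, inactive) kcal/mol
    energy_sd: float = 0.5
    seed: int = 0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0 <= self.active_fraction <= 1):
            raise ValueError("active_fraction must be in [0, 1]")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if Chem.MolFromSmarts(self.planted_substructure) is None:
            raise ValueError(f"invalid SMARTS: {self.planted_substructure!r}")


def _assemble(rng: np.random.Generator, active: bool, planted: str) -> str:
    scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    slots = [s for s in ("a", "b") if "{" + s + "}" in scaffold]
    subs = {s: SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for s in slots}
    if active:
        subs[slots[int(rng.integers(len(slots)))]] = planted
    return scaffold.format(**{s: subs.get(s, "") for s in ("a", "b")})


def planted_indicator(smiles_list, pattern: str = DEFAULT_PLANTED) -> np.ndarray:
    """1 where the molecule contains the planted substructure (SMARTS match)."""
    patt = Chem.MolFromSmarts(pattern)
    out = np.zeros(len(smiles_list), dtype=int)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is not None and mol.HasSubstructMatch(patt):
            out[i] = 1
    return out


def generate(config: SyntheticConfig) -> tuple[Dataset, list[DockingRecord]]:
    """Generate a labeled dataset plus per-molecule binding energies.

    Deterministic for a fixed seed: two calls with the same config return
    byte-identical SMILES, labels and energies.
    """
    rng = np.random.default_rng(config.seed)
    true_labels = (rng.random(config.n_molecules) < config.active_fraction).astype(int)
    flips = (rng.random(config.n_molecules) < config.label_noise).astype(int)
    observed = true_labels ^ flips
    records = []
    for i, lab in enumerate(true_labels):
        smi = _assemble(rng, bool(lab), config.planted_substructure)
        assert Chem.MolFromSmiles(smi) is not None, f"grammar produced invalid SMILES {smi!r}"
        records.append(
            MoleculeRecord(
                id=f"syn{i:05d}", smiles=smi, label=int(observed[i]), source=config.source
            )
        )
    mu_a, mu_i = config.energy_means
    mus = np.where(observed == 1, mu_a, mu_i)
    energies = rng.normal(mus, config.energy_sd)
    docking = [DockingRecord(id=r.id, energy=float(e)) for r, e in zip(records, energies)]
    return Dataset(records), docking


# Class counts of the two emulated assay sources: (active, inactive).
SOURCE_SHAPES = {"assayA": (1066, 5000), "assayB": (83, 517)}


def make_imbalanced_pair(
    config: SyntheticConfig | None = None, scale: float = 1.0
) -> tuple[Dataset, Dataset]:
    """Two datasets matching the 1066/5000 and 83/517 source shape.

    ``scale`` shrinks each class count by ceiling, so small test fixtures
    keep both classes in both sources.  Merging the pair at scale 1 gives
    1149 actives and 5517 inactives — 6666 records.
    """
    config = config or SyntheticConfig()
    out = []
    for offset, (source, (n_act, n_inact)) in enumerate(SOURCE_SHAPES.items()):
        n_act_s = math.ceil(n_act * scale)
        n_inact_s = math.ceil(n_inact * scale)
        rng = np.random.default_rng(config.seed + offset)
        records = []
        for j in range(n_act_s + n_inact_s):
            active = j < n_act_s
            smi = _assemble(rng, active, config.planted_substructure)
            records.append(
                MoleculeRecord(id=f"{source}-{j:05d}", smiles=smi, label=int(active), source=source)
            )
        out.append(Dataset(records))
    return out[0], out[1]
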