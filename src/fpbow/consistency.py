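"""Docking-consistency labeling: energy thresholds and agreement metrics.

Docking programs report a binding energy in kcal/mol per molecule (lower =
stronger predicted binding).  A threshold α converts energies to activity
labels: energy < α ⇒ active, energy ≥ α ⇒ inactive (the boundary counts as
inactive — conservative for screening).  α is chosen by scanning all
midpoints between consecutive sorted energies (plus ±∞ sentinels) for the
cut that best agrees with the experimental labels; the result is flagged
when even the best agreement falls short of the target (80% by default).

Agreement between docking-derived labels and model predictions is reported
over a TA/TI/FA/FI table ("A"/"I" = active/inactive):

    consistency     = (TA + TI) / (TA + TI + FA + FI)
    active-recall   = TA / (TA + FI)
    inactive-recall = TI / (TI + FA)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DockingRecord",
    "ThresholdResult",
    "ConsistencyReport",
    "read_energy_csv",
    "best_pose_energies",
    "label_by_energy",
    "select_threshold",
    "consistency_metrics",
]


@dataclass(frozen=True)
class DockingRecord:
    """One molecule's docking outcome."""

    id: str
    energy: float  # kcal/mol; lower = stronger binding

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"energy must be finite, got {self.energy}")


@dataclass(frozen=True)
class ThresholdResult:
    alpha: float
    agreement: float
    meets_target: bool
    target_agreement: float


@dataclass(frozen=True)
class ConsistencyReport:
    ta: int
    ti: int
    fa: int
    fi: int
    consistency: float
    active_recall: float
    inactive_recall: float

    @property
    def n(self) -> int:
        return self.ta + self.ti + self.fa + self.fi


def read_energy_csv(path: str | Path, id_col: str = "id", energy_col: str = "energy_kcal_mol") -> list[DockingRecord]:
    df = pd.read_csv(path)
    return [DockingRecord(id=str(r[id_col]), energy=float(r[energy_col])) for _, r in df.iterrows()]


def best_pose_energies(records: Sequence[DockingRecord]) -> list[DockingRecord]:
    """Collapse multiple poses per molecule to the lowest (best) energy."""
    best: dict[str, float] = {}
    order: list[str] = []
    for r in records:
        if r.id not in best:
            order.append(r.id)
            best[r.id] = r.energy
        else:
            best[r.id] = min(best[r.id], r.energy)
    return [DockingRecord(id=i, energy=best[i]) for i in order]


def _energies(records: Sequence[DockingRecord] | np.ndarray) -> np.ndarray:
    if len(records) and isinstance(records[0], DockingRecord):
        return np.array([r.energy for r in records], dtype=float)
    return np.asarray(records, dtype=float)


def label_by_energy(records: Sequence[DockingRecord] | np.ndarray, alpha: float) -> np.ndarray:
    """energy < alpha ⇒ 1 (active); energy ≥ alpha ⇒ 0 (inactive)."""
    if not math.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return (_energies(records) < alpha).astype(int)


def select_threshold(
    records: Sequence[DockingRecord] | np.ndarray,
    experimental_labels: Sequence[int],
    target_agreement: float = 0.8,
) -> ThresholdResult:
    """Pick the energy cut that best agrees with the experimental labels.

    Candidates are the midpoints between consecutive distinct sorted
    energies plus sentinels below/above every energy (the all-inactive and
    all-active labelings).  Ties in agreement break toward the most
    negative α (strongest-binding cut).  The result is flagged when the
    best agreement is below ``target_agreement``.
    """
    energies = _energies(records)
    labels = np.asarray(experimental_labels, dtype=int)
    if energies.shape != labels.shape:
        raise ValueError("records and labels differ in length")
    if np.unique(labels).size < 2:
        raise ValueError("need at least one record of each experimental class")
    distinct = np.unique(energies)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    best_alpha, best_agree = None, -1.0
    for alpha in candidates:  # ascending: first max is the most negative tie
        agree = float(np.mean((energies < alpha).astype(int) == labels))
        if agree > best_agree:
            best_alpha, best_agree = float(alpha), agree
    return ThresholdResult(
        alpha=best_alpha,
        agreement=best_agree,
        meets_target=best_agree >= target_agreement,
        target_agreement=target_agreement,
    )


def consistency_metrics(
    docking_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConsistencyReport:
    """TA/TI/FA/FI table and the three agreement rates.

    The docking label is the reference; the letter names the *predicted*
    class and T/F whether it agrees with docking.  TA = both active,
    TI = both inactive, FI = docking active but predicted inactive,
    FA = docking inactive but predicted active.  Hence active-recall
    TA/(TA+FI) recalls the docking actives and inactive-recall TI/(TI+FA)
    the docking inactives.  Zero-denominator recalls are NaN.
    """
    d = np.asarray(docking_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if d.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if not (np.isin(d, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    ta = int(np.sum((d == 1) & (p == 1)))
    ti = int(np.sum((d == 0) & (p == 0)))
    fi = int(np.sum((d == 1) & (p == 0)))
    fa = int(np.sum((d == 0) & (p == 1)))
    n = ta + ti + fa + fi
    return ConsistencyReport(
        ta=ta,
        ti=ti,
        fa=fa,
        fi=fi,
        consistency=(ta + ti) / n if n else math.nan,
        active_recall=ta / (ta + fi) if (ta + fi) else math.nan,
        inactive_recall=ti / (ti + fa) if (ti + fa) else math.nan,
    )
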