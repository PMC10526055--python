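"""Few-shot reference-dataset construction.

From a molecule pool, build the six task families used for constrained
generation: structural subsets (exactly 1/2/3 aromatic rings, halogenated)
drawn at random, and property subsets (top QED, top penalized logP) taken
as the highest scorers.  Each task yields nested 5 ⊆ 10 ⊆ 50 ⊆ 100-shot
subsets: the 100-shot set is drawn from the pool, the 50-shot from those
100, and so on, all seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics, properties
from .chem import MoleculeRecord, count_aromatic_rings, has_halogen

STRUCTURE_TASKS = ("ring_1", "ring_2", "ring_3", "halogen")
PROPERTY_TASKS = ("qed_top", "plogp_top")
ALL_TASKS = STRUCTURE_TASKS + PROPERTY_TASKS

DEFAULT_SHOT_SIZES = (100, 50, 10, 5)

_TASK_SCORES = {"qed_top": "QED", "plogp_top": "PLOGP_RAW"}


@dataclass
class FewShotDataset:
    task: str
    shots: int
    molecules: list[MoleculeRecord]
    parent: Optional["FewShotDataset"] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.molecules) != self.shots:
            raise ValueError(
                f"{self.task}: got {len(self.molecules)} molecules for "
                f"{self.shots} shots"
            )
        if self.parent is not None:
            parent_keys = {m.canonical_smiles for m in self.parent.molecules}
            if not {m.canonical_smiles for m in self.molecules} <= parent_keys:
                raise ValueError(f"{self.task}: subset not nested in parent")

    @property
    def smiles(self) -> list[str]:
        return [m.canonical_smiles for m in self.molecules]


def task_predicate(task: str) -> metrics.StructurePredicate:
    if task == "halogen":
        return metrics.halogen_predicate
    if task.startswith("ring_"):
        return metrics.ring_count_predicate(int(task.split("_")[1]))
    raise ValueError(f"no structure predicate for task {task!r}")


def filter_structure(pool: list[MoleculeRecord], task: str,
                     aromatic_only: bool = True) -> list[MoleculeRecord]:
    """Pool members satisfying a structural task, order preserved.

    ``aromatic_only=False`` switches the ring tasks from aromatic-ring
    counts to total SSSR ring counts.
    """
    valid = [r for r in pool if r.is_valid]
    if task == "halogen":
        kept = [r for r in valid if has_halogen(r)]
    elif task.startswith("ring_"):
        k = int(task.split("_")[1])
        if aromatic_only:
            kept = [r for r in valid if count_aromatic_rings(r) == k]
        else:
            from .chem import count_rings

            kept = [r for r in valid if count_rings(r) == k]
    else:
        raise ValueError(f"unknown structure task {task!r}")
    if not kept:
        raise ValueError(f"no pool molecules satisfy task {task!r}")
    return kept


def top_k_by_property(pool: list[MoleculeRecord], score: str,
                      k: int) -> list[MoleculeRecord]:
    """The k highest scorers, descending; ties broken by canonical SMILES.

    By construction top-5 ⊆ top-10 ⊆ ... for any fixed pool.
    """
    valid = [r for r in pool if r.is_valid]
    if k > len(valid):
        raise ValueError(f"k={k} exceeds pool size {len(valid)}")
    fn = properties.PROPERTY_FUNCTIONS[score]
    scored = sorted(valid, key=lambda r: (-fn(r), r.canonical_smiles))
    return scored[:k]


def nested_subsample(filtered_pool: list[MoleculeRecord], task: str,
                     sizes: tuple[int, ...] = DEFAULT_SHOT_SIZES,
                     seed: int = 0) -> list[FewShotDataset]:
    """Seeded nested sampling: each size is drawn from the previous subset.

    ``sizes`` must be strictly decreasing; returns datasets largest first.
    """
    if list(sizes) != sorted(sizes, reverse=True):
        raise ValueError(f"sizes must be strictly decreasing: {sizes}")
    if len(filtered_pool) < max(sizes):
        raise ValueError(
            f"pool of {len(filtered_pool)} too small; need >= {max(sizes)}"
        )
    rng = np.random.default_rng(seed)
    datasets: list[FewShotDataset] = []
    current = list(filtered_pool)
    parent = None
    for size in sizes:
        idx = rng.choice(len(current), size=size, replace=False)
        current = [current[i] for i in sorted(idx)]
        parent = FewShotDataset(task=task, shots=size, molecules=current,
                                parent=parent, seed=seed)
        datasets.append(parent)
    return datasets


def build_task_datasets(pool: list[MoleculeRecord], task: str,
                        sizes: tuple[int, ...] = DEFAULT_SHOT_SIZES,
                        seed: int = 0,
                        aromatic_only: bool = True) -> list[FewShotDataset]:
    """Few-shot datasets for one task: filter/rank the pool, then nest."""
    if task in STRUCTURE_TASKS:
        filtered = filter_structure(pool, task, aromatic_only=aromatic_only)
        return nested_subsample(filtered, task, sizes, seed)
    if task in PROPERTY_TASKS:
        # property tasks take the top scorers outright, so the k-shot set
        # IS the top-k and nesting holds by construction
        datasets: list[FewShotDataset] = []
        parent = None
        for size in sizes:
            mols = top_k_by_property(pool, _TASK_SCORES[task], size)
            parent_ds = FewShotDataset(task=task, shots=size, molecules=mols,
                                       parent=parent, seed=seed)
            datasets.append(parent_ds)
            parent = parent_ds
        return datasets
    raise ValueError(f"unknown task {task!r}")


def dataset_stats(ds: FewShotDataset,
                  normalizer: properties.ScoreNormalizer | None = None) -> dict:
    """One summary row: counts, diversity, mean scores, ring/halogen census."""
    mols = ds.molecules
    if not mols:
        raise ValueError("empty dataset")
    ring_counts = [count_aromatic_rings(m) for m in mols]
    row = {
        "task": ds.task,
        "num": len(mols),
        "diversity": (metrics.diversity(mols) if len(mols) >= 2 else None),
        "qed": float(np.mean([properties.qed(m) for m in mols])),
        "plogp_raw": float(
            np.mean([properties.penalized_logp_raw(m) for m in mols])
        ),
        "ring_0": sum(c == 0 for c in ring_counts),
        "ring_1": sum(c == 1 for c in ring_counts),
        "ring_2": sum(c == 2 for c in ring_counts),
        "ring_3": sum(c == 3 for c in ring_counts),
        "ring_4plus": sum(c >= 4 for c in ring_counts),
        "halogen": sum(has_halogen(m) for m in mols),
    }
    if normalizer is not None:
        row["plogp_norm"] = float(
            np.mean(
                [properties.normalize(properties.penalized_logp_raw(m), normalizer)
                 for m in mols]
            )
        )
    return row


def stats_table(datasets: list[FewShotDataset],
                normalizer: properties.ScoreNormalizer | None = None
                ) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        row = dataset_stats(ds, normalizer)
        row["shots"] = ds.shots
        rows.append(row)
    return pd.DataFrame(rows)
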