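"""Evaluation metrics for generated molecule sets.

* diversity   = 1 − mean pairwise Tanimoto similarity over distinct pairs
                (extended-connectivity fingerprints);
* uniqueness  = |distinct canonical structures among valid| / |valid|;
* quality     = |distinct structures satisfying the task predicate| /
                |generated| — the numerator is deduplicated, the denominator
                is the full generated multiset.

For sets larger than ``PAIRWISE_CAP`` molecules, diversity is computed on a
seeded random subsample (recorded in the report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import properties
from .chem import (MoleculeRecord, count_aromatic_rings, has_halogen,
                   rdkit_fingerprint, bulk_tanimoto,
                   DEFAULT_FP_RADIUS, DEFAULT_FP_NBITS)

PAIRWISE_CAP = 5000

StructurePredicate = Callable[[MoleculeRecord], bool]


def ring_count_predicate(k: int) -> StructurePredicate:
    """Molecules with exactly ``k`` aromatic rings."""
    def pred(record: MoleculeRecord) -> bool:
        return count_aromatic_rings(record) == k

    pred.__name__ = f"ring_count_{k}"
    return pred


def halogen_predicate(record: MoleculeRecord) -> bool:
    return has_halogen(record)


@dataclass
class MetricReport:
    n_generated: int
    n_valid: int
    n_unique: int
    diversity: float | None
    uniqueness: float
    quality: float | None = None
    mean_scores: dict[str, float] = field(default_factory=dict)
    diversity_subsample: int | None = None

    def to_dict(self) -> dict:
        out = {
            "n_generated": self.n_generated,
            "n_valid": self.n_valid,
            "n_unique": self.n_unique,
            "diversity": self.diversity,
            "uniqueness": self.uniqueness,
            "quality": self.quality,
        }
        out.update({f"mean_{k}": v for k, v in self.mean_scores.items()})
        if self.diversity_subsample is not None:
            out["diversity_subsample"] = self.diversity_subsample
        return out

    def to_text(self) -> str:
        return "".join(f"{k}\t{v}\n" for k, v in self.to_dict().items()
                       if v is not None)


def diversity(records: list[MoleculeRecord],
              radius: int = DEFAULT_FP_RADIUS,
              n_bits: int = DEFAULT_FP_NBITS,
              subsample_seed: int = 0) -> float:
    """1 − mean pairwise Tanimoto similarity over all distinct pairs."""
    valid = [r for r in records if r.is_valid]
    if len(valid) < 2:
        raise ValueError("diversity undefined for fewer than two valid molecules")
    if len(valid) > PAIRWISE_CAP:
        rng = np.random.default_rng(subsample_seed)
        idx = rng.choice(len(valid), size=PAIRWISE_CAP, replace=False)
        valid = [valid[i] for i in idx]
    # fingerprints depend only on structure: compute once per distinct SMILES
    fp_cache: dict[str, object] = {}
    fps = []
    for r in valid:
        if r.canonical_smiles not in fp_cache:
            fp_cache[r.canonical_smiles] = rdkit_fingerprint(r, radius, n_bits)
        fps.append(fp_cache[r.canonical_smiles])
    total = 0.0
    for i in range(len(fps) - 1):
        total += float(bulk_tanimoto(fps[i], fps[i + 1:]).sum())
    n_pairs = len(fps) * (len(fps) - 1) / 2
    return 1.0 - total / n_pairs


def uniqueness(records: list[MoleculeRecord]) -> float:
    """Distinct canonical structures over valid samples."""
    valid = [r for r in records if r.is_valid]
    if not valid:
        raise ValueError("uniqueness undefined with zero valid molecules")
    return len({r.canonical_smiles for r in valid}) / len(valid)


def quality(records: list[MoleculeRecord],
            predicate: StructurePredicate) -> float:
    """Deduplicated satisfying structures over the full generated count."""
    if not records:
        raise ValueError("quality undefined on an empty set")
    desired = {
        r.canonical_smiles
        for r in records
        if r.is_valid and predicate(r)
    }
    return len(desired) / len(records)


def evaluate(records: list[MoleculeRecord],
             predicate: StructurePredicate | None = None,
             score_names: tuple[str, ...] = (),
             normalizer: properties.ScoreNormalizer | None = None,
             subsample_seed: int = 0) -> MetricReport:
    """Full evaluation report for a generated set.

    ``score_names`` selects property means (over valid molecules) from
    ``properties.PROPERTY_FUNCTIONS``; with a ``normalizer``, a
    ``PLOGP_NORM`` mean is added on top of ``PLOGP_RAW``.
    """
    if not records:
        raise ValueError("cannot evaluate an empty generated set")
    valid = [r for r in records if r.is_valid]
    n_unique = len({r.canonical_smiles for r in valid})
    div = diversity(records, subsample_seed=subsample_seed) if len(valid) >= 2 else None
    means: dict[str, float] = {}
    for name in score_names:
        fn = properties.PROPERTY_FUNCTIONS[name]
        means[name] = float(np.mean([fn(r) for r in valid]))
    if normalizer is not None and "PLOGP_RAW" in means:
        means["PLOGP_NORM"] = float(
            np.mean([properties.normalize(properties.penalized_logp_raw(r),
                                          normalizer) for r in valid])
        )
    return MetricReport(
        n_generated=len(records),
        n_valid=len(valid),
        n_unique=n_unique,
        diversity=div,
        uniqueness=uniqueness(records),
        quality=quality(records, predicate) if predicate is not None else None,
        mean_scores=means,
        diversity_subsample=PAIRWISE_CAP if len(valid) > PAIRWISE_CAP else None,
    )
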