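"""Molecular property scoring: QED, penalized logP, synthetic accessibility.

Scores used both to build property-constrained reference sets (top-QED /
top-PlogP subsets of a pool) and to evaluate generated molecules.

Penalized logP follows the composition standard in latent-space molecule
optimization:  ``logP - SA - cycle_penalty``  where SA is the raw 1-10
synthetic-accessibility score and the cycle penalty is the excess of the
largest ring over six atoms.  Raw penalized logP is unbounded; reported
values are min-max normalized against a stated reference pool so that the
best pool member scores 1.0.

Activity models (e.g. a DRD2 bioactivity classifier) are deliberately not
bundled: they are plugged in through a registry keyed by name.  A
deterministic substructure-based mock ("mock_halogen") ships for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from rdkit.Chem import Crippen, QED as rdQED

from .chem import MoleculeRecord, has_halogen, to_mol

_sascorer = None


def _get_sascorer():
    """RDKit's contributed synthetic-accessibility scorer, loaded lazily."""
    global _sascorer
    if _sascorer is None:
        import os
        import sys

        from rdkit.Chem import RDConfig

        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # type: ignore

        _sascorer = sascorer
    return _sascorer


def qed(record: MoleculeRecord) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    return float(rdQED.qed(to_mol(record)))


def sa_raw(record: MoleculeRecord) -> float:
    """Raw synthetic-accessibility score on the 1 (easy) .. 10 (hard) scale."""
    return float(_get_sascorer().calculateScore(to_mol(record)))


def sa_normalized(record: MoleculeRecord) -> float:
    """SA rescaled to [0, 1] with 1 = easiest to synthesize: (10 - SA) / 9."""
    return float(np.clip((10.0 - sa_raw(record)) / 9.0, 0.0, 1.0))


def cycle_penalty(record: MoleculeRecord) -> float:
    """Excess of the largest ring over 6 atoms; 0 for acyclic molecules."""
    rings = to_mol(record).GetRingInfo().AtomRings()
    if not rings:
        return 0.0
    return float(max(0, max(len(r) for r in rings) - 6))


def penalized_logp_raw(record: MoleculeRecord) -> float:
    """Crippen logP minus raw SA minus the large-ring cycle penalty."""
    return float(
        Crippen.MolLogP(to_mol(record)) - sa_raw(record) - cycle_penalty(record)
    )


@dataclass(frozen=True)
class ScoreNormalizer:
    """Min-max rescaler fitted on a reference pool of raw scores."""

    ref_min: float
    ref_max: float

    def __post_init__(self) -> None:
        if not self.ref_max > self.ref_min:
            raise ValueError(
                f"ref_max ({self.ref_max}) must exceed ref_min ({self.ref_min})"
            )


def fit_normalizer(values: Iterable[float]) -> ScoreNormalizer:
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two reference values")
    return ScoreNormalizer(ref_min=float(vals.min()), ref_max=float(vals.max()))


def normalize(value: float, norm: ScoreNormalizer) -> float:
    """Clipped min-max normalization into [0, 1]."""
    return float(
        np.clip((value - norm.ref_min) / (norm.ref_max - norm.ref_min), 0.0, 1.0)
    )


def denormalize(value: float, norm: ScoreNormalizer) -> float:
    return float(norm.ref_min + value * (norm.ref_max - norm.ref_min))


# --- pluggable activity scorers ------------------------------------------

ActivityScorer = Callable[[MoleculeRecord], float]

_ACTIVITY_REGISTRY: dict[str, ActivityScorer] = {}


def register_activity_scorer(name: str, scorer: ActivityScorer) -> None:
    """Register a per-molecule activity-probability function under ``name``."""
    _ACTIVITY_REGISTRY[name] = scorer


def activity_scores(records: list[MoleculeRecord], name: str) -> list[float]:
    """Activity probabilities in [0, 1], one per molecule, from a plugin."""
    if name not in _ACTIVITY_REGISTRY:
        raise KeyError(
            f"no activity scorer registered under {name!r}; "
            f"available: {sorted(_ACTIVITY_REGISTRY)}"
        )
    scorer = _ACTIVITY_REGISTRY[name]
    out = [float(scorer(r)) for r in records]
    if any(not 0.0 <= v <= 1.0 for v in out):
        raise ValueError(f"activity scorer {name!r} returned values outside [0, 1]")
    return out


def _mock_halogen_scorer(record: MoleculeRecord) -> float:
    """Deterministic test scorer: 1.0 for halogenated molecules, else 0.0."""
    return 1.0 if has_halogen(record) else 0.0


register_activity_scorer("mock_halogen", _mock_halogen_scorer)

PROPERTY_FUNCTIONS: dict[str, Callable[[MoleculeRecord], float]] = {
    "QED": qed,
    "PLOGP_RAW": penalized_logp_raw,
    "SA_NORM": sa_normalized,
}
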