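"""SMILES parsing, canonicalization, fingerprints and structural predicates.

Molecules enter the pipeline as one-SMILES-per-line text files.  Every line
becomes a :class:`MoleculeRecord`; unparsable lines are kept (flagged invalid)
so that downstream ratios over "valid samples" have well-defined denominators.

All chemistry is delegated to RDKit; this module only fixes the conventions
(canonical SMILES as the identity of a structure, Morgan/ECFP fingerprints
with radius 2 and 2048 bits as the default similarity representation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

#: community-standard extended-connectivity fingerprint parameters
DEFAULT_FP_RADIUS = 2
DEFAULT_FP_NBITS = 2048


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule.  ``canonical_smiles`` is the structure's identity.

    Invalid records keep their raw text but have an empty canonical form.
    """

    raw_smiles: str
    canonical_smiles: str
    is_valid: bool
    source_line: int = 0

    @classmethod
    def from_smiles(cls, smiles: str, source_line: int = 0) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return cls(smiles, "", False, source_line)
        return cls(smiles, Chem.MolToSmiles(mol), True, source_line)

    def require_valid(self) -> None:
        if not self.is_valid:
            raise ValueError(
                f"invalid molecule (line {self.source_line}): {self.raw_smiles!r}"
            )


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length extended-connectivity bit vector."""

    bits: np.ndarray  # uint8 0/1, length n_bits
    radius: int
    n_bits: int

    def popcount(self) -> int:
        return int(self.bits.sum())


@lru_cache(maxsize=16384)
def _mol_from_canonical(canonical_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:  # cannot happen for a string RDKit itself produced
        raise ValueError(f"unparsable canonical SMILES: {canonical_smiles!r}")
    return mol


def to_mol(record: MoleculeRecord) -> Chem.Mol:
    """RDKit Mol for a valid record (cached on the canonical form)."""
    record.require_valid()
    return _mol_from_canonical(record.canonical_smiles)


def parse_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Parse a one-SMILES-per-line file; blank lines skipped, order kept.

    An optional whitespace-separated name column after the SMILES is ignored.
    Raises ``FileNotFoundError`` if the file is missing and ``ValueError`` if
    no line parses to a valid molecule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SMILES file not found: {path}")
    records: list[MoleculeRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        smiles = stripped.split()[0]
        records.append(MoleculeRecord.from_smiles(smiles, source_line=lineno))
    n_invalid = sum(not r.is_valid for r in records)
    if n_invalid:
        logger.warning("%d invalid SMILES line(s) in %s", n_invalid, path)
    if not any(r.is_valid for r in records):
        raise ValueError(f"zero valid molecules in {path}")
    return records


def write_smiles_file(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write canonical SMILES, one per line (invalid records are skipped)."""
    Path(path).write_text(
        "".join(r.canonical_smiles + "\n" for r in records if r.is_valid)
    )


def canonicalize(smiles: str) -> str:
    """Canonical SMILES of ``smiles``; idempotent; raises on unparsable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def count_aromatic_rings(record: MoleculeRecord) -> int:
    """Number of aromatic rings in the smallest-set-of-smallest-rings."""
    mol = to_mol(record)
    ring_info = mol.GetRingInfo()
    n = 0
    for bond_ring in ring_info.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            n += 1
    return n


def count_rings(record: MoleculeRecord) -> int:
    """Total SSSR ring count (aromatic or not)."""
    return to_mol(record).GetRingInfo().NumRings()


def has_halogen(record: MoleculeRecord) -> bool:
    """True iff the molecule contains F, Cl, Br or I."""
    mol = to_mol(record)
    return any(atom.GetSymbol() in HALOGENS for atom in mol.GetAtoms())


def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def rdkit_fingerprint(record: MoleculeRecord, radius: int = DEFAULT_FP_RADIUS,
                      n_bits: int = DEFAULT_FP_NBITS):
    """RDKit ``ExplicitBitVect`` form, for bulk similarity computations."""
    return _morgan_generator(radius, n_bits).GetFingerprint(to_mol(record))


def fingerprint(record: MoleculeRecord, radius: int = DEFAULT_FP_RADIUS,
                n_bits: int = DEFAULT_FP_NBITS) -> FingerprintVector:
    """Extended-connectivity fingerprint of a valid molecule."""
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    bv = rdkit_fingerprint(record, radius, n_bits)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return FingerprintVector(bits=bits, radius=radius, n_bits=n_bits)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero vectors are defined as identical (similarity 1.0).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


def bulk_tanimoto(fp, fps) -> np.ndarray:
    """Similarities of one RDKit fingerprint against a list (C-accelerated)."""
    if not fps:
        return np.empty(0)
    return np.asarray(DataStructs.BulkTanimotoSimilarity(fp, list(fps)))
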