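"""Encoder/decoder contract between molecules and the GAN's latent space.

The adaptation method is codec-agnostic: it only needs a frozen map from
molecules to fixed-length real vectors and back.  In production that map is
a pre-trained molecular VAE (e.g. a junction-tree VAE with 100% decode
validity); here a deterministic :class:`ToyCodec` provides the same contract
over a finite molecule library so the full pipeline runs and is testable
without external weights.

The toy codec embeds each library molecule as a standardized physicochemical
descriptor vector (zero-padded to ``latent_dim``) and decodes an arbitrary
latent vector to the nearest library descriptor in Euclidean distance —
hence, like its VAE counterpart, it decodes *every* latent vector to a valid
molecule.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .chem import HALOGENS, MoleculeRecord, to_mol

#: default latent dimensionality (matches the generator output width)
DEFAULT_LATENT_DIM = 56


class LatentCodec(ABC):
    """Contract: encode molecules to latent vectors and decode them back."""

    latent_dim: int

    @abstractmethod
    def encode(self, records: list[MoleculeRecord]) -> np.ndarray:
        """(n, latent_dim) array, order-preserving, deterministic."""

    @abstractmethod
    def decode(self, latents: np.ndarray) -> list[MoleculeRecord]:
        """One valid molecule per row."""


def descriptor_vector(record: MoleculeRecord) -> np.ndarray:
    """Raw physicochemical descriptor used by the toy codec (length 15)."""
    mol = to_mol(record)
    counts = {s: 0 for s in ("C", "N", "O", "F", "Cl", "Br", "S")}
    n_halogen = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        if sym in HALOGENS:
            n_halogen += 1
    n_aromatic = sum(
        all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
        for ring in mol.GetRingInfo().BondRings()
    )
    return np.array(
        [
            mol.GetNumHeavyAtoms(),
            n_aromatic,
            n_halogen,
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumRotatableBonds(mol),
            Descriptors.MolWt(mol) / 100.0,
            Crippen.MolLogP(mol),
            counts["C"],
            counts["N"],
            counts["O"],
            counts["F"],
            counts["Cl"],
            counts["Br"],
            counts["S"],
        ],
        dtype=float,
    )


class ToyCodec(LatentCodec):
    """Deterministic descriptor/nearest-neighbor codec over a finite library.

    Attributes
    ----------
    library : the valid, structurally distinct molecules the codec knows.
    descriptors_ : (n_library, latent_dim) standardized descriptor matrix;
        columns have zero mean and unit variance over the library (constant
        columns are left centered).
    """

    def __init__(self, library: list[MoleculeRecord],
                 latent_dim: int = DEFAULT_LATENT_DIM):
        records = [r for r in library if r.is_valid]
        seen: dict[str, MoleculeRecord] = {}
        for r in records:
            seen.setdefault(r.canonical_smiles, r)
        records = list(seen.values())
        if len(records) < 2:
            raise ValueError("toy codec needs >= 2 valid, distinct molecules")

        raw = np.stack([descriptor_vector(r) for r in records])
        # collisions (two structures, one descriptor, up to float noise) get
        # a deterministic index coordinate so encode stays injective
        rounded = np.round(raw, 9)
        if len(np.unique(rounded, axis=0)) < len(records):
            idx_col = np.arange(len(records), dtype=float)[:, None]
            raw = np.hstack([raw, idx_col])
        if latent_dim < raw.shape[1]:
            raise ValueError(
                f"latent_dim {latent_dim} < descriptor width {raw.shape[1]}"
            )

        mean = raw.mean(axis=0)
        std = raw.std(axis=0)
        std_safe = np.where(std > 0, std, 1.0)
        standardized = (raw - mean) / std_safe

        self.library = records
        self.latent_dim = latent_dim
        self.descriptors_ = np.zeros((len(records), latent_dim))
        self.descriptors_[:, : raw.shape[1]] = standardized
        self._index = {r.canonical_smiles: i for i, r in enumerate(records)}

    def encode(self, records: list[MoleculeRecord]) -> np.ndarray:
        missing = [
            r.raw_smiles
            for r in records
            if not r.is_valid or r.canonical_smiles not in self._index
        ]
        if missing:
            raise ValueError(f"molecules outside the codec library: {missing}")
        rows = [self._index[r.canonical_smiles] for r in records]
        return self.descriptors_[rows].copy()

    def decode(self, latents: np.ndarray) -> list[MoleculeRecord]:
        latents = np.atleast_2d(np.asarray(latents, dtype=float))
        if latents.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent width {latents.shape[1]} != latent_dim {self.latent_dim}"
            )
        # squared distances to every library descriptor
        d2 = (
            (latents**2).sum(axis=1, keepdims=True)
            - 2.0 * latents @ self.descriptors_.T
            + (self.descriptors_**2).sum(axis=1)
        )
        out: list[MoleculeRecord] = []
        for row in d2:
            best = row.min()
            # ties broken by lexicographically smallest canonical SMILES
            tied = np.flatnonzero(row <= best + 1e-9 * max(1.0, abs(best)))
            pick = min(tied, key=lambda i: self.library[i].canonical_smiles)
            out.append(self.library[pick])
        return out
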