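"""Synthetic test inputs: a toy molecule library and latent distributions.

The toy library is a deterministic enumeration of small organic molecules
covering every combination of aromatic-ring count (0-3) and halogenation
(with/without F, Cl or Br), so structural filters, predicates and few-shot
adaptation all have non-trivial targets.  Latent fixtures are Gaussians and
affine-shifted Gaussians with known moments, used as recovery oracles for
the GAN and the adaptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import MoleculeRecord, count_aromatic_rings, has_halogen

# hand-curated enumeration, one list per (aromatic-ring count, halogenated)
# cell; every entry is validated and census-checked at build time
_PLAIN: dict[int, list[str]] = {
    0: ["CC", "CCC", "CCCC", "CCCCC", "CCO", "CCCO", "CCN", "CCCN",
        "CC(C)O", "CC(C)C", "CCOC", "CC(C)N"],
    1: ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
        "COc1ccccc1", "CC(=O)c1ccccc1", "c1ccncc1", "Cc1ccncc1",
        "Cc1ccc(C)cc1", "Cc1ccc(O)cc1", "CCOc1ccccc1"],
    2: ["c1ccc2ccccc2c1", "Cc1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",
        "c1ccc2ncccc2c1", "c1ccc2[nH]ccc2c1", "Oc1ccc2ccccc2c1",
        "Cc1ccc(-c2ccccc2)cc1", "Nc1ccc2ccccc2c1", "COc1ccc2ccccc2c1",
        "Oc1ccc(-c2ccccc2)cc1", "Cc1ccc2[nH]ccc2c1", "CCc1ccc2ccccc2c1"],
    3: ["c1ccc2cc3ccccc3cc2c1", "c1ccc2c(c1)ccc1ccccc12",
        "c1ccc2nc3ccccc3cc2c1", "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
        "c1ccc2c(c1)[nH]c1ccccc12", "c1ccc(-c2ccc3ccccc3c2)cc1",
        "Cc1ccc2cc3ccccc3cc2c1", "Cc1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
        "Oc1ccc(-c2ccc3ccccc3c2)cc1", "Cc1ccc2c(c1)[nH]c1ccccc12",
        "Nc1ccc(-c2ccc(-c3ccccc3)cc2)cc1", "Oc1ccc2cc3ccccc3cc2c1"],
}
_HALO: dict[int, list[str]] = {
    0: ["CCCl", "CCF", "CCBr", "CCCCl", "CCCF", "CCCBr", "CC(C)Cl",
        "ClCCCl", "FC(F)CC", "CCCCBr", "OCCCl", "NCCCl"],
    1: ["Clc1ccccc1", "Fc1ccccc1", "Brc1ccccc1", "Cc1ccc(Cl)cc1",
        "Cc1ccc(F)cc1", "Oc1ccc(Cl)cc1", "Clc1ccc(Cl)cc1",
        "FC(F)(F)c1ccccc1", "Clc1ccncc1", "Nc1ccc(Br)cc1",
        "COc1ccc(Cl)cc1", "Fc1ccc(F)cc1"],
    2: ["Clc1ccc2ccccc2c1", "Fc1ccc2ccccc2c1", "Brc1ccc2ccccc2c1",
        "Clc1ccc(-c2ccccc2)cc1", "Fc1ccc(-c2ccccc2)cc1",
        "Clc1ccc(-c2ccc(F)cc2)cc1", "Clc1ccc2ncccc2c1",
        "Cc1ccc2cc(Cl)ccc2c1", "Oc1ccc(-c2ccc(Cl)cc2)cc1",
        "Brc1ccc(-c2ccccc2)cc1", "Fc1ccc2[nH]ccc2c1",
        "Clc1ccc2[nH]ccc2c1"],
    3: ["Clc1ccc2cc3ccccc3cc2c1", "Fc1ccc2cc3ccccc3cc2c1",
        "Brc1ccc2cc3ccccc3cc2c1", "Clc1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
        "Fc1ccc(-c2ccc3ccccc3c2)cc1", "Clc1ccc2nc3ccccc3cc2c1",
        "Fc1ccc(-c2ccc(-c3ccccc3)cc2)cc1", "Clc1ccc(-c2ccc3ccccc3c2)cc1",
        "Brc1ccc(-c2ccc(-c3ccccc3)cc2)cc1", "Clc1ccc2c(c1)[nH]c1ccccc12",
        "Fc1ccc2c(c1)[nH]c1ccccc12", "Cc1ccc2cc3cc(Cl)ccc3cc2c1"],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Toy-library parameters; the enumeration itself is deterministic."""

    n_molecules: int = 48
    ring_range: tuple[int, int] = (0, 3)
    halogen_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ring_range
        if not (0 <= lo <= hi <= 3):
            raise ValueError(f"ring_range must lie within 0..3: {self.ring_range}")
        if not 0.0 <= self.halogen_fraction <= 1.0:
            raise ValueError("halogen_fraction must be in [0, 1]")


def toy_molecule_library(spec: FixtureSpec = FixtureSpec()) -> list[MoleculeRecord]:
    """Deterministic library covering every (ring count, halogen) cell.

    Molecules are interleaved round-robin across ring cells, alternating
    halogenated and plain streams in proportion ``halogen_fraction``, then
    truncated to ``n_molecules``.
    """
    lo, hi = spec.ring_range
    rings = list(range(lo, hi + 1))
    n_cells = 2 * len(rings)
    if spec.n_molecules < max(10, n_cells):
        raise ValueError(
            f"n_molecules={spec.n_molecules} too small to cover {n_cells} "
            f"(ring, halogen) cells (need >= {max(10, n_cells)})"
        )
    n_halo = round(spec.halogen_fraction * spec.n_molecules)
    halo_stream = _interleave([_HALO[r] for r in rings])
    plain_stream = _interleave([_PLAIN[r] for r in rings])
    if n_halo > len(halo_stream) or spec.n_molecules - n_halo > len(plain_stream):
        raise ValueError("requested library exceeds the built-in enumeration")
    smiles = halo_stream[:n_halo] + plain_stream[: spec.n_molecules - n_halo]

    records, seen = [], set()
    for i, smi in enumerate(smiles):
        rec = MoleculeRecord.from_smiles(smi, source_line=i + 1)
        if not rec.is_valid:
            raise AssertionError(f"library entry failed to parse: {smi}")
        if rec.canonical_smiles in seen:
            raise AssertionError(f"duplicate library structure: {smi}")
        seen.add(rec.canonical_smiles)
        records.append(rec)
    _check_census(records, rings)
    return records


def _interleave(lists: list[list[str]]) -> list[str]:
    out = []
    for i in range(max(len(c) for c in lists)):
        for c in lists:
            if i < len(c):
                out.append(c[i])
    return out


def _check_census(records: list[MoleculeRecord], rings: list[int]) -> None:
    for smi, expect_rings, expect_halo in [
        (r.canonical_smiles, count_aromatic_rings(r), has_halogen(r))
        for r in records
    ]:
        if expect_rings not in rings:
            raise AssertionError(
                f"{smi}: {expect_rings} aromatic rings outside range {rings}"
            )


def library_cell_census(records: list[MoleculeRecord]) -> dict[tuple[int, bool], int]:
    """Count of molecules per (aromatic-ring count, halogenated) cell."""
    census: dict[tuple[int, bool], int] = {}
    for r in records:
        key = (count_aromatic_rings(r), has_halogen(r))
        census[key] = census.get(key, 0) + 1
    return census


def gaussian_latents(mean: np.ndarray, cov: np.ndarray, n: int,
                     seed: int) -> np.ndarray:
    """n seeded draws from N(mean, cov); cov must be symmetric PSD."""
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10 * max(1.0, abs(eigvals.max())):
        raise ValueError("covariance must be positive semidefinite")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mean, cov, size=n, method="svd")


def affine_target_latents(mean: np.ndarray, cov: np.ndarray,
                          A_star: np.ndarray, b_star: np.ndarray, n: int,
                          seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw z ~ N(mean, cov) and emit A*·z + b*, with the ground truth.

    Returns ``(samples, A_star, b_star)``; the transformed distribution has
    mean A*·mean + b* and covariance A*·cov·A*ᵀ.
    """
    A_star = np.atleast_2d(np.asarray(A_star, dtype=float))
    b_star = np.asarray(b_star, dtype=float)
    source = gaussian_latents(mean, cov, n, seed)
    if A_star.shape[1] != source.shape[1] or b_star.shape[0] != A_star.shape[0]:
        raise ValueError("affine transform shapes inconsistent with source")
    return source @ A_star.T + b_star, A_star, b_star
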