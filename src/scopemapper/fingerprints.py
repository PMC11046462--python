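"""Extended-connectivity fingerprints and Jaccard (Tanimoto) distances.

ECFPs encode circular atom environments up to a bond radius, folded to a
fixed-length binary vector; the Jaccard distance between two such vectors
is the structural dissimilarity the whole workflow is built on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import MoleculeSet

__all__ = [
    "FingerprintMatrix",
    "compute_fingerprints",
    "jaccard_distance",
    "pairwise_jaccard",
]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class FingerprintMatrix:
    """Binary ECFP matrix with its generation parameters.

    Rows align one-to-one with ``molecule_ids``; folding parameters are
    carried along so a fitted map can detect incompatible fingerprints.
    """

    bits: np.ndarray  # (n_molecules, n_bits) uint8 in {0, 1}
    radius: int
    n_bits: int
    molecule_ids: tuple[str, ...]

    def __post_init__(self):
        bits = np.asarray(self.bits)
        if bits.ndim != 2 or bits.shape[0] != len(self.molecule_ids):
            raise ValueError("bits must be (n_molecules, n_bits) aligned with molecule_ids")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")

    def __len__(self) -> int:
        return self.bits.shape[0]

    def same_params(self, other: "FingerprintMatrix") -> bool:
        return self.radius == other.radius and self.n_bits == other.n_bits


def compute_fingerprints(
    mols: MoleculeSet,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> FingerprintMatrix:
    """Morgan/ECFP binary fingerprints for every record of a MoleculeSet.

    ``radius`` counts bond steps (radius 2 is the common ECFP4-equivalent);
    ``n_bits`` must be a power of two >= 256. Chirality is not encoded:
    the workflow operates at scaffold level and supplier catalogs often
    omit stereochemistry.
    """
    if len(mols) == 0:
        raise ValueError("empty MoleculeSet")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 256 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError("n_bits must be a power of two >= 256")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=False
    )
    rows = np.zeros((len(mols), n_bits), dtype=np.uint8)
    for i, rec in enumerate(mols):
        mol = Chem.MolFromSmiles(rec.smiles_canonical)
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return FingerprintMatrix(
        bits=rows, radius=radius, n_bits=n_bits, molecule_ids=tuple(mols.ids)
    )


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard (Tanimoto) distance 1 - |a AND b| / |a OR b| of two bit vectors.

    A true metric on nonzero binary vectors; raises if both vectors are
    all-zero (the ratio is undefined there).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ZeroDivisionError("Jaccard distance undefined for two all-zero vectors")
    inter = int(np.count_nonzero(a & b))
    return 1.0 - inter / union


def pairwise_jaccard(
    fps: FingerprintMatrix, pairs: Sequence[tuple[int, int]]
) -> list[float]:
    """Jaccard distances for an explicit list of row-index pairs."""
    n = len(fps)
    bits = fps.bits.astype(bool)
    out = []
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"pair ({i}, {j}) out of range for {n} fingerprints")
        out.append(jaccard_distance(bits[i], bits[j]))
    return out
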