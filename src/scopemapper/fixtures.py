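"""Deterministic synthetic molecule sets with known scaffold-family structure.

A reference chemical library (a drug library in the original use case) is
not redistributable, so tests and demos run on generated molecule sets
instead: each family shares a distinctive core scaffold and varies only a
small substituent, giving small intra-family and large inter-family
fingerprint distances — the structural-cluster statistics the mapping and
clustering stages assume. Family membership is recorded on every record
and serves as ground truth for structure-recovery checks.

Generation is enumeration-first: each family is a core template with one
substitution slot crossed with a substituent list; the seed controls only
which grid points are sampled, never their validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, MoleculeSet, canonicalize
from .selection import OLEFIN_SMARTS

__all__ = [
    "FamilySpec",
    "GenerationError",
    "generate_reference",
    "generate_candidates",
    "default_reference_families",
    "default_candidate_families",
]


class GenerationError(ValueError):
    """A template/substituent combination did not produce a valid molecule."""


#: Small substituents shared across families. Each is a valid SMILES
#: fragment when spliced into a branch slot ``({})`` or appended to an atom.
_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "C(C)C", "CO",
    "CCO", "CCCO", "COC", "CCOC", "CCOCC", "CC(C)O", "CCF", "CCCl",
    "C(F)(F)F", "CC#N", "CCC#N", "C1CC1", "CC1CC1", "C1CCC1", "CCCOC", "CC(C)(C)C",
)


@dataclass(frozen=True)
class FamilySpec:
    """One scaffold family: a core template with a substitution slot.

    ``core_smiles_template`` contains a single ``{}`` placeholder that is
    filled with each substituent fragment; ``count`` molecules are emitted
    (a seeded sample of the enumeration grid).
    """

    name: str
    core_smiles_template: str
    substituents: tuple[str, ...] = _SUBSTITUENTS
    count: int = 20


def default_reference_families(count: int = 20) -> list[FamilySpec]:
    """The shipped 15-family reference preset (drug-like chemotype stand-ins).

    Cores span saturated chains, aromatics, heteroaromatics, a sugar-like
    pyranose, carbonyl chemotypes (amide, urea, sulfonamide, lactam,
    benzamide) and saturated N/S heterocycles, mirroring the diversity
    axes a drug library exhibits.
    """
    cores = [
        ("alkyl", "CCCCCCCC{}"),
        ("styrene", "C=Cc1ccc({})cc1"),
        ("pyridine", "c1ccnc({})c1"),
        ("pyranose", "OCC1OC({})C(O)C(O)C1O"),
        ("amide", "CCCCC(=O)N{}"),
        ("urea", "CCNC(=O)N{}"),
        ("sulfonamide", "c1ccccc1S(=O)(=O)N{}"),
        ("terpenoid", "CC1=CCC(CC1)C(C)(C){}"),
        ("lactam", "O=C1CCCCCN1{}"),
        ("aniline", "Nc1ccc({})cc1"),
        ("phenol", "Oc1ccc({})cc1"),
        ("halobenzene", "Clc1ccc({})cc1Cl"),
        ("morpholine", "C1COCCN1{}"),
        ("thiophene", "c1ccc({})s1"),
        ("benzamide", "NC(=O)c1ccc({})cc1"),
    ]
    return [FamilySpec(name=n, core_smiles_template=t, count=count) for n, t in cores]


def default_candidate_families(count: int = 12) -> list[FamilySpec]:
    """Olefin-bearing analogs of the reference families (candidate preset)."""
    cores = [
        ("alkene", "C=CCCCCCC{}"),
        ("styrene", "C=Cc1ccc({})cc1"),
        ("vinylpyridine", "C=Cc1ccnc({})c1"),
        ("glycal", "OCC1OC=CC({})C1O"),
        ("acrylamide", "C=CC(=O)N{}"),
        ("allylurea", "C=CCNC(=O)N{}"),
        ("vinylsulfonamide", "C=CS(=O)(=O)N{}"),
        ("terpene", "CC1=CCC(CC1)C(=C){}"),
        ("allyllactam", "C=CCN1C(=O)CCCC1{}"),
        ("vinylaniline", "Nc1ccc(cc1)C=C{}"),
        ("vinylphenol", "Oc1ccc(cc1)C=C{}"),
        ("halostyrene", "Clc1ccc(cc1)C=C{}"),
        ("allylmorpholine", "C1COCCN1CC=C{}"),
        ("vinylthiophene", "C=Cc1ccc({})s1"),
        ("cinnamamide", "NC(=O)C=Cc1ccc({})cc1"),
    ]
    return [FamilySpec(name=n, core_smiles_template=t, count=count) for n, t in cores]


def _emit_family(spec: FamilySpec, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Sample (substituent, canonical SMILES) pairs for one family."""
    if spec.count > len(spec.substituents):
        raise GenerationError(
            f"family {spec.name!r}: count {spec.count} exceeds the "
            f"{len(spec.substituents)}-point enumeration grid"
        )
    order = rng.permutation(len(spec.substituents))
    out = []
    for idx in order[: spec.count]:
        sub = spec.substituents[idx]
        smiles = spec.core_smiles_template.format(sub)
        if Chem.MolFromSmiles(smiles) is None:
            raise GenerationError(
                f"family {spec.name!r}: template {spec.core_smiles_template!r} "
                f"with substituent {sub!r} gives unparseable SMILES {smiles!r}"
            )
        out.append((sub, canonicalize(smiles)))
    return out


def _assemble(
    families: Sequence[FamilySpec],
    seed: int,
    min_total: int = 50,
    prices: bool = False,
    price_rng_offset: int = 7919,
) -> MoleculeSet:
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    if sum(f.count for f in families) < min_total:
        raise ValueError(f"need a total count of >= {min_total} for embedding stability")
    rng = np.random.default_rng(seed)
    price_rng = np.random.default_rng(seed + price_rng_offset)
    out = MoleculeSet()
    seen: set[str] = set()
    for fam in families:
        for i, (_sub, canon) in enumerate(_emit_family(fam, rng)):
            if canon in seen:
                continue  # cross-family collision: keep first occurrence
            seen.add(canon)
            mol = Chem.MolFromSmiles(canon)
            from rdkit.Chem import Descriptors

            price = float(np.round(price_rng.lognormal(mean=np.log(40.0), sigma=0.8), 2))
            avail = bool(price_rng.random() < 0.85)
            out.records.append(
                MoleculeRecord(
                    id=f"{fam.name}_{i:03d}",
                    smiles_raw=canon,
                    smiles_canonical=canon,
                    mw=float(Descriptors.MolWt(mol)),
                    price_per_g=price if prices else None,
                    available=avail if prices else None,
                    family=fam.name,
                )
            )
    return out


def generate_reference(
    families: Optional[Sequence[FamilySpec]] = None, seed: int = 42
) -> MoleculeSet:
    """Generate the reference library fixture (no prices, family-tagged).

    Deterministic for a given seed; all molecules are emitted in canonical
    form and deduplicated across families (first occurrence wins).
    """
    return _assemble(families or default_reference_families(), seed, prices=False)


def generate_candidates(
    families: Optional[Sequence[FamilySpec]] = None,
    require_smarts: str = OLEFIN_SMARTS,
    seed: int = 42,
) -> MoleculeSet:
    """Generate a candidate substrate list fixture.

    Every emitted molecule matches ``require_smarts`` (olefin by default) —
    a violation is a generation error, not a silent drop. Price-per-gram
    and availability columns are populated from a seeded distribution
    (lognormal centered near 40 currency units/g; ~85% available) so the
    affordability filters have something to act on.
    """
    query = Chem.MolFromSmarts(require_smarts)
    if query is None:
        raise ValueError(f"require_smarts does not compile: {require_smarts!r}")
    out = _assemble(families or default_candidate_families(), seed, prices=True)
    for rec in out.records:
        if not Chem.MolFromSmiles(rec.smiles_canonical).HasSubstructMatch(query):
            raise GenerationError(
                f"candidate {rec.id} ({rec.smiles_canonical}) does not match "
                f"required pattern {require_smarts!r}"
            )
    return out
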