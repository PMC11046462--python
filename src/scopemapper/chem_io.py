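"""Reading, standardizing and writing molecule records.

Supplier catalogs and reference libraries list molecules inconsistently:
salts, charged forms, duplicate entries under different SMILES spellings.
Everything downstream (fingerprints, the map, the filters) assumes one
canonical neutral parent structure per record, so this module is the single
gate through which molecules enter the workflow.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "MoleculeSet",
    "ValidationError",
    "SchemaError",
    "canonicalize",
    "read_molecules",
    "from_smiles_list",
    "write_table",
]


class ValidationError(ValueError):
    """A SMILES string could not be parsed or standardized."""


class SchemaError(ValueError):
    """An input table lacks a required column."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule with optional catalog metadata.

    ``mw`` is always computed from the standardized structure so the
    molecular-weight filter has a single source of truth.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str
    mw: float
    price_per_g: Optional[float] = None
    available: Optional[bool] = None
    family: Optional[str] = None


@dataclass
class MoleculeSet:
    """Ordered, deduplicated molecule records plus a machine-readable reject log.

    Invariants: canonical SMILES are unique across ``records``, and every
    input row lands in exactly one of ``records`` / ``rejects``.
    """

    records: list[MoleculeRecord] = field(default_factory=list)
    rejects: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles_canonical for r in self.records]

    def mols(self) -> list[Chem.Mol]:
        return [Chem.MolFromSmiles(r.smiles_canonical) for r in self.records]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "smiles": r.smiles_canonical,
                    "smiles_raw": r.smiles_raw,
                    "mw": r.mw,
                    "price_per_g": r.price_per_g,
                    "available": r.available,
                    "family": r.family,
                }
                for r in self.records
            ]
        )


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def canonicalize(smiles_raw: str) -> str:
    """Canonical SMILES of the neutralized largest covalent fragment.

    Salt / solvent fragments are stripped (largest fragment by heavy-atom
    count wins) and charges are neutralized where a neutral form exists.
    Idempotent: applying it to its own output returns the same string.

    Raises
    ------
    ValidationError
        If the SMILES cannot be parsed.
    """
    if smiles_raw is None or not str(smiles_raw).strip():
        raise ValidationError("empty SMILES")
    mol = Chem.MolFromSmiles(str(smiles_raw))
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles_raw!r}")
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def _standardize_rows(
    rows: Iterable[Mapping[str, object]],
) -> MoleculeSet:
    """Build a MoleculeSet from raw row dicts with keys smiles[, id, ...]."""
    out = MoleculeSet()
    seen: dict[str, str] = {}  # canonical smiles -> first id
    used_ids: set[str] = set()
    for i, row in enumerate(rows):
        raw = str(row.get("smiles") or "").strip()
        if not raw:
            out.rejects.append((str(row.get("smiles", "")), "empty"))
            continue
        try:
            canon = canonicalize(raw)
        except ValidationError:
            out.rejects.append((raw, "parse_error"))
            continue
        if canon in seen:
            out.rejects.append((raw, "duplicate"))
            continue
        rid = str(row.get("id") or "").strip() or f"mol{i}"
        if rid in used_ids:
            out.rejects.append((raw, "duplicate_id"))
            continue
        mol = Chem.MolFromSmiles(canon)
        price = row.get("price_per_g")
        avail = row.get("available")
        rec = MoleculeRecord(
            id=rid,
            smiles_raw=raw,
            smiles_canonical=canon,
            mw=float(Descriptors.MolWt(mol)),
            price_per_g=None if price in (None, "") else float(price),  # type: ignore[arg-type]
            available=None if avail in (None, "") else _as_bool(avail),
            family=(str(row["family"]) if row.get("family") not in (None, "") else None),
        )
        seen[canon] = rid
        used_ids.add(rid)
        out.records.append(rec)
    return out


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ValidationError(f"not a boolean: {value!r}")


def from_smiles_list(
    smiles: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    families: Optional[Sequence[str]] = None,
) -> MoleculeSet:
    """Standardize an in-memory list of SMILES into a MoleculeSet."""
    rows = []
    for i, smi in enumerate(smiles):
        row: dict[str, object] = {"smiles": smi}
        if ids is not None:
            row["id"] = ids[i]
        if families is not None:
            row["family"] = families[i]
        rows.append(row)
    return _standardize_rows(rows)


def read_molecules(path: str | Path, format: Optional[str] = None) -> MoleculeSet:
    """Read a .smi or .csv molecule file into a standardized MoleculeSet.

    ``.smi`` dialect: whitespace-separated ``SMILES id`` per line, ``#``
    comments and blank lines ignored. CSV must carry a ``smiles`` column
    (case-insensitive); ``id``, ``price_per_g``, ``available`` and
    ``family`` columns are picked up when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("smi" if path.suffix.lower() in (".smi", ".smiles") else "csv")
    if fmt == "smi":
        rows = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            row: dict[str, object] = {"smiles": parts[0]}
            if len(parts) > 1:
                row["id"] = parts[1].strip()
            rows.append(row)
        return _standardize_rows(rows)
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty CSV")
            colmap = {name.lower().strip(): name for name in reader.fieldnames}
            if "smiles" not in colmap:
                raise SchemaError(f"{path}: no 'smiles' column (found {reader.fieldnames})")
            rows = []
            for rec in reader:
                row = {
                    key: rec.get(colmap[key])
                    for key in ("smiles", "id", "price_per_g", "available", "family")
                    if key in colmap
                }
                rows.append(row)
        return _standardize_rows(rows)
    raise ValueError(f"unknown format: {fmt!r}")


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write flat records as UTF-8 CSV, preserving input row order.

    With zero rows an empty header-only file is written (header unknown,
    so the file contains just a newline-terminated empty header when the
    key set cannot be inferred).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fieldnames: list[str] = list(rows[0].keys()) if rows else []
    for row in rows:
        if list(row.keys()) != fieldnames:
            raise ValueError("all rows must share one key set")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
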