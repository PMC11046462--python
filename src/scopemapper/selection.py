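"""Candidate filtering and per-cluster representative selection.

Candidates first pass reaction-compatibility filters (molecular weight,
price, SMARTS-encoded substructure rules), are projected onto the frozen
map, and each cluster then claims the projected candidate closest to its
center. When the centermost candidate is unavailable or already claimed,
the next-closest candidates up to a top-n fallback depth are considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeSet

__all__ = [
    "FilterSpec",
    "SelectionConfig",
    "ClusterSelection",
    "SelectionResult",
    "DEFAULT_EXCLUDE_SMARTS",
    "OLEFIN_SMARTS",
    "apply_filters",
    "rank_candidates",
    "select_representatives",
]

DEFAULT_MW_MAX = 700.0  # Da
DEFAULT_PRICE_MAX = 100.0  # currency units per gram
DEFAULT_TOP_N = 5

#: Any non-aromatic carbon-carbon double bond (the substrate-class pattern
#: for an olefin scope).
OLEFIN_SMARTS = "[CX3]=[CX3]"

#: Named exclusion rules shipped as editable data. The tetra-substituted
#: alkene pattern matches a C=C whose four substituents are all carbon; the
#: free-amine pattern matches primary/secondary aliphatic amines that are
#: neither amides, sulfonamides nor anilines.
DEFAULT_EXCLUDE_SMARTS: dict[str, str] = {
    "tetrasubstituted_alkene": "[C]([#6])([#6])=[C]([#6])[#6]",
    "free_amine": "[NX3;H2,H1;!$([NX3][#6X3]=[OX1,SX1,NX2]);!$([NX3]S(=O)=O);!$([NX3]c)]",
}


def _compile(patterns: Mapping[str, str]) -> dict[str, Chem.Mol]:
    out = {}
    for name, smarts in patterns.items():
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"SMARTS pattern {name!r} does not compile: {smarts!r}")
        out[name] = query
    return out


@dataclass(frozen=True)
class FilterSpec:
    """Reaction-compatibility filter: thresholds plus named SMARTS rules.

    A candidate survives iff mw < mw_max, price_per_g < price_max, it
    matches every require_smarts pattern and none of the exclude_smarts
    patterns. All SMARTS are compiled at construction time so a bad
    pattern fails at config load, never mid-run. ``keep_missing_price``
    controls candidates with no price column (kept by default: price
    filtering is an affordability convenience and dropping unknowns would
    bias toward catalog completeness).
    """

    mw_max: Optional[float] = DEFAULT_MW_MAX
    price_max: Optional[float] = DEFAULT_PRICE_MAX
    exclude_smarts: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUDE_SMARTS)
    )
    require_smarts: Mapping[str, str] = field(default_factory=dict)
    keep_missing_price: bool = True

    def __post_init__(self):
        for thr, label in ((self.mw_max, "mw_max"), (self.price_max, "price_max")):
            if thr is not None and thr <= 0:
                raise ValueError(f"{label} must be strictly positive")
        _compile(self.exclude_smarts)
        _compile(self.require_smarts)


@dataclass(frozen=True)
class SelectionConfig:
    """How representatives are drawn from the ranked lists.

    ``top_n`` is the fallback depth per cluster; ``unique`` forbids one
    candidate from representing two clusters (a scope table lists distinct
    compounds).
    """

    top_n: int = DEFAULT_TOP_N
    unique: bool = True

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class ClusterSelection:
    """Ranked candidates and the chosen representative for one cluster."""

    cluster_name: str
    ranked: list[tuple[str, float]]  # (candidate id, distance to center), nondecreasing
    chosen: Optional[str]
    warning: Optional[str] = None


@dataclass
class SelectionResult:
    per_cluster: list[ClusterSelection]

    @property
    def n_served(self) -> int:
        return sum(1 for c in self.per_cluster if c.chosen is not None)

    @property
    def chosen_ids(self) -> list[str]:
        return [c.chosen for c in self.per_cluster if c.chosen is not None]

    def to_rows(self, smiles_by_id: Optional[Mapping[str, str]] = None) -> list[dict]:
        rows = []
        for sel in self.per_cluster:
            for rank, (cid, dist) in enumerate(sel.ranked, start=1):
                rows.append(
                    {
                        "cluster_name": sel.cluster_name,
                        "rank": rank,
                        "candidate_id": cid,
                        "smiles": (smiles_by_id or {}).get(cid, ""),
                        "distance": f"{dist:.6f}",
                        "chosen": cid == sel.chosen,
                    }
                )
        return rows


def apply_filters(
    candidates: MoleculeSet, spec: FilterSpec
) -> tuple[MoleculeSet, list[dict]]:
    """Split candidates into survivors and a first-failed-rule rejection log.

    Rules are checked in a fixed order (mw, price, require patterns,
    exclude patterns); the log records one row per rejected molecule with
    the first rule that failed.
    """
    require = _compile(spec.require_smarts)
    exclude = _compile(spec.exclude_smarts)
    kept = MoleculeSet()
    log: list[dict] = []

    for rec in candidates:
        reason = None
        detail = ""
        if spec.mw_max is not None and rec.mw >= spec.mw_max:
            reason, detail = "mw", f"{rec.mw:.1f} >= {spec.mw_max:g}"
        elif spec.price_max is not None:
            if rec.price_per_g is None:
                if not spec.keep_missing_price:
                    reason, detail = "price", "missing price"
            elif rec.price_per_g >= spec.price_max:
                reason, detail = "price", f"{rec.price_per_g:.2f} >= {spec.price_max:g}"
        if reason is None:
            mol = Chem.MolFromSmiles(rec.smiles_canonical)
            for name, query in require.items():
                if not mol.HasSubstructMatch(query):
                    reason, detail = f"require:{name}", "pattern not matched"
                    break
            if reason is None:
                for name, query in exclude.items():
                    if mol.HasSubstructMatch(query):
                        reason, detail = f"exclude:{name}", "pattern matched"
                        break
        if reason is None:
            kept.records.append(rec)
        else:
            log.append({"candidate_id": rec.id, "rule": reason, "detail": detail})
    return kept, log


def rank_candidates(
    centers: np.ndarray,
    candidate_coords: np.ndarray,
    candidate_ids: Sequence[str],
    tiebreak_keys: Optional[Sequence[str]] = None,
) -> list[list[tuple[int, float]]]:
    """Per-center candidate rankings by Euclidean distance in the embedding.

    Every candidate is ranked against every center (cluster membership of
    the candidate itself is irrelevant; proximity to the center is what
    the selection uses). Ties are broken by ``tiebreak_keys``
    (canonical SMILES by convention), falling back to candidate ids.
    Returns, per center, a list of (candidate index, distance) sorted by
    nondecreasing distance.
    """
    centers = np.asarray(centers, dtype=float)
    coords = np.asarray(candidate_coords, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty candidate set")
    if coords.shape[0] != len(candidate_ids):
        raise ValueError("candidate_coords rows must align with candidate_ids")
    keys = list(tiebreak_keys) if tiebreak_keys is not None else list(candidate_ids)
    ranked = []
    for center in centers:
        d = np.linalg.norm(coords - center[None, :], axis=1)
        order = sorted(range(len(d)), key=lambda i: (d[i], keys[i], candidate_ids[i]))
        ranked.append([(i, float(d[i])) for i in order])
    return ranked


def select_representatives(
    ranked: Sequence[Sequence[tuple[int, float]]],
    config: SelectionConfig,
    candidate_ids: Sequence[str],
    availability: Optional[Sequence[bool]] = None,
    cluster_names: Optional[Sequence[str]] = None,
) -> SelectionResult:
    """Greedy nearest-first assignment of one representative per cluster.

    Clusters are processed in order of their best (smallest) rank-1
    candidate distance (ties by cluster name); each takes the closest
    available, not-yet-consumed candidate within its ``top_n``. A cluster
    whose top-n is exhausted is reported unserved with a warning — never a
    failure.
    """
    k = len(ranked)
    names = list(cluster_names) if cluster_names is not None else [
        n for n in _default_names(k)
    ]
    if len(names) != k:
        raise ValueError("cluster_names must cover all ranked lists")
    avail = list(availability) if availability is not None else [True] * len(candidate_ids)

    order = sorted(range(k), key=lambda c: (ranked[c][0][1] if ranked[c] else np.inf, names[c]))
    consumed: set[int] = set()
    out: dict[int, ClusterSelection] = {}
    for c in order:
        entries = list(ranked[c])[: config.top_n]
        chosen = None
        warning = None
        for idx, _dist in entries:
            if not avail[idx]:
                continue
            if config.unique and idx in consumed:
                continue
            chosen = idx
            break
        if chosen is None:
            warning = (
                f"cluster {names[c]}: no available candidate within top_{config.top_n}"
            )
        else:
            consumed.add(chosen)
        out[c] = ClusterSelection(
            cluster_name=names[c],
            ranked=[(candidate_ids[i], d) for i, d in ranked[c]],
            chosen=candidate_ids[chosen] if chosen is not None else None,
            warning=warning,
        )
    return SelectionResult(per_cluster=[out[c] for c in range(k)])


def _default_names(k: int) -> list[str]:
    from .clustering import cluster_names as _names

    return _names(k)
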