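"""Fit, score and reuse the 2-D chemical-space map.

The reference library is embedded from fingerprint space into the plane
with UMAP using the Jaccard metric, so the embedding optimizes the same
geometry the quality metric D is measured on. A fitted map is frozen: new
candidate molecules are projected onto it without refitting.

Two quality metrics steer hyperparameter choice:

* D — correlation between pairwise fingerprint Jaccard distances and the
  corresponding Euclidean distances in the projection (distance
  preservation), estimated on a seeded sample of unordered pairs;
* S — silhouette score of a clustering of the embedding (cluster
  separation), computed by the clustering module.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

from .fingerprints import FingerprintMatrix

__all__ = [
    "EmbedParams",
    "TrainedMap",
    "EmbeddingQuality",
    "fit_map",
    "project",
    "embedding_quality",
    "scan_embed_params",
    "save_map",
    "load_map",
]

MAP_FORMAT_VERSION = 1
DEFAULT_N_PAIRS = 50_000


@dataclass(frozen=True)
class EmbedParams:
    """UMAP hyperparameters governing the local/global information balance.

    ``n_neighbors`` (N_b) sets how many neighbors define the local manifold
    (larger = more global structure); ``min_dist`` (M_d) is the floor on
    embedded point spacing (smaller = tighter local packing). Defaults are
    the workflow's optimized values: N_b = 30, M_d = 0.1.
    """

    n_neighbors: int = 30
    min_dist: float = 0.1
    metric: str = "jaccard"
    seed: int = 42

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not (0.0 <= self.min_dist < 1.0):
            raise ValueError("min_dist must be in [0, 1)")


@dataclass
class TrainedMap:
    """A frozen 2-D embedding of the reference library.

    ``coords`` holds one row per reference molecule; ``project`` maps any
    fingerprint matrix generated with the same (radius, n_bits) onto the
    plane using the frozen fit.
    """

    coords: np.ndarray  # (n, 2)
    params: EmbedParams
    reference_ids: tuple[str, ...]
    fingerprint_radius: int
    fingerprint_n_bits: int
    _reducer: object = field(repr=False, default=None)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if coords.shape[0] != len(self.reference_ids):
            raise ValueError("coords rows must align with reference_ids")
        if not np.isfinite(coords).all():
            raise ValueError("coords must be finite")
        self.coords = coords

    def project(self, fps: FingerprintMatrix) -> np.ndarray:
        return project(self, fps)


@dataclass(frozen=True)
class EmbeddingQuality:
    """Distance-preservation score D with its pair-sampling provenance."""

    D: float
    n_pairs: int
    seed: int

    def __post_init__(self):
        if not -1.0 <= self.D <= 1.0 + 1e-12:
            raise ValueError("correlation out of [-1, 1]")


def fit_map(fps: FingerprintMatrix, params: EmbedParams = EmbedParams()) -> TrainedMap:
    """Fit the 2-D UMAP embedding of a reference fingerprint matrix.

    Deterministic under a fixed ``params.seed`` (UMAP runs single-threaded
    when seeded). Requires more molecules than ``n_neighbors``.
    """
    import umap  # deferred: numba compilation is slow at import

    n = len(fps)
    if n <= params.n_neighbors:
        raise ValueError(
            f"need more molecules ({n}) than n_neighbors ({params.n_neighbors})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            metric=params.metric,
            random_state=params.seed,
        )
        coords = reducer.fit_transform(fps.bits.astype(np.float32))
    return TrainedMap(
        coords=np.asarray(coords, dtype=float),
        params=params,
        reference_ids=fps.molecule_ids,
        fingerprint_radius=fps.radius,
        fingerprint_n_bits=fps.n_bits,
        _reducer=reducer,
    )


def project(trained: TrainedMap, fps: FingerprintMatrix) -> np.ndarray:
    """Project new molecules onto a frozen map; returns an m x 2 array.

    The fingerprints must have been generated with the same radius and bit
    length as the reference fingerprints the map was fitted on.
    """
    if fps.radius != trained.fingerprint_radius or fps.n_bits != trained.fingerprint_n_bits:
        raise ValueError(
            "fingerprint parameters (radius=%d, n_bits=%d) do not match the map "
            "(radius=%d, n_bits=%d)"
            % (fps.radius, fps.n_bits, trained.fingerprint_radius, trained.fingerprint_n_bits)
        )
    if len(fps) == 0:
        return np.empty((0, 2), dtype=float)
    if trained._reducer is None:
        raise ValueError("map carries no frozen reducer (was it loaded from coords only?)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = trained._reducer.transform(fps.bits.astype(np.float32))
    return np.asarray(out, dtype=float)


def sample_pairs(n: int, n_pairs: int, seed: int) -> np.ndarray:
    """Sample unordered index pairs, without replacement when possible."""
    total = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs >= total:
        i, j = np.triu_indices(n, k=1)
        return np.column_stack([i, j])
    # sample flat upper-triangle positions without replacement
    flat = rng.choice(total, size=n_pairs, replace=False)
    # invert the row-major upper-triangle enumeration
    i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    return np.column_stack([i, j])


def embedding_quality(
    fps: FingerprintMatrix,
    coords: np.ndarray,
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
    estimator: str = "pearson",
) -> EmbeddingQuality:
    """Metric D: correlation of fingerprint vs embedded pairwise distances.

    Pearson correlation (Spearman available via ``estimator``) over a
    seeded sample of unordered molecule pairs. Raises on degenerate input
    (zero variance in either distance list).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(fps)
    if coords.shape[0] != n:
        raise ValueError("coords rows must match fingerprint rows")
    if n < 3:
        raise ValueError("need at least 3 molecules")
    if n_pairs < 10:
        raise ValueError("n_pairs must be >= 10")
    pairs = sample_pairs(n, n_pairs, seed)
    bits = fps.bits.astype(bool)
    a, b = pairs[:, 0], pairs[:, 1]
    inter = np.count_nonzero(bits[a] & bits[b], axis=1)
    union = np.count_nonzero(bits[a] | bits[b], axis=1)
    if (union == 0).any():
        raise ZeroDivisionError("all-zero fingerprint pair encountered")
    fp_d = 1.0 - inter / union
    emb_d = np.linalg.norm(coords[a] - coords[b], axis=1)
    if np.ptp(fp_d) == 0 or np.ptp(emb_d) == 0:
        raise ValueError("degenerate input: zero variance in a distance list")
    if estimator == "pearson":
        r = pearsonr(fp_d, emb_d).statistic
    elif estimator == "spearman":
        r = spearmanr(fp_d, emb_d).statistic
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return EmbeddingQuality(D=float(r), n_pairs=len(pairs), seed=seed)


def scan_embed_params(
    fps: FingerprintMatrix,
    grid: Sequence[EmbedParams],
    k_clusters: int = 15,
    n_pairs: int = DEFAULT_N_PAIRS,
    pair_seed: int = 0,
):
    """Score a hyperparameter grid by (D, S); returns a tidy DataFrame.

    Each grid point is fitted independently; D comes from
    :func:`embedding_quality` and S from clustering the embedding at
    ``k_clusters``. Grid points violating fit preconditions are recorded
    as ``status='failed'`` rows and the scan continues. Rows are sorted by
    descending rank-sum of (D, S), which avoids mixing the two scales.
    """
    import pandas as pd

    from .clustering import cluster_map, silhouette_score

    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    rows = []
    for p in grid:
        row = {
            "n_neighbors": p.n_neighbors,
            "min_dist": p.min_dist,
            "D": np.nan,
            "S": np.nan,
            "status": "ok",
        }
        try:
            trained = fit_map(fps, p)
            row["D"] = embedding_quality(fps, trained.coords, n_pairs, pair_seed).D
            model = cluster_map(trained.coords, k_clusters)
            row["S"] = silhouette_score(trained.coords, model.labels).S
        except (ValueError, ZeroDivisionError) as exc:
            row["status"] = f"failed: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    rank_sum = table.loc[ok, "D"].rank() + table.loc[ok, "S"].rank()
    table["rank_sum"] = np.nan
    table.loc[ok, "rank_sum"] = rank_sum
    return table.sort_values(
        "rank_sum", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)


def save_map(trained: TrainedMap, path: str | Path) -> None:
    """Persist a fitted map (versioned pickle embedding fingerprint params)."""
    payload = {
        "format_version": MAP_FORMAT_VERSION,
        "map": trained,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("wb") as fh:
        pickle.dump(payload, fh)


def load_map(path: str | Path) -> TrainedMap:
    with Path(path).open("rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MAP_FORMAT_VERSION:
        raise ValueError(f"unsupported map format: {payload.get('format_version')!r}")
    return payload["map"]
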