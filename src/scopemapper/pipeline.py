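"""End-to-end orchestration: reference map -> clusters -> filtered candidates
-> projection -> one representative per cluster.

A run is fully described by a :class:`RunConfig`; every artifact (CSV
tables, the frozen map, a JSON manifest of all parameters and seeds) lands
in one output directory, and rerunning from the same manifest reproduces
the CSVs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import fixtures
from .chem_io import MoleculeSet, read_molecules, write_table
from .clustering import (
    DEFAULT_K,
    DEFAULT_K_MAX,
    DEFAULT_K_MIN,
    cluster_map,
    scan_cluster_numbers,
    silhouette_score,
)
from .fingerprints import DEFAULT_N_BITS, DEFAULT_RADIUS, compute_fingerprints
from .mapping import EmbedParams, embedding_quality, fit_map, project, save_map
from .selection import (
    DEFAULT_EXCLUDE_SMARTS,
    FilterSpec,
    SelectionConfig,
    apply_filters,
    rank_candidates,
    select_representatives,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("scopemapper")


@dataclass
class RunConfig:
    """Every knob of one workflow run.

    ``reference`` / ``candidates`` are file paths; when either is None the
    packaged fixture generator stands in (reference: 15 scaffold families,
    candidates: olefin-bearing analogs). Defaults carry the workflow's
    published constants: N_b = 30, M_d = 0.1, k = 15 (scan 10-25), MW
    < 700 Da, price < 100 per gram, top-5 fallback.
    """

    reference: Optional[str] = None
    candidates: Optional[str] = None
    outdir: str = "scopemapper_run"
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_N_BITS
    n_neighbors: int = 30
    min_dist: float = 0.1
    k: int = DEFAULT_K
    k_scan_min: int = DEFAULT_K_MIN
    k_scan_max: int = DEFAULT_K_MAX
    run_k_scan: bool = False
    linkage: str = "ward"
    mw_max: Optional[float] = 700.0
    price_max: Optional[float] = 100.0
    exclude_smarts: dict = field(default_factory=lambda: dict(DEFAULT_EXCLUDE_SMARTS))
    require_smarts: dict = field(default_factory=dict)
    keep_missing_price: bool = True
    top_n: int = 5
    unique: bool = True
    quality_pairs: int = 50_000
    seed: int = 42
    make_plot: bool = True

    def embed_params(self) -> EmbedParams:
        return EmbedParams(
            n_neighbors=self.n_neighbors, min_dist=self.min_dist, seed=self.seed
        )

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            mw_max=self.mw_max,
            price_max=self.price_max,
            exclude_smarts=dict(self.exclude_smarts),
            require_smarts=dict(self.require_smarts),
            keep_missing_price=self.keep_missing_price,
        )

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(top_n=self.top_n, unique=self.unique)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _stage(name: str, **counts) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def _mol_rows(mols: MoleculeSet) -> list[dict]:
    return [
        {
            "id": r.id,
            "smiles": r.smiles_canonical,
            "smiles_raw": r.smiles_raw,
            "mw": f"{r.mw:.3f}",
            "price_per_g": "" if r.price_per_g is None else f"{r.price_per_g:.2f}",
            "available": "" if r.available is None else str(r.available).lower(),
            "family": r.family or "",
        }
        for r in mols
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and write all artifacts into ``config.outdir``.

    Returns a dict with the in-memory results (map, cluster model,
    selection, quality metrics) and the paths of everything written. Any
    stage failure raises with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    stage = "load_reference"
    try:
        # --- reference library -------------------------------------------
        if config.reference:
            reference = read_molecules(config.reference)
        else:
            reference = fixtures.generate_reference(seed=config.seed)
        _stage(stage, n_records=len(reference), n_rejects=len(reference.rejects))
        paths["reference"] = str(out / "reference_standardized.csv")
        write_table(_mol_rows(reference), paths["reference"])
        paths["reference_rejects"] = str(out / "reference_rejects.csv")
        write_table(
            [{"input": s, "reason": r} for s, r in reference.rejects],
            paths["reference_rejects"],
        )

        # --- fingerprints + map ------------------------------------------
        stage = "fingerprints"
        ref_fps = compute_fingerprints(reference, config.radius, config.n_bits)
        _stage(stage, n_records=len(ref_fps), radius=config.radius, n_bits=config.n_bits)

        stage = "fit_map"
        trained = fit_map(ref_fps, config.embed_params())
        _stage(stage, n_records=len(trained.reference_ids))
        paths["map"] = str(out / "map.pkl")
        save_map(trained, paths["map"])

        stage = "embedding_quality"
        quality = embedding_quality(
            ref_fps, trained.coords, n_pairs=config.quality_pairs, seed=config.seed
        )
        _stage(stage, D=f"{quality.D:.4f}", n_pairs=quality.n_pairs)

        # --- clustering ---------------------------------------------------
        stage = "clustering"
        model = cluster_map(trained.coords, config.k, linkage=config.linkage)
        sil = silhouette_score(trained.coords, model.labels)
        _stage(stage, k=model.k, S=f"{sil.S:.4f}")
        paths["cluster_report"] = str(out / "cluster_report.csv")
        write_table(
            [
                {
                    "id": rid,
                    "x": f"{xy[0]:.6f}",
                    "y": f"{xy[1]:.6f}",
                    "cluster_index": int(lbl),
                    "cluster_name": model.names[lbl],
                }
                for rid, xy, lbl in zip(trained.reference_ids, trained.coords, model.labels)
            ],
            paths["cluster_report"],
        )
        paths["centers"] = str(out / "centers.csv")
        write_table(
            [
                {
                    "cluster_name": model.names[i],
                    "x": f"{model.centers[i, 0]:.6f}",
                    "y": f"{model.centers[i, 1]:.6f}",
                    "size": int(model.sizes[i]),
                }
                for i in range(model.k)
            ],
            paths["centers"],
        )
        scan_table = None
        if config.run_k_scan:
            stage = "k_scan"
            scan_table = scan_cluster_numbers(
                trained.coords, config.k_scan_min, config.k_scan_max, config.linkage
            )
            paths["k_scan"] = str(out / "cluster_scan.csv")
            write_table(
                [{"k": int(r.k), "S": f"{r.S:.6f}"} for r in scan_table.itertuples()],
                paths["k_scan"],
            )

        # --- candidates ---------------------------------------------------
        stage = "load_candidates"
        if config.candidates:
            candidates = read_molecules(config.candidates)
        else:
            candidates = fixtures.generate_candidates(seed=config.seed)
        _stage(stage, n_records=len(candidates), n_rejects=len(candidates.rejects))

        stage = "filter_candidates"
        surviving, reject_log = apply_filters(candidates, config.filter_spec())
        _stage(stage, n_in=len(candidates), n_kept=len(surviving), n_rejected=len(reject_log))
        paths["candidates_filtered"] = str(out / "candidates_filtered.csv")
        write_table(_mol_rows(surviving), paths["candidates_filtered"])
        paths["candidate_rejects"] = str(out / "candidate_rejects.csv")
        write_table(
            [{"input": s, "rule": "standardization", "detail": r} for s, r in candidates.rejects]
            + [
                {"input": row["candidate_id"], "rule": row["rule"], "detail": row["detail"]}
                for row in reject_log
            ],
            paths["candidate_rejects"],
        )

        # --- projection + selection ---------------------------------------
        stage = "project"
        cand_fps = (
            compute_fingerprints(surviving, config.radius, config.n_bits)
            if len(surviving)
            else None
        )
        cand_coords = (
            project(trained, cand_fps) if cand_fps is not None else np.empty((0, 2))
        )
        _stage(stage, n_records=cand_coords.shape[0])
        paths["coordinates"] = str(out / "coordinates.csv")
        write_table(
            [
                {"id": rid, "x": f"{xy[0]:.6f}", "y": f"{xy[1]:.6f}", "set": "reference"}
                for rid, xy in zip(trained.reference_ids, trained.coords)
            ]
            + [
                {"id": rec.id, "x": f"{xy[0]:.6f}", "y": f"{xy[1]:.6f}", "set": "candidate"}
                for rec, xy in zip(surviving, cand_coords)
            ],
            paths["coordinates"],
        )

        stage = "select"
        if len(surviving):
            ranked = rank_candidates(
                model.centers,
                cand_coords,
                surviving.ids,
                tiebreak_keys=surviving.smiles,
            )
            selection = select_representatives(
                ranked,
                config.selection_config(),
                surviving.ids,
                availability=[r.available is not False for r in surviving],
                cluster_names=model.names,
            )
        else:
            from .selection import ClusterSelection, SelectionResult

            selection = SelectionResult(
                per_cluster=[
                    ClusterSelection(
                        cluster_name=name, ranked=[], chosen=None,
                        warning=f"cluster {name}: no candidates survived filtering",
                    )
                    for name in model.names
                ]
            )
        for sel in selection.per_cluster:
            if sel.warning:
                log.warning("stage=select %s", sel.warning)
        _stage(stage, n_clusters=model.k, n_served=selection.n_served)
        paths["selection_report"] = str(out / "selection_report.csv")
        smiles_by_id = {r.id: r.smiles_canonical for r in surviving}
        write_table(selection.to_rows(smiles_by_id), paths["selection_report"])

        # --- manifest + plot -----------------------------------------------
        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "counts": {
                "reference": len(reference),
                "reference_rejects": len(reference.rejects),
                "candidates_in": len(candidates),
                "candidates_kept": len(surviving),
                "clusters": model.k,
                "clusters_served": selection.n_served,
            },
            "metrics": {"D": quality.D, "S": sil.S},
            "artifacts": paths,
        }
        paths["manifest"] = str(out / "manifest.json")
        Path(paths["manifest"]).write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        if config.make_plot:
            stage = "plot"
            paths["plot"] = str(out / "map_scatter.png")
            _scatter(trained.coords, cand_coords, model, paths["plot"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "reference": reference,
        "map": trained,
        "cluster_model": model,
        "quality": quality,
        "silhouette": sil,
        "candidates": surviving,
        "candidate_coords": cand_coords,
        "selection": selection,
        "k_scan": scan_table,
        "paths": paths,
    }


def _scatter(ref_coords, cand_coords, model, path) -> None:
    """Static reference + candidate scatter with labeled cluster centers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(ref_coords[:, 0], ref_coords[:, 1], s=12, c="lightsteelblue",
               label="reference", linewidths=0)
    if len(cand_coords):
        ax.scatter(cand_coords[:, 0], cand_coords[:, 1], s=12, c="darkblue",
                   label="candidates", linewidths=0)
    for i, name in enumerate(model.names):
        ax.annotate(name, model.centers[i], fontsize=11, fontweight="bold",
                    ha="center", va="center")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
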