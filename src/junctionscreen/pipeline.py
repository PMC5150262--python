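"""End-to-end pipeline orchestration with reproducible manifests.

Stages run in order — image quantification, plate Z-scoring + hit
selection, phenotypic clustering, PPI commute-kernel validation, function
enrichment — each writing its own outputs into the run directory. Any
stage can be skipped by supplying its upstream output (e.g. a wells CSV
instead of images). A manifest JSON records the full configuration, seeds
and per-stage row counts; outputs carry no timestamps, so a rerun with the
same config and seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import enrichment as _enrichment
from . import imaging as _imaging
from . import ppi as _ppi
from . import screen as _screen
from .synthetic import (
    MonolayerSpec,
    PlantedPPISpec,
    ScreenSimSpec,
    generate_annotations,
    generate_monolayer_images,
    generate_ppi_network,
    generate_screen_table,
    write_edge_list,
    write_well_images,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]

RAW_FROM_PCT = {
    "ecad_raw": "ecad_pct_area",
    "juna_raw": "juna_pct_area",
    "cyta_raw": "cyta_pct_area",
}


@dataclass
class RunConfig:
    """All paths and tunables of one pipeline run.

    Defaults equal the screen's published operating point: similarity
    bandwidth sigma=1, mutual kNN with 30 neighbours, candidate cutoff
    1.65, validation cutoff 1.0, cluster grid k=2..12, ~10,000
    randomizations, enrichment threshold 0.25, minimum confluence 90%.
    """

    outdir: str = "run"
    images_dir: str | None = None
    platemap: str | None = None
    wells: str | None = None
    edges: str | None = None
    annotations: str | None = None

    threshold_policy: str = "otsu"
    min_coverage: float = 90.0
    nucleus_min_area: int = 50

    control_role: str = "pos_ctrl"
    robust: bool = True
    cutoff: float = 1.65
    validation_cutoff: float = 1.0

    method: str = "spectral"
    distance: str = "mahalanobis"
    k: int | str = "auto"
    k_min: int = 2
    k_max: int = 12
    sigma: float = 1.0
    n_neighbors: int = 30
    laplacian: str = "sym"

    n_random: int = 10_000
    enrichment_threshold: float = 0.25
    seed: int = 0
    plots: bool = False

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the configuration has inputs for.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Raises with the stage name when a requested stage misses its input.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # --- stage 1: image quantification --------------------------------
    if config.wells:
        wells = pd.read_csv(config.wells)
        manifest["stages"]["quantify"] = {"skipped": True, "rows": len(wells)}
    elif config.images_dir and config.platemap:
        platemap = pd.read_csv(config.platemap)
        quant = _imaging.quantify_directory(
            config.images_dir,
            platemap,
            threshold_policy=config.threshold_policy,
            min_coverage=config.min_coverage,
            nucleus_min_area=config.nucleus_min_area,
        )
        wells = quant.copy()
        for raw, pct in RAW_FROM_PCT.items():
            wells[raw] = wells.get(pct)
        n = _write_csv(wells, outdir / "wells.csv")
        manifest["stages"]["quantify"] = {"skipped": False, "rows": n}
    else:
        raise ValueError(
            "stage 'quantify': supply either wells= or images_dir= + platemap="
        )

    # --- stage 2: Z-scores, candidates, screen statistics -------------
    zscores = _screen.plate_zscores(
        wells, control_role=config.control_role, robust=config.robust
    )
    agg, rejects = _screen.aggregate_and_select(zscores, cutoff=config.cutoff)
    corr = _screen.correlate_parameters(agg)
    _write_csv(zscores, outdir / "zscores.csv")
    _write_csv(agg, outdir / "aggregate.csv")
    _write_csv(rejects, outdir / "rejects.csv")
    _write_csv(corr, outdir / "correlations.csv")
    candidates = agg[agg["candidate"]].reset_index(drop=True)
    _write_csv(candidates, outdir / "candidates.csv")
    manifest["stages"]["score"] = {
        "rows": len(agg),
        "n_candidates": int(len(candidates)),
        "n_rejected": int(len(rejects)),
        "normalization": "robust" if config.robust else "moment",
        "cutoff": config.cutoff,
    }

    # --- stage 3: phenotypic clustering -------------------------------
    zcols = ["median_z_ecad", "median_z_juna", "median_z_cyta"]
    X = candidates[zcols].to_numpy(float)
    labels_df = None
    if len(candidates) >= max(4, config.k_min + 1):
        if config.k == "auto":
            selector = _cluster.ClusterGridSelector(
                methods=(config.method,),
                metrics=(config.distance,),
                k_values=tuple(
                    k for k in range(config.k_min, config.k_max + 1) if k <= len(X)
                ),
                sigma=config.sigma,
                n_neighbors=config.n_neighbors,
                laplacian=config.laplacian,
                random_state=config.seed,
            ).fit(X)
            model = selector.best_model_
            _write_csv(selector.report_, outdir / "cluster_grid.csv")
            manifest["stages"]["cluster"] = {"selected": selector.best_params_}
        else:
            model = _cluster.PhenotypeClustering(
                method=config.method,
                metric=config.distance,
                n_clusters=int(config.k),
                sigma=config.sigma,
                n_neighbors=config.n_neighbors,
                laplacian=config.laplacian,
                random_state=config.seed,
            ).fit(X)
            manifest["stages"]["cluster"] = {
                "selected": {
                    "method": config.method,
                    "metric": config.distance,
                    "k": int(config.k),
                }
            }
        labels_df = pd.DataFrame(
            {"gene": candidates["gene"], "cluster": model.labels_}
        )
        sil = pd.DataFrame(
            {
                "gene": candidates["gene"],
                "cluster": model.labels_,
                "silhouette": model.silhouette_values_,
            }
        )
        _write_csv(labels_df, outdir / "clusters.csv")
        _write_csv(sil, outdir / "silhouette.csv")
        manifest["stages"]["cluster"].update(
            rows=len(labels_df),
            n_negative_silhouette=model.n_negative_silhouette_,
            mean_silhouette=float(model.mean_silhouette_),
        )
        if config.plots:
            _diagnostic_plots(candidates, model, outdir)
    else:
        manifest["stages"]["cluster"] = {"skipped": True, "reason": "too few candidates"}

    # --- stage 4: PPI commute-kernel validation -----------------------
    if config.edges and labels_df is not None:
        from .synthetic.ppi import read_edge_list

        edges = read_edge_list(config.edges)
        partition = dict(zip(labels_df["gene"], labels_df["cluster"]))
        test = _ppi.CKMaxTest(
            n_random=config.n_random, random_state=config.seed
        ).fit(edges, partition)
        result = {
            "observed_ck_max": test.observed_score_,
            "empirical_p": test.p_value_,
            "n_random": config.n_random,
            "seed": config.seed,
            "coverage": test.coverage_,
        }
        (outdir / "ppi_result.json").write_text(json.dumps(result, indent=2, sort_keys=True))
        _write_csv(test.density_, outdir / "ppi_null_density.csv")
        manifest["stages"]["ppi"] = result
    else:
        manifest["stages"]["ppi"] = {"skipped": True}

    # --- stage 5: function enrichment ---------------------------------
    if config.annotations and labels_df is not None:
        ann = pd.read_csv(config.annotations)
        profile = _enrichment.compute_enrichment(ann, labels_df)
        long = profile.to_long(threshold=config.enrichment_threshold)
        _write_csv(long, outdir / "enrichment.csv")
        dendro = _enrichment.cluster_enrichment_profile(profile)
        (outdir / "enrichment_dendrograms.json").write_text(
            json.dumps(dendro, indent=2, sort_keys=True)
        )
        manifest["stages"]["enrich"] = {
            "rows": len(long),
            "n_enriched": int(long["enriched"].sum()),
            "threshold": config.enrichment_threshold,
            "coverage": profile.coverage,
        }
        if config.plots:
            _enrichment.plot_enrichment_heatmap(
                profile, outdir / "enrichment_heatmap.png", config.enrichment_threshold
            )
    else:
        manifest["stages"]["enrich"] = {"skipped": True}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")
    return manifest


def _diagnostic_plots(candidates: pd.DataFrame, model, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zcols = ["median_z_ecad", "median_z_juna", "median_z_cyta"]
    X = candidates[zcols].to_numpy(float)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(X[:, 0], X[:, 1], X[:, 2], c=model.labels_, cmap="tab10", s=15)
    ax.set_xlabel("E-cad Z")
    ax.set_ylabel("Jun-A Z")
    ax.set_zlabel("Cyt-A Z")
    fig.colorbar(sc, ax=ax, shrink=0.6, label="cluster")
    fig.savefig(outdir / "clusters_3d.png", dpi=150)
    plt.close(fig)

    s = model.silhouette_values_
    order = np.lexsort((-s, model.labels_))
    fig, ax = plt.subplots(figsize=(5, 6))
    ax.barh(
        np.arange(len(s)),
        s[order],
        color=plt.cm.tab10(model.labels_[order] % 10),
        height=1.0,
    )
    ax.set_xlabel("silhouette value")
    ax.set_ylabel("candidates (grouped by cluster)")
    fig.tight_layout()
    fig.savefig(outdir / "silhouette.png", dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------

TINY_CENTERS = ((4.0, 4.0, 0.0), (-4.0, -4.0, 0.0), (4.0, -4.0, 4.0), (-4.0, 4.0, -4.0))


def _level_spec(z: np.ndarray, seed: int, field_size=(192, 192), n_cells=36) -> MonolayerSpec:
    """Map a well's Z triple onto junction geometry/intensity parameters."""
    return MonolayerSpec(
        field_size=field_size,
        n_cells=n_cells,
        junction_coverage=float(np.clip(0.75 + 0.05 * z[0], 0.05, 1.0)),
        actin_junction_coverage=float(np.clip(0.75 + 0.05 * z[1], 0.05, 1.0)),
        cytoplasmic_actin_level=float(np.clip(0.3 + 0.03 * z[2], 0.05, 0.6)),
        seed=seed,
    )


def make_fixtures(preset: str, outdir: str | Path, seed: int = 0) -> dict:
    """Write a synthetic dataset for one of the named presets.

    * ``tiny`` — 24 genes, 2 plates, 3 replicates, 4 planted clusters,
      rendered well images + platemap, PPI edges and annotations: the full
      pipeline exercised end to end at minimal cost.
    * ``screen156`` — measurement tables at the screen's published scale:
      156 candidates, 9 planted clusters, 3 replicates (no images).
    * ``ppi_planted`` — 156 proteins in 9 blocks with a planted-partition
      interaction network only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    info: dict = {"preset": preset, "seed": seed}

    if preset == "tiny":
        spec = ScreenSimSpec(
            n_genes=24,
            n_plates=2,
            replicates=3,
            controls_per_plate=4,
            cluster_centers=TINY_CENTERS,
            within_cluster_sd=0.5,
            seed=seed,
        )
        table, labels = generate_screen_table(spec)
        platemap = table[["plate", "well", "gene", "oligo", "role", "replicate"]]
        truth = dict(
            zip(labels["gene"], labels[["z_ecad_true", "z_juna_true", "z_cyta_true"]].to_numpy())
        )
        images_dir = outdir / "images"
        rng_base = np.random.SeedSequence(seed)
        children = rng_base.spawn(len(platemap))
        for i, rec in enumerate(platemap.to_dict("records")):
            role = rec["role"]
            if role == "sample":
                z = truth[rec["gene"]]
            elif role == "pos_ctrl":
                z = np.zeros(3)
            else:  # neg_ctrl: junctions not induced
                z = np.array([-12.0, -12.0, 0.0])
            wspec = _level_spec(np.asarray(z, float), seed=int(children[i].generate_state(1)[0] % (2**31)))
            # plate ids must be unique per replicate on disk
            plate_id = f"{rec['plate']}r{rec['replicate']}"
            images, _ = generate_monolayer_images(wspec, plate=plate_id, well=rec["well"])
            write_well_images(images, images_dir)
        pm = platemap.copy()
        pm["plate"] = pm["plate"] + "r" + pm["replicate"].astype(str)
        pm.to_csv(outdir / "platemap.csv", index=False)
        labels.to_csv(outdir / "labels.csv", index=False)
        membership = dict(zip(labels["gene"], labels["cluster"]))
        edges = generate_ppi_network(
            PlantedPPISpec(membership=membership, p_within=0.5, p_between=0.02, n_background_nodes=10, seed=seed)
        )
        write_edge_list(edges, outdir / "edges.tsv")
        vocab = _enrichment.load_function_vocabulary()
        ann = generate_annotations(
            list(labels["gene"]),
            planted_class_per_cluster={i: vocab[i] for i in range(len(TINY_CENTERS))},
            cluster_of=membership,
            seed=seed,
        )
        ann.to_csv(outdir / "annotations.csv", index=False)
        info.update(n_genes=24, n_wells=len(platemap), n_clusters=len(TINY_CENTERS))

    elif preset == "screen156":
        spec = ScreenSimSpec(seed=seed)
        table, labels = generate_screen_table(spec)
        table.to_csv(outdir / "wells.csv", index=False)
        labels.to_csv(outdir / "labels.csv", index=False)
        membership = dict(zip(labels["gene"], labels["cluster"]))
        edges = generate_ppi_network(
            PlantedPPISpec(membership=membership, p_within=0.3, p_between=0.01, n_background_nodes=100, seed=seed)
        )
        write_edge_list(edges, outdir / "edges.tsv")
        vocab = _enrichment.load_function_vocabulary()
        ann = generate_annotations(
            list(labels["gene"]),
            planted_class_per_cluster={i: vocab[i % len(vocab)] for i in range(9)},
            cluster_of=membership,
            seed=seed,
        )
        ann.to_csv(outdir / "annotations.csv", index=False)
        info.update(n_genes=spec.n_genes, n_clusters=len(spec.cluster_centers))

    elif preset == "ppi_planted":
        genes = [f"GENE{i:04d}" for i in range(156)]
        sizes = [18, 18, 18, 17, 17, 17, 17, 17, 17]
        membership = dict(zip(genes, np.repeat(np.arange(9), sizes)))
        edges = generate_ppi_network(
            PlantedPPISpec(membership=membership, p_within=0.3, p_between=0.01, seed=seed)
        )
        write_edge_list(edges, outdir / "edges.tsv")
        pd.DataFrame(
            {"gene": genes, "cluster": [membership[g] for g in genes]}
        ).to_csv(outdir / "labels.csv", index=False)
        info.update(n_genes=156, n_clusters=9)
    else:
        raise ValueError(f"unknown preset: {preset!r}")

    (outdir / "fixture_info.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return info
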