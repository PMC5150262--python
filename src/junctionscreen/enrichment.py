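"""Per-cluster enrichment of curated actin-remodelling functions.

Each candidate gene carries one or more manually curated actin-function
classes from a fixed 13-name vocabulary. For every (function, cluster)
cell two shares are computed:

* ``share_of_class`` — genes in the cluster carrying the function, divided
  by all annotated genes carrying it anywhere (the grey-bar layer);
* ``share_of_cluster`` — annotation instances of the function within the
  cluster, divided by all annotation instances in the cluster (the
  yellow-bar layer; a multi-function gene counts once per function).

A cell is flagged enriched when share_of_class >= 0.25 (inclusive). The
cross-cluster structure of the enrichment matrix is summarized by
agglomerative clustering of its rows (functions) and columns (clusters)
for heat-map rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

__all__ = [
    "load_function_vocabulary",
    "EnrichmentProfile",
    "compute_enrichment",
    "flag_enriched",
    "cluster_enrichment_profile",
    "plot_enrichment_heatmap",
]


def load_function_vocabulary() -> list[str]:
    """The 13 curated actin-function class names (user-replaceable data)."""
    text = resources.files("junctionscreen.data").joinpath("actin_functions.yaml").read_text()
    return list(yaml.safe_load(text)["functions"])


@dataclass
class EnrichmentProfile:
    share_of_class: pd.DataFrame  # functions x clusters
    share_of_cluster: pd.DataFrame  # functions x clusters
    counts: pd.DataFrame  # raw gene counts per (function, cluster)
    class_totals: pd.Series  # annotated genes per function
    cluster_annotation_totals: pd.Series  # annotation instances per cluster
    coverage: dict = field(default_factory=dict)

    def to_long(self, threshold: float = 0.25) -> pd.DataFrame:
        flags = flag_enriched(self, threshold)
        rows = []
        for f in self.share_of_class.index:
            for c in self.share_of_class.columns:
                rows.append(
                    {
                        "cluster": c,
                        "function": f,
                        "share_of_class": self.share_of_class.loc[f, c],
                        "share_of_cluster": self.share_of_cluster.loc[f, c],
                        "enriched": bool(flags.loc[f, c]),
                    }
                )
        return pd.DataFrame(rows)


def compute_enrichment(
    annotations: pd.DataFrame, labels: pd.DataFrame | Mapping
) -> EnrichmentProfile:
    """Both enrichment layers for every function x cluster cell.

    ``annotations``: (gene, function) rows, possibly several per gene.
    ``labels``: (gene, cluster) table or mapping. Unannotated genes are
    excluded from denominators and counted in the coverage report;
    annotated genes without a cluster stay in class totals (so a column's
    shares sum to 1 only when every annotated gene is clustered).
    """
    if annotations is None or len(annotations) == 0:
        raise ValueError("empty annotation table")
    ann = annotations[["gene", "function"]].drop_duplicates()
    vocab = load_function_vocabulary()
    unknown = set(ann["function"]) - set(vocab)
    if unknown:
        raise ValueError(f"unknown function classes: {sorted(unknown)}")

    if isinstance(labels, pd.DataFrame):
        cluster_of = dict(zip(labels["gene"], labels["cluster"]))
    else:
        cluster_of = dict(labels)
    clusters = sorted(set(cluster_of.values()), key=str)

    class_totals = ann.groupby("function")["gene"].nunique()
    class_totals = class_totals.reindex(vocab, fill_value=0)

    ann = ann.assign(cluster=ann["gene"].map(cluster_of))
    in_cluster = ann.dropna(subset=["cluster"])

    counts = (
        in_cluster.groupby(["function", "cluster"])["gene"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(index=vocab, columns=clusters, fill_value=0)
    )
    inst = (
        in_cluster.groupby(["function", "cluster"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=vocab, columns=clusters, fill_value=0)
    )
    cluster_annotation_totals = inst.sum(axis=0)

    denom_class = class_totals.replace(0, np.nan)
    share_of_class = counts.div(denom_class, axis=0).fillna(0.0)
    denom_cluster = cluster_annotation_totals.replace(0, np.nan)
    share_of_cluster = inst.div(denom_cluster, axis=1).fillna(0.0)

    clustered_genes = set(cluster_of)
    annotated_genes = set(annotations["gene"])
    coverage = {
        "n_clustered_genes": len(clustered_genes),
        "n_annotated_genes": len(annotated_genes),
        "n_clustered_unannotated": len(clustered_genes - annotated_genes),
        "n_annotated_unclustered": len(annotated_genes - clustered_genes),
    }
    return EnrichmentProfile(
        share_of_class=share_of_class,
        share_of_cluster=share_of_cluster,
        counts=counts,
        class_totals=class_totals,
        cluster_annotation_totals=cluster_annotation_totals,
        coverage=coverage,
    )


def flag_enriched(profile: EnrichmentProfile, threshold: float = 0.25) -> pd.DataFrame:
    """Enriched iff share_of_class >= threshold (inclusive) and non-empty."""
    return (profile.share_of_class >= threshold) & (profile.counts > 0)


def cluster_enrichment_profile(
    profile: EnrichmentProfile, linkage: str = "average"
) -> dict:
    """Agglomerative ordering of functions and clusters for the heat map.

    Returns linkage matrices and leaf orders for rows (functions) and
    columns (clusters) of the share_of_class matrix. Deterministic given
    the input ordering.
    """
    M = profile.share_of_class.to_numpy(dtype=float)

    def _tree(data: np.ndarray, names: list) -> dict:
        if data.shape[0] < 2:
            return {"linkage": None, "leaves": list(names)}
        Z = scipy_linkage(pdist(data), method=linkage)
        order = leaves_list(Z)
        return {"linkage": Z.tolist(), "leaves": [names[i] for i in order]}

    return {
        "functions": _tree(M, list(profile.share_of_class.index)),
        "clusters": _tree(M.T, list(profile.share_of_class.columns)),
    }


def plot_enrichment_heatmap(profile: EnrichmentProfile, path=None, threshold: float = 0.25):
    """Heat map of share_of_class with enriched cells outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cluster_enrichment_profile(profile)
    M = profile.share_of_class.loc[order["functions"]["leaves"], order["clusters"]["leaves"]]
    flags = flag_enriched(profile, threshold).loc[M.index, M.columns]
    fig, ax = plt.subplots(figsize=(1 + 0.6 * M.shape[1], 1 + 0.4 * M.shape[0]))
    im = ax.imshow(M.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(M.shape[1]), [str(c) for c in M.columns], rotation=90)
    ax.set_yticks(range(M.shape[0]), list(M.index))
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            if flags.iat[i, j]:
                ax.add_patch(
                    plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, ec="red", lw=1.5)
                )
    fig.colorbar(im, ax=ax, label="share of class")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
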