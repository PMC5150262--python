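"""Simulated RNAi-screen measurement tables with planted phenotype clusters.

Emulates the structure the normalization and clustering stages assume: wells
on plates, untransfected positive controls (junctions induced) and
no-junction negative controls on every plate, replicate experiments, an
additive per-plate shift, and gene effects planted as 3-vectors
(E-cad, Jun-A, Cyt-A) in control-referenced Z units.

Each plate's positive-control draws are standardized to exact sample
mean/SD before scaling, so moment-mode Z-scoring recovers the planted
centers *exactly* in the noiseless limit — which makes hit-selection
consistency checkable without tolerance games.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenSimSpec", "generate_screen_table", "DEFAULT_CLUSTER_CENTERS"]

PARAMS = ("ecad", "juna", "cyta")

#: Nine planted phenotype centers in Z space at moderate separation
#: (pairwise distance >= 4 control SDs; the screen's candidate clusters).
DEFAULT_CLUSTER_CENTERS = (
    (4.0, 4.0, 0.0),
    (-4.0, -4.0, 0.0),
    (4.0, -4.0, 0.0),
    (-4.0, 4.0, 0.0),
    (0.0, 0.0, 4.0),
    (0.0, 0.0, -4.0),
    (4.0, 0.0, -4.0),
    (-4.0, 0.0, 4.0),
    (0.0, 4.0, 4.0),
)


def _default_sizes(n_genes: int, n_clusters: int) -> tuple[int, ...]:
    base = n_genes // n_clusters
    rem = n_genes - base * n_clusters
    return tuple(base + (1 if i < rem else 0) for i in range(n_clusters))


@dataclass(frozen=True)
class ScreenSimSpec:
    n_genes: int = 156
    n_plates: int = 2
    replicates: int = 3
    controls_per_plate: int = 8
    cluster_centers: tuple = DEFAULT_CLUSTER_CENTERS
    cluster_sizes: tuple | None = None
    within_cluster_sd: float = 0.5
    plate_shift: float = 0.0
    control_baseline: tuple = (50.0, 40.0, 30.0)
    control_sd: tuple = (10.0, 8.0, 6.0)
    seed: int = 0

    def resolved_sizes(self) -> tuple[int, ...]:
        if self.cluster_sizes is not None:
            return tuple(self.cluster_sizes)
        return _default_sizes(self.n_genes, len(self.cluster_centers))

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_genes < 1 or self.n_plates < 1:
            raise ValueError("n_genes and n_plates must be positive")
        if self.controls_per_plate < 2:
            raise ValueError("need >= 2 control wells per plate for Z-scoring")
        if self.within_cluster_sd < 0:
            raise ValueError("within_cluster_sd must be >= 0")
        sizes = self.resolved_sizes()
        if sum(sizes) != self.n_genes:
            raise ValueError("cluster_sizes must sum to n_genes")
        if len(sizes) != len(self.cluster_centers):
            raise ValueError("one size per cluster center required")


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    names, i = [], 0
    while len(names) < n:
        names.append(f"{rows[i // 24 % 16]}{i % 24 + 1:02d}")
        i += 1
    return names


def _standardized(draws: np.ndarray) -> np.ndarray:
    """Rescale draws to exact sample mean 0 / SD 1 (ddof=0)."""
    mu = draws.mean()
    sd = draws.std()
    if sd == 0:
        return np.zeros_like(draws)
    return (draws - mu) / sd


def generate_screen_table(
    spec: ScreenSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a primary screen.

    Returns
    -------
    table : DataFrame
        Columns plate, well, gene, oligo, role, replicate, qc_pass,
        ecad_raw, juna_raw, cyta_raw — one row per well per replicate.
    labels : DataFrame
        Ground truth: gene, cluster and the planted Z center per parameter.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.resolved_sizes()
    centers = np.asarray(spec.cluster_centers, dtype=float)

    genes = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    gene_cluster = np.repeat(np.arange(len(sizes)), sizes)
    gene_center = centers[gene_cluster]

    labels = pd.DataFrame(
        {
            "gene": genes,
            "cluster": gene_cluster,
            "z_ecad_true": gene_center[:, 0],
            "z_juna_true": gene_center[:, 1],
            "z_cyta_true": gene_center[:, 2],
        }
    )

    # round-robin chunks of genes per plate
    per_plate = int(np.ceil(spec.n_genes / spec.n_plates))
    baseline = np.asarray(spec.control_baseline)
    csd = np.asarray(spec.control_sd)

    rows = []
    for rep in range(1, spec.replicates + 1):
        for p in range(spec.n_plates):
            plate = f"P{p + 1:02d}"
            shift = spec.plate_shift * p
            plate_genes = genes[p * per_plate : (p + 1) * per_plate]
            idx = slice(p * per_plate, p * per_plate + len(plate_genes))
            n_wells = len(plate_genes) + 2 * spec.controls_per_plate
            wells = _well_names(n_wells)
            w = 0
            # positive controls: exact mean/SD after standardization
            pos = np.column_stack(
                [
                    _standardized(rng.standard_normal(spec.controls_per_plate))
                    for _ in PARAMS
                ]
            )
            for i in range(spec.controls_per_plate):
                vals = baseline + shift + pos[i] * csd
                rows.append((plate, wells[w], "POS_CTRL", "none", "pos_ctrl", rep, True, *vals))
                w += 1
            for i in range(spec.controls_per_plate):
                vals = (
                    baseline
                    + shift
                    - 3.0 * csd
                    + rng.standard_normal(3) * csd * min(spec.within_cluster_sd, 1.0)
                )
                rows.append((plate, wells[w], "NEG_CTRL", "none", "neg_ctrl", rep, True, *vals))
                w += 1
            noise = rng.standard_normal((len(plate_genes), 3)) * spec.within_cluster_sd
            for j, gene in enumerate(plate_genes):
                z = gene_center[idx][j] + noise[j]
                vals = baseline + shift + z * csd
                rows.append((plate, wells[w], gene, "pool", "sample", rep, True, *vals))
                w += 1

    table = pd.DataFrame(
        rows,
        columns=[
            "plate",
            "well",
            "gene",
            "oligo",
            "role",
            "replicate",
            "qc_pass",
            "ecad_raw",
            "juna_raw",
            "cyta_raw",
        ],
    )
    return table, labels
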