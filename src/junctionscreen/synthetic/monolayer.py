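"""Synthetic confluent-monolayer fluorescence images with ground truth.

Renders the three channels an epithelial junction screen acquires per well:
an adhesion-receptor channel (E-cadherin) concentrated in a thin ribbon
along cell-cell boundaries, an F-actin channel split between that junctional
ribbon and a diffuse cytoplasmic pool, and a DNA channel with one nuclear
ellipse per cell. Cells are a Voronoi tessellation of uniformly sampled
seed points; deleting a fraction of cells opens monolayer holes so the
confluence QC has something to reject.

Every generator is deterministic under a fixed seed (bit-identical arrays
and TIFF bytes), and every image ships with the masks it was rendered from,
so segmentation accuracy is checkable against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk

__all__ = [
    "MonolayerSpec",
    "WellImageSet",
    "MonolayerGroundTruth",
    "generate_monolayer_images",
    "write_well_images",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("ecad", "actin", "dna")


@dataclass(frozen=True)
class MonolayerSpec:
    """Parameters of one simulated well/field.

    Intensity ``*_level`` values are relative (0-1) and are mapped onto the
    lower half of the integer range of ``bit_depth`` so additive noise never
    saturates. ``junction_coverage`` / ``actin_junction_coverage`` give the
    fraction of cell-cell boundary segments that actually carry signal,
    emulating incomplete junction assembly (the screen's phenotype axis):
    percent-thresholded-area readouts respond to geometry, not brightness.

    ``gap_fraction`` is the fraction of monolayer area opened as holes:
    whole cells are deleted until the removed area reaches it, and cells at
    the resulting free edges retract by ``gap_margin`` pixels.
    """

    field_size: tuple[int, int] = (512, 512)
    n_cells: int = 64
    junctional_ecad_level: float = 0.8
    cytoplasmic_ecad_level: float = 0.1
    junctional_actin_level: float = 0.7
    cytoplasmic_actin_level: float = 0.3
    gap_fraction: float = 0.0
    junction_coverage: float = 1.0
    actin_junction_coverage: float = 1.0
    noise_sd: float = 150.0
    bit_depth: int = 16
    ribbon_width: int = 3
    gap_margin: int = 3
    seed: int = 0

    def validate(self) -> None:
        levels = (
            self.junctional_ecad_level,
            self.cytoplasmic_ecad_level,
            self.junctional_actin_level,
            self.cytoplasmic_actin_level,
        )
        if any(not (0.0 <= v <= 1.0) for v in levels):
            raise ValueError("all intensity levels must lie in [0, 1]")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must lie in [0, 1)")
        for name in ("junction_coverage", "actin_junction_coverage"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_cells < 4:
            raise ValueError(
                "n_cells must be >= 4: a Voronoi tessellation with fewer "
                "seeds is degenerate"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class WellImageSet:
    """The three registered channel images of one well/field."""

    ecad: np.ndarray
    actin: np.ndarray
    dna: np.ndarray
    plate: str = "P01"
    well: str = "A01"

    def channels(self):
        return dict(zip(CHANNEL_NAMES, (self.ecad, self.actin, self.dna)))


@dataclass
class MonolayerGroundTruth:
    junction_mask: np.ndarray  # ribbon pixels carrying junctional signal
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray  # kept (non-gap) monolayer area
    n_cells: int
    junctional_fraction: float  # fraction of field covered by the ribbon

    def to_json_dict(self) -> dict:
        return {
            "n_cells": int(self.n_cells),
            "junctional_fraction": float(self.junctional_fraction),
            "cell_area_fraction": float(self.cell_mask.mean()),
        }


def _boundary_between_kept_cells(labels: np.ndarray, kept: np.ndarray) -> np.ndarray:
    """Pixels adjacent (4-connectivity) to a *different kept* cell.

    Edges facing a monolayer gap are free edges, not junctions, and are
    excluded by requiring both sides of the label change to be kept.
    """
    bnd = np.zeros(labels.shape, dtype=bool)
    d = (labels[:-1, :] != labels[1:, :]) & kept[:-1, :] & kept[1:, :]
    bnd[:-1, :] |= d
    bnd[1:, :] |= d
    d = (labels[:, :-1] != labels[:, 1:]) & kept[:, :-1] & kept[:, 1:]
    bnd[:, :-1] |= d
    bnd[:, 1:] |= d
    return bnd


def _segment_ids(labels: np.ndarray) -> np.ndarray:
    """Unordered cell-pair id for each boundary pixel (0 elsewhere).

    Used to drop whole boundary *segments* when junction_coverage < 1, so
    missing junctions look like missing cell-cell contacts rather than
    salt-and-pepper dropout.
    """
    n = int(labels.max()) + 2
    pair = np.zeros(labels.shape, dtype=np.int64)

    def assign(sl_a, sl_b):
        a, b = labels[sl_a], labels[sl_b]
        differs = a != b
        code = np.minimum(a, b) * n + np.maximum(a, b)
        for sl in (sl_a, sl_b):
            view = pair[sl]
            view[differs & (view == 0)] = code[differs & (view == 0)]

    assign(np.s_[:-1, :], np.s_[1:, :])
    assign(np.s_[:, :-1], np.s_[:, 1:])
    return pair


def generate_monolayer_images(
    spec: MonolayerSpec, plate: str = "P01", well: str = "A01"
) -> tuple[WellImageSet, MonolayerGroundTruth]:
    """Render one synthetic well and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    yy, xx = np.mgrid[0:h, 0:w]

    seeds = np.column_stack(
        [rng.uniform(0, h, spec.n_cells), rng.uniform(0, w, spec.n_cells)]
    )
    pix = np.column_stack([yy.ravel(), xx.ravel()])

    # Lloyd relaxation: epithelial monolayers are near-centroidal, and
    # relaxed seeds keep nuclei of adjacent cells from overlapping.
    labels = None
    for _ in range(2):
        _, labels = cKDTree(seeds).query(pix, k=1)
        counts = np.bincount(labels, minlength=spec.n_cells).astype(float)
        cy = np.bincount(labels, weights=pix[:, 0], minlength=spec.n_cells)
        cx = np.bincount(labels, weights=pix[:, 1], minlength=spec.n_cells)
        nonempty = counts > 0
        seeds[nonempty, 0] = cy[nonempty] / counts[nonempty]
        seeds[nonempty, 1] = cx[nonempty] / counts[nonempty]
    _, labels = cKDTree(seeds).query(pix, k=1)
    labels = labels.reshape(h, w).astype(np.int64) + 1  # 1-based cell ids

    # gap_fraction is the fraction of monolayer *area* opened: whole cells
    # are deleted in random order until the removed area reaches it. (The
    # confluence QC is area-based, so area is the meaningful unit.)
    gap_ids = []
    if spec.gap_fraction > 0:
        order = rng.permutation(spec.n_cells) + 1
        areas = np.bincount(labels.ravel(), minlength=spec.n_cells + 1)
        removed = 0
        for cid in order:
            gap_ids.append(int(cid))
            removed += int(areas[cid])
            if removed >= spec.gap_fraction * h * w:
                break
    n_gap = len(gap_ids)
    if n_gap:
        gap_region = np.isin(labels, gap_ids)
        if spec.gap_margin > 0:
            # cells retract at free edges: widen the hole slightly
            gap_region = dilation(gap_region, disk(spec.gap_margin))
        kept = ~gap_region
    else:
        kept = np.ones((h, w), dtype=bool)

    boundary = _boundary_between_kept_cells(labels, kept)

    # Drop whole cell-pair boundary segments for incomplete junction assembly.
    seg = _segment_ids(labels)
    seg_ids = np.unique(seg[boundary])
    keep_ecad = rng.random(seg_ids.size) < spec.junction_coverage
    keep_actin = rng.random(seg_ids.size) < spec.actin_junction_coverage
    ecad_segs = set(seg_ids[keep_ecad].tolist())
    actin_segs = set(seg_ids[keep_actin & keep_ecad].tolist())

    radius = max((spec.ribbon_width - 1) // 2, 0)
    footprint = disk(radius) if radius else None

    def ribbon(selected: set) -> np.ndarray:
        m = boundary & np.isin(seg, list(selected))
        if footprint is not None and m.any():
            m = dilation(m, footprint)
        return m & kept

    ecad_ribbon = ribbon(ecad_segs) if ecad_segs else np.zeros((h, w), bool)
    actin_ribbon = ribbon(actin_segs) if actin_segs else np.zeros((h, w), bool)

    # Nuclei: one ellipse per kept cell, centred at the Voronoi seed.
    cell_radius = np.sqrt(h * w / spec.n_cells / np.pi)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    kept_cells = 0
    for cid in range(1, spec.n_cells + 1):
        # draw from rng unconditionally to keep the stream aligned across
        # gap_fraction values of the same seed
        a = rng.uniform(0.26, 0.36) * cell_radius
        b = rng.uniform(0.18, 0.26) * cell_radius
        theta = rng.uniform(0, np.pi)
        if cid in gap_ids:
            continue
        r0, c0 = seeds[cid - 1]
        if not kept[int(min(r0, h - 1)), int(min(c0, w - 1))]:
            continue
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        nucleus_mask[rr, cc] = True
        kept_cells += 1

    amp = float(2 ** (spec.bit_depth - 1))
    base = 0.01 * amp

    ecad = np.full((h, w), base)
    ecad += kept * (spec.cytoplasmic_ecad_level * amp)
    ecad += ecad_ribbon * (spec.junctional_ecad_level * amp)

    smooth = gaussian_filter(rng.standard_normal((h, w)), sigma=8)
    rngspan = np.ptp(smooth)
    smooth = (smooth - smooth.min()) / rngspan if rngspan > 0 else np.zeros_like(smooth)
    cyt_field = spec.cytoplasmic_actin_level * amp * (0.6 + 0.4 * smooth)
    actin = np.full((h, w), base)
    actin += kept * cyt_field
    actin += actin_ribbon * (spec.junctional_actin_level * amp)

    dna = np.full((h, w), base)
    dna += nucleus_mask * (0.8 * amp)

    vmax = float(2**spec.bit_depth - 1)
    dtype = np.uint16 if spec.bit_depth == 16 else np.uint8
    out = []
    for img in (ecad, actin, dna):
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
        out.append(np.clip(np.rint(img), 0, vmax).astype(dtype))

    images = WellImageSet(ecad=out[0], actin=out[1], dna=out[2], plate=plate, well=well)
    truth = MonolayerGroundTruth(
        junction_mask=ecad_ribbon,
        nucleus_mask=nucleus_mask,
        cell_mask=kept,
        n_cells=kept_cells,
        junctional_fraction=float(ecad_ribbon.mean()),
    )
    return images, truth


def write_well_images(
    images: WellImageSet,
    outdir: str | Path,
    truth: MonolayerGroundTruth | None = None,
    spec: MonolayerSpec | None = None,
) -> list[Path]:
    """Write per-channel 16-bit TIFFs named {plate}_{well}_{channel}.tif.

    Ground truth, when given, is written as PNG masks plus a JSON sidecar.
    """
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, img in images.channels().items():
        path = outdir / f"{images.plate}_{images.well}_{name}.tif"
        tifffile.imwrite(path, img, photometric="minisblack")
        written.append(path)
    if truth is not None:
        stem = f"{images.plate}_{images.well}"
        for name, mask in (
            ("junction_mask", truth.junction_mask),
            ("nucleus_mask", truth.nucleus_mask),
            ("cell_mask", truth.cell_mask),
        ):
            path = outdir / f"{stem}_{name}.png"
            iio.imwrite(path, (mask.astype(np.uint8) * 255))
            written.append(path)
        sidecar = truth.to_json_dict()
        if spec is not None:
            sidecar["spec"] = asdict(spec)
        path = outdir / f"{stem}_truth.json"
        path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        written.append(path)
    return written
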