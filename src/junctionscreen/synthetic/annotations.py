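"""Synthetic gene -> actin-function annotation tables.

Genes draw functions from the fixed curated vocabulary; clusters can be
given a planted over-represented class at a configurable rate so the
enrichment stage has a recoverable signal (rate 1.0 drives the planted
class to a 100% share within its cluster; rate equal to background leaves
nothing to find).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..enrichment import load_function_vocabulary

__all__ = ["generate_annotations"]


def generate_annotations(
    genes: Sequence[str],
    n_classes: int = 13,
    planted_class_per_cluster: Mapping[int, str] | None = None,
    cluster_of: Mapping[str, int] | None = None,
    planted_rate: float = 0.8,
    extra_function_prob: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a (gene, function) table; each gene carries >= 1 function."""
    vocab = load_function_vocabulary()[:n_classes]
    planted = dict(planted_class_per_cluster or {})
    for cls in planted.values():
        if cls not in vocab:
            raise ValueError(f"unknown function class: {cls!r}")
    if planted and cluster_of is None:
        raise ValueError("cluster_of is required when planting classes")

    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        cluster = cluster_of.get(gene) if cluster_of else None
        target = planted.get(cluster) if cluster is not None else None
        if target is not None and rng.random() < planted_rate:
            first = target
        else:
            first = vocab[rng.integers(len(vocab))]
        funcs = {first}
        while rng.random() < extra_function_prob:
            funcs.add(vocab[rng.integers(len(vocab))])
        rows.extend((gene, f) for f in sorted(funcs))
    return pd.DataFrame(rows, columns=["gene", "function"])
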