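"""Planted-partition protein-interaction networks.

A stochastic block model over candidate proteins: edges appear with
probability ``p_within`` inside a phenotype block and ``p_between`` across
blocks, plus optional background "neighbour" proteins attached uniformly at
random. When ``p_within > p_between`` the planted blocks are genuinely
closer in interaction space, which is what the commute-kernel coherence
test is supposed to detect; with ``p_within == p_between`` the network
carries no block signal and the test must calibrate to uniform p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["PlantedPPISpec", "generate_ppi_network", "write_edge_list", "read_edge_list"]


@dataclass(frozen=True)
class PlantedPPISpec:
    membership: Mapping[str, int] = field(default_factory=dict)
    p_within: float = 0.3
    p_between: float = 0.01
    n_background_nodes: int = 0
    background_degree: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not self.membership:
            raise ValueError("membership must map at least one gene to a block")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if self.n_background_nodes < 0 or self.background_degree < 1:
            raise ValueError("invalid background-node configuration")


def generate_ppi_network(spec: PlantedPPISpec) -> list[tuple[str, str]]:
    """Draw a simple undirected edge list from the planted-partition model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nodes = list(spec.membership)
    blocks = np.asarray([spec.membership[n] for n in nodes])
    n = len(nodes)

    iu, ju = np.triu_indices(n, k=1)
    same = blocks[iu] == blocks[ju]
    prob = np.where(same, spec.p_within, spec.p_between)
    drawn = rng.random(iu.size) < prob
    edges = [(nodes[a], nodes[b]) for a, b in zip(iu[drawn], ju[drawn])]

    for k in range(spec.n_background_nodes):
        bg = f"BG{k:04d}"
        deg = min(spec.background_degree, n)
        targets = rng.choice(n, size=deg, replace=False)
        edges.extend((bg, nodes[t]) for t in targets)
    return edges


def write_edge_list(edges, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)
    return path


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    return list(df.itertuples(index=False, name=None))
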