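"""Pearson co-occurrence networks.

A co-occurrence network (CoN) is the complete weighted graph over taxa
whose edge weights are sample Pearson correlations of abundances. Here
its only role is to supply the sign and magnitude attached to each edge
of the learned Bayesian-network structure, so no threshold or p-value
filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .abundance import AbundanceMatrix


@dataclass
class CoNetwork:
    nodes: list[str]
    weights: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, r in self.weights.items():
            if len(pair) != 2:
                raise ValueError(f"self-pair or malformed pair {set(pair)!r}")
            if abs(r) > 1 + 1e-12:
                raise ValueError(f"|r| > 1 for pair {sorted(pair)}: {r}")

    def weight(self, u: str, v: str) -> float:
        return self.weights[frozenset((u, v))]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, r in self.weights.items():
            u, v = sorted(pair)
            g.add_edge(u, v, weight=float(r))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_conet(m: AbundanceMatrix) -> CoNetwork:
    """Complete Pearson-correlation graph over the columns of ``m``.

    Every column must be non-constant; weights are symmetric and clipped
    to [-1, 1] against floating-point overshoot.
    """
    if m.n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {m.n_samples}")
    sd = m.values.std(axis=0)
    if np.any(sd == 0):
        bad = m.taxon_names[int(np.nonzero(sd == 0)[0][0])]
        raise ValueError(f"taxon {bad!r} is constant across samples")
    corr = np.clip(np.corrcoef(m.values, rowvar=False), -1.0, 1.0)
    weights = {
        frozenset((m.taxon_names[i], m.taxon_names[j])): float(corr[i, j])
        for i in range(m.n_taxa) for j in range(i + 1, m.n_taxa)
    }
    return CoNetwork(list(m.taxon_names), weights)
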