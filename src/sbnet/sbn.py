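"""Signed Bayesian networks: PDAG edges annotated with co-occurrence
signs and bootstrap direction support.

``build_sbn`` joins the learned structure with the co-occurrence
network: every edge keeps its orientation (or lack of one) and gains the
Pearson correlation of its endpoints, whose sign renders the edge green
(positive) or red (negative) on export. ``bootstrap_support`` re-runs
the learner on randomized inputs and records, for every ordered pair,
how often each orientation was reported; ``attach_support`` copies those
frequencies onto the network's edges (the opacity channel in Cytoscape).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .abundance import AbundanceMatrix
from .conet import CoNetwork
from .pc_stable import PDAG, pc_stable

log = logging.getLogger(__name__)

_SIGN_COLOR = {"positive": "green", "negative": "red", "zero": "grey"}


def _sign_of(r: float) -> str:
    if r > 0:
        return "positive"
    if r < 0:
        return "negative"
    return "zero"


@dataclass(frozen=True)
class SignedEdge:
    """One sBN edge. Undirected edges store their endpoints in canonical
    lexicographic order."""

    source: str
    target: str
    directed: bool
    r: float
    sign: str
    support: float | None = None

    def __post_init__(self) -> None:
        if self.sign != _sign_of(self.r):
            raise ValueError(f"sign {self.sign!r} inconsistent with r={self.r}")
        if not self.directed and self.source > self.target:
            raise ValueError("undirected edge endpoints must be sorted")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.source, self.target))


@dataclass
class SignedBayesNet:
    """Signed BN: node mean abundances plus a set of signed edges whose
    pair set equals the source PDAG's edge set exactly."""

    nodes: dict         # taxon -> mean abundance (>= 0)
    edges: list[SignedEdge] = field(default_factory=list)

    def edge_for(self, u: str, v: str) -> SignedEdge:
        for e in self.edges:
            if e.pair == frozenset((u, v)):
                return e
        raise KeyError(f"no edge between {u!r} and {v!r}")

    # -- export --------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name, mean in self.nodes.items():
            g.add_node(name, mean_abundance=float(mean))
        for e in self.edges:
            g.add_edge(
                e.source, e.target,
                r=float(e.r),
                sign=e.sign,
                color=_SIGN_COLOR[e.sign],
                orientation="directed" if e.directed else "undirected",
                **({"support": float(e.support)} if e.support is not None else {}),
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edge_tsv(self, path) -> None:
        """Cytoscape-importable edge-attribute table."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "target", "orientation", "r", "sign",
                        "support"])
            key = lambda e: (e.source, e.target)
            for e in sorted(self.edges, key=key):
                w.writerow([
                    e.source, e.target,
                    "directed" if e.directed else "undirected",
                    f"{e.r:.6f}", e.sign,
                    "" if e.support is None else f"{e.support:.4f}",
                ])


def read_edge_tsv(path) -> SignedBayesNet:
    """Rebuild a network from :meth:`SignedBayesNet.write_edge_tsv` output
    (node mean abundances are not stored in the table and default to 0)."""
    edges, nodes = [], {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            support = float(row["support"]) if row["support"] else None
            r = float(row["r"])
            edges.append(SignedEdge(
                row["source"], row["target"],
                row["orientation"] == "directed", r, _sign_of(r), support,
            ))
            nodes.setdefault(row["source"], 0.0)
            nodes.setdefault(row["target"], 0.0)
    return SignedBayesNet(nodes, edges)


# ----------------------------------------------------------------------

def build_sbn(g: PDAG, c: CoNetwork, m: AbundanceMatrix) -> SignedBayesNet:
    """Annotate every PDAG edge with its co-occurrence correlation.

    Signing adds attributes, never edges: the output edge set equals
    ``g``'s exactly. Node sizes carry each taxon's mean abundance in ``m``.
    """
    missing = [v for v in g.nodes if v not in c.nodes]
    if missing:
        raise ValueError(f"node(s) missing from co-occurrence network: {missing}")
    missing = [v for v in g.nodes if v not in m.taxon_names]
    if missing:
        raise ValueError(f"node(s) missing from abundance matrix: {missing}")
    nodes = {v: float(m.column(v).mean()) for v in g.nodes}
    edges = []
    for u, v in sorted(g.directed_edges):
        r = c.weight(u, v)
        edges.append(SignedEdge(u, v, True, r, _sign_of(r)))
    for pair in sorted(g.undirected_edges, key=sorted):
        u, v = sorted(pair)
        r = c.weight(u, v)
        edges.append(SignedEdge(u, v, False, r, _sign_of(r)))
    return SignedBayesNet(nodes, edges)


# ----------------------------------------------------------------------
# Bootstrap direction support

@dataclass
class BootstrapSupport:
    """Orientation frequencies over ``B`` randomized learner re-runs.

    ``directed[(u, v)]`` is the fraction of runs reporting the arrow
    ``u -> v``; ``undirected[{u, v}]`` the fraction reporting the edge
    without orientation. The remainder up to 1 is the fraction of runs in
    which the pair was not connected at all.
    """

    B: int
    seed: int
    mode: str
    nodes: list[str] = field(default_factory=list)
    directed: dict = field(default_factory=dict)
    undirected: dict = field(default_factory=dict)

    def frequency(self, u: str, v: str, directed: bool) -> float:
        if directed:
            return self.directed.get((u, v), 0.0)
        return self.undirected.get(frozenset((u, v)), 0.0)

    def absent(self, u: str, v: str) -> float:
        pair = frozenset((u, v))
        present = (self.directed.get((u, v), 0.0)
                   + self.directed.get((v, u), 0.0)
                   + self.undirected.get(pair, 0.0))
        return 1.0 - present


def bootstrap_support(data, B: int = 200, seed: int = 0,
                      alpha: float = 0.05, test="fisher_z",
                      mode: str = "permute_vars",
                      names: list[str] | None = None,
                      max_cond: int | None = None) -> BootstrapSupport:
    """Estimate edge-direction support from ``B`` randomized re-runs.

    In ``permute_vars`` mode (default) each replicate permutes the
    variable (column) order before running the learner — the quantity the
    residual orientation rules depend on, skeleton and collider
    orientations being order-independent. ``resample_rows`` draws a
    non-parametric bootstrap sample of the rows instead.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if mode not in ("permute_vars", "resample_rows"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if names is None:
        names = [f"V{i}" for i in range(p)]
    rng = np.random.default_rng(seed)
    directed: dict = {}
    undirected: dict = {}
    for b in range(B):
        if mode == "permute_vars":
            perm = rng.permutation(p)
            rep_data = data[:, perm]
            rep_names = [names[k] for k in perm]
        else:
            rows = rng.integers(0, n, size=n)
            rep_data = data[rows]
            rep_names = list(names)
        try:
            g = pc_stable(rep_data, alpha=alpha, test=test,
                          max_cond=max_cond, names=rep_names)
        except Exception as exc:
            raise RuntimeError(
                f"bootstrap replicate {b} (seed {seed}) failed: {exc}"
            ) from exc
        for arrow in g.directed_edges:
            directed[arrow] = directed.get(arrow, 0) + 1
        for pair in g.undirected_edges:
            undirected[pair] = undirected.get(pair, 0) + 1
    return BootstrapSupport(
        B=B, seed=seed, mode=mode, nodes=list(names),
        directed={k: v / B for k, v in directed.items()},
        undirected={k: v / B for k, v in undirected.items()},
    )


def attach_support(net: SignedBayesNet, freqs: BootstrapSupport) -> SignedBayesNet:
    """Copy bootstrap frequencies onto the network's edges.

    A directed edge gets the frequency of its own arrow; an undirected
    edge the frequency of appearing undirected. An edge never reproduced
    in any replicate gets support 0 with a warning.
    """
    known = set(freqs.nodes)
    new_edges = []
    for e in net.edges:
        if e.source not in known or e.target not in known:
            raise KeyError(
                f"pair ({e.source!r}, {e.target!r}) not covered by the "
                f"bootstrap frequencies"
            )
        support = freqs.frequency(e.source, e.target, e.directed)
        if support == 0.0:
            log.warning("edge %r-%r: reported orientation never reproduced "
                        "in %d replicates", e.source, e.target, freqs.B)
        new_edges.append(replace(e, support=support))
    return SignedBayesNet(dict(net.nodes), new_edges)
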