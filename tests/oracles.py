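"""Independent brute-force oracles used to check the learner.

Everything here is deliberately naive and independent of the package's
PC-stable code path: the CPDAG of a DAG is obtained by enumerating every
orientation of its skeleton and keeping the acyclic ones with the same
collider set (Markov equivalence), then taking the orientation consensus.
Feasible for the <= 5-node graphs the equivalence checks use.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def v_structures(g: nx.DiGraph) -> set:
    """Collider triples (i, j, k), i < k, with i -> j <- k and i, k
    non-adjacent."""
    out = set()
    und = g.to_undirected()
    for j in g.nodes:
        preds = sorted(g.predecessors(j))
        for i, k in itertools.combinations(preds, 2):
            if not und.has_edge(i, k):
                out.add((i, j, k))
    return out


def brute_force_cpdag(dag: nx.DiGraph):
    """(undirected_pairs, directed_arrows) of the CPDAG of ``dag``.

    Enumerates all 2^m orientations of the skeleton, keeps those that are
    acyclic DAGs with the same v-structures (the Markov equivalence class),
    and marks an edge directed iff every class member orients it the same
    way.
    """
    skeleton = sorted(frozenset(e) for e in dag.edges)
    target_v = v_structures(dag)
    members = []
    for choice in itertools.product([0, 1], repeat=len(skeleton)):
        g = nx.DiGraph()
        g.add_nodes_from(dag.nodes)
        for bit, pair in zip(choice, skeleton):
            u, v = sorted(pair)
            g.add_edge(u, v) if bit == 0 else g.add_edge(v, u)
        if nx.is_directed_acyclic_graph(g) and v_structures(g) == target_v:
            members.append(g)
    assert members, "equivalence class must contain the DAG itself"
    undirected, directed = set(), set()
    for pair in skeleton:
        u, v = sorted(pair)
        orientations = {("uv" if m.has_edge(u, v) else "vu") for m in members}
        if len(orientations) == 1:
            directed.add((u, v) if orientations == {"uv"} else (v, u))
        else:
            undirected.add(pair)
    return undirected, directed


def residual_partial_correlation(data: np.ndarray, i: int, j: int, S) -> float:
    """Partial correlation via the regression-residual route: residualize
    columns i and j on the columns in S with least squares, then take the
    plain Pearson correlation of the residuals."""
    S = sorted(S)
    if not S:
        return float(np.corrcoef(data[:, i], data[:, j])[0, 1])
    X = np.column_stack([np.ones(data.shape[0]), data[:, S]])
    res = []
    for c in (i, j):
        beta, *_ = np.linalg.lstsq(X, data[:, c], rcond=None)
        res.append(data[:, c] - X @ beta)
    return float(np.corrcoef(res[0], res[1])[0, 1])
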