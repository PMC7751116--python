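"""Order-independent PC-stable structure learning.

The learner recovers a partially directed acyclic graph (PDAG) over taxa
in three steps:

1. ``learn_skeleton`` — start from the complete undirected graph and
   delete edges by level-wise conditional-independence testing, freezing
   every node's adjacency set at the start of each level so the outcome
   does not depend on the order in which variables are visited.
2. ``orient_v_structures`` — orient unshielded triples ``i - j - k`` as
   colliders ``i -> j <- k`` when ``j`` is absent from the separating set
   that removed the ``i, k`` edge.
3. ``apply_orientation_rules`` — propagate orientations with the three
   standard rules (no new colliders, no directed cycles) to a fixpoint.

``pc_stable`` composes the three steps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .citest import CITestResult, DegenerateConditioningError, gaussian_ci_test

import numpy as np

log = logging.getLogger(__name__)


class PDAGError(ValueError):
    """Internal-consistency violation in a PDAG."""


@dataclass
class PDAG:
    """Mixed graph with undirected and directed edges plus sepset records.

    ``undirected_edges`` holds unordered pairs (frozensets of two node
    names); ``directed_edges`` holds ordered ``(source, target)`` tuples.
    ``sepsets`` maps each non-adjacent pair removed during the skeleton
    search to the conditioning set that separated it.
    """

    nodes: list[str]
    undirected_edges: set[frozenset] = field(default_factory=set)
    directed_edges: set[tuple] = field(default_factory=set)
    sepsets: dict[frozenset, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise PDAGError("duplicate node names")
        for u, v in self.directed_edges:
            if u == v:
                raise PDAGError(f"self-loop on {u!r}")
            if (v, u) in self.directed_edges:
                raise PDAGError(f"edge {u!r}/{v!r} directed both ways")
            if frozenset((u, v)) in self.undirected_edges:
                raise PDAGError(f"edge {u!r}/{v!r} both directed and undirected")
        for e in self.undirected_edges:
            if len(e) != 2:
                raise PDAGError(f"malformed undirected edge {set(e)!r}")

    # -- queries -------------------------------------------------------
    def adjacent(self, u: str, v: str) -> bool:
        return (frozenset((u, v)) in self.undirected_edges
                or (u, v) in self.directed_edges
                or (v, u) in self.directed_edges)

    def neighbors(self, u: str) -> set:
        """All nodes adjacent to ``u`` regardless of orientation."""
        out = {next(iter(e - {u})) for e in self.undirected_edges if u in e}
        out |= {b for a, b in self.directed_edges if a == u}
        out |= {a for a, b in self.directed_edges if b == u}
        return out

    def parents(self, u: str) -> set:
        return {a for a, b in self.directed_edges if b == u}

    @property
    def n_edges(self) -> int:
        return len(self.undirected_edges) + len(self.directed_edges)

    def edge_pairs(self) -> set:
        """All adjacent pairs as frozensets."""
        return set(self.undirected_edges) | {
            frozenset(e) for e in self.directed_edges
        }

    def copy(self) -> "PDAG":
        return PDAG(list(self.nodes), set(self.undirected_edges),
                    set(self.directed_edges), dict(self.sepsets))

    # -- mutation ------------------------------------------------------
    def orient(self, u: str, v: str) -> None:
        """Turn the undirected edge ``u - v`` into ``u -> v``."""
        e = frozenset((u, v))
        if e not in self.undirected_edges:
            raise PDAGError(f"no undirected edge {u!r} - {v!r} to orient")
        self.undirected_edges.discard(e)
        self.directed_edges.add((u, v))

    # -- export --------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """DiGraph with an ``orientation`` edge attribute; undirected
        edges are stored once, endpoints in lexicographic order."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in sorted(self.directed_edges):
            g.add_edge(u, v, orientation="directed")
        for e in sorted(self.undirected_edges, key=sorted):
            u, v = sorted(e)
            g.add_edge(u, v, orientation="undirected")
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path) -> "PDAG":
        g = nx.read_graphml(path)
        pdag = cls(list(g.nodes))
        for u, v, attrs in g.edges(data=True):
            if attrs.get("orientation") == "undirected":
                pdag.undirected_edges.add(frozenset((u, v)))
            else:
                pdag.directed_edges.add((u, v))
        return pdag


# ----------------------------------------------------------------------
# Step 1: skeleton

def _resolve_ci(test, alpha):
    """Return callable (data, i, j, S) -> bool (independent)."""
    if callable(test):
        def ci(data, i, j, S):
            res = test(data, i, j, S)
            return res.independent if isinstance(res, CITestResult) else bool(res)
        return ci

    def ci(data, i, j, S):
        return gaussian_ci_test(data, i, j, S, alpha=alpha, method=test).independent

    return ci


def learn_skeleton(data, alpha: float = 0.05, test="fisher_z",
                   max_cond: int | None = None,
                   names: list[str] | None = None) -> PDAG:
    """PC-stable adjacency search.

    At each level ``l = 0, 1, 2, ...`` the adjacency sets of all nodes are
    frozen before any deletion, then every still-adjacent ordered pair
    ``(i, j)`` is tested against all size-``l`` subsets of the frozen
    ``adj(i) \\ {j}`` (enumerated lexicographically). The first separating
    set found is recorded in ``sepsets``. Conditioning sets with an exactly
    collinear correlation submatrix — routine on compositional data — are
    skipped rather than treated as separating.

    ``test`` is ``"fisher_z"``, ``"t"``, or a callable
    ``(data, i, j, S) -> bool | CITestResult`` (e.g. a d-separation
    oracle, in which case ``data`` may be None and ``names`` is required).
    """
    if data is not None:
        data = np.asarray(data, dtype=float)
        n, p = data.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 variables, got {p}")
        sd = data.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.nonzero(sd == 0)[0][0])
            label = names[bad] if names else str(bad)
            raise ValueError(f"column {label!r} has zero variance")
        if names is None:
            names = [f"V{i}" for i in range(p)]
        if len(names) != p:
            raise ValueError("names length does not match data columns")
    else:
        if not callable(test):
            raise ValueError("data is required unless test is a callable oracle")
        if names is None:
            raise ValueError("names are required when data is None")
        p = len(names)

    ci = _resolve_ci(test, alpha)
    adj = {i: set(range(p)) - {i} for i in range(p)}
    sepsets: dict[frozenset, frozenset] = {}
    by_name = names.__getitem__  # canonical order: node names, not columns

    def _separating_set(i, j, frozen, level):
        """First separating set of size ``level`` under the canonical
        name-lexicographic enumeration (both sides of the pair), or None.
        The enumeration depends only on node names, never on column
        order, so the recorded sepsets — and with them the collider
        decisions downstream — are invariant to variable order."""
        a, b = sorted((i, j), key=by_name)
        seen = set()
        for side, other in ((a, b), (b, a)):
            candidates = sorted(frozen[side] - {other}, key=by_name)
            for S in itertools.combinations(candidates, level):
                if S in seen:
                    continue
                seen.add(S)
                try:
                    independent = ci(data, i, j, set(S))
                except DegenerateConditioningError:
                    log.debug("skipping collinear conditioning set %s for "
                              "(%d, %d)", S, i, j)
                    continue
                except Exception as exc:
                    raise type(exc)(
                        f"CI test failed for pair ({names[i]!r}, "
                        f"{names[j]!r}) given {[names[s] for s in S]}: {exc}"
                    ) from exc
                if independent:
                    return frozenset(S)
        return None

    level = 0
    while True:
        if max_cond is not None and level > max_cond:
            break
        frozen = {i: frozenset(adj[i]) for i in range(p)}
        pairs = [
            (i, j) for i in range(p) for j in sorted(adj[i], key=by_name)
            if by_name(i) < by_name(j)
            and (len(frozen[i] - {j}) >= level or len(frozen[j] - {i}) >= level)
        ]
        pairs.sort(key=lambda e: (by_name(e[0]), by_name(e[1])))
        if not pairs:
            break
        for i, j in pairs:
            S = _separating_set(i, j, frozen, level)
            if S is not None:
                adj[i].discard(j)
                adj[j].discard(i)
                sepsets[frozenset((names[i], names[j]))] = frozenset(
                    names[s] for s in S
                )
        level += 1

    pdag = PDAG(list(names), sepsets=sepsets)
    for i in range(p):
        for j in adj[i]:
            pdag.undirected_edges.add(frozenset((names[i], names[j])))
    return pdag


# ----------------------------------------------------------------------
# Step 2: v-structures

def orient_v_structures(g: PDAG) -> PDAG:
    """Orient unshielded triples as colliders.

    For every triple ``i - j - k`` with ``i`` and ``k`` non-adjacent,
    orient ``i -> j <- k`` iff ``j`` is not in the separating set of
    ``(i, k)``. All candidate arrows are collected before any edge is
    oriented, so the step is independent of node order; if two triples
    demand opposite arrows on one edge, that edge is left undirected.
    """
    if g.directed_edges:
        raise PDAGError("orient_v_structures expects an undirected skeleton")
    out = g.copy()
    demanded: set[tuple] = set()
    for j in g.nodes:
        nbrs = sorted(g.neighbors(j))
        for i, k in itertools.combinations(nbrs, 2):
            if g.adjacent(i, k):
                continue
            pair = frozenset((i, k))
            if pair not in g.sepsets:
                raise PDAGError(
                    f"missing sepset for non-adjacent pair ({i!r}, {k!r})"
                )
            if j not in g.sepsets[pair]:
                demanded.add((i, j))
                demanded.add((k, j))
    for u, v in sorted(demanded):
        if (v, u) in demanded:
            if u < v:
                log.warning(
                    "conflicting v-structure orientations for edge "
                    "%r - %r; leaving undirected", u, v
                )
            continue
        e = frozenset((u, v))
        if e in out.undirected_edges:
            out.orient(u, v)
    return out


# ----------------------------------------------------------------------
# Step 3: orientation rules

def _rule1(g: PDAG) -> bool:
    """i -> j and j - k with i, k non-adjacent  =>  j -> k."""
    for e in sorted(g.undirected_edges, key=sorted):
        for j, k in itertools.permutations(sorted(e)):
            if frozenset((j, k)) not in g.undirected_edges:
                break  # oriented meanwhile
            if any(not g.adjacent(i, k) for i in sorted(g.parents(j)) if i != k):
                g.orient(j, k)
                return True
    return False


def _rule2(g: PDAG) -> bool:
    """j - k and a chain j -> i -> k  =>  j -> k."""
    for e in sorted(g.undirected_edges, key=sorted):
        for j, k in itertools.permutations(sorted(e)):
            if frozenset((j, k)) not in g.undirected_edges:
                break
            mid = {b for a, b in g.directed_edges if a == j}
            if any((i, k) in g.directed_edges for i in sorted(mid)):
                g.orient(j, k)
                return True
    return False


def _rule3(g: PDAG) -> bool:
    """j - k with j - i -> k and j - l -> k, i and l non-adjacent  =>  j -> k."""
    for e in sorted(g.undirected_edges, key=sorted):
        for j, k in itertools.permutations(sorted(e)):
            if frozenset((j, k)) not in g.undirected_edges:
                break
            cands = sorted(
                i for i in g.parents(k)
                if frozenset((j, i)) in g.undirected_edges
            )
            for i, l in itertools.combinations(cands, 2):
                if not g.adjacent(i, l):
                    g.orient(j, k)
                    return True
    return False


def apply_orientation_rules(g: PDAG) -> PDAG:
    """Apply rules 1-3 in order, restarting after each orientation, until
    a full pass changes nothing. Only undirected edges are ever oriented,
    so no directed edge is removed or reversed."""
    out = g.copy()
    changed = True
    while changed:
        changed = _rule1(out) or _rule2(out) or _rule3(out)
    return out


# ----------------------------------------------------------------------

def pc_stable(data, alpha: float = 0.05, test="fisher_z",
              max_cond: int | None = None,
              names: list[str] | None = None) -> PDAG:
    """Full PC-stable run: skeleton, v-structures, orientation rules.

    Deterministic given ``data``, ``alpha``, ``test`` and the column
    order; the skeleton and the collider orientations are additionally
    invariant to the column order.
    """
    skel = learn_skeleton(data, alpha=alpha, test=test,
                          max_cond=max_cond, names=names)
    return apply_orientation_rules(orient_v_structures(skel))
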