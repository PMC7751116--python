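"""Synthetic data generators for end-to-end validation.

Two generators cover the two things the pipeline must demonstrably do:

* ``sample_random_dag`` / ``sample_linear_gaussian`` produce
  linear-Gaussian data faithful to a known DAG, the standard benchmark
  for constraint-based structure recovery. ``d_separation_ci`` wraps a
  known DAG as a perfect conditional-independence oracle.

* ``simulate_succession`` emulates longitudinal compositional abundance
  under a programmed colonization order: each taxon's latent abundance
  rises logistically after its onset and decays exponentially once its
  successor arrives, so consecutive colonizers are negatively correlated
  inside the handover window. Per-subject affine time distortion mimics
  imperfect temporal alignment across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .abundance import AbundanceMatrix


# ----------------------------------------------------------------------
# Linear-Gaussian ground truth

@dataclass
class TrueDAG:
    """Ground-truth DAG with linear edge weights.

    Weights are kept away from zero (|w| >= 0.1) so the induced
    distribution stays comfortably faithful to the graph.
    """

    nodes: list[str]
    edges: dict            # (parent, child) -> weight
    noise_sd: float | dict = 1.0

    def node_noise_sd(self, v: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(v, 1.0))
        return float(self.noise_sd)

    def __post_init__(self) -> None:
        sds = (self.noise_sd.values() if isinstance(self.noise_sd, dict)
               else [self.noise_sd])
        if any(sd <= 0 for sd in sds):
            raise ValueError("noise_sd must be positive")
        for (u, v), w in self.edges.items():
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if abs(w) < 0.1:
                raise ValueError(f"edge ({u!r}, {v!r}) weight {w} too close to 0")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("edge set contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def skeleton(self) -> set:
        return {frozenset(e) for e in self.edges}


def sample_random_dag(p: int, edge_prob: float, seed: int = 0) -> TrueDAG:
    """Erdos-Renyi DAG over a random topological order.

    Edge weights are uniform on +/-[0.3, 1.0].
    """
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < edge_prob <= 1):
        raise ValueError("edge_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(p)]
    order = rng.permutation(p)
    edges = {}
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < edge_prob:
                w = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
                edges[(names[order[a]], names[order[b]])] = float(w)
    return TrueDAG(names, edges)


def sample_linear_gaussian(dag: TrueDAG, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` samples from the linear structural-equation model
    ``X_v = sum_u w_uv X_u + eps_v`` with iid Gaussian noise, columns in
    ``dag.nodes`` order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = {v: i for i, v in enumerate(dag.nodes)}
    data = np.zeros((n, len(dag.nodes)))
    for v in nx.topological_sort(dag.to_networkx()):
        col = rng.normal(0.0, dag.node_noise_sd(v), size=n)
        for (u, w_v), w in dag.edges.items():
            if w_v == v:
                col += w * data[:, idx[u]]
        data[:, idx[v]] = col
    return data


def d_separation_ci(dag: TrueDAG, names: list[str] | None = None):
    """Perfect CI oracle: independence iff d-separation in ``dag``.

    Returns a callable ``(data, i, j, S) -> bool`` over column indices
    into ``names`` (default: ``dag.nodes``); ``data`` is ignored, so the
    learner can run with ``data=None``.
    """
    g = dag.to_networkx()
    names = list(dag.nodes) if names is None else list(names)

    def ci(data, i, j, S) -> bool:
        return nx.is_d_separator(
            g, {names[i]}, {names[j]}, {names[s] for s in S}
        )

    return ci


# ----------------------------------------------------------------------
# Colonization-order succession simulator

@dataclass
class SuccessionSpec:
    """Programmed colonization order.

    ``taxa`` lists ``(name, onset_time, growth_rate, decline_rate)`` in
    colonization order with strictly increasing onsets. Each subject is
    sampled at ``timepoints`` equally spaced nominal times spanning the
    colonization window; per-subject dynamics run on an affinely
    distorted clock (scale lognormal with sd ``warp_sd``) while the
    nominal times are recorded, emulating imperfect temporal alignment.
    Observation noise is multiplicative log-normal with sd ``noise_sd``;
    rows are renormalized to compositions afterwards.
    """

    taxa: list
    n_subjects: int = 20
    timepoints: int = 12
    noise_sd: float = 0.3
    warp_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("need at least 2 taxa")
        onsets = [t[1] for t in self.taxa]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onset times must be strictly increasing "
                             "along the colonization order")
        if self.noise_sd < 0 or self.warp_sd < 0:
            raise ValueError("noise_sd and warp_sd must be non-negative")


#: Floor keeping latent abundances positive before renormalization.
_LATENT_FLOOR = 1e-4


def default_succession_spec(**overrides) -> SuccessionSpec:
    """Three-class succession emulating the preterm infant gut:
    Bacilli first, displaced by Gammaproteobacteria, displaced in turn by
    Clostridia. Onsets 0/3/9 put the two handovers in the first and
    second halves of the 0-12 observation window."""
    kw = dict(
        taxa=[
            ("Bacilli", 0.0, 1.5, 1.0),
            ("Gammaproteobacteria", 3.0, 1.5, 1.0),
            ("Clostridia", 9.0, 1.5, 1.0),
        ],
    )
    kw.update(overrides)
    return SuccessionSpec(**kw)


def succession_latents(spec: SuccessionSpec, times: np.ndarray) -> np.ndarray:
    """Closed-form latent trajectories at ``times`` (len(times) x p).

    Taxon ``i`` follows ``logistic(g_i * (t - onset_i))`` and, if it has
    a successor, decays by ``exp(-d_i * max(0, t - onset_{i+1}))`` once
    the successor's onset has passed.
    """
    times = np.asarray(times, dtype=float)
    p = len(spec.taxa)
    lat = np.empty((times.size, p))
    for i, (name, onset, growth, decline) in enumerate(spec.taxa):
        rise = 1.0 / (1.0 + np.exp(-growth * (times - onset)))
        if i + 1 < p:
            next_onset = spec.taxa[i + 1][1]
            rise = rise * np.exp(-decline * np.maximum(0.0, times - next_onset))
        lat[:, i] = rise + _LATENT_FLOOR
    return lat


def simulate_succession(spec: SuccessionSpec,
                        seed: int | None = None) -> AbundanceMatrix:
    """Longitudinal compositional abundances under ``spec``.

    Returns a relative AbundanceMatrix with one row per (subject,
    timepoint) and nominal sampling times attached.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = [t[0] for t in spec.taxa]
    t0 = spec.taxa[0][1]
    t1 = spec.taxa[-1][1] + 3.0
    nominal = np.linspace(t0, t1, spec.timepoints)
    center = 0.5 * (t0 + t1)

    rows, ids, times = [], [], []
    for s in range(spec.n_subjects):
        scale = float(np.exp(rng.normal(0.0, spec.warp_sd)))
        shift = float(rng.normal(0.0, 2.0 * spec.warp_sd))
        warped = center + scale * (nominal - center) + shift
        lat = succession_latents(spec, warped)
        if spec.noise_sd > 0:
            lat = lat * np.exp(rng.normal(0.0, spec.noise_sd, size=lat.shape))
        lat = lat / lat.sum(axis=1, keepdims=True)
        for k in range(spec.timepoints):
            rows.append(lat[k])
            ids.append(f"S{s:02d}_T{k:02d}")
            times.append(nominal[k])
    return AbundanceMatrix(
        np.asarray(rows), ids, names,
        times=np.asarray(times), is_relative=True,
    )
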