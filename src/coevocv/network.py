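"""Residue-level energetic-coupling networks and allosteric pathways.

For every eligible residue pair the free-energy surface is projected
onto the pair's minimum-distance coordinate; the gap between the lowest
basin and the highest barrier of that 1-D profile measures how tightly
the pair's contact state is coupled to the global conformational change.
These couplings form the weights of an undirected residue graph. Strong
coupling should make a path cheap, so Dijkstra runs on edge costs
1/(coupling + eps) (or optionally max-coupling minus coupling), and
betweenness centrality on the same costs ranks residues by their share
of optimal communication pathways. A PCA across simulation conditions
(per-residue total coupling vectors) summarises how ligands reshape the
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from .cv_learning import DistanceTrajectory
from .free_energy import energetic_coupling, make_bins, project_fes
from .units import RT_STANDARD_KJ_PER_MOL

logger = logging.getLogger(__name__)

#: Cost offset keeping 1/(coupling + eps) finite (kJ/mol).
COST_EPSILON: float = 1e-6


@dataclass
class CouplingNetwork:
    """Undirected residue graph weighted by energetic coupling (kJ/mol)."""

    graph: nx.Graph
    cost_transform: str = "inverse"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if data.get("coupling", 0.0) < 0:
                raise ValueError("couplings must be non-negative")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self, nodes: list | None = None) -> np.ndarray:
        nodes = sorted(self.graph.nodes) if nodes is None else nodes
        return nx.to_numpy_array(self.graph, nodelist=nodes, weight="coupling")

    def residue_coupling_vector(self, nodes: list) -> np.ndarray:
        """Per-residue total coupling (adjacency row sums) over ``nodes``."""
        adj = self.adjacency(nodes)
        return adj.sum(axis=1)


def _edge_costs(graph: nx.Graph, transform: str) -> None:
    couplings = [d["coupling"] for _, _, d in graph.edges(data=True)]
    cmax = max(couplings) if couplings else 0.0
    for _, _, data in graph.edges(data=True):
        if transform == "inverse":
            data["cost"] = 1.0 / (data["coupling"] + COST_EPSILON)
        elif transform == "max_minus":
            data["cost"] = (cmax - data["coupling"]) + COST_EPSILON
        else:
            raise ValueError(f"unknown cost transform {transform!r}")


def build_coupling_network(
    trajectory: DistanceTrajectory,
    frame_energies: np.ndarray,
    *,
    source_bin_counts: np.ndarray | None = None,
    n_bins: int = 30,
    rt: float = RT_STANDARD_KJ_PER_MOL,
    contact_threshold_nm: float = 0.6,
    min_contact_fraction: float = 0.05,
    min_coupling: float | None = None,
    cost_transform: str = "inverse",
) -> CouplingNetwork:
    """Build the residue coupling graph from per-pair FES projections.

    Eligible pairs are those whose minimum distance drops below
    ``contact_threshold_nm`` in at least ``min_contact_fraction`` of
    frames (pairs that never form a contact cannot report on a
    conformational change). For each eligible pair the frame energies
    are projected onto the pair distance and the barrier-to-basin gap
    becomes the edge weight between the two residues; edges with
    coupling <= ``min_coupling`` are dropped. The default floor is RT:
    a barrier below thermal energy is not metastability, and the
    ~RT/sqrt(n) shot noise of bin free energies can fake shallower
    double wells on single-basin pairs. Node identifiers are the
    residue ids of the trajectory's pair list.
    """
    if min_coupling is None:
        min_coupling = rt
    graph = nx.Graph()
    for i, j in trajectory.pairs:
        graph.add_node(i)
        graph.add_node(j)
    n_kept = 0
    for k, (i, j) in enumerate(trajectory.pairs):
        d = trajectory.distances[:, k]
        if (d < contact_threshold_nm).mean() < min_contact_fraction:
            continue
        edges = make_bins(float(d.min()), float(d.max()) + 1e-12, n_bins)
        profile = project_fes(
            frame_energies, d, edges, rt=rt, source_bin_counts=source_bin_counts
        )
        coupling = energetic_coupling(profile)
        if coupling > min_coupling:
            existing = graph.get_edge_data(i, j)
            if existing is None or existing["coupling"] < coupling:
                graph.add_edge(i, j, coupling=float(coupling))
            n_kept += 1
    if graph.number_of_edges() == 0:
        logger.warning("no pair produced a positive energetic coupling; empty graph")
    _edge_costs(graph, cost_transform)
    return CouplingNetwork(
        graph=graph,
        cost_transform=cost_transform,
        metadata={
            "n_bins": n_bins,
            "contact_threshold_nm": contact_threshold_nm,
            "min_contact_fraction": min_contact_fraction,
            "rt": rt,
        },
    )


def network_from_couplings(
    couplings: dict[tuple, float], cost_transform: str = "inverse"
) -> CouplingNetwork:
    """Build a network directly from a pair -> coupling mapping."""
    graph = nx.Graph()
    for (i, j), c in couplings.items():
        if c < 0:
            raise ValueError("couplings must be non-negative")
        graph.add_edge(i, j, coupling=float(c))
    _edge_costs(graph, cost_transform)
    return CouplingNetwork(graph=graph, cost_transform=cost_transform)


@dataclass
class PathwayReport:
    """Shortest coupling pathways from one source plus node centralities."""

    source: object
    paths: dict[object, tuple[list, float] | None]
    betweenness: dict[object, float]
    cost_transform: str = "inverse"


def shortest_coupling_paths(
    network: CouplingNetwork, source, sinks: list
) -> PathwayReport:
    """Dijkstra pathways from ``source`` to each sink on the edge costs.

    Unreachable sinks are reported as None rather than raising; the
    source as its own sink gives the empty path at cost 0.
    """
    g = network.graph
    if source not in g:
        raise ValueError(f"source {source!r} not in the network")
    for s in sinks:
        if s not in g:
            raise ValueError(f"sink {s!r} not in the network")
    paths: dict[object, tuple[list, float] | None] = {}
    for sink in sinks:
        try:
            cost, path = nx.single_source_dijkstra(g, source, sink, weight="cost")
            paths[sink] = (path, float(cost))
        except nx.NetworkXNoPath:
            paths[sink] = None
    return PathwayReport(
        source=source,
        paths=paths,
        betweenness=betweenness(network),
        cost_transform=network.cost_transform,
    )


def betweenness(network: CouplingNetwork) -> dict[object, float]:
    """Normalised weighted betweenness centrality on the edge costs."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(network.graph, weight="cost", normalized=True)


def condition_pca(
    coupling_vectors: dict[str, dict], n_components: int = 2
) -> tuple[dict[str, np.ndarray], np.ndarray, list]:
    """PCA across simulation conditions of their coupling vectors.

    ``coupling_vectors`` maps condition name -> {key: coupling}; keys
    (residues or pairs) are unioned across conditions with missing
    entries treated as 0. Returns per-condition scores on the leading
    components, the variance-explained fractions and the key order.
    """
    if len(coupling_vectors) < 2:
        raise ValueError("condition PCA needs at least 2 conditions")
    keys = sorted({k for vec in coupling_vectors.values() for k in vec})
    names = list(coupling_vectors)
    x = np.array([[coupling_vectors[name].get(k, 0.0) for k in keys] for name in names])
    n_components = min(n_components, len(names), len(keys))
    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(x)
    variance = pca.explained_variance_ratio_
    variance = np.nan_to_num(variance)  # degenerate: identical conditions
    return {name: scores[k] for k, name in enumerate(names)}, variance, keys
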