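"""Median-joining haplotype networks.

The construction follows the classic two-step heuristic: first a minimum
spanning network (MSN) over the observed haplotypes — the union of all
minimum spanning trees, relaxed by a tolerance ``epsilon`` — then an
iterative median-joining step that proposes per-column majority-consensus
medians ("median vectors", unsampled intermediate haplotypes) for
connected triplets, keeps the cheapest novel ones, and rebuilds the MSN
until a fixpoint. Obsolete medians (degree < 2, or off every minimal
observed-to-observed connection) are pruned at the end.

Edges are weighted by the Hamming distance (number of substitutions)
between the sequences at their endpoints. An edge (u, v) belongs to the
MSN at tolerance eps iff d(u, v) <= minimax(u, v) + eps, where
minimax(u, v) is the smallest possible value of the largest edge on any
path from u to v (the cost at which their components first connect);
eps = 0 therefore yields exactly the union of all MSTs, and edge sets
grow monotonically with eps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .haplotypes import HaplotypeTable
from .seq_io import SampleMetadata

logger = logging.getLogger(__name__)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class NetworkNode:
    node_id: str
    sequence: str
    observed: bool
    frequency: int = 0
    species_counts: dict = field(default_factory=dict)


class HaplotypeNetwork:
    """Observed haplotypes plus inferred medians, connected by an MSN."""

    def __init__(self, epsilon: int = 0):
        self.epsilon = int(epsilon)
        self.graph = nx.Graph()
        self._nodes: dict[str, NetworkNode] = {}
        self.converged: bool = True
        self.quasi_median_fallbacks: int = 0

    # -- node bookkeeping -------------------------------------------------
    def add_node(self, node: NetworkNode) -> None:
        self._nodes[node.node_id] = node
        self.graph.add_node(
            node.node_id,
            observed=node.observed,
            frequency=node.frequency,
            species=",".join(
                f"{sp}:{c}" for sp, c in sorted(node.species_counts.items())
            ),
        )

    def node(self, node_id: str) -> NetworkNode:
        return self._nodes[node_id]

    @property
    def nodes(self) -> list[NetworkNode]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    @property
    def observed_ids(self) -> list[str]:
        return sorted(i for i, n in self._nodes.items() if n.observed)

    @property
    def median_ids(self) -> list[str]:
        return sorted(i for i, n in self._nodes.items() if not n.observed)

    def edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    def sequences(self) -> dict[str, str]:
        return {i: n.sequence for i, n in self._nodes.items()}

    # -- MSN --------------------------------------------------------------
    def rebuild_edges(self) -> None:
        """Recompute the epsilon-relaxed MSN edge set over current nodes."""
        ids = sorted(self._nodes)
        self.graph.remove_edges_from(list(self.graph.edges))
        if len(ids) < 2:
            return
        seqs = self.sequences()
        dist = {
            (u, v): hamming(seqs[u], seqs[v])
            for u, v in itertools.combinations(ids, 2)
        }
        minimax = _minimax_distances(ids, dist)
        for (u, v), d in dist.items():
            if d <= minimax[(u, v)] + self.epsilon:
                self.graph.add_edge(u, v, weight=d)


def _minimax_distances(ids, dist) -> dict[tuple[str, str], int]:
    """Minimax path cost between all pairs, via max-edge on an MST path.

    Any MST realises the minimax distance for every pair, so one MST of
    the complete Hamming graph suffices.
    """
    g = nx.Graph()
    g.add_nodes_from(ids)
    for (u, v), d in dist.items():
        g.add_edge(u, v, weight=d)
    mst = nx.minimum_spanning_tree(g, weight="weight")
    out: dict[tuple[str, str], int] = {}
    for src in ids:
        # DFS over the MST tracking the running max edge weight
        stack = [(src, None, 0)]
        while stack:
            node, parent, running = stack.pop()
            if node != src:
                key = (src, node) if src < node else (node, src)
                out[key] = running
            for nbr in mst.neighbors(node):
                if nbr != parent:
                    w = mst[node][nbr]["weight"]
                    stack.append((nbr, node, max(running, w)))
    return out


def build_msn(
    haplotypes: HaplotypeTable,
    epsilon: int = 0,
    metadata: SampleMetadata | None = None,
) -> HaplotypeNetwork:
    """Minimum spanning network over the observed haplotypes."""
    if len(haplotypes) < 2:
        raise ValueError("a network requires at least 2 distinct haplotypes")
    net = HaplotypeNetwork(epsilon=epsilon)
    comp = haplotypes.species_composition(metadata) if metadata is not None else {}
    for h in haplotypes:
        net.add_node(
            NetworkNode(
                node_id=h.haplotype_id,
                sequence=h.sequence,
                observed=True,
                frequency=h.count,
                species_counts=dict(comp.get(h.haplotype_id, {})),
            )
        )
    net.rebuild_edges()
    return net


def _triplet_median(
    seq_u: str, seq_v: str, seq_w: str, ids: tuple[str, str, str]
) -> tuple[str, bool]:
    """Per-column majority consensus of three sequences.

    At columns where all three states differ no new state is invented:
    the whole column set is copied from the triplet member closest (in
    Hamming distance) to the other two, ties broken by lexicographic
    node id. Returns (median, fallback_used).
    """
    fallback_donor = None
    fallback_used = any(
        len({a, b, c}) == 3 for a, b, c in zip(seq_u, seq_v, seq_w)
    )
    if fallback_used:
        seqs = dict(zip(ids, (seq_u, seq_v, seq_w)))
        ranked = sorted(
            ids,
            key=lambda i: (
                sum(hamming(seqs[i], seqs[j]) for j in ids if j != i),
                i,
            ),
        )
        fallback_donor = seqs[ranked[0]]
    out = []
    for j, (a, b, c) in enumerate(zip(seq_u, seq_v, seq_w)):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(fallback_donor[j])
    return "".join(out), fallback_used


def median_join(
    network_or_table,
    epsilon: int = 0,
    max_iter: int = 20,
    metadata: SampleMetadata | None = None,
) -> HaplotypeNetwork:
    """Median-joining network: MSN plus iteratively added median vectors.

    Candidate triplets are node triples carrying at least two of their
    three links in the current network (the standard restriction); per
    iteration every novel median within ``epsilon`` of the cheapest
    connection cost is added and the MSN rebuilt. Stops at a fixpoint or
    after ``max_iter`` iterations (then ``converged`` is False).
    """
    if isinstance(network_or_table, HaplotypeTable):
        net = build_msn(network_or_table, epsilon=epsilon, metadata=metadata)
    else:
        net = network_or_table
        net.epsilon = int(epsilon)
        net.rebuild_edges()

    median_counter = itertools.count(1)
    existing = {n.sequence for n in net.nodes}
    net.converged = False
    for _ in range(max_iter):
        candidates: dict[str, int] = {}
        seqs = net.sequences()
        # a triple carries >= 2 of its 3 links iff some node is adjacent
        # to the other two, so enumerate (center, neighbor pair)
        triples: set[tuple[str, str, str]] = set()
        for center in sorted(net._nodes):
            for a, b in itertools.combinations(sorted(net.graph.neighbors(center)), 2):
                triples.add(tuple(sorted((center, a, b))))
        for u, v, w in sorted(triples):
            med, fallback = _triplet_median(seqs[u], seqs[v], seqs[w], (u, v, w))
            if fallback:
                net.quasi_median_fallbacks += 1
                logger.warning(
                    "quasi-median fallback used for triplet (%s, %s, %s)", u, v, w
                )
            if med in existing:
                continue
            d = {x: hamming(med, seqs[x]) for x in (u, v, w)}
            # only true Steiner points are admissible: the median must lie
            # on the geodesic of every pair, else it can lengthen
            # observed-to-observed paths in the rebuilt MSN
            on_geodesics = all(
                d[a] + d[b] == hamming(seqs[a], seqs[b])
                for a, b in ((u, v), (u, w), (v, w))
            )
            if not on_geodesics:
                logger.warning(
                    "median candidate for (%s, %s, %s) rejected: off-geodesic",
                    u, v, w,
                )
                continue
            cost = d[u] + d[v] + d[w]
            if med not in candidates or cost < candidates[med]:
                candidates[med] = cost
        if not candidates:
            net.converged = True
            break
        cmin = min(candidates.values())
        accepted = sorted(
            (cost, med) for med, cost in candidates.items()
            if cost <= cmin + net.epsilon
        )
        for _, med in accepted:
            node_id = f"MV{next(median_counter)}"
            net.add_node(
                NetworkNode(node_id=node_id, sequence=med, observed=False)
            )
            existing.add(med)
        net.rebuild_edges()
    else:
        logger.warning("median joining hit max_iter=%d before fixpoint", max_iter)

    _prune_obsolete_medians(net)
    _complete_observed_geodesics(net)
    return net


def _complete_observed_geodesics(net: HaplotypeNetwork) -> None:
    """Add a direct edge for observed pairs whose network path exceeds
    their Hamming distance.

    Hamming distance is a metric, so every network path is at least the
    direct distance; under homoplasy the relaxed-MST criterion can leave
    a pair connected only through a longer detour, which would make the
    displayed substitution counts overstate their divergence. The direct
    link restores the geodesic without touching any existing edge.
    """
    seqs = net.sequences()
    sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
    for a, b in itertools.combinations(net.observed_ids, 2):
        d = hamming(seqs[a], seqs[b])
        if sp[a].get(b, float("inf")) > d:
            logger.warning(
                "restoring direct link %s--%s (%d) over a %s-step detour",
                a, b, d, sp[a].get(b),
            )
            net.graph.add_edge(a, b, weight=d)


def _prune_obsolete_medians(net: HaplotypeNetwork) -> None:
    """Drop medians off every minimal observed-observed connection, then
    repeatedly drop medians of degree < 2, rebuilding the MSN after removals."""
    changed = True
    while changed:
        changed = False
        obs = net.observed_ids
        sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
        for mid in net.median_ids:
            on_minimal = any(
                abs(sp[a].get(mid, float("inf")) + sp[mid].get(b, float("inf"))
                    - sp[a][b]) < 1e-9
                for a, b in itertools.combinations(obs, 2)
                if b in sp.get(a, {})
            )
            if not on_minimal or net.graph.degree(mid) < 2:
                net.graph.remove_node(mid)
                del net._nodes[mid]
                changed = True
        if changed:
            net.rebuild_edges()


def export_network(network: HaplotypeNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML (default), DOT, or a TSV edge list."""
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("graph haplotype_network {\n")
            for node in network.nodes:
                shape = "circle" if node.observed else "point"
                fh.write(
                    f'  "{node.node_id}" [shape={shape}, frequency={node.frequency}];\n'
                )
            for u, v, w in network.edges():
                fh.write(f'  "{u}" -- "{v}" [label={w}, weight={w}];\n')
            fh.write("}\n")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_a\tnode_b\tsubstitutions\n")
            for u, v, w in network.edges():
                fh.write(f"{u}\t{v}\t{w}\n")
    else:
        raise ValueError(f"unknown network export format {fmt!r}")
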