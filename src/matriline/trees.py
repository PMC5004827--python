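"""Neighbor-joining trees, species monophyly tests and matriline swap detection.

The NJ tree on K2P distances is the desk-scale topology surface for the
package: it supports per-species monophyly checks and the detection of
individuals whose mtDNA clusters inside another species (field
misidentification or mitochondrial introgression). Swap calls combine
tree evidence (smallest enclosing species-pure clade) with network
evidence (nearest observed haplotype cluster) and are tiered: confirmed
when both agree, tentative when only one line of evidence flags the
individual.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .haplotypes import HaplotypeTable
from .network import HaplotypeNetwork
from .seq_io import SampleMetadata

logger = logging.getLogger(__name__)


def nj_tree(
    dm: DistanceMatrix, outgroup_ids: list[str] | None = None
) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: joins are tie-broken on the lexicographically smallest
    (id, id) pair. Negative branch lengths are clamped to zero with the
    slack moved to the sister branch (total edge length conserved) and
    logged. The tree is unrooted unless ``outgroup_ids`` is given, in
    which case it is rerooted on the edge above the outgroup MRCA.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("distance matrix contains undefined entries")

    # active nodes: id -> newick subtree string; ids order gives tie-break
    newick: dict[str, str] = {i: i.replace(" ", "_") for i in dm.ids}
    dist: dict[frozenset, float] = {
        frozenset((a, b)): float(dm.matrix[i, j])
        for i, a in enumerate(dm.ids)
        for j, b in enumerate(dm.ids)
        if i < j
    }
    active = sorted(dm.ids)
    counter = itertools.count(1)

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * d(a, b) - r[a] - r[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        _, a, b = best
        dab = d(a, b)
        ba = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        bb = dab - ba
        ba, bb = _clamp_pair(ba, bb, a, b)
        new_id = f"@nj{next(counter)}"
        newick[new_id] = f"({newick[a]}:{ba:.10f},{newick[b]}:{bb:.10f})"
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_id, c))] = 0.5 * (d(a, c) + d(b, c) - dab)
        active = sorted(set(active) - {a, b} | {new_id})

    if len(active) == 3:
        a, b, c = active
        ba = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        bb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        bc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        ba, bb, bc = (max(x, 0.0) for x in (ba, bb, bc))
        nwk = (
            f"({newick[a]}:{ba:.10f},{newick[b]}:{bb:.10f},{newick[c]}:{bc:.10f});"
        )
    else:  # exactly 2 (possible when called recursively on tiny inputs)
        a, b = active
        nwk = f"({newick[a]}:{d(a, b) / 2:.10f},{newick[b]}:{d(a, b) / 2:.10f});"

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = False
    if outgroup_ids:
        taxa = [tree.taxon_namespace.get_taxon(i) for i in outgroup_ids]
        if any(t is None for t in taxa):
            raise ValueError(f"outgroup ids not in tree: {outgroup_ids}")
        mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else tree.find_node_with_taxon_label(outgroup_ids[0])
        tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
        tree.is_rooted = True
    return tree


def _clamp_pair(ba: float, bb: float, a: str, b: str) -> tuple[float, float]:
    if ba < 0:
        logger.warning("negative NJ branch %.3g on %s clamped; slack to sister", ba, a)
        bb += ba
        ba = 0.0
    if bb < 0:
        logger.warning("negative NJ branch %.3g on %s clamped; slack to sister", bb, b)
        ba = max(ba + bb, 0.0)
        bb = 0.0
    return ba, bb


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyResult:
    species: str
    is_monophyletic: bool
    offending: tuple[str, ...] = ()


def _species_haplotype_sets(haplotypes: HaplotypeTable, metadata: SampleMetadata):
    comp = haplotypes.species_composition(metadata)
    by_species: dict[str, set[str]] = {}
    for hap_id, counter in comp.items():
        for sp in counter:
            by_species.setdefault(sp, set()).add(hap_id)
    return comp, by_species


def _leaf_labels(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def test_monophyly(
    tree_or_network,
    haplotypes: HaplotypeTable,
    metadata: SampleMetadata,
    species: str,
) -> MonophylyResult:
    """Is ``species`` an exclusive clade (tree) or exclusive cluster (network)?

    Tree mode: true iff some edge bipartition isolates exactly the
    species' haplotypes. Network mode: true iff the species' observed
    haplotypes form one connected component once other species' observed
    haplotypes are removed (inferred medians may mediate connections).
    A haplotype shared with another species defeats monophyly in either
    mode.
    """
    comp, by_species = _species_haplotype_sets(haplotypes, metadata)
    if species not in by_species:
        raise ValueError(f"species {species!r} absent from metadata")
    target = by_species[species]
    mixed = tuple(sorted(h for h in target if len(comp[h]) > 1))
    if mixed:
        return MonophylyResult(species, False, offending=mixed)

    if isinstance(tree_or_network, HaplotypeNetwork):
        net = tree_or_network
        keep = set(net.median_ids) | target
        sub = net.graph.subgraph(keep)
        import networkx as nx

        present = [h for h in target if h in net.graph]
        if len(present) <= 1:
            return MonophylyResult(species, True)
        comp0 = None
        for component in nx.connected_components(sub):
            if target & component:
                if comp0 is None:
                    comp0 = component
                else:
                    stranded = tuple(sorted(target - comp0))
                    return MonophylyResult(species, False, offending=stranded)
        return MonophylyResult(species, True)

    tree: dendropy.Tree = tree_or_network
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not target <= all_leaves:
        raise ValueError("haplotype table and tree leaves are inconsistent")
    if len(target) in (1, len(all_leaves)):
        return MonophylyResult(species, True)
    for node in tree.preorder_internal_node_iter():
        clade = _leaf_labels(node)
        if clade == target or (all_leaves - clade) == target:
            return MonophylyResult(species, True)
    mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(h) for h in target])
    offending = tuple(sorted(_leaf_labels(mrca) - target))
    return MonophylyResult(species, False, offending=offending)


# ---------------------------------------------------------------------------
# swap detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwapRecord:
    individual_id: str
    field_species: str
    assigned_species: str
    tier: str  # "confirmed" | "tentative"
    evidence: str

    def __post_init__(self):
        if self.assigned_species == self.field_species:
            raise ValueError("a swap record must reassign to a different species")


class SwapReport(list):
    def confirmed(self) -> list[SwapRecord]:
        return [r for r in self if r.tier == "confirmed"]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("individual_id\tfield_species\tassigned_species\ttier\tevidence\n")
            for r in self:
                fh.write(
                    f"{r.individual_id}\t{r.field_species}\t{r.assigned_species}\t"
                    f"{r.tier}\t{r.evidence}\n"
                )


def _majority(label_counts, field_species: str) -> str | None:
    """Majority species among neighbours; None = consistent or ambiguous."""
    if not label_counts:
        return None
    top = max(label_counts.values())
    winners = {sp for sp, c in label_counts.items() if c == top}
    if field_species in winners:
        return None
    if len(winners) == 1:
        return next(iter(winners))
    return None


MIN_CONTEXT = 3  # other individuals required before a foreign vote counts


def _tree_assignment(
    tree: dendropy.Tree,
    individual: str,
    hap_of: dict[str, str],
    members_of: dict[str, tuple[str, ...]],
    labels: dict[str, str],
) -> str | None:
    """Species vote from the smallest enclosing clade with other individuals.

    If that clade already contains the individual's own species the
    placement is consistent. Otherwise the clade is grown until at least
    ``MIN_CONTEXT`` other individuals vote, which breaks the 1-vs-1
    symmetry of an individual paired with a single swapped neighbour.
    """
    from collections import Counter

    leaf = tree.find_node_with_taxon_label(hap_of[individual])
    field = labels[individual]
    node = leaf
    seen_informative = False
    while node is not None:
        others = [
            m
            for lf in node.leaf_iter()
            for m in members_of[lf.taxon.label]
            if m != individual
        ]
        if others:
            counts = Counter(labels[m] for m in others)
            if not seen_informative and field in counts:
                return None
            seen_informative = True
            if len(others) >= MIN_CONTEXT or node.parent_node is None:
                return _majority(counts, field)
        node = node.parent_node
    return None


def _network_assignment(
    network: HaplotypeNetwork,
    individual: str,
    hap_of: dict[str, str],
    members_of: dict[str, tuple[str, ...]],
    labels: dict[str, str],
) -> str | None:
    """Species vote from the nearest observed haplotypes (weighted shortest
    paths; inferred medians may mediate). Same neighbourhood-growing rule
    as the tree vote: consistent if the closest shell carries the own
    species, otherwise grow shells until ``MIN_CONTEXT`` voters."""
    from collections import Counter

    import networkx as nx

    hap = hap_of[individual]
    field = labels[individual]
    lengths = nx.single_source_dijkstra_path_length(network.graph, hap, weight="weight")
    shells: dict[float, list[str]] = {}
    for nid, d in lengths.items():
        if nid != hap and network.node(nid).observed and members_of[nid]:
            shells.setdefault(d, []).append(nid)
    co = [m for m in members_of[hap] if m != individual]
    if co:
        shells[0.0] = shells.get(0.0, [])
    if not shells and not co:
        return None
    voters = list(co)
    seen_informative = bool(co)
    if co and field in {labels[m] for m in co}:
        return None
    for d in sorted(shells):
        new = [m for nid in shells[d] for m in members_of[nid]]
        if not new:
            continue
        if not seen_informative:
            if field in {labels[m] for m in new}:
                return None
            seen_informative = True
        voters.extend(new)
        if len(voters) >= MIN_CONTEXT:
            break
    if not voters:
        return None
    return _majority(Counter(labels[m] for m in voters), field)


def detect_swaps(
    tree: dendropy.Tree | None,
    network: HaplotypeNetwork | None,
    haplotypes: HaplotypeTable,
    metadata: SampleMetadata,
    max_rounds: int | None = None,
) -> SwapReport:
    """Flag individuals whose matriline clusters inside another species.

    Each individual's neighbourhood — the smallest enclosing clade with
    other individuals (tree) and the co-carriers or nearest observed
    haplotypes (network) — votes by majority species. When both sources
    are supplied a flag is ``confirmed`` if they agree on the same
    foreign species and ``tentative`` otherwise; with a single source an
    unambiguous foreign majority is ``confirmed``. Flagged individuals
    are relabelled to their assigned species and detection repeats until
    a fixpoint, so several swapped individuals that cluster together
    cannot shield one another. Individuals whose field species has a
    single sampled individual are never flagged (insufficient evidence).
    """
    if tree is None and network is None:
        raise ValueError("at least one of tree or network is required")
    hap_of = {m: h.haplotype_id for h in haplotypes for m in h.members}
    members_of = {h.haplotype_id: h.members for h in haplotypes}
    if network is not None:
        for mid in network.median_ids:
            members_of.setdefault(mid, ())
    species_n = {sp: len(ids) for sp, ids in metadata.by_species().items()}

    rooted_tree = None
    if tree is not None:
        rooted_tree = tree.clone(depth=1)
        if not rooted_tree.is_rooted:
            rooted_tree.reroot_at_midpoint(update_bipartitions=False)

    labels = {m: metadata.species_of(m) for m in hap_of}
    flagged: dict[str, SwapRecord] = {}
    max_rounds = max_rounds or len(labels)
    for _ in range(max_rounds):
        new: list[SwapRecord] = []
        for individual in sorted(hap_of):
            if individual in flagged:
                continue
            field_species = metadata.species_of(individual)
            if species_n.get(field_species, 0) < 2:
                continue
            votes = {}
            if rooted_tree is not None:
                votes["tree"] = _tree_assignment(
                    rooted_tree, individual, hap_of, members_of, labels
                )
            if network is not None:
                votes["network"] = _network_assignment(
                    network, individual, hap_of, members_of, labels
                )
            hits = {k: v for k, v in votes.items() if v is not None}
            if not hits:
                continue
            distinct = sorted(set(hits.values()))
            if len(votes) == 2:
                tier = "confirmed" if (len(hits) == 2 and len(distinct) == 1) else "tentative"
            else:
                tier = "confirmed"
            assigned = hits.get("tree", hits.get("network"))
            new.append(
                SwapRecord(
                    individual_id=individual,
                    field_species=field_species,
                    assigned_species=assigned,
                    tier=tier,
                    evidence=";".join(f"{k}={v}" for k, v in sorted(hits.items())),
                )
            )
        if not new:
            break
        for rec in new:
            flagged[rec.individual_id] = rec
            labels[rec.individual_id] = rec.assigned_species

    # validation sweeps: re-vote every flagged individual under the final
    # labels (with its own label restored); drop flags that are no longer
    # supported — they were artefacts of voting before neighbours were
    # relabelled — and refresh tier/evidence for the ones that stand
    def vote(individual: str, lab: dict) -> dict:
        votes = {}
        if rooted_tree is not None:
            votes["tree"] = _tree_assignment(
                rooted_tree, individual, hap_of, members_of, lab
            )
        if network is not None:
            votes["network"] = _network_assignment(
                network, individual, hap_of, members_of, lab
            )
        return votes

    for _ in range(max_rounds):
        dropped = False
        for individual in sorted(flagged):
            field_species = metadata.species_of(individual)
            trial = dict(labels)
            trial[individual] = field_species
            votes = vote(individual, trial)
            hits = {k: v for k, v in votes.items() if v is not None}
            if not hits:
                del flagged[individual]
                labels[individual] = field_species
                dropped = True
                continue
            distinct = sorted(set(hits.values()))
            if len(votes) == 2:
                tier = "confirmed" if (len(hits) == 2 and len(distinct) == 1) else "tentative"
            else:
                tier = "confirmed"
            assigned = hits.get("tree", hits.get("network"))
            flagged[individual] = SwapRecord(
                individual_id=individual,
                field_species=field_species,
                assigned_species=assigned,
                tier=tier,
                evidence=";".join(f"{k}={v}" for k, v in sorted(hits.items())),
            )
            labels[individual] = assigned
        if not dropped:
            break

    report = SwapReport(flagged[i] for i in sorted(flagged))
    return report


def bootstrap_clade_support(
    alignment,
    ids=None,
    n_replicates: int = 100,
    seed: int | None = 0,
    model: str = "k2p",
) -> dict[frozenset, float]:
    """Site-bootstrap clade frequencies for the NJ tree (reporting only).

    Returns bipartition (as a frozenset of the smaller leaf-label side)
    -> fraction of replicates containing it.
    """
    from .distances import distance_matrix
    from .seq_io import AlignedSequenceSet

    sub = alignment if ids is None else alignment.subset(ids)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    all_leaves = frozenset(sub.ids)
    for _ in range(n_replicates):
        cols = rng.integers(0, sub.length, size=sub.length)
        boot = AlignedSequenceSet(
            ids=sub.ids,
            seqs=tuple("".join(s[j] for j in cols) for s in sub.seqs),
            filter_mode=sub.filter_mode,
        )
        tree = nj_tree(distance_matrix(boot, model=model))
        for node in tree.preorder_internal_node_iter():
            clade = frozenset(_leaf_labels(node))
            if 1 < len(clade) < len(all_leaves):
                side = min(clade, all_leaves - clade, key=lambda s: (len(s), sorted(s)))
                counts[side] = counts.get(side, 0) + 1
    return {k: v / n_replicates for k, v in counts.items()}
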