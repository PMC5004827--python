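"""Synthetic aligned mtDNA datasets with known ground truth.

The generator emulates a small radiation sampled at a single
non-recombining matrilineal locus: a known species tree with split times
in years, within-species genealogies (star-like expansion by default,
Kingman coalescent optionally), an optional mitochondrial introgression
event (individuals of a recipient species carrying donor matrilines),
and sequence evolution under the K2P model — a continuous-time 4-state
chain with equal base frequencies in which transitions are favoured over
each transversion by the rate ratio kappa.

Every dataset carries a :class:`SimulationTruth` (true genealogy, split
times, introgressed individuals, realized mutation count) so that each
downstream stage — haplotype collapsing, diversity, dating, networks,
swap detection — can be tested against known answers. All randomness
flows through one :class:`numpy.random.Generator` seeded from the
config, so identical configs give byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .seq_io import AlignedSequenceSet, SampleMetadata, SampleRecord

BASES = "AGCT"  # index coding: purines 0,1; pyrimidines 2,3


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class IntrogressionEvent:
    """Complete matriline replacement: ``n_individuals`` of ``recipient``
    carry mtDNA that re-attaches inside ``donor``'s genealogy at ``time``."""

    donor: str
    recipient: str
    n_individuals: int
    time: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for one synthetic dataset.

    Parameters
    ----------
    species_tree : str
        Ultrametric newick with branch lengths in years; leaf labels are
        the species.
    sample_sizes : dict
        species -> number of sampled individuals (>= 1).
    seq_length : int
        Alignment length in bp (default 588, a control-region segment).
    mu : float
        Substitutions/site/year (default 3.68e-8, the canid
        control-region calibration).
    kappa : float
        Transition : (single) transversion rate ratio (default 4, a
        realistic mammalian control-region value).
    within_mode : str
        'star' (default): every lineage of a species coalesces at once at
        ``expansion_time``, mimicking post-expansion star genealogies;
        'coalescent': Kingman coalescent with expected pairwise
        coalescence time ``theta`` (years).
    expansion_time : float
        Age (years) of the within-species star node; clamped below the
        species' parent split.
    theta : float
        Expected pairwise within-species coalescence time in years
        (coalescent mode only).
    """

    species_tree: str
    sample_sizes: dict
    seq_length: int = 588
    mu: float = 3.68e-8
    kappa: float = 4.0
    within_mode: str = "star"
    expansion_time: float = 100_000.0
    theta: float = 50_000.0
    introgression: tuple[IntrogressionEvent, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.seq_length < 1 or self.mu <= 0 or self.kappa <= 0:
            raise SimulationConfigError("seq_length, mu and kappa must be positive")
        if self.within_mode not in ("star", "coalescent"):
            raise SimulationConfigError("within_mode must be 'star' or 'coalescent'")
        if any(n < 1 for n in self.sample_sizes.values()):
            raise SimulationConfigError("sample sizes must be >= 1")


@dataclass(frozen=True)
class SimulationTruth:
    genealogy_newick: str
    split_times: dict
    introgressed: tuple[tuple[str, str], ...]  # (individual_id, donor species)
    n_mutations: int
    n_transitions: int
    n_transversions: int
    n_homoplasic_sites: int = 0  # sites hit by more than one mutation

    def split_time(self, species_a: str, species_b: str) -> float:
        return self.split_times[frozenset((species_a, species_b))]


class _Node:
    __slots__ = ("name", "time", "children", "parent")

    def __init__(self, name: str, time: float):
        self.name = name
        self.time = time
        self.children: list[_Node] = []
        self.parent: _Node | None = None

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


def _parse_species_tree(newick: str):
    """Return (dendropy tree, species list, node ages, pair split times)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if len(species) != len(set(species)):
        raise SimulationConfigError("duplicate species labels in tree")
    age = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            age[node] = 0.0
        else:
            kids = node.child_nodes()
            ages = [age[k] + (k.edge.length or 0.0) for k in kids]
            if max(ages) - min(ages) > 1e-6 * max(max(ages), 1.0):
                raise SimulationConfigError("species tree is not ultrametric")
            age[node] = max(ages)
    split = {}
    leaves = list(tree.leaf_node_iter())
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            m = tree.mrca(taxa=[a.taxon, b.taxon])
            split[frozenset((a.taxon.label, b.taxon.label))] = age[m]
    return tree, species, age, split


def _build_genealogy(config: SimulationConfig, rng: np.random.Generator):
    """Coalesce sampled lineages bottom-up along the species tree."""
    tree, species, age, split = _parse_species_tree(config.species_tree)
    if set(config.sample_sizes) != set(species):
        raise SimulationConfigError(
            f"sample_sizes keys {sorted(config.sample_sizes)} do not match "
            f"tree species {species}"
        )

    tips: dict[str, list[_Node]] = {}
    introgressed: list[tuple[str, str]] = []
    intro_by_recipient: dict[str, list[IntrogressionEvent]] = {}
    for ev in config.introgression:
        for sp in (ev.donor, ev.recipient):
            if sp not in species:
                raise SimulationConfigError(f"unknown species {sp!r} in introgression")
        if ev.time >= split[frozenset((ev.donor, ev.recipient))]:
            raise SimulationConfigError(
                "introgression time is older than the donor/recipient split"
            )
        if ev.n_individuals > config.sample_sizes[ev.recipient]:
            raise SimulationConfigError("more introgressed individuals than sampled")
        intro_by_recipient.setdefault(ev.recipient, []).append(ev)

    width = max(2, len(str(max(config.sample_sizes.values()))))
    for sp in species:
        tips[sp] = [
            _Node(f"{sp}_{k:0{width}d}", 0.0)
            for k in range(1, config.sample_sizes[sp] + 1)
        ]

    # move introgressed tips (the last ones of each recipient) to donor pools
    donate: dict[str, list[tuple[_Node, IntrogressionEvent]]] = {}
    for recipient, events in intro_by_recipient.items():
        pool = tips[recipient]
        for ev in events:
            moved, tips[recipient] = pool[-ev.n_individuals:], pool[: -ev.n_individuals]
            pool = tips[recipient]
            for node in moved:
                donate.setdefault(ev.donor, []).append((node, ev))
                introgressed.append((node.name, ev.donor))

    def parent_age(tree_node) -> float:
        return age[tree_node.parent_node] if tree_node.parent_node else float("inf")

    counter = [0]

    def join_all(nodes: list[_Node], t: float) -> _Node:
        counter[0] += 1
        anc = _Node(f"@a{counter[0]}", t)
        for nd in nodes:
            anc.add(nd)
        return anc

    def kingman(pool: list[_Node], t0: float, t_end: float) -> tuple[list[_Node], float]:
        t = t0
        pool = list(pool)
        while len(pool) > 1:
            k = len(pool)
            wait = rng.exponential(config.theta / (k * (k - 1) / 2))
            if t + wait >= t_end:
                return pool, t_end
            t += wait
            i, j = sorted(rng.choice(k, size=2, replace=False))
            b = pool.pop(j)
            a = pool.pop(i)
            pool.append(join_all([a, b], t))
        return pool, t

    pools: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = node.taxon.label
            pool = list(tips[sp])
            cap = parent_age(node)
            if config.within_mode == "star":
                if len(pool) > 1:
                    t_star = min(config.expansion_time, 0.99 * cap)
                    pool = [join_all(pool, t_star)]
            else:
                pool, _ = kingman(pool, 0.0, cap)
            # re-attach incoming matrilines at their stated event times
            for tip, ev in sorted(
                donate.get(sp, []), key=lambda pair: (pair[1].time, pair[0].name)
            ):
                pool = _attach_lineage(pool, tip, ev.time, rng, counter)
            pools[node] = pool
        else:
            t = age[node]
            merged = [nd for kid in node.child_nodes() for nd in pools[kid]]
            if node.parent_node is None:
                if config.within_mode == "coalescent":
                    merged, t_done = kingman(merged, t, float("inf"))
                    root = merged[0] if len(merged) == 1 else join_all(merged, t_done)
                else:
                    root = merged[0] if len(merged) == 1 else join_all(merged, t)
                pools[node] = [root]
            else:
                if config.within_mode == "coalescent":
                    merged, _ = kingman(merged, t, parent_age(node))
                    pools[node] = merged
                else:
                    pools[node] = [join_all(merged, t)] if len(merged) > 1 else merged
    root = pools[tree.seed_node][0]
    return root, split, introgressed


def _attach_lineage(
    pool: list[_Node], tip: _Node, t: float, rng: np.random.Generator, counter
) -> list[_Node]:
    """Join ``tip`` to a uniformly chosen lineage of ``pool`` active at
    time ``t``; lineages whose root is younger than t are attached above
    their root, others at a random extant branch (a pendant tip when the
    pool is a post-star tree)."""
    host_idx = int(rng.integers(len(pool)))
    host = pool[host_idx]
    # collect branches of `host` spanning time t (child.time <= t <= parent.time)
    spanning: list[_Node] = []

    def walk(node: _Node):
        for ch in node.children:
            if ch.time <= t <= node.time:
                spanning.append(ch)
            if ch.time < t:
                walk(ch)

    if host.time <= t:
        spanning = [host]
    else:
        walk(host)
        if not spanning:
            spanning = [host]
    target = spanning[int(rng.integers(len(spanning)))]
    counter[0] += 1
    joint = _Node(f"@a{counter[0]}", t)
    parent = target.parent
    if parent is not None:
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
    joint.add(target)
    joint.add(tip)
    joint.parent = parent
    if parent is None:
        pool = [n for n in pool if n is not target]
        pool.insert(host_idx, joint)
    return pool


def _genealogy_newick(root: _Node) -> str:
    def rec(node: _Node) -> str:
        bl = (node.parent.time - node.time) if node.parent else 0.0
        if not node.children:
            return f"{node.name}:{bl:.1f}"
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}):{bl:.1f}"

    return rec(root) + ";"


def _evolve_sequences(
    root: _Node, config: SimulationConfig, rng: np.random.Generator
):
    """Drop per-site Poisson K2P mutations along every branch."""
    L = config.seq_length
    p_ts = config.kappa / (config.kappa + 2.0)
    seqs: dict[str, np.ndarray] = {}
    n_mut = n_ts = n_tv = 0
    site_hits = np.zeros(L, dtype=np.int64)
    root_seq = rng.integers(0, 4, size=L).astype(np.int8)

    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if not node.children:
            seqs[node.name] = seq
            continue
        for child in node.children:
            dt = node.time - child.time
            child_seq = seq.copy()
            k = rng.poisson(config.mu * dt * L)
            for _ in range(k):
                site = int(rng.integers(L))
                site_hits[site] += 1
                b = child_seq[site]
                if rng.random() < p_ts:
                    child_seq[site] = b ^ 1  # A<->G, C<->T
                    n_ts += 1
                else:
                    # one of the two bases of the other chemical class
                    other = 2 - (b // 2) * 2  # 2 if purine, 0 if pyrimidine
                    child_seq[site] = other + int(rng.integers(2))
                    n_tv += 1
                n_mut += 1
            stack.append((child, child_seq))
    return seqs, n_mut, n_ts, n_tv, int((site_hits > 1).sum())


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[AlignedSequenceSet, SampleMetadata, SimulationTruth]:
    """Generate one dataset: alignment, field metadata and ground truth.

    Introgressed individuals keep their recipient species as the field
    label (that is the point: field label and matriline disagree); the
    truth table records their donor.
    """
    rng = np.random.default_rng(config.seed)
    root, split, introgressed = _build_genealogy(config, rng)
    seqs, n_mut, n_ts, n_tv, n_homoplasic = _evolve_sequences(root, config, rng)

    ids = sorted(seqs)
    decode = np.array(list(BASES))
    alignment = AlignedSequenceSet(
        ids=tuple(ids),
        seqs=tuple("".join(decode[seqs[i]]) for i in ids),
        filter_mode="complete_deletion",
    )
    metadata = SampleMetadata(
        SampleRecord(individual_id=i, species=i.rsplit("_", 1)[0]) for i in ids
    )
    truth = SimulationTruth(
        genealogy_newick=_genealogy_newick(root),
        split_times=dict(split),
        introgressed=tuple(sorted(introgressed)),
        n_mutations=n_mut,
        n_transitions=n_ts,
        n_transversions=n_tv,
        n_homoplasic_sites=n_homoplasic,
    )
    return alignment, metadata, truth


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

_RADIATION_TREE = (
    "(vetulus:1353000,(sechurae:964000,((fulvipes:706000,gymnocercus:706000)"
    ":190000,(culpaeus:366000,griseus:366000):530000):68000):389000);"
)

FIXTURES: dict[str, SimulationConfig] = {
    "two_species_clean": SimulationConfig(
        species_tree="(alpha:1000000,beta:1000000);",
        sample_sizes={"alpha": 12, "beta": 12},
        seed=11,
    ),
    # a six-species radiation shaped like a recent fox-like diversification:
    # basal split 1.353 My, youngest 0.366 My, 118 individuals
    "six_species_radiation": SimulationConfig(
        species_tree=_RADIATION_TREE,
        sample_sizes={
            "culpaeus": 32, "vetulus": 27, "griseus": 28,
            "gymnocercus": 24, "fulvipes": 6, "sechurae": 1,
        },
        seed=42,
    ),
    # six recipient individuals carrying donor matrilines from a recent
    # hybridization (20 ky); field labels stay with the recipient species
    "introgression_6": SimulationConfig(
        species_tree=_RADIATION_TREE,
        sample_sizes={
            "culpaeus": 32, "vetulus": 27, "griseus": 22,
            "gymnocercus": 30, "fulvipes": 6, "sechurae": 1,
        },
        introgression=(
            IntrogressionEvent(
                donor="griseus", recipient="gymnocercus",
                n_individuals=6, time=20_000.0,
            ),
        ),
        seed=7,
    ),
}


def make_fixture(name: str, outdir=None, seed: int | None = None):
    """Build a registered toy dataset; optionally write it to ``outdir``.

    Writes ``alignment.fasta``, ``metadata.tsv``, ``truth_genealogy.nwk``
    and ``truth.tsv`` (split times and introgressed individuals) when
    ``outdir`` is given. Returns (alignment, metadata, truth).
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    config = FIXTURES[name]
    if seed is not None:
        config = replace(config, seed=seed)
    alignment, metadata, truth = simulate_dataset(config)
    if outdir is not None:
        from pathlib import Path

        from .seq_io import write_alignment, write_metadata

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(alignment, outdir / "alignment.fasta")
        write_metadata(metadata, outdir / "metadata.tsv")
        (outdir / "truth_genealogy.nwk").write_text(truth.genealogy_newick + "\n")
        with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("record\tkey\tvalue\n")
            for pair, t in sorted(truth.split_times.items(), key=lambda kv: sorted(kv[0])):
                fh.write(f"split_time\t{'|'.join(sorted(pair))}\t{t:.1f}\n")
            for ind, donor in truth.introgressed:
                fh.write(f"introgressed\t{ind}\t{donor}\n")
            fh.write(f"n_mutations\ttotal\t{truth.n_mutations}\n")
    return alignment, metadata, truth
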