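"""Haplotype collapsing and alignment site statistics.

A haplotype is an exact-match equivalence class of sequences over the
retained alignment columns; collapsing the alignment into haplotypes is
the entry point for diversity indices, the haplotype network and the
tree analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .seq_io import AlignedSequenceSet, MISSING_STATES, SampleMetadata

BASES = "ACGT"

SITE_CONSTANT = "constant"
SITE_SINGLETON = "variable_singleton"
SITE_INFORMATIVE = "parsimony_informative"


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


class HaplotypeTable:
    """Distinct sequences with their carriers.

    Haplotype ids are assigned in order of first appearance in the
    alignment (H1, H2, ...), so permuting the input records changes ids
    but never the partition of individuals.
    """

    def __init__(self, haplotypes: list[Haplotype], alignment_length: int):
        self.haplotypes = list(haplotypes)
        self.alignment_length = alignment_length
        self._by_id = {h.haplotype_id: h for h in self.haplotypes}
        self._hap_of_member = {
            m: h.haplotype_id for h in self.haplotypes for m in h.members
        }

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def __getitem__(self, haplotype_id: str) -> Haplotype:
        return self._by_id[haplotype_id]

    @property
    def n_individuals(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def counts(self) -> tuple[int, ...]:
        return tuple(h.count for h in self.haplotypes)

    def haplotype_of(self, individual_id: str) -> str:
        return self._hap_of_member[individual_id]

    def expand(self) -> dict[str, str]:
        """individual_id -> sequence (inverse of collapsing)."""
        return {m: h.sequence for h in self.haplotypes for m in h.members}

    def to_alignment(self) -> AlignedSequenceSet:
        """One sequence per haplotype, ids = haplotype ids."""
        return AlignedSequenceSet(
            ids=tuple(h.haplotype_id for h in self.haplotypes),
            seqs=tuple(h.sequence for h in self.haplotypes),
            filter_mode="complete_deletion",
        )

    def species_composition(self, metadata: SampleMetadata) -> dict[str, Counter]:
        """haplotype_id -> Counter of species labels among its members."""
        return {
            h.haplotype_id: Counter(metadata.species_of(m) for m in h.members)
            for h in self.haplotypes
        }

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("haplotype_id\tcount\tmembers\tsequence\n")
            for h in self.haplotypes:
                fh.write(
                    f"{h.haplotype_id}\t{h.count}\t{','.join(h.members)}\t{h.sequence}\n"
                )


def _require_filtered(alignment: AlignedSequenceSet, what: str) -> None:
    if alignment.has_missing():
        raise ValueError(
            f"{what} requires a complete-deletion filtered alignment with no "
            "N or '-' states; re-read with filter_mode='complete_deletion'"
        )


def collapse_haplotypes(alignment: AlignedSequenceSet) -> HaplotypeTable:
    """Collapse sequences into exact-equality haplotype classes."""
    _require_filtered(alignment, "haplotype collapsing")
    order: dict[str, list[str]] = {}
    for seq_id, seq in alignment.items():
        order.setdefault(seq, []).append(seq_id)
    haplotypes = [
        Haplotype(haplotype_id=f"H{k}", sequence=seq, members=tuple(members))
        for k, (seq, members) in enumerate(order.items(), start=1)
    ]
    return HaplotypeTable(haplotypes, alignment_length=alignment.length)


@dataclass(frozen=True)
class SiteClassification:
    """Per-column category and state counts for a filtered alignment."""

    categories: tuple[str, ...]
    state_counts: tuple[dict, ...]

    @property
    def n_variable(self) -> int:
        return sum(c != SITE_CONSTANT for c in self.categories)

    @property
    def n_informative(self) -> int:
        return sum(c == SITE_INFORMATIVE for c in self.categories)

    @property
    def n_constant(self) -> int:
        return sum(c == SITE_CONSTANT for c in self.categories)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("column\tcategory\t" + "\t".join(BASES) + "\n")
            for j, (cat, counts) in enumerate(
                zip(self.categories, self.state_counts), start=1
            ):
                row = "\t".join(str(counts.get(b, 0)) for b in BASES)
                fh.write(f"{j}\t{cat}\t{row}\n")


def classify_sites(alignment: AlignedSequenceSet) -> SiteClassification:
    """Classify every retained column as constant, singleton-variable or
    parsimony informative.

    A column is variable iff it carries >= 2 distinct states, and
    parsimony informative iff >= 2 states are each carried by >= 2
    sequences.
    """
    _require_filtered(alignment, "site classification")
    if alignment.n < 2:
        raise ValueError("site classification requires at least 2 sequences")
    categories = []
    state_counts = []
    for j in range(alignment.length):
        counts = Counter(s[j] for s in alignment.seqs)
        if len(counts) == 1:
            cat = SITE_CONSTANT
        elif sum(v >= 2 for v in counts.values()) >= 2:
            cat = SITE_INFORMATIVE
        else:
            cat = SITE_SINGLETON
        categories.append(cat)
        state_counts.append(dict(counts))
    return SiteClassification(tuple(categories), tuple(state_counts))


def base_composition(
    alignment: AlignedSequenceSet, basis: str = "individuals"
) -> dict[str, float]:
    """Frequencies of A, C, G, T over all retained cells.

    ``basis='individuals'`` counts every sequence (the default);
    ``basis='haplotypes'`` counts each distinct haplotype once, since for
    published datasets it is often unclear which basis was used.
    Frequencies sum to 1.
    """
    if basis == "individuals":
        seqs = alignment.seqs
    elif basis == "haplotypes":
        seqs = tuple({s: None for s in alignment.seqs})
    else:
        raise ValueError("basis must be 'individuals' or 'haplotypes'")
    counts = Counter()
    for s in seqs:
        counts.update(s)
    for state in MISSING_STATES:
        counts.pop(state, None)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("alignment has no unambiguous cells")
    return {b: counts.get(b, 0) / total for b in BASES}


def shared_haplotypes(
    table: HaplotypeTable, metadata: SampleMetadata
) -> list[tuple[str, tuple[str, ...]]]:
    """Haplotypes carried by more than one species.

    Returns ``[(haplotype_id, (species, ...)), ...]``; empty when every
    haplotype is private to a single species (reciprocal sorting at the
    haplotype level).
    """
    out = []
    for hap_id, comp in table.species_composition(metadata).items():
        if len(comp) > 1:
            out.append((hap_id, tuple(sorted(comp))))
    return out
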