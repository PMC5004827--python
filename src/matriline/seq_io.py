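"""Reading, filtering and writing aligned mtDNA sequence data.

The analyses downstream (haplotype collapsing, site classification, K2P
distances, networks) all operate on a column-filtered alignment in which
every retained column carries an unambiguous base in every sequence
("complete deletion" of ambiguous/gapped columns). This module owns that
filtering rule and the validation of inputs.

Conventions
-----------
* Sequences are uppercase strings over ``{A, C, G, T, N, -}``; IUPAC
  ambiguity codes other than N (R, Y, S, W, K, M, B, D, H, V) are mapped
  to N on input and counted in a warning.
* ``-`` (gap) is treated as missing data, never as a fifth state.
* Column indices are 0-based half-open internally; all user-facing
  reports use 1-based indices of the *original* (pre-filter) alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_STATES = frozenset("ACGTN-")
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")
MISSING_STATES = frozenset("N-")

FILTER_MODES = ("complete_deletion", "pairwise", "none")


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged rows, empty input)."""


class SequenceParseError(ValueError):
    """Raised for illegal characters; names the offending record and column."""


class MetadataError(ValueError):
    """Raised for inconsistent sample metadata."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An aligned set of homologous sequences after optional column filtering.

    Attributes
    ----------
    ids : tuple of str
        Sequence identifiers, unique, in input order.
    seqs : tuple of str
        Uppercase sequences over ``{A,C,G,T,N,-}``, all of equal length.
    excluded_columns : tuple of int
        1-based indices (in the original alignment) of columns removed by
        complete-deletion filtering. Empty when no filtering was applied.
    filter_mode : str
        One of ``complete_deletion``, ``pairwise``, ``none``.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    excluded_columns: tuple[int, ...] = field(default=())
    filter_mode: str = "complete_deletion"

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment contains no sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.length == 0:
            raise AlignmentError("alignment has zero columns")

    @property
    def length(self) -> int:
        """Number of retained alignment columns."""
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def sequence(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def subset(self, keep_ids: Iterable[str]) -> "AlignedSequenceSet":
        """Restrict to a subset of sequences, preserving input order."""
        keep = set(keep_ids)
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        pairs = [(i, s) for i, s in zip(self.ids, self.seqs) if i in keep]
        return AlignedSequenceSet(
            ids=tuple(i for i, _ in pairs),
            seqs=tuple(s for _, s in pairs),
            excluded_columns=self.excluded_columns,
            filter_mode=self.filter_mode,
        )

    def has_missing(self) -> bool:
        return any(set(s) & MISSING_STATES for s in self.seqs)

    def items(self):
        return zip(self.ids, self.seqs)


def _normalize_sequence(raw: str, record_id: str) -> tuple[str, int]:
    """Uppercase, map extended ambiguity codes to N; reject anything else.

    Returns the canonical sequence and the number of mapped ambiguity codes.
    """
    seq = raw.upper()
    n_mapped = 0
    out = []
    for col, ch in enumerate(seq, start=1):
        if ch in VALID_STATES:
            out.append(ch)
        elif ch in AMBIGUITY_CODES:
            out.append("N")
            n_mapped += 1
        else:
            raise SequenceParseError(
                f"illegal character {ch!r} in record {record_id!r} at column {col}"
            )
    return "".join(out), n_mapped


def filter_columns(
    ids: Iterable[str], seqs: Iterable[str], mode: str = "complete_deletion"
) -> AlignedSequenceSet:
    """Apply the column-exclusion rule to already-validated sequences.

    In ``complete_deletion`` mode every column containing N or '-' in any
    sequence is removed and recorded (1-based) in ``excluded_columns``.
    ``pairwise`` and ``none`` keep all columns; pairwise deletion is then
    the distance kernel's responsibility.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"filter_mode must be one of {FILTER_MODES}, got {mode!r}")
    ids = tuple(ids)
    seqs = tuple(seqs)
    if mode != "complete_deletion":
        return AlignedSequenceSet(ids=ids, seqs=seqs, excluded_columns=(), filter_mode=mode)

    length = len(seqs[0]) if seqs else 0
    bad = sorted(
        {j for s in seqs for j, ch in enumerate(s) if ch in MISSING_STATES}
    )
    if len(bad) == length:
        raise AlignmentError("complete deletion removed every column")
    bad_set = set(bad)
    kept = [j for j in range(length) if j not in bad_set]
    new_seqs = tuple("".join(s[j] for j in kept) for s in seqs)
    if bad:
        logger.warning("complete deletion removed %d of %d columns", len(bad), length)
    return AlignedSequenceSet(
        ids=ids,
        seqs=new_seqs,
        excluded_columns=tuple(j + 1 for j in bad),
        filter_mode="complete_deletion",
    )


def read_alignment(fasta_path, filter_mode: str = "complete_deletion") -> AlignedSequenceSet:
    """Read an aligned multi-FASTA and apply the column-exclusion rule.

    Raises
    ------
    AlignmentError
        Empty file or ragged (unequal-length) records.
    SequenceParseError
        A character outside the IUPAC nucleotide alphabet.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {fasta_path}")
    ids = []
    seqs = []
    total_mapped = 0
    for rec in records:
        seq, n_mapped = _normalize_sequence(str(rec.seq), rec.id)
        ids.append(rec.id)
        seqs.append(seq)
        total_mapped += n_mapped
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"records have unequal lengths {sorted(lengths)}: input is not an alignment"
        )
    if total_mapped:
        logger.warning(
            "mapped %d extended ambiguity codes (R,Y,...) to N", total_mapped
        )
    return filter_columns(ids, seqs, mode=filter_mode)


def write_alignment(alignment: AlignedSequenceSet, fasta_path) -> None:
    """Write the (filtered) alignment as plain multi-FASTA."""
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in alignment.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def write_exclusion_report(alignment: AlignedSequenceSet, tsv_path) -> None:
    """Write the removed columns (1-based original indices) as a TSV."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("excluded_column_1based\n")
        for col in alignment.excluded_columns:
            fh.write(f"{col}\n")


@dataclass(frozen=True)
class SampleRecord:
    individual_id: str
    species: str
    locality: str | None = None
    group: str | None = None


class SampleMetadata(Mapping):
    """Mapping of individual_id -> :class:`SampleRecord`.

    Every individual in the alignment it was validated against has exactly
    one record; extra rows (individuals absent from the alignment) are
    allowed and produce a warning at read time.
    """

    def __init__(self, records: Iterable[SampleRecord]):
        self._records: dict[str, SampleRecord] = {}
        for rec in records:
            if rec.individual_id in self._records:
                raise MetadataError(f"duplicate individual_id {rec.individual_id!r}")
            if not rec.species:
                raise MetadataError(
                    f"empty species label for individual {rec.individual_id!r}"
                )
            self._records[rec.individual_id] = rec

    def __getitem__(self, key: str) -> SampleRecord:
        return self._records[key]

    def __iter__(self):
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def species_of(self, individual_id: str) -> str:
        return self._records[individual_id].species

    def species_labels(self) -> tuple[str, ...]:
        """Distinct species labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self._records.values():
            seen.setdefault(rec.species, None)
        return tuple(seen)

    def by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rec in self._records.values():
            out.setdefault(rec.species, []).append(rec.individual_id)
        return out

    def validate_against(self, alignment: AlignedSequenceSet) -> None:
        missing = [i for i in alignment.ids if i not in self._records]
        if missing:
            raise MetadataError(
                f"alignment ids missing from metadata: {missing}"
            )
        extra = [i for i in self._records if i not in set(alignment.ids)]
        if extra:
            warnings.warn(
                f"{len(extra)} metadata rows have no sequence in the alignment: "
                f"{extra[:10]}",
                stacklevel=2,
            )


def read_metadata(tsv_path, alignment: AlignedSequenceSet) -> SampleMetadata:
    """Read the sample metadata TSV and validate it against the alignment.

    Expected header: ``individual_id``, ``species`` (required) and
    optionally ``locality`` and ``group``.
    """
    import csv

    tsv_path = Path(tsv_path)
    with open(tsv_path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise MetadataError(f"{tsv_path} is empty")
        required = {"individual_id", "species"}
        missing_cols = required - set(reader.fieldnames)
        if missing_cols:
            raise MetadataError(
                f"metadata is missing required columns: {sorted(missing_cols)}"
            )
        records = [
            SampleRecord(
                individual_id=row["individual_id"].strip(),
                species=row["species"].strip(),
                locality=(row.get("locality") or None),
                group=(row.get("group") or None),
            )
            for row in reader
        ]
    meta = SampleMetadata(records)
    meta.validate_against(alignment)
    return meta


def write_metadata(metadata: SampleMetadata, tsv_path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("individual_id\tspecies\tlocality\tgroup\n")
        for rec in metadata.values():
            fh.write(
                f"{rec.individual_id}\t{rec.species}\t{rec.locality or ''}\t{rec.group or ''}\n"
            )
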