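"""Sequence and alignment-hit I/O.

FASTA reading/writing goes through Biopython.  Local alignment hits are
consumed from a fixed 10-column TAB-separated dialect (BLAST-tabular-like):

    query_id  reference_id  identities  alignment_length
    query_start  query_end  ref_start  ref_end  evalue  score

Coordinates are 1-based inclusive; a reference hit with start > end encodes a
minus-strand match.  Reference accessions are resolved to taxon ids through a
2-column mapping table; hits whose accession is absent from the mapping are
dropped and counted, never silently lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = (
    "query_id", "reference_id", "identities", "alignment_length",
    "query_start", "query_end", "ref_start", "ref_end", "evalue", "score",
)


class SequenceError(ValueError):
    pass


class AlignmentParseError(ValueError):
    pass


class SequenceStore:
    """Uppercase nucleotide sequences keyed by unique id."""

    def __init__(self, sequences: Optional[dict[str, str]] = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for sid, seq in sequences.items():
                self.add(sid, seq)

    def add(self, seq_id: str, sequence: str) -> None:
        if seq_id in self._seqs:
            raise SequenceError(f"duplicate sequence id {seq_id!r}")
        if not sequence:
            raise SequenceError(f"empty sequence for id {seq_id!r}")
        self._seqs[seq_id] = sequence.upper()

    def __getitem__(self, seq_id: str) -> str:
        try:
            return self._seqs[seq_id]
        except KeyError:
            raise SequenceError(f"unknown sequence id {seq_id!r}") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self):
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    def length(self, seq_id: str) -> int:
        return len(self[seq_id])


@dataclass
class LocalAlignmentRecord:
    """One local alignment hit of a query against a reference sequence."""

    query_id: str
    reference_id: str
    query_start: int  # 1-based inclusive, start <= end
    query_end: int
    ref_start: int    # as given by the aligner; start > end encodes minus strand
    ref_end: int
    score: float
    identities: int
    alignment_length: int
    evalue: Optional[float] = None
    reference_taxon: Optional[int] = None

    @property
    def minus_strand(self) -> bool:
        return self.ref_start > self.ref_end

    @property
    def ref_low(self) -> int:
        return min(self.ref_start, self.ref_end)

    @property
    def ref_high(self) -> int:
        return max(self.ref_start, self.ref_end)

    def __post_init__(self):
        if not (1 <= self.query_start <= self.query_end):
            raise AlignmentParseError(
                f"bad query interval [{self.query_start},{self.query_end}] for {self.query_id}"
            )
        if self.identities > self.alignment_length:
            raise AlignmentParseError(
                f"identities {self.identities} exceed alignment length {self.alignment_length}"
            )


def read_fasta(path) -> SequenceStore:
    """Load a FASTA file; the header token before the first whitespace is the id."""
    store = SequenceStore()
    for record in SeqIO.parse(str(path), "fasta"):
        store.add(record.id, str(record.seq))
    return store


def write_fasta(store: SequenceStore, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in sorted(store):
            fh.write(f">{sid}\n")
            seq = store[sid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mapping(path) -> dict[str, int]:
    """2-column TSV: reference accession -> taxon_id."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AlignmentParseError(f"{path}:{ln}: expected 2 columns")
            mapping[parts[0]] = int(parts[1])
    return mapping


def write_mapping(mapping: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(mapping):
            fh.write(f"{acc}\t{mapping[acc]}\n")


def parse_alignments(
    path,
    mapping: dict[str, int],
    taxonomy: Optional[TaxonomyTree] = None,
) -> list[LocalAlignmentRecord]:
    """Parse the tabular alignment dialect, resolving reference taxa.

    Rows whose accession is missing from the mapping (or whose mapped taxon is
    absent from the taxonomy, when one is given) are dropped and counted in a
    single warning.  Malformed rows raise with their line number.
    """
    records: list[LocalAlignmentRecord] = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(ALIGNMENT_COLUMNS):
                raise AlignmentParseError(
                    f"{path}:{ln}: expected {len(ALIGNMENT_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                rec = LocalAlignmentRecord(
                    query_id=parts[0],
                    reference_id=parts[1],
                    identities=int(parts[2]),
                    alignment_length=int(parts[3]),
                    query_start=int(parts[4]),
                    query_end=int(parts[5]),
                    ref_start=int(parts[6]),
                    ref_end=int(parts[7]),
                    evalue=float(parts[8]),
                    score=float(parts[9]),
                )
            except (ValueError, AlignmentParseError) as exc:
                raise AlignmentParseError(f"{path}:{ln}: {exc}") from None
            taxon = mapping.get(rec.reference_id)
            if taxon is None or (taxonomy is not None and taxon not in taxonomy):
                dropped += 1
                continue
            rec.reference_taxon = taxon
            records.append(rec)
    if dropped:
        logger.warning("dropped %d alignment rows with unmapped accessions", dropped)
    return records


def write_alignments(records: list[LocalAlignmentRecord], path) -> None:
    """Write records in the same 10-column dialect parse_alignments reads."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in records:
            ev = 0.0 if r.evalue is None else r.evalue
            fh.write(
                f"{r.query_id}\t{r.reference_id}\t{r.identities}\t{r.alignment_length}\t"
                f"{r.query_start}\t{r.query_end}\t{r.ref_start}\t{r.ref_end}\t"
                f"{ev:g}\t{r.score:g}\n"
            )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def subsequence(store: SequenceStore, seq_id: str, start: int, end: int, minus_strand: bool = False) -> str:
    """1-based inclusive slice; reverse-complemented when minus_strand."""
    seq = store[seq_id]
    if not (1 <= start <= end <= len(seq)):
        raise SequenceError(
            f"slice [{start},{end}] out of bounds for {seq_id!r} (length {len(seq)})"
        )
    sub = seq[start - 1 : end]
    return reverse_complement(sub) if minus_strand else sub
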