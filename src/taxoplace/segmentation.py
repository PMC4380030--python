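"""Query segmentation and reference-segment extension.

Overlapping local-alignment regions on a query are merged into maximal
segments (interval-union connected components; sharing at least one base —
merely abutting intervals stay separate).  For every contributing hit the
matched reference region is extended on both sides by the number of query
bases the hit is short of its segment, so that each reference segment is
length-matched to the query segment; extensions are clipped at reference
sequence boundaries without redistribution, which is the only case where a
reference segment comes out shorter.  Minus-strand reference segments are
reverse-complemented into query orientation, so every downstream pairwise
alignment is same-orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqdata import LocalAlignmentRecord, SequenceStore, subsequence


@dataclass(frozen=True)
class QuerySegment:
    """Maximal homology-supported interval on a query (1-based inclusive)."""

    query_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReferenceSegment:
    """Length-matched, query-oriented homolog of one query segment."""

    reference_id: str
    reference_taxon: int
    start: int
    end: int
    minus_strand: bool
    sequence: str
    source_score: float
    source_identities: int


@dataclass
class HomologSet:
    """One query segment with its homologous reference segments."""

    segment: QuerySegment
    query_sequence: str
    homologs: list[ReferenceSegment]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; abutting intervals not merged."""
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:  # shares >=1 base with the running interval
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def extend_reference(
    record: LocalAlignmentRecord,
    segment: QuerySegment,
    reference_store: SequenceStore,
) -> ReferenceSegment:
    """Extend the hit's reference interval to match the query segment length.

    The left/right query deficits are applied on the reference in query
    orientation (swapped for minus-strand hits) and clipped at the reference
    ends without redistributing the shortfall.
    """
    if not (segment.start <= record.query_start and record.query_end <= segment.end):
        raise ValueError(
            f"hit query interval [{record.query_start},{record.query_end}] "
            f"not contained in segment [{segment.start},{segment.end}]"
        )
    left = record.query_start - segment.start
    right = segment.end - record.query_end
    if record.minus_strand:
        left, right = right, left
    lo = record.ref_low - left
    hi = record.ref_high + right
    ref_len = reference_store.length(record.reference_id)
    lo = max(1, lo)
    hi = min(ref_len, hi)
    seq = subsequence(reference_store, record.reference_id, lo, hi, record.minus_strand)
    if record.reference_taxon is None:
        raise ValueError(f"record for {record.reference_id} has unresolved taxon")
    return ReferenceSegment(
        reference_id=record.reference_id,
        reference_taxon=record.reference_taxon,
        start=lo,
        end=hi,
        minus_strand=record.minus_strand,
        sequence=seq,
        source_score=record.score,
        source_identities=record.identities,
    )


def build_segments(
    records: list[LocalAlignmentRecord],
    query_store: SequenceStore,
    reference_store: SequenceStore,
) -> list[HomologSet]:
    """Merge one query's hits into segments and attach extended homologs.

    All records must share one query_id.  Each record contributes exactly one
    ReferenceSegment to exactly one HomologSet; unaligned flanking query
    regions appear in no segment.  Output is sorted by segment start and is
    invariant under permutation of the input records.
    """
    if not records:
        return []
    query_ids = {r.query_id for r in records}
    if len(query_ids) != 1:
        raise ValueError(f"records span multiple queries: {sorted(query_ids)}")
    query_id = records[0].query_id
    merged = merge_intervals([(r.query_start, r.query_end) for r in records])
    segments = [QuerySegment(query_id, lo, hi) for lo, hi in merged]

    out = []
    for seg in segments:
        members = [
            r for r in records if seg.start <= r.query_start and r.query_end <= seg.end
        ]
        members.sort(key=lambda r: (r.query_start, r.query_end, r.reference_id, r.ref_low))
        homologs = [extend_reference(r, seg, reference_store) for r in members]
        qseq = subsequence(query_store, query_id, seg.start, seg.end)
        out.append(HomologSet(segment=seg, query_sequence=qseq, homologs=homologs))
    return out
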