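"""Orchestration of the three-stage workflow over whole samples.

Stage 1 (local alignment) is consumed from tabular files; stage 2 segments
each query and places every segment; stage 3 bins the per-segment taxa into
one prediction per query.  Queries are independent, so stage 2 runs on a
per-query task pool (threads; the alignment kernel releases the GIL) and the
output is canonically sorted by (query_id, segment start) — results are
bit-identical for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Iterable, Optional, Sequence

from .binner import BinnerConfig, QueryPrediction, bin_sample
from .rpa import SegmentAssignment, rpa_assign
from .segmentation import build_segments
from .seqdata import LocalAlignmentRecord, SequenceStore
from .taxonomy import TaxonomyTree


def group_by_query(records: Iterable[LocalAlignmentRecord]) -> dict[str, list[LocalAlignmentRecord]]:
    grouped: dict[str, list[LocalAlignmentRecord]] = {}
    for r in records:
        grouped.setdefault(r.query_id, []).append(r)
    return grouped


def assign_segments(
    query_store: SequenceStore,
    reference_store: SequenceStore,
    records: Sequence[LocalAlignmentRecord],
    taxonomy: TaxonomyTree,
    workers: int = 1,
) -> list[SegmentAssignment]:
    """Stage 2 for a whole sample: one SegmentAssignment per query segment."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    grouped = group_by_query(records)
    query_ids = sorted(grouped)

    def one_query(qid: str) -> list[SegmentAssignment]:
        out = []
        for hs in build_segments(grouped[qid], query_store, reference_store):
            out.append(rpa_assign(hs, taxonomy))
        return out

    if workers == 1:
        per_query = [one_query(qid) for qid in query_ids]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            per_query = list(pool.map(one_query, query_ids))
    assignments = [a for group in per_query for a in group]
    assignments.sort(key=lambda a: (a.query_id, a.start))
    return assignments


def bin_assignments(
    assignments: Sequence[SegmentAssignment],
    taxonomy: TaxonomyTree,
    config: Optional[BinnerConfig] = None,
) -> dict[str, QueryPrediction]:
    """Stage 3: consensus prediction per query."""
    per_query: dict[str, list[SegmentAssignment]] = {}
    for a in assignments:
        per_query.setdefault(a.query_id, []).append(a)
    return bin_sample(per_query, taxonomy, config)


def classify_sample(
    query_store: SequenceStore,
    reference_store: SequenceStore,
    records: Sequence[LocalAlignmentRecord],
    taxonomy: TaxonomyTree,
    binner_config: Optional[BinnerConfig] = None,
    workers: int = 1,
) -> dict[str, QueryPrediction]:
    """Stages 2 + 3 end-to-end."""
    assignments = assign_segments(query_store, reference_store, records, taxonomy, workers)
    return bin_assignments(assignments, taxonomy, binner_config)


def make_classifier(
    query_store: SequenceStore,
    reference_store: SequenceStore,
    records: Sequence[LocalAlignmentRecord],
    taxonomy: TaxonomyTree,
    binner_config: Optional[BinnerConfig] = None,
):
    """Build the cross-validation callable: (query_id, allowed_reference_taxa)
    -> predicted taxon or None.  Hits to masked reference taxa are filtered
    out before segmentation, so the classifier never sees excluded data."""
    grouped = group_by_query(records)

    def classify(query_id: str, allowed_taxa: frozenset) -> Optional[int]:
        recs = [
            r for r in grouped.get(query_id, [])
            if r.reference_taxon in allowed_taxa
        ]
        if not recs:
            return None
        preds = classify_sample(
            query_store, reference_store, recs, taxonomy, binner_config
        )
        pred = preds.get(query_id)
        return pred.taxon if pred is not None and pred.is_assigned else None

    return classify
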