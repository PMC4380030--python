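"""Consensus binning: one taxon per query by support-weighted majority.

Each assigned segment votes with weight equal to its support (identical
bases to the closest reference segment), and the vote counts for every node
on the root-to-taxon path — a vote for a species is also a vote for its
genus, family and so on.  Starting at the root, the consensus descends to
the unique child holding at least ``majority_fraction`` (default 70%) of the
total support and at least ``min_support`` identical bases (default 50 bp),
and stops where no child qualifies.  Limited or contradictory segment
information therefore falls back to higher-ranking taxa rather than forcing
a deep guess.

Optional filters mirror the tool surface: ``min_identity`` drops segments
whose support/length ratio is too low before voting, and
``min_sample_abundance`` blanks predictions whose taxon bin is too rare
across the whole sample.  Both are off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .rpa import UNASSIGNED_TAXID, SegmentAssignment
from .taxonomy import TaxonomyTree


@dataclass
class BinnerConfig:
    majority_fraction: float = 0.70
    min_support: int = 50
    min_identity: Optional[float] = None
    min_sample_abundance: Optional[float] = None

    def __post_init__(self):
        if not (0.5 < self.majority_fraction <= 1.0):
            raise ValueError("majority_fraction must be in (0.5, 1.0]")
        if self.min_support < 0:
            raise ValueError("min_support must be non-negative")


@dataclass
class QueryPrediction:
    query_id: str
    taxon: Optional[int]  # None = unassigned
    total_support: int
    winning_support: int

    @property
    def is_assigned(self) -> bool:
        return self.taxon is not None


def bin_query(
    assignments: Sequence[SegmentAssignment],
    taxonomy: TaxonomyTree,
    config: Optional[BinnerConfig] = None,
) -> QueryPrediction:
    """Combine one query's segment assignments into a single prediction.

    Unassigned segments carry zero weight and are ignored; segments failing
    the optional identity filter likewise.
    """
    if config is None:
        config = BinnerConfig()
    query_ids = {a.query_id for a in assignments}
    if len(query_ids) > 1:
        raise ValueError(f"assignments span multiple queries: {sorted(query_ids)}")
    query_id = assignments[0].query_id if assignments else ""

    voters = [a for a in assignments if a.is_assigned and a.support > 0]
    if config.min_identity is not None:
        voters = [a for a in voters if a.support / a.length >= config.min_identity]

    if not voters:
        return QueryPrediction(query_id, None, 0, 0)

    weight: dict[int, int] = {}
    total = 0
    for a in voters:
        if a.assigned_taxon not in taxonomy:
            raise ValueError(f"assignment taxon {a.assigned_taxon} absent from taxonomy")
        total += a.support
        for tid in taxonomy.path_to_root(a.assigned_taxon):
            weight[tid] = weight.get(tid, 0) + a.support

    threshold = config.majority_fraction * total
    children: dict[int, list[int]] = {}
    for tid in weight:
        parent = taxonomy.parent(tid)
        if parent != tid:
            children.setdefault(parent, []).append(tid)

    node = taxonomy.root_id
    if weight.get(node, 0) < config.min_support:
        return QueryPrediction(query_id, None, total, 0)
    while True:
        qualifying = [
            c for c in children.get(node, [])
            if weight[c] >= threshold and weight[c] >= config.min_support
        ]
        if len(qualifying) != 1:  # none, or tied children: stop conservatively
            break
        node = qualifying[0]
    return QueryPrediction(query_id, node, total, weight[node])


def bin_sample(
    per_query: dict[str, Sequence[SegmentAssignment]],
    taxonomy: TaxonomyTree,
    config: Optional[BinnerConfig] = None,
) -> dict[str, QueryPrediction]:
    """Bin every query; apply the optional sample-abundance post-filter."""
    if config is None:
        config = BinnerConfig()
    preds = {qid: bin_query(list(asg), taxonomy, config) for qid, asg in per_query.items()}
    if config.min_sample_abundance is not None and preds:
        counts: dict[int, int] = {}
        for p in preds.values():
            if p.is_assigned:
                counts[p.taxon] = counts.get(p.taxon, 0) + 1
        n_assigned = sum(counts.values())
        rare = {t for t, c in counts.items() if c / n_assigned < config.min_sample_abundance}
        for p in preds.values():
            if p.is_assigned and p.taxon in rare:
                p.taxon = None
                p.winning_support = 0
    return preds


# -- GFF3 segment-prediction dialect ----------------------------------------------
#
# One feature per segment: seqid = query_id, type "segment", score = support,
# attributes taxid (0 when unassigned) and seqlen (segment length).

GFF_SOURCE = "taxoplace"


def write_segment_gff3(assignments: Iterable[SegmentAssignment], path) -> None:
    rows = sorted(assignments, key=lambda a: (a.query_id, a.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in rows:
            taxid = a.assigned_taxon if a.is_assigned else UNASSIGNED_TAXID
            fh.write(
                f"{a.query_id}\t{GFF_SOURCE}\tsegment\t{a.start}\t{a.end}\t"
                f"{a.support}\t.\t.\ttaxid={taxid};seqlen={a.length}\n"
            )


def read_segment_gff3(path) -> dict[str, list[SegmentAssignment]]:
    """Read the segment GFF3 dialect back into per-query assignment lists."""
    per_query: dict[str, list[SegmentAssignment]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            taxid = int(attrs.get("taxid", UNASSIGNED_TAXID))
            a = SegmentAssignment(
                query_id=parts[0],
                start=int(parts[3]),
                end=int(parts[4]),
                assigned_taxon=None if taxid == UNASSIGNED_TAXID else taxid,
                support=int(float(parts[5])) if parts[5] != "." else 0,
            )
            per_query.setdefault(a.query_id, []).append(a)
    return per_query


def write_predictions_tsv(preds: dict[str, QueryPrediction], path) -> None:
    """3-column TSV: query_id, taxon_id or 'unassigned', winning_support."""
    with open(path, "w") as fh:
        for qid in sorted(preds):
            p = preds[qid]
            taxon = str(p.taxon) if p.is_assigned else "unassigned"
            fh.write(f"{qid}\t{taxon}\t{p.winning_support}\n")
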