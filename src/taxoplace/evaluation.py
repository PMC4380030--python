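"""Assessment machinery: macro precision/recall, leave-one-taxon-out
cross-validation, and contig-chunk consistency.

All metrics are basepair-weighted and computed per taxonomic rank after
projecting both predictions and truths to that rank.  A prediction above the
evaluated rank (no ancestor at it) is neither correct nor incorrect there —
it simply contributes no rank-level bin.  Before scoring, the smallest
predicted bins are removed as likely noise, up to 1% of total assigned
basepairs.  Macro-precision averages per-bin precision unweighted over the
surviving predicted bins; macro-recall averages the recovered fraction over
the truly existing bins; the overall precision pools correct over assigned
basepairs across the species, genus and family ranks.

For samples without known truth, consistency is measured instead: long
contigs are cut into 2 kb chunks, each chunk classified independently, a
per-contig consensus taxon chosen as the candidate (chunk taxon or ancestor
thereof) matched exactly by the most chunks, and the fraction of chunks
agreeing with their contig's consensus reported per predicted taxon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .taxonomy import TaxonomyTree

#: Fraction of total assigned basepairs allowed to be removed as small bins.
SMALL_BIN_FRACTION = 0.01

#: Chunking constants: contigs longer than CHUNK_MIN_CONTIG are split into
#: CHUNK_SIZE pieces (terminal remainder kept as a short chunk).
CHUNK_MIN_CONTIG = 10_000
CHUNK_SIZE = 2_000

#: Cross-validation scenarios: minimum simulated taxonomic distance between
#: query and reference.  None is the idealized all-data case.
DEFAULT_SCENARIOS: tuple[Optional[str], ...] = (
    None, "species", "genus", "family", "order", "class", "phylum",
)


@dataclass(frozen=True)
class LabeledAssignment:
    """One classified sequence with its true taxon."""

    sequence_id: str
    length: int
    predicted_taxon: Optional[int]  # None = unassigned
    true_taxon: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"non-positive length for {self.sequence_id}")


@dataclass
class BinStats:
    assigned_bp: int = 0
    correct_bp: int = 0


@dataclass
class RankReport:
    """Metrics for one rank after projection and small-bin removal."""

    rank: str
    macro_precision: Optional[float]
    macro_recall: Optional[float]
    predicted_bin_count: int
    true_bin_count: int
    pooled_assigned_bp: int
    pooled_correct_bp: int
    predicted_bins: dict[int, BinStats] = field(default_factory=dict)
    removed_bins: list[int] = field(default_factory=list)


@dataclass
class EvaluationReport:
    per_rank: dict[str, RankReport] = field(default_factory=dict)

    @property
    def overall_precision(self) -> Optional[float]:
        """Pooled species+genus+family correct bp over assigned bp."""
        assigned = correct = 0
        for rank in ("species", "genus", "family"):
            r = self.per_rank.get(rank)
            if r is not None:
                assigned += r.pooled_assigned_bp
                correct += r.pooled_correct_bp
        if assigned == 0:
            return None
        return correct / assigned

    def to_dict(self) -> dict:
        out = {
            "overall_precision": self.overall_precision,
            "ranks": {},
        }
        for rank, r in self.per_rank.items():
            out["ranks"][rank] = {
                "macro_precision": r.macro_precision,
                "macro_recall": r.macro_recall,
                "predicted_bin_count": r.predicted_bin_count,
                "true_bin_count": r.true_bin_count,
            }
        return out

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tmacro_precision\tmacro_recall\tpredicted_bins\ttrue_bins\n")
            for rank, r in self.per_rank.items():
                mp = "NA" if r.macro_precision is None else f"{r.macro_precision:.6f}"
                mr = "NA" if r.macro_recall is None else f"{r.macro_recall:.6f}"
                fh.write(f"{rank}\t{mp}\t{mr}\t{r.predicted_bin_count}\t{r.true_bin_count}\n")
            op = self.overall_precision
            fh.write("overall_species_to_family\t%s\t\t\t\n" % ("NA" if op is None else f"{op:.6f}"))


def evaluate_rank(
    assignments: Sequence[LabeledAssignment],
    taxonomy: TaxonomyTree,
    rank: str,
    small_bin_fraction: float = SMALL_BIN_FRACTION,
) -> RankReport:
    """Compute the rank slice of the evaluation report."""
    if not assignments:
        raise ValueError("empty assignment list")
    taxonomy.rank_index(rank)

    proj_pred: dict[str, Optional[int]] = {}
    proj_true: dict[str, Optional[int]] = {}
    for a in assignments:
        proj_pred[a.sequence_id] = (
            None if a.predicted_taxon is None
            else taxonomy.ancestor_at_rank(a.predicted_taxon, rank)
        )
        proj_true[a.sequence_id] = taxonomy.ancestor_at_rank(a.true_taxon, rank)

    # predicted bins at this rank
    bins: dict[int, BinStats] = {}
    for a in assignments:
        p = proj_pred[a.sequence_id]
        if p is None:
            continue
        st = bins.setdefault(p, BinStats())
        st.assigned_bp += a.length
        if proj_true[a.sequence_id] == p:
            st.correct_bp += a.length

    # greedy small-bin removal (ascending bp) up to 1% of assigned bp
    total_assigned = sum(st.assigned_bp for st in bins.values())
    budget = small_bin_fraction * total_assigned
    removed: list[int] = []
    cum = 0
    for tid in sorted(bins, key=lambda t: (bins[t].assigned_bp, t)):
        if cum + bins[tid].assigned_bp > budget:
            break
        cum += bins[tid].assigned_bp
        removed.append(tid)
    removed_set = set(removed)
    surviving = {t: st for t, st in bins.items() if t not in removed_set}

    macro_precision = (
        sum(st.correct_bp / st.assigned_bp for st in surviving.values()) / len(surviving)
        if surviving else None
    )

    # true bins: removed predictions no longer count as recovered
    true_bins: dict[int, BinStats] = {}
    for a in assignments:
        t = proj_true[a.sequence_id]
        if t is None:
            continue
        st = true_bins.setdefault(t, BinStats())
        st.assigned_bp += a.length  # here: total true bp of the bin
        p = proj_pred[a.sequence_id]
        if p == t and p not in removed_set:
            st.correct_bp += a.length
    macro_recall = (
        sum(st.correct_bp / st.assigned_bp for st in true_bins.values()) / len(true_bins)
        if true_bins else None
    )

    return RankReport(
        rank=rank,
        macro_precision=macro_precision,
        macro_recall=macro_recall,
        predicted_bin_count=len(surviving),
        true_bin_count=len(true_bins),
        pooled_assigned_bp=sum(st.assigned_bp for st in surviving.values()),
        pooled_correct_bp=sum(st.correct_bp for st in surviving.values()),
        predicted_bins=surviving,
        removed_bins=removed,
    )


def evaluate(
    assignments: Sequence[LabeledAssignment],
    taxonomy: TaxonomyTree,
    ranks: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    if ranks is None:
        ranks = taxonomy.rank_ladder
    report = EvaluationReport()
    for rank in ranks:
        report.per_rank[rank] = evaluate_rank(assignments, taxonomy, rank)
    return report


# -- cross-validation --------------------------------------------------------------

Classifier = Callable[[str, frozenset], Optional[int]]


def cross_validate(
    queries: Sequence[tuple[str, int, int]],
    reference_taxa: Iterable[int],
    taxonomy: TaxonomyTree,
    classifier: Classifier,
    scenarios: Sequence[Optional[str]] = DEFAULT_SCENARIOS,
    ranks: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Run the leave-one-taxon-out experiments and pool their assignments.

    `queries` holds (query_id, length, true_taxon).  For each scenario the
    reference taxa sharing the query's clade at the scenario rank are masked
    before calling `classifier(query_id, allowed_reference_taxa)`.  All
    scenario assignments are pooled into one combined report.
    """
    reference_taxa = set(reference_taxa)
    pooled: list[LabeledAssignment] = []
    for scenario in scenarios:
        for qid, length, true_taxon in queries:
            allowed = taxonomy.mask_clade(reference_taxa, true_taxon, scenario)
            predicted = classifier(qid, frozenset(allowed))
            pooled.append(LabeledAssignment(
                sequence_id=f"{scenario or 'none'}:{qid}",
                length=length,
                predicted_taxon=predicted,
                true_taxon=true_taxon,
            ))
    return evaluate(pooled, taxonomy, ranks)


# -- consistency analysis ----------------------------------------------------------

def chunk_intervals(contig_length: int) -> list[tuple[int, int]]:
    """1-based inclusive chunk intervals; contigs <= 10 kb are not chunked,
    longer ones are cut into 2 kb chunks with a short terminal remainder."""
    if contig_length <= CHUNK_MIN_CONTIG:
        return [(1, contig_length)]
    out = []
    start = 1
    while start <= contig_length:
        out.append((start, min(start + CHUNK_SIZE - 1, contig_length)))
        start += CHUNK_SIZE
    return out


@dataclass
class ConsistencyReport:
    contig_taxa: dict[str, int]
    per_taxon_consistency: dict[int, float]
    macro_consistency: Optional[float]
    overall_consistency: Optional[float]

    def to_dict(self) -> dict:
        return {
            "macro_consistency": self.macro_consistency,
            "overall_consistency": self.overall_consistency,
            "per_taxon_consistency": {str(t): v for t, v in self.per_taxon_consistency.items()},
        }


def consistency_analysis(
    contig_chunks: dict[str, Sequence[tuple[Optional[int], int]]],
    taxonomy: TaxonomyTree,
) -> ConsistencyReport:
    """Chunk-level agreement with a per-contig consensus taxon.

    `contig_chunks` maps contig id to (predicted_taxon_or_None, chunk_length)
    pairs.  The contig taxon is the candidate (an assigned chunk taxon or any
    ancestor of one) matched exactly by the most chunks; ties prefer the
    deepest candidate, then the smallest taxon id.  Consistency of a taxon
    bin is the fraction of its chunks (by count) whose assignment equals
    their contig's taxon.
    """
    contig_taxa: dict[str, int] = {}
    per_taxon: dict[int, list[int]] = {}  # taxon -> [matches, chunks]
    matched = assigned = 0

    for contig, chunks in contig_chunks.items():
        taxa = [t for t, _ in chunks if t is not None]
        if not taxa:
            continue
        candidates: set[int] = set()
        for t in taxa:
            candidates.update(taxonomy.path_to_root(t))
        best = max(
            candidates,
            key=lambda c: (sum(1 for t in taxa if t == c), taxonomy.depth(c), -c),
        )
        contig_taxa[contig] = best
        for t in taxa:
            stats = per_taxon.setdefault(t, [0, 0])
            stats[1] += 1
            assigned += 1
            if t == best:
                stats[0] += 1
                matched += 1

    per_taxon_consistency = {t: m / n for t, (m, n) in per_taxon.items()}
    macro = (
        sum(per_taxon_consistency.values()) / len(per_taxon_consistency)
        if per_taxon_consistency else None
    )
    overall = matched / assigned if assigned else None
    return ConsistencyReport(contig_taxa, per_taxon_consistency, macro, overall)


# -- labeled-assignment TSV dialect ------------------------------------------------

def read_labeled_tsv(path) -> list[LabeledAssignment]:
    """TSV of (sequence_id, length, predicted_taxon, true_taxon); predicted
    may be 'unassigned' or 0."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            pred: Optional[int]
            if parts[2] in ("unassigned", "0", ""):
                pred = None
            else:
                pred = int(parts[2])
            out.append(LabeledAssignment(parts[0], int(parts[1]), pred, int(parts[3])))
    return out


def write_labeled_tsv(assignments: Sequence[LabeledAssignment], path) -> None:
    with open(path, "w") as fh:
        for a in assignments:
            pred = "unassigned" if a.predicted_taxon is None else str(a.predicted_taxon)
            fh.write(f"{a.sequence_id}\t{a.length}\t{pred}\t{a.true_taxon}\n")
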