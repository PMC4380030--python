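"""Realignment placement: assign a taxon to one query segment.

The placement approximates the query's evolutionary neighborhood with a
linear number of pairwise alignments instead of a multiple alignment and a
tree.  Under a roughly constant rate of evolution (ultrametric distances),
any two members of a monophyletic clade are closer to each other than either
is to anything outside the clade, so the clade around the query can be
recovered with distance thresholds anchored at two segments:

0.  The pivot ``s`` is the reference segment with the best input aligner
    score against the query ``q``.
1.  Pass one aligns every segment (and ``q``) to ``s``; taxa at edit
    distance ``<= d(s, q)`` join the working set ``M``.
2.  The outgroup ``o`` is the segment nearest to ``s`` that is strictly
    farther than ``q``; it pulls the final assignment one node above the
    query's sister clade.  Pass two aligns everything to ``o`` and adds taxa
    at distance ``<= d(o, q)`` to ``M``.
3.  The assignment is the LCA of ``M`` in the reference taxonomy; if no
    outgroup exists, fewer than two homologs are available, or the LCA is
    the taxonomy root, the segment stays unassigned.

Distances are raw unit-cost edit distances between the oriented segment
strings (segments in one homolog set are length-matched by construction, so
no normalization is applied).  Exactly ``2n`` alignments are performed for
``n`` homologs when both passes run.  The pairwise kernel also reports the
number of identical aligned bases, maximized over all cost-optimal
alignments; the match count between ``q`` and ``s`` is the segment's support,
the vote weight used by the consensus binner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .segmentation import HomologSet, ReferenceSegment
from .taxonomy import TaxonomyTree

#: Sentinel for "no taxon assigned" in file outputs (API uses None).
UNASSIGNED_TAXID = 0

# A/C/G/T -> 0..3, N and anything else -> 4.  Code 4 never matches, not even
# itself: N is treated as a mismatch against everything for conservative
# distance estimates.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True, nogil=True)
def _edit_dp(a: np.ndarray, b: np.ndarray):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    prev_d = np.empty(m + 1, dtype=np.int32)
    prev_m = np.empty(m + 1, dtype=np.int32)
    cur_d = np.empty(m + 1, dtype=np.int32)
    cur_m = np.empty(m + 1, dtype=np.int32)
    for j in range(m + 1):
        prev_d[j] = j
        prev_m[j] = 0
    for i in range(1, n + 1):
        cur_d[0] = i
        cur_m[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            is_match = ai == b[j - 1] and ai != 4
            # diagonal
            best_d = prev_d[j - 1] + (0 if is_match else 1)
            best_m = prev_m[j - 1] + (1 if is_match else 0)
            # deletion (gap in b)
            d = prev_d[j] + 1
            if d < best_d or (d == best_d and prev_m[j] > best_m):
                best_d = d
                best_m = prev_m[j]
            # insertion (gap in a)
            d = cur_d[j - 1] + 1
            if d < best_d or (d == best_d and cur_m[j - 1] > best_m):
                best_d = d
                best_m = cur_m[j - 1]
            cur_d[j] = best_d
            cur_m[j] = best_m
        prev_d, cur_d = cur_d, prev_d
        prev_m, cur_m = cur_m, prev_m
    return prev_d[m], prev_m[m]


def edit_distance_with_matches(a: str, b: str) -> tuple[int, int]:
    """Levenshtein distance and identical-base count of an optimal global
    alignment (matches maximized among cost-optimal alignments)."""
    if not a or not b:
        raise ValueError("edit distance of empty sequence")
    d, m = _edit_dp(encode(a), encode(b))
    return int(d), int(m)


def edit_distance(a: str, b: str) -> int:
    return edit_distance_with_matches(a, b)[0]


@dataclass
class SegmentAssignment:
    """Placement result for one query segment."""

    query_id: str
    start: int
    end: int
    assigned_taxon: Optional[int]  # None = unassigned
    support: int
    neighborhood: set[int] = field(default_factory=set)
    pivot_taxon: Optional[int] = None
    outgroup_taxon: Optional[int] = None
    alignment_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_assigned(self) -> bool:
        return self.assigned_taxon is not None


def _pivot_key(h: ReferenceSegment):
    # best score first; ties: more identities, lexicographically smallest
    # reference id, smallest reference start
    return (-h.source_score, -h.source_identities, h.reference_id, h.start)


def rpa_assign(hs: HomologSet, taxonomy: TaxonomyTree) -> SegmentAssignment:
    """Run the two-pass placement on one homolog set."""
    seg = hs.segment
    result = SegmentAssignment(
        query_id=seg.query_id, start=seg.start, end=seg.end,
        assigned_taxon=None, support=0,
    )
    homologs = hs.homologs
    for h in homologs:
        if h.reference_taxon not in taxonomy:
            raise ValueError(
                f"homolog taxon {h.reference_taxon} absent from taxonomy"
            )
    if len(homologs) < 2:
        return result  # needs at least pivot and outgroup

    order = sorted(range(len(homologs)), key=lambda i: _pivot_key(homologs[i]))
    s_idx = order[0]
    s = homologs[s_idx]
    result.pivot_taxon = s.reference_taxon

    q = hs.query_sequence
    n_alignments = 0

    # Pass 1: everything against the pivot
    d_sq, support = edit_distance_with_matches(s.sequence, q)
    n_alignments += 1
    result.support = support
    d_s = {}
    for i, h in enumerate(homologs):
        if i == s_idx:
            continue
        d_s[i], _ = edit_distance_with_matches(s.sequence, h.sequence)
        n_alignments += 1
    M: set[int] = {s.reference_taxon}
    for i, d in d_s.items():
        if d <= d_sq:
            M.add(homologs[i].reference_taxon)

    # Outgroup: nearest segment to s strictly farther than q
    candidates = [i for i, d in d_s.items() if d > d_sq]
    if not candidates:
        result.alignment_count = n_alignments
        result.neighborhood = M
        return result
    o_idx = min(candidates, key=lambda i: (d_s[i],) + _pivot_key(homologs[i]))
    o = homologs[o_idx]
    result.outgroup_taxon = o.reference_taxon
    M.add(o.reference_taxon)

    # Pass 2: everything against the outgroup
    d_oq, _ = edit_distance_with_matches(o.sequence, q)
    n_alignments += 1
    for i, h in enumerate(homologs):
        if i == o_idx:
            continue
        d, _ = edit_distance_with_matches(o.sequence, h.sequence)
        n_alignments += 1
        if d <= d_oq:
            M.add(h.reference_taxon)

    result.alignment_count = n_alignments
    result.neighborhood = M
    assigned = taxonomy.lca(M)
    if assigned == taxonomy.root_id:
        return result  # too diverse: unassigned
    result.assigned_taxon = assigned
    return result
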