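# Methods

## Model and assumptions

`taxoplace` assigns taxa to nucleotide query segments by approximating the
query's evolutionary neighborhood with pairwise edit distances instead of a
multiple alignment and tree. The single modeling assumption is
*ultrametricity*: homologous segments evolve at a roughly constant rate, so
the distance between any two members of a monophyletic clade is smaller
than the distance from either member to anything outside the clade. Under
that assumption a clade can be grown greedily from an internal distance
threshold, which is what the two passes do — pass 1 collects everything at
least as close to the pivot as the query, pass 2 (anchored at the first
segment strictly farther from the pivot than the query) extends the
neighborhood past the sister clade so the final LCA includes one outgroup
and therefore covers the query's own branch point. Deviations from
ultrametricity, gene-tree/species-tree discordance, or non-homologous
segments enlarge the working set *M*; because the assignment is lca(M),
errors push the result to *higher* (safer) ranks rather than to wrong
low-rank taxa. That is the source of the method's conservativeness and the
reason the unassignment rules (no outgroup, fewer than two homologs, LCA at
the root) are left exactly as stated rather than patched with extra
filters.

Distances are raw integer edit distances. Segments within one homolog set
are length-matched by construction (reference segments are extended to the
query segment length), so length normalization would only matter for
segments clipped at a reference boundary; we keep raw counts and accept the
slight bias against clipped segments. The alignment kernel is an exact
O(nm) dynamic program (numba-compiled, GIL-free) that returns both the
distance and the number of identical aligned bases, the latter maximized
over all cost-optimal alignments; banding was considered and rejected
because correctness of the thresholds matters more than speed at the
scales this package targets. `N` characters mismatch everything, including
`N`, to keep distance estimates conservative.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| majority_fraction | 0.70 | fraction of summed support | consensus descent threshold; must exceed 0.5 so the qualifying child is unique |
| min_support | 50 | identical bases (bp) | minimum evidence for any consensus assignment |
| min_identity | off | fraction | optional pre-filter dropping low-identity segments before voting |
| min_sample_abundance | off | fraction of assigned queries | optional post-filter blanking rare bins |
| small-bin removal | 1% | of total assigned bp | evaluation-time removal of smallest predicted bins |
| chunking | >10 kb → 2 kb chunks | bp | consistency analysis of long contigs |

Tie-breaks are fixed and deterministic throughout: the pivot is chosen by
aligner score, then identity count, then lexicographic reference id, then
reference start; the outgroup by distance to the pivot with the same
ladder; the consistency consensus by exact-match count, then depth, then
smallest taxon id. Segmentation merges intervals sharing at least one base;
abutting intervals are not merged (they carry no shared homology evidence).
Reference-segment extension clips at sequence boundaries without
redistribution. "No rank" taxonomy nodes are transparent to rank
projection: they are walked through and never returned, so rank-level
evaluation sees only the seven canonical ranks.

## Consensus traversal

The root-to-leaf descent (vote for a taxon counts for all its ancestors;
descend while the unique child carries ≥ majority_fraction of the total and
≥ min_support) is our concrete realization of a support-weighted majority
with conservative fall-back. With majority_fraction > 0.5 at most one child
can qualify, so the returned node is exactly the deepest node whose whole
path meets both thresholds — the property the exhaustive-scoring oracle in
the tests checks. When descent stops at the root itself with sufficient
support, the root is returned as the (maximally uninformative) prediction;
only a root failing min_support, or a query with no assigned segments,
yields "unassigned".

## Synthetic worlds

The generator emulates the ingredients the pipeline consumes: a ranked
taxonomy from uniform branching (per-rank child counts may be fixed,
ranged, or per-rank), genomes evolved from a random root by per-site
substitution at a constant per-branch rate (optionally with small indels,
tracked through per-base root coordinates so homologous positions stay
identifiable), query fragments sampled uniformly from designated query
leaves, and hit records fabricated from the true homologous coordinates
with identity counted by direct comparison and score = identities. Records
below a configurable identity floor are withheld to emulate aligner
sensitivity. Defaults — 10 kb genomes, 5% substitutions/site/branch
(typical inter-species nucleotide divergence per taxonomy level and the
regime in which clade recovery is exercised), 1 kb fragments, 50% identity
floor — are the study conditions for all end-to-end tests.

What the worlds deliberately do **not** model: sequencing error and read
simulation, assembly chimerism, genome rearrangement, lateral transfer,
compositional biases, and uneven taxon sampling. Passing tests therefore
demonstrate the algorithmic contracts (thresholds, budgets, determinism,
conservative fall-back, clade recovery under the ultrametric premise) —
not classification accuracy on real communities, where reference coverage
and rate variation dominate.

## Problem sizes

End-to-end checks use desk-scale worlds chosen to keep the full suite
around a minute: 100 replicate 8-species clades (3-rank ladder, 2 children
per node, one held-out query species each) for clade-recovery accuracy,
and one 48-species world (3 phyla × 2 orders × 2 families × 2 genera × 2
species; 8 query species × 3 fragments) shared by the idealized-precision
and novel-family-conservativeness tests. The placement cost is 2·n exact
alignments per query segment (n = number of homologs), quadratic in
fragment length per alignment.

## Numerical and degenerate-input choices

Empty taxon sets, empty sequences, records with unmapped accessions,
queries without hits, contigs with no assigned chunks and empty GFF3 inputs
all have defined behavior (error, counted drop, absence from output, or
empty output — never silent loss). Coordinates are 1-based inclusive at
every module boundary; minus-strand hits are reverse-complemented into
query orientation once, at reference-segment extraction. Worker-count
parallelism is a per-query thread pool with a canonical output sort, so
outputs are byte-identical for any worker count.

## Known limitations

- Raw (unnormalized) distances make clipped reference segments look
  artificially close; rare in practice, but a known bias.
- The pivot is trusted from the input aligner's score ranking; a spurious
  top hit degrades the neighborhood (mitigated only by the LCA's
  conservativeness).
- LCA is computed by depth-aligned walking (no RMQ preprocessing);
  adequate at desk scale, not tuned for million-node taxonomies.
- Merged/deleted taxon remapping, protein-level realignment, and running
  the aligner itself are out of scope.
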