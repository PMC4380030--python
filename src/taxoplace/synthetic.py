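"""Ground-truthed synthetic worlds for every pipeline stage.

A world consists of a ranked taxonomy generated by uniform branching, one
genome per node evolved from a random root genome by per-site substitution
(optionally with a small indel rate) along each branch, query fragments
sampled from designated query leaves, and alignment records fabricated from
the true homologous coordinates of each fragment against every leaf genome.
Because every branch applies the same substitution rate, expected pairwise
distances grow with path length in the tree — the ultrametric premise the
placement algorithm exploits — and every record's identity count is computed
by direct base comparison at homologous positions, so the generator doubles
as an oracle for segmentation, placement and evaluation tests.

Records whose identity fraction falls below ``min_alignment_identity`` are
withheld, emulating the sensitivity limit of a real nucleotide aligner.
All randomness flows from a single generator seeded once per world; a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .seqdata import LocalAlignmentRecord, SequenceStore, write_alignments, write_fasta, write_mapping
from .taxonomy import NO_RANK, TaxonNode, TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ChildSpec = Union[int, tuple[int, int], dict[str, Union[int, tuple[int, int]]]]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Desk-scale study conditions for one synthetic world.

    Defaults model a small multi-phylum community: 10 kb genomes diverging
    by 5% substitutions per site per branch (a realistic inter-species
    nucleotide divergence per taxonomy level), 1 kb query fragments, and an
    aligner that stops reporting hits below 50% identity.
    """

    seed: int = 0
    ranks: tuple[str, ...] = ("species", "genus", "family", "phylum")
    children_per_node: ChildSpec = 3
    genome_length: int = 10_000
    substitution_rate_per_branch: float = 0.05
    indel_rate_per_branch: float = 0.0
    fragment_length: int = 1_000
    fragments_per_query_taxon: int = 3
    n_query_taxa: int = 9
    min_alignment_identity: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.substitution_rate_per_branch < 0.75):
            raise ConfigError("substitution rate must be in [0, 0.75)")
        if not (0.0 <= self.indel_rate_per_branch < 0.25):
            raise ConfigError("indel rate must be in [0, 0.25)")
        if self.genome_length <= 0 or self.fragment_length <= 0:
            raise ConfigError("lengths must be positive")
        if self.fragment_length > self.genome_length:
            raise ConfigError("fragment_length exceeds genome_length")
        if not self.ranks:
            raise ConfigError("empty rank list")
        if self.fragments_per_query_taxon <= 0 or self.n_query_taxa <= 0:
            raise ConfigError("query counts must be positive")
        for rank in self.ranks:
            self._children_for(rank, check_only=True)

    def _children_for(self, rank: str, rng: Optional[np.random.Generator] = None, check_only: bool = False) -> int:
        spec = self.children_per_node
        if isinstance(spec, dict):
            try:
                spec = spec[rank]
            except KeyError:
                raise ConfigError(f"no children_per_node entry for rank {rank!r}") from None
        if isinstance(spec, tuple):
            lo, hi = spec
            if lo < 1 or hi < lo:
                raise ConfigError(f"bad children range {spec}")
            if check_only:
                return lo
            return int(rng.integers(lo, hi + 1))
        if int(spec) < 1:
            raise ConfigError("children_per_node must be >= 1")
        return int(spec)


@dataclass
class SyntheticWorld:
    """In-memory world plus writers for the on-disk dialects."""

    config: SimulationConfig
    taxonomy: TaxonomyTree
    reference_store: SequenceStore          # leaf genomes, id "ref<taxid>"
    query_store: SequenceStore              # fragments, id "q<taxid>_<k>"
    truth: dict[str, int]                   # query_id -> source leaf taxon
    mapping: dict[str, int]                 # reference id -> taxon
    alignments: list[LocalAlignmentRecord]
    withheld_records: int
    query_taxa: list[int]
    leaf_taxa: list[int]
    fragment_coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "taxonomy": outdir / "taxonomy.tsv",
            "reference": outdir / "reference.fasta",
            "queries": outdir / "queries.fasta",
            "alignments": outdir / "alignments.tsv",
            "mapping": outdir / "mapping.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.taxonomy.to_tsv(paths["taxonomy"])
        write_fasta(self.reference_store, paths["reference"])
        write_fasta(self.query_store, paths["queries"])
        write_alignments(self.alignments, paths["alignments"])
        write_mapping(self.mapping, paths["mapping"])
        with open(paths["truth"], "w") as fh:
            for qid in sorted(self.truth):
                fh.write(f"{qid}\t{self.truth[qid]}\t{self.query_store.length(qid)}\n")
        return paths


def _evolve(
    genome: np.ndarray,
    coords: np.ndarray,
    rng: np.random.Generator,
    sub_rate: float,
    indel_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One branch of evolution: per-site substitution, then optional indels.

    `coords` carries each base's coordinate in the root genome (-1 for
    inserted bases) so homologous positions stay identifiable after indels.
    A substitution always changes the base (uniform over the other three).
    """
    child = genome.copy()
    if sub_rate > 0:
        mask = rng.random(child.shape[0]) < sub_rate
        n = int(mask.sum())
        if n:
            child[mask] = (child[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    child_coords = coords
    if indel_rate > 0:
        keep = rng.random(child.shape[0]) >= indel_rate / 2.0
        insert_after = rng.random(child.shape[0]) < indel_rate / 2.0
        pieces = []
        coord_pieces = []
        for i in range(child.shape[0]):
            if keep[i]:
                pieces.append(child[i : i + 1])
                coord_pieces.append(coords[i : i + 1])
            if insert_after[i]:
                pieces.append(rng.integers(0, 4, size=1).astype(np.uint8))
                coord_pieces.append(np.array([-1], dtype=np.int64))
        if pieces:
            child = np.concatenate(pieces)
            child_coords = np.concatenate(coord_pieces)
        else:
            child = np.empty(0, dtype=np.uint8)
            child_coords = np.empty(0, dtype=np.int64)
    return child, child_coords


def _decode(genome: np.ndarray) -> str:
    return bytes(_BASES[genome]).decode("ascii")


def simulate_world(config: SimulationConfig) -> SyntheticWorld:
    """Generate a complete synthetic world from one seeded generator."""
    rng = np.random.default_rng(config.seed)

    # taxonomy by uniform branching, highest rank first under a "no rank" root
    root_id = 1
    nodes = [TaxonNode(root_id, root_id, NO_RANK, "root")]
    next_id = 2
    level_nodes = [root_id]
    for rank in reversed(config.ranks):
        new_level = []
        for parent in level_nodes:
            k = config._children_for(rank, rng)
            for _ in range(k):
                nodes.append(TaxonNode(next_id, parent, rank, f"{rank}_{next_id}"))
                new_level.append(next_id)
                next_id += 1
        level_nodes = new_level
    taxonomy = TaxonomyTree(nodes)
    leaf_taxa = sorted(level_nodes)

    # genomes evolved down the tree (children generated in node-id order)
    root_genome = rng.integers(0, 4, size=config.genome_length).astype(np.uint8)
    root_coords = np.arange(config.genome_length, dtype=np.int64)
    genomes: dict[int, tuple[np.ndarray, np.ndarray]] = {root_id: (root_genome, root_coords)}
    children: dict[int, list[int]] = {}
    for n in nodes:
        if n.taxon_id != n.parent_id:
            children.setdefault(n.parent_id, []).append(n.taxon_id)
    stack = [root_id]
    while stack:
        parent = stack.pop(0)
        pg, pc = genomes[parent]
        for child in sorted(children.get(parent, [])):
            genomes[child] = _evolve(
                pg, pc, rng,
                config.substitution_rate_per_branch,
                config.indel_rate_per_branch,
            )
            stack.append(child)

    reference_store = SequenceStore()
    mapping: dict[str, int] = {}
    for leaf in leaf_taxa:
        rid = f"ref{leaf}"
        reference_store.add(rid, _decode(genomes[leaf][0]))
        mapping[rid] = leaf

    # query fragments from designated query leaves
    n_query = min(config.n_query_taxa, len(leaf_taxa))
    query_taxa = sorted(
        int(t) for t in rng.choice(np.array(leaf_taxa), size=n_query, replace=False)
    )
    query_store = SequenceStore()
    truth: dict[str, int] = {}
    fragment_coords: dict[str, tuple[int, int]] = {}
    fragments: list[tuple[str, int, int, int]] = []  # qid, leaf, start0, end0
    for leaf in query_taxa:
        genome, _ = genomes[leaf]
        glen = genome.shape[0]
        flen = min(config.fragment_length, glen)
        for k in range(config.fragments_per_query_taxon):
            start0 = int(rng.integers(0, glen - flen + 1))
            qid = f"q{leaf}_{k}"
            query_store.add(qid, _decode(genome[start0 : start0 + flen]))
            truth[qid] = leaf
            fragment_coords[qid] = (start0 + 1, start0 + flen)
            fragments.append((qid, leaf, start0, start0 + flen))

    # fabricate alignment records from true homologous coordinates
    records: list[LocalAlignmentRecord] = []
    withheld = 0
    no_indels = config.indel_rate_per_branch == 0.0
    for qid, leaf, start0, end0 in fragments:
        qgenome, qcoords = genomes[leaf]
        frag = qgenome[start0:end0]
        flen = end0 - start0
        for ref_leaf in leaf_taxa:
            rgenome, rcoords = genomes[ref_leaf]
            if no_indels:
                rseg = rgenome[start0:end0]
                identities = int((frag == rseg).sum())
                ref_lo, ref_hi = start0 + 1, end0
                aln_len = flen
            else:
                hom = _homologous_interval(qcoords[start0:end0], rcoords)
                if hom is None:
                    withheld += 1
                    continue
                ref_lo, ref_hi, identities = _indel_identities(
                    frag, qcoords[start0:end0], rgenome, rcoords, hom
                )
                aln_len = max(flen, ref_hi - ref_lo + 1)
            if identities < config.min_alignment_identity * flen:
                withheld += 1
                continue
            records.append(LocalAlignmentRecord(
                query_id=qid,
                reference_id=f"ref{ref_leaf}",
                query_start=1,
                query_end=flen,
                ref_start=ref_lo,
                ref_end=ref_hi,
                score=float(identities),
                identities=identities,
                alignment_length=aln_len,
                evalue=0.0,
                reference_taxon=ref_leaf,
            ))

    return SyntheticWorld(
        config=config,
        taxonomy=taxonomy,
        reference_store=reference_store,
        query_store=query_store,
        truth=truth,
        mapping=mapping,
        alignments=records,
        withheld_records=withheld,
        query_taxa=query_taxa,
        leaf_taxa=leaf_taxa,
        fragment_coords=fragment_coords,
    )


def _homologous_interval(frag_coords: np.ndarray, ref_coords: np.ndarray):
    """Root-coordinate anchored interval of the fragment on a reference."""
    anchored = frag_coords[frag_coords >= 0]
    if anchored.size == 0:
        return None
    lo, hi = int(anchored.min()), int(anchored.max())
    idx = np.nonzero((ref_coords >= lo) & (ref_coords <= hi))[0]
    if idx.size == 0:
        return None
    return int(idx.min()), int(idx.max())


def _indel_identities(frag, frag_coords, rgenome, rcoords, hom):
    lo_idx, hi_idx = hom
    ref_lo, ref_hi = lo_idx + 1, hi_idx + 1  # 1-based
    ref_by_root = {}
    for i in range(lo_idx, hi_idx + 1):
        c = rcoords[i]
        if c >= 0:
            ref_by_root[int(c)] = rgenome[i]
    identities = 0
    for i in range(frag.shape[0]):
        c = frag_coords[i]
        if c >= 0 and int(c) in ref_by_root and ref_by_root[int(c)] == frag[i]:
            identities += 1
    return ref_lo, ref_hi, identities
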