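"""Ranked reference taxonomy: loading, LCA and clade masking.

The taxonomy is a rooted tree of taxon nodes, each carrying a rank from the
canonical NCBI ladder (species < genus < family < order < class < phylum <
superkingdom) or the pseudo-rank ``"no rank"``.  All downstream stages —
neighborhood placement, consensus binning and the evaluation harness — reduce
to three primitives defined here: lowest common ancestor over a taxon set,
projection of a taxon to a fixed rank, and masking of a query's clade from a
reference set (leave-one-taxon-out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

#: Canonical rank ladder, lowest (most specific) first.
CANONICAL_RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

NO_RANK = "no rank"


class TaxonomyError(ValueError):
    """Structural or lookup problem in a taxonomy."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: identifier, parent link, rank label and scientific name."""

    taxon_id: int
    parent_id: int
    rank: str
    name: str = ""

    @property
    def is_root(self) -> bool:
        return self.taxon_id == self.parent_id


class TaxonomyTree:
    """Rooted ranked taxonomy with LCA, rank projection and clade masking.

    Invariants are checked at construction: exactly one root (a node that is
    its own parent), every parent resolves, and parent links are acyclic.
    Nodes whose rank is not on the ladder are normalized to ``"no rank"``;
    such nodes are transparent to :meth:`ancestor_at_rank` (skipped, never
    returned).
    """

    def __init__(self, nodes: Iterable[TaxonNode], rank_ladder: Sequence[str] = CANONICAL_RANKS):
        self.rank_ladder = tuple(rank_ladder)
        self._rank_index = {r: i for i, r in enumerate(self.rank_ladder)}
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id}")
            if node.rank not in self._rank_index:
                node = TaxonNode(node.taxon_id, node.parent_id, NO_RANK, node.name)
            self.nodes[node.taxon_id] = node
        self._validate()
        self._depth: dict[int, int] = {}

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        roots = [n.taxon_id for n in self.nodes.values() if n.is_root]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}: {roots}")
        self.root_id: int = roots[0]
        for node in self.nodes.values():
            if not node.is_root and node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"taxon {node.taxon_id} has missing parent {node.parent_id}"
                )
        # acyclicity: walk every node to the root, memoizing visited ids
        ok: set[int] = {self.root_id}
        for start in self.nodes:
            path = []
            tid = start
            while tid not in ok:
                path.append(tid)
                tid = self.nodes[tid].parent_id
                if tid in path:
                    raise TaxonomyError(f"cycle in parent links at taxon {tid}")
            ok.update(path)

    @classmethod
    def from_ncbi_dump(cls, nodes_path, names_path, rank_ladder: Sequence[str] = CANONICAL_RANKS) -> "TaxonomyTree":
        """Load an NCBI-style taxonomy dump (``nodes.dmp`` + ``names.dmp``).

        Fields are separated by ``\\t|\\t`` and records terminated by ``\\t|``.
        Only ``scientific name`` rows of the names file are used.
        """
        names: dict[int, str] = {}
        with open(names_path) as fh:
            for line in fh:
                fields = _split_dump_line(line)
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]
        nodes = []
        with open(nodes_path) as fh:
            for line in fh:
                fields = _split_dump_line(line)
                if len(fields) < 3:
                    raise TaxonomyError(f"malformed nodes.dmp line: {line!r}")
                tid, pid, rank = int(fields[0]), int(fields[1]), fields[2]
                nodes.append(TaxonNode(tid, pid, rank, names.get(tid, "")))
        return cls(nodes, rank_ladder)

    @classmethod
    def from_tsv(cls, path, rank_ladder: Sequence[str] = CANONICAL_RANKS) -> "TaxonomyTree":
        """Load the simplified 4-column dialect: taxon_id, parent_id, rank, name."""
        nodes = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise TaxonomyError(f"{path}:{ln}: expected >=3 tab-separated columns")
                name = parts[3] if len(parts) > 3 else ""
                nodes.append(TaxonNode(int(parts[0]), int(parts[1]), parts[2], name))
        return cls(nodes, rank_ladder)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")

    # -- basic queries -------------------------------------------------------------

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon_id {taxon_id}") from None

    def parent(self, taxon_id: int) -> int:
        return self.node(taxon_id).parent_id

    def depth(self, taxon_id: int) -> int:
        """Number of edges from the node to the root (root has depth 0)."""
        cached = self._depth.get(taxon_id)
        if cached is not None:
            return cached
        node = self.node(taxon_id)
        d = 0 if node.is_root else self.depth(node.parent_id) + 1
        self._depth[taxon_id] = d
        return d

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Node ids from the taxon up to and including the root."""
        path = [taxon_id]
        node = self.node(taxon_id)
        while not node.is_root:
            node = self.nodes[node.parent_id]
            path.append(node.taxon_id)
        return path

    def is_ancestor(self, ancestor: int, taxon_id: int) -> bool:
        """True if `ancestor` is an ancestor-or-self of `taxon_id`."""
        tid = taxon_id
        self.node(ancestor)
        while True:
            if tid == ancestor:
                return True
            node = self.node(tid)
            if node.is_root:
                return False
            tid = node.parent_id

    # -- LCA -----------------------------------------------------------------------

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxa.

        Computed by iterated pairwise depth-aligned parent walking.
        """
        it = iter(set(taxa))
        try:
            acc = next(it)
        except StopIteration:
            raise TaxonomyError("lca of empty taxon set") from None
        self.node(acc)
        for tid in it:
            acc = self._lca_pair(acc, tid)
        return acc

    def _lca_pair(self, a: int, b: int) -> int:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self.nodes[a].parent_id
            da -= 1
        while db > da:
            b = self.nodes[b].parent_id
            db -= 1
        while a != b:
            a = self.nodes[a].parent_id
            b = self.nodes[b].parent_id
        return a

    # -- rank projection and clade masking -----------------------------------------

    def rank_index(self, rank: str) -> int:
        try:
            return self._rank_index[rank]
        except KeyError:
            raise TaxonomyError(f"rank {rank!r} not on the ladder {self.rank_ladder}") from None

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> Optional[int]:
        """The unique ancestor-or-self at `rank`, or None if the lineage skips it.

        ``"no rank"`` nodes are transparent: they are walked through and never
        returned.  A node already above the requested rank projects to None.
        """
        target = self.rank_index(rank)
        tid = taxon_id
        while True:
            node = self.node(tid)
            if node.rank != NO_RANK:
                idx = self._rank_index[node.rank]
                if idx == target:
                    return tid
                if idx > target:
                    return None
            if node.is_root:
                return None
            tid = node.parent_id

    def mask_clade(
        self,
        reference_taxa: Iterable[int],
        query_taxon: int,
        exclusion_rank: Optional[str],
    ) -> set[int]:
        """Remove from `reference_taxa` every taxon inside the query's clade
        at `exclusion_rank` (leave-one-taxon-out).  With ``exclusion_rank=None``
        the reference set is returned unchanged (the idealized scenario).
        """
        reference_taxa = set(reference_taxa)
        if exclusion_rank is None:
            return reference_taxa
        self.node(query_taxon)
        query_clade = self.ancestor_at_rank(query_taxon, exclusion_rank)
        if query_clade is None:
            return reference_taxa
        return {
            t for t in reference_taxa
            if self.ancestor_at_rank(t, exclusion_rank) != query_clade
        }


def _split_dump_line(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def write_ncbi_dump(tree: TaxonomyTree, nodes_path, names_path) -> None:
    """Write a tree in the NCBI dump dialect (round-trip counterpart)."""
    with open(nodes_path, "w") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t|\t{n.parent_id}\t|\t{n.rank}\t|\n")
    with open(names_path, "w") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t|\t{n.name or str(n.taxon_id)}\t|\t\t|\tscientific name\t|\n")
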