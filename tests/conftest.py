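"""Shared fixtures: small hand-built taxonomies and homolog-set builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from taxoplace.segmentation import HomologSet, QuerySegment, ReferenceSegment
from taxoplace.taxonomy import NO_RANK, TaxonNode, TaxonomyTree

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_tree(edges, rank_ladder=None):
    """Build a TaxonomyTree from (taxon_id, parent_id, rank) triples."""
    nodes = [TaxonNode(t, p, r, f"n{t}") for t, p, r in edges]
    if rank_ladder is None:
        return TaxonomyTree(nodes)
    return TaxonomyTree(nodes, rank_ladder)


@pytest.fixture
def clade_tree():
    """The worked placement topology: root > R > {X > (A,B,S), C, D, O}.

    R is an order, X a family; leaves are species.  Ids: root=1, R=2, X=3,
    A=4, B=5, S=6, C=7, D=8, O=9.
    """
    return make_tree([
        (1, 1, NO_RANK),
        (2, 1, "order"),
        (3, 2, "family"),
        (4, 3, "species"),
        (5, 3, "species"),
        (6, 3, "species"),
        (7, 2, "species"),
        (8, 2, "species"),
        (9, 2, "species"),
    ])


@pytest.fixture
def two_species_tree():
    """root > genus 2 > species {3, 4}; used for binner threshold sweeps."""
    return make_tree([
        (1, 1, NO_RANK),
        (2, 1, "genus"),
        (3, 2, "species"),
        (4, 2, "species"),
    ])


def random_tree(rng: np.random.Generator, n_nodes: int,
                ranks=("species", "genus", "family", "phylum"), strict=False):
    """Random ranked tree: each node attaches to an earlier non-species node.

    With strict=True every child sits exactly one rank below its parent
    (complete lineages); otherwise ranks may be skipped.
    """
    ladder = list(ranks)
    edges = [(1, 1, NO_RANK)]
    rank_of = {1: len(ladder)}  # above the top rank
    for tid in range(2, n_nodes + 1):
        candidates = [t for t, r in rank_of.items() if r > 0]
        parent = int(rng.choice(candidates))
        pr = rank_of[parent]
        r = pr - 1 if strict else int(rng.integers(0, pr))
        rank_of[tid] = r
        edges.append((tid, parent, ladder[r] if r < len(ladder) else NO_RANK))
    return make_tree(edges)


def mutate(seq: str, positions) -> str:
    """Deterministic substitution at given 0-based positions (A>C>G>T>A)."""
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = nxt[chars[p]]
    return "".join(chars)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_homolog_set(query_seq, homolog_specs, query_id="q", start=1):
    """Build a HomologSet from (sequence, taxon, score) or
    (sequence, taxon, score, identities) tuples."""
    segment = QuerySegment(query_id, start, start + len(query_seq) - 1)
    homologs = []
    for i, spec in enumerate(homolog_specs):
        seq, taxon, score = spec[:3]
        identities = spec[3] if len(spec) > 3 else int(score)
        homologs.append(ReferenceSegment(
            reference_id=f"ref{i}",
            reference_taxon=taxon,
            start=1,
            end=len(seq),
            minus_strand=False,
            sequence=seq,
            source_score=float(score),
            source_identities=identities,
        ))
    return HomologSet(segment=segment, query_sequence=query_seq, homologs=homologs)
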