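"""COG-style protein families from all-vs-all similarity.

An edge joins two proteins when some hit in either direction has e-value
<= 1e-20 and HSP coverage of the shorter sequence strictly above 50%.
Every 3-clique of that graph seeds a family; families sharing at least
two members are merged, and merging is iterated to a fixpoint.  Requiring
a true 3-clique (all three pairwise edges) follows the original COG
construction; a two-edge "triangle" is a star and over-merges.

The fixpoint is unique regardless of edge or merge order, which the test
suite checks by shuffling against a brute-force oracle.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .core_model import PipelineConfig, ProteinFamily, SimilarityHit

Edge = frozenset


def qualifying_edges(hits: Iterable[SimilarityHit],
                     config: PipelineConfig) -> set[frozenset[str]]:
    """Symmetric edge set over proteins passing the e-value and coverage
    cuts.  Coverage uses the shorter of the two sequence lengths; a hit in
    either direction suffices."""
    edges: set[frozenset[str]] = set()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue <= config.family_evalue and h.coverage() > config.family_min_coverage:
            edges.add(frozenset((h.query_id, h.subject_id)))
    return edges


def _triangles(edges: set[frozenset[str]]) -> list[frozenset[str]]:
    adj: dict[str, set[str]] = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    tris: set[frozenset[str]] = set()
    for e in edges:
        u, v = tuple(e)
        for w in adj[u] & adj[v]:
            tris.add(frozenset((u, v, w)))
    return sorted(tris, key=sorted)


def merge_clusters(clusters: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    """Iteratively merge any two clusters sharing >= 2 members until no
    such pair remains.

    Implemented as union-find over cluster ids with a registry mapping
    each unordered member pair to its owning cluster: whenever two
    clusters claim the same pair they are unioned and the merged set is
    re-registered, so pairs created by earlier merges keep triggering
    later ones.  The result equals naive repeated pairwise merging.
    """
    parent = list(range(len(clusters)))
    members: dict[int, set[str]] = {i: set(c) for i, c in enumerate(clusters)}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pair_owner: dict[frozenset[str], int] = {}
    stack = sorted(members, reverse=True)
    while stack:
        cid = find(stack.pop())
        if cid not in members:
            continue
        merged_into = None
        for pair in map(frozenset, combinations(sorted(members[cid]), 2)):
            owner = pair_owner.get(pair)
            owner = find(owner) if owner is not None else None
            if owner is None or owner == cid:
                pair_owner[pair] = cid
            else:
                # union: absorb cid into owner, reprocess the union
                parent[cid] = owner
                members[owner] |= members.pop(cid)
                stack.append(owner)
                merged_into = owner
                break
        if merged_into is not None:
            continue
    return sorted((frozenset(m) for m in members.values()), key=sorted)


def triangle_cluster(edges: set[frozenset[str]],
                     species_of: Mapping[str, str] | None = None,
                     ) -> list[ProteinFamily]:
    """Enumerate all 3-cliques, seed one cluster per clique, and merge
    clusters sharing >= 2 members to a fixpoint.  Proteins in no 3-clique
    stay unclustered.  ``species_of`` optionally maps protein ids to
    species ids for the family members (defaults to a single species)."""
    merged = merge_clusters(_triangles(edges))
    families = []
    for i, club in enumerate(merged):
        members = frozenset(
            ((species_of or {}).get(p, "self"), p) for p in club
        )
        families.append(ProteinFamily(f"F{i:05d}", members))
    return families


def classify_unique_specific(proteome: Iterable[str],
                             hits_cross: Iterable[SimilarityHit],
                             annotated_elsewhere: Mapping[str, bool],
                             config: PipelineConfig) -> dict[str, str]:
    """Label each protein of the focal proteome.

    shared    has a cross-species hit at e-value <= 1e-10
    unique    no qualifying cross-species hit
    specific  unique and not annotated in any of the other species
    """
    best: dict[str, float] = {}
    for h in hits_cross:
        if h.query_id not in best or h.evalue < best[h.query_id]:
            best[h.query_id] = h.evalue
    labels = {}
    for p in proteome:
        ev = best.get(p)
        if ev is not None and ev <= config.homolog_evalue:
            labels[p] = "shared"
        elif annotated_elsewhere.get(p, False):
            labels[p] = "unique"
        else:
            labels[p] = "specific"
    return labels
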