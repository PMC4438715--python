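"""1:1:1 ortholog identification across three species.

Two strategies are implemented:

* **BBH** — bidirectional best hits per species pair with stringent filters
  (E-value cutoff, identity >= 60%, tie-dropping), assembled into triplets by
  triangle closure; genes appearing in more than one triangle are excluded as
  multi-copy, and triplets containing an internal stop codon are excluded.

* **MCL** — Markov clustering of the cross-species similarity graph (edges
  weighted by -log10 E-value, capped), followed by per-species representative
  selection: in a cluster with several members of one species, the member
  with the highest total similarity to the other species' members is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .search import SimilarityHit

EXCL_MULTI_COPY = "multi-copy"
EXCL_INTERNAL_STOP = "internal-stop"
EXCL_LOW_IDENTITY = "low-identity"
EXCL_MISSING_SPECIES = "missing-species"


@dataclass
class OrthologTriplet:
    """One gene per species, with provenance and exclusion status."""

    gene_ids: dict  # species -> gene id
    method: str  # "BBH" | "MCL"
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self):
        if not self.excluded and len(self.gene_ids) != 3:
            raise ValueError("a retained triplet needs exactly one gene per species")


def _best_hits(hits: list[SimilarityHit]) -> dict:
    """Single best hit per query; queries whose best hit ties (equal E-value
    and bitscore) with another subject are dropped for reproducibility."""
    by_query: dict = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    best: dict = {}
    for qid, hs in by_query.items():
        hs = sorted(hs, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        if len(hs) > 1 and hs[0].evalue == hs[1].evalue and hs[0].bitscore == hs[1].bitscore:
            continue  # ambiguous best hit
        best[qid] = hs[0]
    return best


def bbh_pairs(
    hits_ab: list[SimilarityHit],
    hits_ba: list[SimilarityHit],
    evalue_cutoff: float = 1e-6,
    min_identity: float = 60.0,
):
    """Reciprocal best-hit pairs between two species.

    (a, b) is kept iff b is a's unique best hit and a is b's unique best hit,
    both hits have E < cutoff, and both identities are >= ``min_identity``.
    Returns (pairs, exclusion_log); mutual best pairs failing the identity
    rule are logged with reason "low-identity".
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    excluded = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is None or back.subject_id != a:
            continue
        if hit.evalue >= evalue_cutoff or back.evalue >= evalue_cutoff:
            continue
        if hit.identity_pct < min_identity or back.identity_pct < min_identity:
            excluded.append((a, b, EXCL_LOW_IDENTITY))
            continue
        pairs.append((a, b))
    return pairs, excluded


def triplets_from_bbh(pairs_ab, pairs_bc, pairs_ac, records_by_species: dict) -> list[OrthologTriplet]:
    """Assemble 1:1:1 triplets by triangle closure over three pair lists.

    ``records_by_species`` maps species name -> list of CodingRecord, in the
    same (A, B, C) order as the pair lists. A gene participating in more than
    one triangle marks all its triangles multi-copy; triangles containing a
    sequence with an internal stop are excluded.
    """
    sp_a, sp_b, sp_c = records_by_species.keys()
    set_ac = set(pairs_ac)
    bc_by_b: dict = {}
    for b, c in set(pairs_bc):
        bc_by_b.setdefault(b, []).append(c)
    triangles = [
        (a, b, c)
        for a, b in set(pairs_ab)
        for c in bc_by_b.get(b, ())
        if (a, c) in set_ac
    ]

    usage: dict = {}
    for tri in triangles:
        for g in tri:
            usage[g] = usage.get(g, 0) + 1

    stops = {
        rec.id
        for recs in records_by_species.values()
        for rec in recs
        if rec.has_internal_stop
    }

    out = []
    for a, b, c in sorted(triangles):
        ids = {sp_a: a, sp_b: b, sp_c: c}
        if any(usage[g] > 1 for g in (a, b, c)):
            out.append(OrthologTriplet(ids, "BBH", excluded=True, exclusion_reason=EXCL_MULTI_COPY))
        elif any(g in stops for g in (a, b, c)):
            out.append(OrthologTriplet(ids, "BBH", excluded=True, exclusion_reason=EXCL_INTERNAL_STOP))
        else:
            out.append(OrthologTriplet(ids, "BBH"))
    return out


# ---------------------------------------------------------------------------
# Markov clustering

EDGE_WEIGHT_CAP = 200.0


def build_similarity_graph(hit_lists, species_of: dict) -> nx.Graph:
    """Undirected similarity graph over genes, weighted by -log10(E-value)
    capped at 200; reciprocal hits keep the larger weight."""
    g = nx.Graph()
    for gene, sp in species_of.items():
        g.add_node(gene, species=sp)
    for hits in hit_lists:
        for h in hits:
            if h.query_id == h.subject_id:
                continue
            w = EDGE_WEIGHT_CAP if h.evalue <= 0 else min(-math.log10(h.evalue), EDGE_WEIGHT_CAP)
            w = max(w, 0.0)
            if g.has_edge(h.query_id, h.subject_id):
                g[h.query_id][h.subject_id]["weight"] = max(g[h.query_id][h.subject_id]["weight"], w)
            else:
                g.add_edge(h.query_id, h.subject_id, weight=w)
    return g


def mcl_cluster(graph: nx.Graph, inflation: float = 1.5, max_iter: int = 200, tol: float = 1e-6):
    """Markov clustering of a weighted similarity graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1 for isolated nodes); the column-stochastic matrix is then
    alternately squared (expansion) and entrywise powered (inflation) until
    the maximum entry change is below ``tol``. Clusters are read off the
    attractor structure; overlapping attractor sets are merged. Singletons
    are allowed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop

    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        inflated[inflated < 1e-12] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated

    # attractors: rows with significant mass; cluster = attractor row support
    attractors = [i for i in range(n) if m[i, i] > 1e-6]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in attractors:
        for j in np.nonzero(m[i] > 1e-6)[0]:
            union(i, int(j))
    clusters: dict = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(nodes[i])
    return sorted((frozenset(c) for c in clusters.values()), key=lambda c: sorted(c)[0])


def select_representatives(cluster, hits, records_by_species: dict) -> OrthologTriplet:
    """Reduce one cluster to a 1:1:1 triplet.

    Clusters missing a species are excluded. For a species with several
    members, the member with the highest summed bitscore against all
    non-conspecific cluster members is kept (ties: longest protein, then
    lexicographically smallest id). Internal-stop screening then applies to
    the chosen representatives.
    """
    rec_of = {rec.id: rec for recs in records_by_species.values() for rec in recs}
    species_of = {rec.id: rec.species for rec in rec_of.values()}
    members: dict = {}
    for g in cluster:
        sp = species_of.get(g)
        if sp is None:
            raise KeyError(f"cluster member {g} not in records")
        members.setdefault(sp, []).append(g)

    gene_ids_all = {sp: sorted(ms) for sp, ms in members.items()}
    if set(members) != set(records_by_species):
        return OrthologTriplet(
            {sp: ",".join(ms) for sp, ms in gene_ids_all.items()},
            "MCL", excluded=True, exclusion_reason=EXCL_MISSING_SPECIES,
        )

    score: dict = {}
    for h in hits:
        if h.query_id in cluster and h.subject_id in cluster:
            if species_of[h.query_id] != species_of[h.subject_id]:
                key = (h.query_id, h.subject_id)
                score[key] = max(score.get(key, 0.0), h.bitscore)

    chosen: dict = {}
    for sp, ms in sorted(members.items()):
        def total_bitscore(g):
            return sum(v for (q, s), v in score.items() if q == g or s == g)

        chosen[sp] = min(ms, key=lambda g: (-total_bitscore(g), -len(rec_of[g].protein), g))
    if any(rec_of[g].has_internal_stop for g in chosen.values()):
        return OrthologTriplet(chosen, "MCL", excluded=True, exclusion_reason=EXCL_INTERNAL_STOP)
    return OrthologTriplet(chosen, "MCL")
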