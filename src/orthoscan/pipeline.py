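"""End-to-end scan: search -> orthology -> codon alignment -> dN/dS -> calls.

Thin orchestration over the per-stage modules, returning a result object
carrying every intermediate table so studies (simulated or real) can be
interrogated at any stage. Ground-truth evaluation helpers for simulated
studies live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import alignment_qc, backtranslate, global_align
from .dnds import ml_pairwise, ng86, yn00
from .orthology import (
    OrthologTriplet,
    bbh_pairs,
    build_similarity_graph,
    mcl_cluster,
    select_representatives,
    triplets_from_bbh,
)
from .scan import (
    FILTERED,
    FilterConfig,
    FocalResult,
    apply_filters,
    call_psg,
    focal_contrast,
    summarize,
)
from .search import all_vs_all, longest_isoforms

_ESTIMATORS = {"NG86": ng86, "YN": yn00, "ML-MA": ml_pairwise}


@dataclass
class PipelineResult:
    species: tuple
    focal: str
    method: str
    strategy: str
    hits: dict  # (query_species, target_species) -> hit list
    triplets: list
    estimates: pd.DataFrame
    kept: pd.DataFrame
    removed: pd.DataFrame
    contrast: FocalResult
    summary: pd.DataFrame
    pair_status: pd.DataFrame


def pair_label(a: str, b: str, order) -> str:
    ia, ib = order.index(a), order.index(b)
    return f"{order[min(ia, ib)]}-{order[max(ia, ib)]}"


def run_search(records, evalue_cutoff: float = 1e-6, isoform_grouping: bool = True) -> dict:
    """All-vs-all similarity search between every ordered species pair."""
    species = list(records)
    search_sets = {
        sp: longest_isoforms(records[sp]) if isoform_grouping else list(records[sp])
        for sp in species
    }
    hits = {}
    for qs in species:
        for ts in species:
            if qs == ts:
                continue
            hits[(qs, ts)] = all_vs_all(search_sets[qs], search_sets[ts], evalue_cutoff=evalue_cutoff)
    return hits


def find_triplets(records, hits, strategy: str = "BBH", evalue_cutoff: float = 1e-6,
                  min_identity: float = 60.0, inflation: float = 1.5) -> list:
    """1:1:1 ortholog triplets by BBH triangle closure or Markov clustering."""
    species = list(records)
    a, b, c = species
    if strategy == "BBH":
        p_ab, _ = bbh_pairs(hits[(a, b)], hits[(b, a)], evalue_cutoff, min_identity)
        p_bc, _ = bbh_pairs(hits[(b, c)], hits[(c, b)], evalue_cutoff, min_identity)
        p_ac, _ = bbh_pairs(hits[(a, c)], hits[(c, a)], evalue_cutoff, min_identity)
        return triplets_from_bbh(p_ab, p_bc, p_ac, records)
    if strategy == "MCL":
        species_of = {rec.id: sp for sp in species for rec in records[sp]}
        graph = build_similarity_graph(list(hits.values()), species_of)
        clusters = mcl_cluster(graph, inflation=inflation)
        all_hits = [h for hs in hits.values() for h in hs]
        return [select_representatives(cl, all_hits, records) for cl in clusters]
    raise ValueError(f"unknown strategy {strategy!r}")


def estimate_pairs(records, triplets, method: str = "YN", qc_kwargs: dict | None = None) -> pd.DataFrame:
    """Codon-align and estimate dN/dS for every retained triplet and pair."""
    estimator = _ESTIMATORS[method]
    species = list(records)
    rec_of = {rec.id: rec for sp in species for rec in records[sp]}
    rows = []
    for tri in triplets:
        if tri.excluded:
            continue
        cluster_id = tri.gene_ids[species[0]]
        for i in range(3):
            for j in range(i + 1, 3):
                ra = rec_of[tri.gene_ids[species[i]]]
                rb = rec_of[tri.gene_ids[species[j]]]
                pa, pb = ra.search_protein, rb.search_protein
                _, row_a, row_b = global_align(pa, pb)
                aln = backtranslate(row_a, row_b, ra.cds, rb.cds, id_a=ra.id, id_b=rb.id)
                qc = alignment_qc(aln, **(qc_kwargs or {}))
                est = estimator(aln)
                rows.append(
                    {
                        "cluster_id": cluster_id,
                        "pair": pair_label(species[i], species[j], species),
                        "id_a": ra.id,
                        "id_b": rb.id,
                        "method": est.method,
                        "dN": est.dN,
                        "dS": est.dS,
                        "omega": est.omega,
                        "kappa": est.kappa,
                        "p_value": est.p_value,
                        "loglik": est.loglik,
                        "aligned_len_bp": est.aligned_len_bp,
                        "qc_pass": qc.passed,
                        "qc_reason": qc.reason,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(
    records: dict,
    focal: str,
    method: str = "YN",
    strategy: str = "BBH",
    evalue_cutoff: float = 1e-6,
    min_identity: float = 60.0,
    filter_config: FilterConfig | None = None,
    isoform_grouping: bool = True,
    strict_contrast: bool = False,
) -> PipelineResult:
    """Run the full selection scan on three species' coding-sequence sets.

    ``records`` maps species name -> list of CodingRecord; the first species
    pairing order is taken from dict order. ``focal`` names the species whose
    lineage is contrasted against the other two.
    """
    species = tuple(records)
    if len(species) != 3:
        raise ValueError("exactly three species required")
    if focal not in species:
        raise ValueError(f"focal species {focal!r} not among {species}")
    cfg = filter_config or FilterConfig()

    hits = run_search(records, evalue_cutoff=evalue_cutoff, isoform_grouping=isoform_grouping)
    triplets = find_triplets(records, hits, strategy=strategy, evalue_cutoff=evalue_cutoff,
                             min_identity=min_identity)
    estimates = estimate_pairs(records, triplets, method=method)

    kept, removed = apply_filters(estimates, cfg)
    called = call_psg(kept, cfg)

    status_rows = []
    if len(called):
        for row in called.itertuples(index=False):
            status_rows.append({"cluster_id": row.cluster_id, "pair": row.pair, "status": row.call})
    if len(removed):
        for row in removed.itertuples(index=False):
            status_rows.append({"cluster_id": row.cluster_id, "pair": row.pair, "status": FILTERED})
    pair_status = pd.DataFrame(status_rows, columns=["cluster_id", "pair", "status"])

    contrast = focal_contrast(pair_status, focal, strict=strict_contrast)
    summary = summarize(called)
    return PipelineResult(
        species=species,
        focal=focal,
        method=method,
        strategy=strategy,
        hits=hits,
        triplets=triplets,
        estimates=estimates,
        kept=kept,
        removed=removed,
        contrast=contrast,
        summary=summary,
        pair_status=pair_status,
    )


# ---------------------------------------------------------------------------
# Ground-truth evaluation for simulated studies

def evaluate_against_truth(result: PipelineResult, truth: pd.DataFrame, focal: str) -> dict:
    """Recovery metrics of the planted signal for a simulated study.

    Cluster ids are matched to truth rows through the focal species' gene id.
    Returns planted-class recovery and false-positive rates plus paralog
    leakage into retained triplets.
    """
    id_col = f"id_{focal}"
    truth_by_focal_id = {row[id_col]: row for _, row in truth.iterrows() if row[id_col]}

    focal_shift_ids = [
        row[id_col] for _, row in truth.iterrows()
        if row["planted_class"] == "focal-shift" and row[id_col]
    ]
    neutral_ids = [
        row[id_col] for _, row in truth.iterrows()
        if row["planted_class"] == "neutral-low" and row[id_col]
    ]
    paralog_seq_ids = {
        row[f"id_{sp}"]
        for _, row in truth.iterrows()
        if row["planted_class"] == "paralog"
        for sp in result.species
        if row[f"id_{sp}"]
    }

    candidates = set(result.contrast.candidates)
    selected_any = set()
    if len(result.kept):
        called = call_psg(result.kept)
        selected_any = set(called.loc[called["call"] == "selected", "cluster_id"])

    retained_ids = {
        g for tri in result.triplets if not tri.excluded for g in tri.gene_ids.values()
    }
    n_focal = len(focal_shift_ids)
    n_neutral = len(neutral_ids)
    return {
        "n_focal_shift": n_focal,
        "n_focal_shift_recovered": sum(1 for g in focal_shift_ids if g in candidates),
        "focal_shift_recovery": (
            sum(1 for g in focal_shift_ids if g in candidates) / n_focal if n_focal else float("nan")
        ),
        "n_neutral": n_neutral,
        "n_neutral_selected_any_pair": sum(1 for g in neutral_ids if g in selected_any),
        "neutral_false_positive_rate": (
            sum(1 for g in neutral_ids if g in selected_any) / n_neutral if n_neutral else float("nan")
        ),
        "paralogs_in_retained_triplets": sorted(paralog_seq_ids & retained_ids),
        "n_retained_triplets": sum(1 for t in result.triplets if not t.excluded),
    }
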