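"""Validity filters, positive-selection calls and the three-way contrast.

Pairwise estimates are filtered (dS < 0.01 removed as unreliable, dS > 1
as saturated, dN > 1, aligned length < 150 bp), genes are called positively
selected per species pair when dN/dS > 0.5 with Fisher P < 0.05 and a clean
alignment, and the focal contrast retains clusters selected in *both*
focal-involving comparisons but not in the comparison between the two
relatives. Venn-style region counts over the three per-pair call sets and
Table-style summaries are emitted alongside.

By default the Fisher-P condition acts at the calling stage only: pairs with
P > 0.05 stay in the filtered set (and its summary means) but cannot be
called selected. Setting ``p_filter_stage="remove"`` excludes them outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

REASON_LOW_DS = "low-dS"
REASON_SATURATED = "saturated"
REASON_HIGH_DN = "high-dN"
REASON_SHORT = "short-alignment"
REASON_HIGH_P = "high-P"

SELECTED = "selected"
NOT_SELECTED = "not-selected"
FILTERED = "filtered"


@dataclass
class FilterConfig:
    """Validity-filter and calling thresholds."""

    ds_min: float = 0.01
    ds_max: float = 1.0
    dn_max: float = 1.0
    min_aligned_bp: int = 150
    p_max: float = 0.05
    omega_threshold: float = 0.5
    p_filter_stage: str = "call"  # "call" | "remove"
    bh_correct: bool = False

    def __post_init__(self):
        if not 0 < self.ds_min < self.ds_max:
            raise ValueError("need 0 < ds_min < ds_max")
        if self.omega_threshold <= 0:
            raise ValueError("omega_threshold must be > 0")
        if self.p_filter_stage not in ("call", "remove"):
            raise ValueError("p_filter_stage must be 'call' or 'remove'")


def _removal_reason(row, cfg: FilterConfig) -> str | None:
    ds, dn = row["dS"], row["dN"]
    if not math.isnan(ds) and ds < cfg.ds_min:
        return REASON_LOW_DS
    if math.isnan(ds) or math.isinf(ds) or ds > cfg.ds_max:
        return REASON_SATURATED
    if math.isnan(dn) or math.isinf(dn) or dn > cfg.dn_max:
        return REASON_HIGH_DN
    if row["aligned_len_bp"] < cfg.min_aligned_bp:
        return REASON_SHORT
    if cfg.p_filter_stage == "remove" and row["p_value"] > cfg.p_max:
        return REASON_HIGH_P
    return None


def apply_filters(estimates: pd.DataFrame, cfg: FilterConfig | None = None):
    """Split estimate rows into kept and removed, logging the first
    applicable removal reason (dS-low, saturated, dN-high, short, then P
    when ``p_filter_stage="remove"``)."""
    cfg = cfg or FilterConfig()
    reasons = estimates.apply(_removal_reason, axis=1, cfg=cfg) if len(estimates) else pd.Series(dtype=object)
    keep_mask = reasons.isna() if len(estimates) else pd.Series(dtype=bool)
    kept = estimates[keep_mask].copy() if len(estimates) else estimates.copy()
    removed = estimates[~keep_mask].copy() if len(estimates) else estimates.copy()
    if len(removed):
        removed["reason"] = reasons[~keep_mask]
    else:
        removed["reason"] = pd.Series(dtype=object)
    return kept, removed


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    cummin = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * n / rank_from_top
        cummin = min(cummin, val)
        adj[i] = cummin
    return adj


def call_psg(kept: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-row positive-selection call for one species pair.

    "selected" iff omega > omega_threshold (strict) AND P < p_max AND the
    alignment QC passed. With ``bh_correct`` the P-values are
    Benjamini-Hochberg adjusted across the rows first (off by default).
    """
    cfg = cfg or FilterConfig()
    out = kept.copy()
    if len(out) == 0:
        out["call"] = pd.Series(dtype=object)
        return out
    p = out["p_value"].to_numpy(dtype=float)
    if cfg.bh_correct:
        p = _bh_adjust(p)
    qc = out["qc_pass"].to_numpy(dtype=bool) if "qc_pass" in out else np.ones(len(out), dtype=bool)
    omega = out["omega"].to_numpy(dtype=float)
    selected = (omega > cfg.omega_threshold) & (p < cfg.p_max) & qc
    selected &= ~np.isnan(omega)
    out["call"] = np.where(selected, SELECTED, NOT_SELECTED)
    return out


@dataclass
class PsgCall:
    """Per-cluster status across the three species-pair comparisons."""

    cluster_id: str
    pair_status: dict  # pair label -> selected | not-selected | filtered (or absent)
    focal_candidate: bool


@dataclass
class FocalResult:
    candidates: list
    relaxed: list
    calls: list
    venn: dict
    venn_pairs: tuple
    missing_log: list = field(default_factory=list)


def focal_contrast(pair_status: pd.DataFrame, focal_species: str, strict: bool = False) -> FocalResult:
    """Three-way aquatic-vs-terrestrial style contrast.

    ``pair_status`` has columns (cluster_id, pair, status) with pair labels of
    the form "speciesX-speciesY" and status in {selected, not-selected,
    filtered}. A cluster is a focal candidate iff both pairs involving
    ``focal_species`` are "selected" and the remaining pair is not "selected";
    in strict mode the remaining pair must be an un-filtered "not-selected".
    The relaxed set contains clusters selected in at least one focal pair.
    Venn region counts are computed over clusters with all three pairs
    un-filtered; clusters missing a pair are logged and skipped for the Venn.
    """
    pairs = sorted(pair_status["pair"].unique())
    if len(pairs) != 3:
        raise ValueError(f"expected 3 species pairs, got {pairs}")
    focal_pairs = [p for p in pairs if focal_species in p.split("-")]
    if len(focal_pairs) != 2:
        raise ValueError(f"focal species {focal_species!r} must appear in exactly 2 pairs")
    other_pair = next(p for p in pairs if p not in focal_pairs)

    status: dict = {}
    for row in pair_status.itertuples(index=False):
        status.setdefault(row.cluster_id, {})[row.pair] = row.status

    calls, candidates, relaxed, missing = [], [], [], []
    venn_counts = {}
    for cid in sorted(status):
        st = status[cid]
        f1, f2 = (st.get(p) for p in focal_pairs)
        other = st.get(other_pair)
        focal_ok = f1 == SELECTED and f2 == SELECTED
        if strict:
            cand = focal_ok and other == NOT_SELECTED
        else:
            cand = focal_ok and other != SELECTED
        calls.append(PsgCall(cid, dict(st), cand))
        if cand:
            candidates.append(cid)
        if f1 == SELECTED or f2 == SELECTED:
            relaxed.append(cid)
        if len(st) < 3:
            missing.append((cid, sorted(set(pairs) - set(st))))
            continue
        if any(st[p] == FILTERED for p in pairs):
            continue
        membership = frozenset(p for p in pairs if st[p] == SELECTED)
        key = "&".join(sorted(membership)) if membership else "none"
        venn_counts[key] = venn_counts.get(key, 0) + 1

    for r in range(1, 4):
        for combo in combinations(pairs, r):
            venn_counts.setdefault("&".join(sorted(combo)), 0)
    venn_counts.setdefault("none", 0)
    return FocalResult(
        candidates=candidates,
        relaxed=relaxed,
        calls=calls,
        venn=venn_counts,
        venn_pairs=tuple(pairs),
        missing_log=missing,
    )


def venn_union_size(venn: dict) -> int:
    """|A ∪ B ∪ C| from exclusive region counts (everything except "none")."""
    return sum(v for k, v in venn.items() if k != "none")


def venn_set_sizes(venn: dict, pairs) -> dict:
    """Per-set totals |A|, |B|, |C| from the exclusive region counts."""
    sizes = {p: 0 for p in pairs}
    for key, count in venn.items():
        if key == "none":
            continue
        for p in key.split("&"):
            sizes[p] += count
    return sizes


def summarize(kept_with_calls: pd.DataFrame, groupby=("pair", "method")) -> pd.DataFrame:
    """Table-style summary per species pair (and estimator/strategy keys).

    Reports the filtered-pair count with mean dN, dS and dN/dS plus median
    and mean aligned lengths, then the same statistics over the selected
    subset. Empty subsets yield NaN means.
    """
    rows = []
    groupby = [g for g in groupby if g in kept_with_calls.columns]
    if not groupby:
        groupby = ["pair"]
    grouped = kept_with_calls.groupby(list(groupby), sort=True) if len(kept_with_calls) else []
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        sel = grp[grp["call"] == SELECTED] if "call" in grp else grp.iloc[0:0]
        row = dict(zip(groupby, key))
        row.update(
            n_after_filter=len(grp),
            mean_dn=grp["dN"].mean(),
            mean_ds=grp["dS"].mean(),
            mean_omega=grp["omega"].mean(),
            median_aligned_bp=grp["aligned_len_bp"].median(),
            mean_aligned_bp=grp["aligned_len_bp"].mean(),
            n_selected=len(sel),
            selected_mean_dn=sel["dN"].mean() if len(sel) else math.nan,
            selected_mean_ds=sel["dS"].mean() if len(sel) else math.nan,
            selected_mean_omega=sel["omega"].mean() if len(sel) else math.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quartet congruence

TOPOLOGY_FOCAL_A = "focal-with-relative_a"
TOPOLOGY_FOCAL_B = "focal-with-relative_b"
TOPOLOGY_FOCAL_OUT = "focal-with-outgroup"
AMBIGUOUS = "ambiguous"


def _quartet_parsimony(x: str, y: str, z: str, w: str) -> int:
    """Fitch parsimony score of the unrooted quartet ((x,y),(z,w))."""
    score = 0
    for a, b, c, d in zip(x, y, z, w):
        s1 = {a} & {b} or {a, b}
        if not ({a} & {b}):
            score += 1
        s2 = {c} & {d} or {c, d}
        if not ({c} & {d}):
            score += 1
        if not (s1 & s2):
            score += 1
    return score


def quartet_congruence(focal: str, relative_a: str, relative_b: str, outgroup: str):
    """Parsimony comparison of the three unrooted quartet topologies.

    All four protein sequences must be aligned to equal length. Returns
    (best_topology, congruent) where ``congruent`` is True iff the uniquely
    best topology groups the focal species with relative A, mirroring the
    species tree ((focal, relativeA), relativeB). Ties give "ambiguous".
    """
    seqs = (focal, relative_a, relative_b, outgroup)
    if any(not s for s in seqs):
        raise ValueError("four non-empty aligned sequences required")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    scores = {
        TOPOLOGY_FOCAL_A: _quartet_parsimony(focal, relative_a, relative_b, outgroup),
        TOPOLOGY_FOCAL_B: _quartet_parsimony(focal, relative_b, relative_a, outgroup),
        TOPOLOGY_FOCAL_OUT: _quartet_parsimony(focal, outgroup, relative_a, relative_b),
    }
    best_score = min(scores.values())
    best = [k for k, v in scores.items() if v == best_score]
    if len(best) > 1:
        return AMBIGUOUS, False
    return best[0], best[0] == TOPOLOGY_FOCAL_A
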