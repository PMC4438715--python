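"""Pairwise dN/dS estimation on codon alignments.

Three estimators are provided:

``ng86``
    Nei-Gojobori counting: per-codon synonymous site fractions, minimal
    mutational pathway averaging for multi-position codon differences, and
    Jukes-Cantor multiple-hit correction. Serves as the transparent
    counting method against which the others are checked.

``yn00``
    An approximate method in the style of Yang & Nielsen: codon frequencies
    estimated by F3x4 from the pair, a transition/transversion ratio (kappa)
    estimated from fourfold-degenerate and nondegenerate sites by K80, site
    and difference counts weighted by kappa and target-codon frequency, and
    a kappa-aware (K80-style) multiple-hit correction per site class. With
    kappa = 1 and uniform frequencies it reduces exactly to NG86 on
    alignments free of multi-position codon differences.

``ml_pairwise``
    Maximum likelihood under a small family of GY94-style models (kappa
    fixed/free x uniform/F3x4 frequencies), with the reported dN, dS and
    omega averaged over models by AICc weight.

A 2x2 Fisher exact test on (rounded) synonymous/nonsynonymous sites and
differences accompanies each estimate; it asks whether substitutions are
distributed across site classes out of proportion to the sites themselves,
i.e. whether omega differs detectably from 1.

Saturated corrections return ``math.inf`` as a sentinel; downstream filters
remove such pairs via the dS > 1 rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.stats import hypergeom

from ._codons import (
    BASES,
    CODON_INDEX,
    GENETIC_CODE,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
)
from .align import CodonAlignment
from .simulate import CodonModel, _flow, _NB_NONSYN, gy94_rate_matrix, transition_kernel

SATURATED = math.inf


class EmptyAlignmentError(ValueError):
    pass


@dataclass
class SubstitutionCounts:
    """Synonymous/nonsynonymous sites and (pathway-averaged) differences."""

    S: float
    N: float
    Sd: float
    Nd: float

    def __post_init__(self):
        if self.S < 0 or self.N < 0 or self.Sd < -1e-12 or self.Nd < -1e-12:
            raise ValueError("counts must be non-negative")


@dataclass
class PairEstimate:
    """One estimator's result for one ortholog pair."""

    method: str
    dN: float
    dS: float
    omega: float  # nan when undefined (dS == 0 or saturated)
    p_value: float
    kappa: float | None = None
    loglik: float | None = None
    counts: SubstitutionCounts | None = None
    aligned_len_bp: int = 0

    @property
    def saturated(self) -> bool:
        return math.isinf(self.dS) or math.isinf(self.dN)


# ---------------------------------------------------------------------------
# NG86 machinery

@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of a sense codon: per position, the
    fraction of the 3 possible nucleotide changes that are synonymous
    (changes to stop codons count as nonsynonymous)."""
    total = 0.0
    for p in range(3):
        syn = 0
        for nt in BASES:
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathways(ca: str, cb: str):
    """Minimal mutational pathways between two sense codons.

    Each pathway is a tuple of steps (source, target, synonymous, transition);
    pathways passing through stop codons are discarded. Returns (pathways,
    diff_positions).
    """
    diffs = tuple(p for p in range(3) if ca[p] != cb[p])
    paths = []
    for order in permutations(diffs):
        cur = ca
        steps = []
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt, GENETIC_CODE[cur] == GENETIC_CODE[nxt], is_transition(cur[p], cb[p])))
            cur = nxt
        if ok:
            paths.append(tuple(steps))
    return tuple(paths), diffs


def _positionwise_counts(ca: str, cb: str) -> tuple[float, float]:
    """Fallback when every minimal pathway is stop-routed: each differing
    position contributes its own comparison, evaluated in the context of
    each source codon and averaged over the two directions."""
    sd = nd = 0.0
    for p in range(3):
        if ca[p] == cb[p]:
            continue
        syn_frac = 0.0
        for src, dst_nt in ((ca, cb[p]), (cb, ca[p])):
            alt = src[:p] + dst_nt + src[p + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[src]:
                syn_frac += 0.5
        sd += syn_frac
        nd += 1.0 - syn_frac
    return sd, nd


def _pair_diff_counts(ca: str, cb: str) -> tuple[float, float]:
    """Unweighted NG86 pathway-averaged (Sd, Nd) for one codon column."""
    if ca == cb:
        return 0.0, 0.0
    paths, _ = _pathways(ca, cb)
    if not paths:
        return _positionwise_counts(ca, cb)
    sd = sum(sum(1 for s in p if s[2]) for p in paths) / len(paths)
    nd = sum(sum(1 for s in p if not s[2]) for p in paths) / len(paths)
    return sd, nd


def ng86_counts(aln: CodonAlignment) -> SubstitutionCounts:
    """Nei-Gojobori site and difference counts over the sense columns."""
    cols = aln.sense_columns()
    if not cols:
        raise EmptyAlignmentError("empty alignment: no usable codon columns")
    S = sum((_syn_site_fraction(a) + _syn_site_fraction(b)) / 2.0 for a, b in cols)
    Sd = Nd = 0.0
    for a, b in cols:
        sd, nd = _pair_diff_counts(a, b)
        Sd += sd
        Nd += nd
    return SubstitutionCounts(S=S, N=3.0 * len(cols) - S, Sd=Sd, Nd=Nd)


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns the SATURATED sentinel (inf) for p >= 3/4.
    """
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _omega_of(dn: float, ds: float) -> float:
    if math.isinf(dn) or math.isinf(ds) or ds == 0:
        return math.nan
    return dn / ds


def ng86(aln: CodonAlignment) -> PairEstimate:
    counts = ng86_counts(aln)
    ds = jc_correct(counts.Sd / counts.S) if counts.S > 0 else math.nan
    dn = jc_correct(counts.Nd / counts.N) if counts.N > 0 else math.nan
    return PairEstimate(
        method="NG86",
        dN=dn,
        dS=ds,
        omega=_omega_of(dn, ds),
        p_value=fisher_validity(counts),
        counts=counts,
        aligned_len_bp=aln.aligned_len_bp,
    )


# ---------------------------------------------------------------------------
# YN00-style approximate method

@lru_cache(maxsize=None)
def _degeneracy(codon: str, pos: int) -> int:
    """Number of synonymous nucleotide changes at a codon position (0..3)."""
    syn = 0
    for nt in BASES:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
            syn += 1
    return syn


def _k80_kappa(ts: float, tv: float, n: float) -> float | None:
    """K80 kappa estimate from transition/transversion proportions."""
    if n <= 0:
        return None
    P, Q = ts / n, tv / n
    if P + Q == 0:
        return None
    x = 1.0 - 2.0 * P - Q
    y = 1.0 - 2.0 * Q
    if x <= 0 or y <= 0:
        return None
    beta_t = -0.25 * math.log(y)
    alpha_t = -0.5 * math.log(x) - beta_t
    if beta_t <= 0:
        return 99.0
    if alpha_t <= 0:
        return None
    return alpha_t / beta_t


def estimate_kappa(cols) -> float:
    """kappa from fourfold-degenerate and nondegenerate sites via K80.

    Site positions are used when both codons of a column agree on the
    degeneracy class (4-fold or 0-fold) at that position. Falls back to 1.0
    when neither class yields an estimate.
    """
    stats = {4: [0.0, 0.0, 0.0], 0: [0.0, 0.0, 0.0]}  # class -> [n, ts, tv]
    for ca, cb in cols:
        for p in range(3):
            da, db = _degeneracy(ca, p), _degeneracy(cb, p)
            for cls, want in ((4, 3), (0, 0)):
                if da == want and db == want:
                    stats[cls][0] += 1
                    if ca[p] != cb[p]:
                        if is_transition(ca[p], cb[p]):
                            stats[cls][1] += 1
                        else:
                            stats[cls][2] += 1
    estimates = []
    for cls in (4, 0):
        n, ts, tv = stats[cls]
        k = _k80_kappa(ts, tv, n)
        if k is not None:
            estimates.append((n, k))
    if not estimates:
        return 1.0
    total = sum(n for n, _ in estimates)
    kappa = sum(n * k for n, k in estimates) / total
    return min(max(kappa, 0.1), 99.0)


def _f3x4_weights(cols) -> dict:
    """Unnormalized F3x4 codon weights (over all 64 codons) from the pair."""
    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for ca, cb in cols:
        for c in (ca, cb):
            for p in range(3):
                counts[p, base_idx[c[p]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    out = {}
    for c0 in BASES:
        for c1 in BASES:
            for c2 in BASES:
                codon = c0 + c1 + c2
                out[codon] = freqs[0, base_idx[c0]] * freqs[1, base_idx[c1]] * freqs[2, base_idx[c2]]
    return out


def _uniform_weights() -> dict:
    return {a + b + c: 1.0 for a in BASES for b in BASES for c in BASES}


def _weighted_site_fraction(codon: str, kappa: float, w: dict) -> float:
    """Synonymous site count of a codon with kappa/frequency-weighted changes.

    Per position, (sum of weights of synonymous changes) / (sum of weights of
    all three changes, stop targets included), summed over positions. With
    kappa = 1 and uniform weights this equals the NG86 site fraction.
    """
    total = 0.0
    for p in range(3):
        syn_w = all_w = 0.0
        for nt in BASES:
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            wt = (kappa if is_transition(codon[p], nt) else 1.0) * w[alt]
            all_w += wt
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                syn_w += wt
        if all_w > 0:
            total += syn_w / all_w
    return total


def _weighted_diff_counts(ca: str, cb: str, kappa: float, w: dict) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) with pathways weighted by the product of
    per-step kappa and target-codon weights, averaged over both directions."""
    if ca == cb:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    for src, dst in ((ca, cb), (cb, ca)):
        paths, _ = _pathways(src, dst)
        if not paths:
            sd, nd = _positionwise_counts(src, dst)
        else:
            weights = []
            for path in paths:
                wt = 1.0
                for _, target, _, ts in path:
                    wt *= (kappa if ts else 1.0) * w[target]
                weights.append(wt)
            z = sum(weights)
            if z == 0:
                weights = [1.0] * len(paths)
                z = float(len(paths))
            sd = sum(wt * sum(1 for s in p if s[2]) for wt, p in zip(weights, paths)) / z
            nd = sum(wt * sum(1 for s in p if not s[2]) for wt, p in zip(weights, paths)) / z
        sd_total += sd / 2.0
        nd_total += nd / 2.0
    return sd_total, nd_total


def _k80_p_of_d(d: float, kappa: float) -> float:
    """Expected proportion of differing sites after distance d under K80
    with transition/transversion rate ratio kappa."""
    beta_t = d / (kappa + 2.0)
    return 0.75 - 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))


def k80_correct(p: float, kappa: float) -> float:
    """Invert the K80 saturation curve p(d; kappa); kappa = 1 reduces exactly
    to Jukes-Cantor. Returns the SATURATED sentinel for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return SATURATED
    if kappa == 1.0:
        return jc_correct(p)
    hi = 1.0
    while _k80_p_of_d(hi, kappa) < p:
        hi *= 2.0
        if hi > 1e4:
            return SATURATED
    return brentq(lambda d: _k80_p_of_d(d, kappa) - p, 0.0, hi, xtol=1e-12, rtol=1e-14)


def yn00_counts(aln: CodonAlignment, kappa: float | None = None, freqs: str = "f3x4"):
    """Weighted site/difference counts and the kappa used.

    ``freqs``: "f3x4" (estimated from the pair) or "uniform".
    """
    cols = aln.sense_columns()
    if not cols:
        raise EmptyAlignmentError("empty alignment: no usable codon columns")
    if kappa is None:
        kappa = estimate_kappa(cols)
    w = _f3x4_weights(cols) if freqs == "f3x4" else _uniform_weights()
    S = sum((_weighted_site_fraction(a, kappa, w) + _weighted_site_fraction(b, kappa, w)) / 2.0 for a, b in cols)
    Sd = Nd = 0.0
    for a, b in cols:
        sd, nd = _weighted_diff_counts(a, b, kappa, w)
        Sd += sd
        Nd += nd
    return SubstitutionCounts(S=S, N=3.0 * len(cols) - S, Sd=Sd, Nd=Nd), kappa


def yn00(aln: CodonAlignment, kappa: float | None = None, freqs: str = "f3x4") -> PairEstimate:
    """YN00-style approximate dN/dS estimate.

    kappa is estimated from degenerate-site classes unless given; sites and
    differences are weighted by kappa and target-codon (F3x4) frequency; the
    multiple-hit correction inverts the kappa-parameterized K80 curve.
    """
    counts, kappa_used = yn00_counts(aln, kappa=kappa, freqs=freqs)
    ds = k80_correct(counts.Sd / counts.S, kappa_used) if counts.S > 0 else math.nan
    dn = k80_correct(counts.Nd / counts.N, kappa_used) if counts.N > 0 else math.nan
    return PairEstimate(
        method="YN",
        dN=dn,
        dS=ds,
        omega=_omega_of(dn, ds),
        p_value=fisher_validity(counts),
        kappa=kappa_used,
        counts=counts,
        aligned_len_bp=aln.aligned_len_bp,
    )


# ---------------------------------------------------------------------------
# Fisher exact validity test

def fisher_validity(counts: SubstitutionCounts) -> float:
    """Two-sided Fisher exact P for the 2x2 table
    [[round(Sd), round(Nd)], [round(S - Sd), round(N - Nd)]].

    Fractional entries are rounded half-even and negative cells clamped to 0;
    any zero margin gives P = 1 by convention. The two-sided P sums
    hypergeometric probabilities of tables at most as probable as the
    observed one (relative tolerance 1e-12).
    """
    a = max(round(counts.Sd), 0)
    b = max(round(counts.Nd), 0)
    c = max(round(counts.S - counts.Sd), 0)
    d = max(round(counts.N - counts.Nd), 0)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# ML with model averaging

#: (name, kappa free?, F3x4 frequencies?)
DEFAULT_MODEL_SET = (
    ("K1-uniform", False, False),
    ("Kfree-uniform", True, False),
    ("K1-F3x4", False, True),
    ("Kfree-F3x4", True, True),
)

T_BOUNDS = (1e-4, 5.0)
OMEGA_BOUNDS = (1e-4, 10.0)
KAPPA_BOUNDS = (0.1, 20.0)
_OUTER_STARTS = ((0.2, 2.0), (1.0, 2.0), (3.0, 5.0))  # (omega, kappa)


def _count_matrix(cols) -> np.ndarray:
    c = np.zeros((N_SENSE, N_SENSE))
    for a, b in cols:
        c[CODON_INDEX[a], CODON_INDEX[b]] += 1.0
    return c


def _f3x4_pi(cols) -> np.ndarray:
    w = _f3x4_weights(cols)
    pi = np.array([w[c] for c in SENSE_CODONS])
    pi = np.maximum(pi, 1e-6)  # absent codons keep a tiny mass (kernel stays well-defined)
    return pi / pi.sum()


class _PairLikelihood:
    """log L(t, kappa, omega) = sum_cols log(pi_a P(t)_ab) for one model."""

    def __init__(self, counts_mat: np.ndarray, pi: np.ndarray):
        self.counts = counts_mat
        self.pi = pi
        self.mask = counts_mat > 0
        self.obs = counts_mat[self.mask]
        self.log_pi_a = np.log(np.maximum(pi, 1e-300))[np.nonzero(self.mask)[0]]

    def loglik(self, t: float, kappa: float, omega: float) -> float:
        model = CodonModel(pi=self.pi, kappa=kappa, omega=omega)
        p = transition_kernel(gy94_rate_matrix(model), self.pi, t)
        vals = np.log(np.maximum(p[self.mask], 1e-300)) + self.log_pi_a
        return float(np.sum(self.obs * vals))

    def profile_t(self, kappa: float, omega: float):
        """Maximize over t for fixed (kappa, omega); reuses one eigen-decomposition."""
        model = CodonModel(pi=self.pi, kappa=kappa, omega=omega)
        q = gy94_rate_matrix(model)
        d = np.sqrt(self.pi)
        b = (q * d[:, None]) / d[None, :]
        b = (b + b.T) / 2.0
        w, u = np.linalg.eigh(b)
        rows, cols_idx = np.nonzero(self.mask)
        left = (u / d[:, None])[rows]
        right = (u * d[:, None])[cols_idx]

        def neg(t: float) -> float:
            pvals = np.sum(left * np.exp(w * t) * right, axis=1)
            vals = np.log(np.maximum(pvals, 1e-300)) + self.log_pi_a
            return -float(np.sum(self.obs * vals))

        res = minimize_scalar(neg, bounds=T_BOUNDS, method="bounded",
                              options={"xatol": 1e-5})
        return float(res.x), -float(res.fun)


def _fit_model(lik: _PairLikelihood, kappa_free: bool):
    """Fit one candidate model; returns (t, kappa, omega, loglik).

    kappa-fixed models profile omega by bounded 1-D search; kappa-free models
    use Nelder-Mead over (log omega, log kappa) from a fixed 3-point start
    grid for determinism. t is profiled out in both cases.
    """
    best = None
    if not kappa_free:
        res = minimize_scalar(
            lambda x: -lik.profile_t(1.0, float(np.clip(math.exp(x), *OMEGA_BOUNDS)))[1],
            bounds=(math.log(OMEGA_BOUNDS[0]), math.log(OMEGA_BOUNDS[1])),
            method="bounded", options={"xatol": 1e-4},
        )
        if not np.isfinite(res.fun):
            return None
        omega = float(np.clip(math.exp(res.x), *OMEGA_BOUNDS))
        t, ll = lik.profile_t(1.0, omega)
        return (t, 1.0, omega, ll)

    def _from_log(x, bounds):
        return float(math.exp(np.clip(x, math.log(bounds[0]), math.log(bounds[1]))))

    def outer(x):
        _, ll = lik.profile_t(_from_log(x[1], KAPPA_BOUNDS), _from_log(x[0], OMEGA_BOUNDS))
        return -ll

    for om0, ka0 in _OUTER_STARTS:
        res = minimize(outer, [math.log(om0), math.log(ka0)], method="Nelder-Mead",
                       options={"xatol": 2e-3, "fatol": 1e-4, "maxiter": 150})
        if not np.isfinite(res.fun):
            continue
        omega = _from_log(res.x[0], OMEGA_BOUNDS)
        kappa = _from_log(res.x[1], KAPPA_BOUNDS)
        t, ll = lik.profile_t(kappa, omega)
        if best is None or ll > best[3]:
            best = (t, kappa, omega, ll)
    return best


def _model_dnds(pi: np.ndarray, kappa: float, omega: float, t: float):
    """Analytic dN/dS at the fitted parameters (sites defined at omega = 1)."""
    fitted = gy94_rate_matrix(CodonModel(pi=pi, kappa=kappa, omega=omega))
    neutral = gy94_rate_matrix(CodonModel(pi=pi, kappa=kappa, omega=1.0))
    f_syn = _flow(fitted, pi, mask=~_NB_NONSYN)
    f_nonsyn = _flow(fitted, pi, mask=_NB_NONSYN)
    s_sites = 3.0 * _flow(neutral, pi, mask=~_NB_NONSYN)  # per codon, nt units
    ds = t * f_syn / s_sites
    dn = t * f_nonsyn / (3.0 - s_sites)
    return dn, ds, s_sites


def ml_pairwise(aln: CodonAlignment, model_set=DEFAULT_MODEL_SET, min_columns: int = 50) -> PairEstimate:
    """ML dN/dS with AICc model averaging over a small GY94 model family.

    Below ``min_columns`` usable codon columns the data cannot support the
    ML fit and the YN00-style estimate is returned with a warning.
    """
    cols = aln.sense_columns()
    if not cols:
        raise EmptyAlignmentError("empty alignment: no usable codon columns")
    n = len(cols)
    if n < min_columns:
        warnings.warn(
            f"only {n} usable codon columns (< {min_columns}); falling back to YN00",
            stacklevel=2,
        )
        return yn00(aln)

    counts_mat = _count_matrix(cols)
    pi_uniform = np.full(N_SENSE, 1.0 / N_SENSE)
    pi_f3x4 = _f3x4_pi(cols)

    fits = []
    failures = []
    for name, kappa_free, use_f3x4 in model_set:
        pi = pi_f3x4 if use_f3x4 else pi_uniform
        lik = _PairLikelihood(counts_mat, pi)
        fit = _fit_model(lik, kappa_free)
        if fit is None:
            failures.append(name)
            continue
        t, kappa, omega, ll = fit
        k_params = 3 if kappa_free else 2  # t, omega (, kappa)
        aicc = 2 * k_params - 2 * ll
        if n - k_params - 1 > 0:
            aicc += 2 * k_params * (k_params + 1) / (n - k_params - 1)
        fits.append({"name": name, "pi": pi, "t": t, "kappa": kappa, "omega": omega,
                     "loglik": ll, "aicc": aicc})
    if not fits:
        raise RuntimeError(f"optimizer failed to converge for all models: {failures}")

    aiccs = np.array([f["aicc"] for f in fits])
    weights = np.exp(-(aiccs - aiccs.min()) / 2.0)
    weights /= weights.sum()

    dn_avg = ds_avg = omega_avg = kappa_avg = 0.0
    s_sites_avg = 0.0
    for wgt, f in zip(weights, fits):
        dn, ds, s_sites = _model_dnds(f["pi"], f["kappa"], f["omega"], f["t"])
        dn_avg += wgt * dn
        ds_avg += wgt * ds
        omega_avg += wgt * f["omega"]
        kappa_avg += wgt * f["kappa"]
        s_sites_avg += wgt * s_sites
    best = max(fits, key=lambda f: f["loglik"])

    # expected substitution counts for the validity test
    S = s_sites_avg * n
    N = 3.0 * n - S
    model_counts = SubstitutionCounts(S=S, N=N, Sd=min(ds_avg * S, S), Nd=min(dn_avg * N, N))
    return PairEstimate(
        method="ML-MA",
        dN=dn_avg,
        dS=ds_avg,
        omega=omega_avg,
        p_value=fisher_validity(model_counts),
        kappa=kappa_avg,
        loglik=best["loglik"],
        counts=model_counts,
        aligned_len_bp=aln.aligned_len_bp,
    )


def aicc_weights(fits_aicc) -> np.ndarray:
    """Normalized AICc weights (exposed for testing)."""
    a = np.asarray(fits_aicc, dtype=float)
    w = np.exp(-(a - a.min()) / 2.0)
    return w / w.sum()
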