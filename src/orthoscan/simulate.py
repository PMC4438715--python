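"""Codon-model simulation of a three-species comparative study.

Sequences evolve under a GY94-style codon model (61 sense codons; parameters
pi, kappa = transition/transversion rate ratio, omega = dN/dS) on the fixed
species tree ((focal, relativeA), relativeB). The study generator plants
per-gene, per-branch omega so the downstream ortholog/selection pipeline can
be validated with complete ground truth:

- ``neutral-low``     purifying selection everywhere (omega = 0.1)
- ``focal-shift``     elevated omega on the focal terminal branch only
- ``all-high``        relaxed constraint on every branch (omega = 0.8)
- ``short``           CDS shorter than 150 bp (should be length-filtered)
- ``internal-stop``   an in-frame stop codon (should be excluded as a cluster)
- paralogs            within-species duplicates with extra divergence

Branch lengths are in expected substitutions per codon for a neutral
(omega = 1) gene; inside ``simulate_study`` each branch kernel is scaled so
the *synonymous* rate is identical across omega classes. An omega shift then
changes only the nonsynonymous output, as selection acting on fixation would,
and the expected pairwise omega of a gene equals the branch-length-weighted
mean of its branch omegas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from ._codons import (
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    SINGLE_STEP_NEIGHBORS,
)
from .sequence_io import CodingRecord, write_fasta

# index arrays over single-nucleotide sense-codon moves, fixed by the code
_NB_I = np.array([n[0] for n in SINGLE_STEP_NEIGHBORS])
_NB_J = np.array([n[1] for n in SINGLE_STEP_NEIGHBORS])
_NB_TS = np.array([n[3] for n in SINGLE_STEP_NEIGHBORS])
_NB_NONSYN = np.array([n[4] for n in SINGLE_STEP_NEIGHBORS])


@dataclass(frozen=True)
class CodonModel:
    """GY94 parameterization: sense-codon frequencies, kappa, omega."""

    pi: np.ndarray
    kappa: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (N_SENSE,):
            raise ValueError(f"pi must have {N_SENSE} entries")
        if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be non-negative and sum to 1 within 1e-12")
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")

    @classmethod
    def uniform(cls, kappa: float = 1.0, omega: float = 1.0) -> "CodonModel":
        return cls(pi=np.full(N_SENSE, 1.0 / N_SENSE), kappa=kappa, omega=omega)

    @classmethod
    def f3x4(cls, position_freqs, kappa: float = 1.0, omega: float = 1.0) -> "CodonModel":
        """Codon frequencies as products of per-position nucleotide frequencies
        (3 x 4 array, rows = codon positions, columns = A,C,G,T), renormalized
        over the 61 sense codons."""
        pf = np.asarray(position_freqs, dtype=float)
        if pf.shape != (3, 4):
            raise ValueError("position_freqs must be 3x4 (positions x ACGT)")
        pf = pf / pf.sum(axis=1, keepdims=True)
        base_idx = {b: k for k, b in enumerate("ACGT")}
        pi = np.array(
            [pf[0, base_idx[c[0]]] * pf[1, base_idx[c[1]]] * pf[2, base_idx[c[2]]] for c in SENSE_CODONS]
        )
        return cls(pi=pi / pi.sum(), kappa=kappa, omega=omega)


def _unscaled_rate_matrix(model: CodonModel) -> np.ndarray:
    q = np.zeros((N_SENSE, N_SENSE))
    rates = model.pi[_NB_J] * np.where(_NB_TS, model.kappa, 1.0) * np.where(_NB_NONSYN, model.omega, 1.0)
    q[_NB_I, _NB_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _flow(q: np.ndarray, pi: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Expected substitution rate at stationarity, optionally over a move subset."""
    rates = q[_NB_I, _NB_J]
    if mask is not None:
        rates = rates * mask
    return float(np.sum(pi[_NB_I] * rates))


def gy94_rate_matrix(model: CodonModel) -> np.ndarray:
    """61x61 GY94 generator, scaled to one expected substitution per codon
    per unit time at stationarity. Rows sum to zero; satisfies detailed
    balance with respect to pi."""
    q = _unscaled_rate_matrix(model)
    total = _flow(q, model.pi)
    if total <= 0:
        raise ValueError("degenerate model: zero substitution rate")
    return q / total


def synonymous_scaled_rate_matrix(model: CodonModel) -> np.ndarray:
    """GY94 generator scaled so the synonymous flux matches the omega=1
    model's synonymous flux under total-rate-1 scaling.

    Under this scaling a branch length means the same number of expected
    synonymous substitutions regardless of omega, so omega shifts leave dS
    untouched and move only dN.
    """
    ref = replace(model, omega=1.0)
    q_ref = gy94_rate_matrix(ref)
    target_syn = _flow(q_ref, ref.pi, mask=~_NB_NONSYN)
    q = _unscaled_rate_matrix(model)
    syn = _flow(q, model.pi, mask=~_NB_NONSYN)
    return q * (target_syn / syn)


def transition_kernel(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetrization (the chain is reversible)."""
    if t < 0:
        raise ValueError("negative branch length")
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    b = (b + b.T) / 2.0
    w, u = np.linalg.eigh(b)
    p = (u * np.exp(w * t)) @ u.T
    p = p / d[:, None] * d[None, :]
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _sample_step(seq_idx: np.ndarray, kernel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(kernel[seq_idx], axis=1)
    u = rng.random(len(seq_idx))
    return np.minimum((cum < u[:, None]).sum(axis=1), N_SENSE - 1)


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def evolve(seq: str, model: CodonModel, t: float, seed: int | None = None,
           rng: np.random.Generator | None = None) -> str:
    """Evolve a sense-codon DNA sequence for time t under exp(Qt).

    Sites are independent; deterministic given the seed (or generator).
    """
    codons = codons_of(seq.upper())
    try:
        idx = np.array([CODON_INDEX[c] for c in codons])
    except KeyError as e:
        raise ValueError(f"non-sense codon in input: {e.args[0]}") from None
    if rng is None:
        rng = np.random.default_rng(seed)
    if t == 0:
        return seq.upper()
    kernel = transition_kernel(gy94_rate_matrix(model), model.pi, t)
    new = _sample_step(idx, kernel, rng)
    return "".join(SENSE_CODONS[i] for i in new)


# ---------------------------------------------------------------------------
# Study simulation

@dataclass(frozen=True)
class SpeciesTree:
    """((focal, relative_a), relative_b) with per-branch lengths.

    Lengths are expected substitutions per codon for an omega=1 gene (see
    module docstring). Defaults were calibrated once so that all three
    pairwise dS land in 0.2-0.4 and the focal terminal branch carries ~36%
    of both focal-pair paths.
    """

    focal: str = "bungei"
    relative_a: str = "brotherusii"
    relative_b: str = "cantoniensis"
    t_focal: float = 0.324
    t_relative_a: float = 0.576
    t_internal: float = 0.05
    t_relative_b: float = 0.526

    def __post_init__(self):
        for t in (self.t_focal, self.t_relative_a, self.t_internal, self.t_relative_b):
            if t < 0:
                raise ValueError("branch lengths must be >= 0")

    @property
    def species(self) -> tuple[str, str, str]:
        return (self.focal, self.relative_a, self.relative_b)

    def path_length(self, a: str, b: str) -> float:
        terms = {
            frozenset((self.focal, self.relative_a)): self.t_focal + self.t_relative_a,
            frozenset((self.focal, self.relative_b)): self.t_focal + self.t_internal + self.t_relative_b,
            frozenset((self.relative_a, self.relative_b)): self.t_relative_a + self.t_internal + self.t_relative_b,
        }
        return terms[frozenset((a, b))]


CLASS_NEUTRAL = "neutral-low"
CLASS_FOCAL_SHIFT = "focal-shift"
CLASS_ALL_HIGH = "all-high"
CLASS_SHORT = "short"
CLASS_INTERNAL_STOP = "internal-stop"
CLASS_PARALOG = "paralog"

DEFAULT_CLASS_PROPORTIONS = {
    CLASS_NEUTRAL: 0.74,
    CLASS_FOCAL_SHIFT: 0.10,
    CLASS_ALL_HIGH: 0.10,
    CLASS_SHORT: 0.03,
    CLASS_INTERNAL_STOP: 0.03,
}


@dataclass
class StudyConfig:
    """Conditions of the simulated three-species study."""

    n_genes: int = 200
    length_range: tuple[int, int] = (150, 600)  # codons, log-uniform
    short_length_range: tuple[int, int] = (20, 49)  # codons (< 150 bp)
    kappa: float = 2.0
    tree: SpeciesTree = field(default_factory=SpeciesTree)
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    omega_neutral: float = 0.1
    omega_focal_shift: float = 1.5
    omega_all_high: float = 0.8
    paralog_rate: float = 0.05
    paralog_extra_t: float = 0.5
    codon_freqs: str = "uniform"  # "uniform" | "f3x4"
    f3x4_position_freqs: tuple = (
        (0.30, 0.20, 0.30, 0.20),
        (0.30, 0.25, 0.20, 0.25),
        (0.20, 0.30, 0.25, 0.25),
    )

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        unknown = set(self.class_proportions) - {
            CLASS_NEUTRAL, CLASS_FOCAL_SHIFT, CLASS_ALL_HIGH, CLASS_SHORT, CLASS_INTERNAL_STOP
        }
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if not 0 <= self.paralog_rate <= 1:
            raise ValueError("paralog_rate must be in [0, 1]")

    def base_model(self, omega: float) -> CodonModel:
        if self.codon_freqs == "uniform":
            return CodonModel.uniform(kappa=self.kappa, omega=omega)
        if self.codon_freqs == "f3x4":
            return CodonModel.f3x4(np.array(self.f3x4_position_freqs), kappa=self.kappa, omega=omega)
        raise ValueError(f"unknown codon_freqs: {self.codon_freqs!r}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tree" in raw:
            raw["tree"] = SpeciesTree(**raw["tree"])
        for key in ("length_range", "short_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as e:
            raise ValueError(f"invalid study config: {e}") from None


def _class_counts(proportions: dict, n: int) -> dict:
    """Deterministic largest-remainder allocation of n genes to classes."""
    items = sorted(proportions.items())
    raw = [(name, p * n) for name, p in items]
    counts = {name: int(np.floor(x)) for name, x in raw}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda kv: (-(kv[1] - np.floor(kv[1])), kv[0]))
    for name, _ in remainders[:short]:
        counts[name] += 1
    return counts


def _class_branch_omegas(cfg: StudyConfig, cls_name: str) -> dict:
    base = cfg.omega_neutral
    om = {"focal": base, "relative_a": base, "relative_b": base, "internal": base}
    if cls_name == CLASS_FOCAL_SHIFT:
        om["focal"] = cfg.omega_focal_shift
    elif cls_name == CLASS_ALL_HIGH:
        om = {k: cfg.omega_all_high for k in om}
    return om


class _KernelCache:
    def __init__(self, cfg: StudyConfig):
        self.cfg = cfg
        self._cache: dict = {}

    def kernel(self, omega: float, t: float) -> np.ndarray:
        key = (omega, t)
        if key not in self._cache:
            model = self.cfg.base_model(omega)
            q = synonymous_scaled_rate_matrix(model)
            self._cache[key] = transition_kernel(q, model.pi, t)
        return self._cache[key]


def simulate_study(cfg: StudyConfig | None = None, seed: int = 0):
    """Simulate the three species' coding-sequence sets with ground truth.

    Returns (records, truth) where records maps species name to a list of
    CodingRecord and truth is a pandas DataFrame with one row per emitted
    gene/paralog, carrying the planted class and per-branch omegas.
    """
    import pandas as pd

    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(seed)
    tree = cfg.tree
    cache = _KernelCache(cfg)
    pi = cfg.base_model(1.0).pi

    counts = _class_counts(cfg.class_proportions, cfg.n_genes)
    classes: list[str] = []
    for name in sorted(counts):
        classes.extend([name] * counts[name])
    rng.shuffle(classes)

    records = {sp: [] for sp in tree.species}
    truth_rows = []
    lo, hi = cfg.length_range

    for gi, cls_name in enumerate(classes):
        gene = f"g{gi + 1:04d}"
        if cls_name == CLASS_SHORT:
            slo, shi = cfg.short_length_range
            length = int(rng.integers(slo, shi + 1))
        else:
            length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        om = _class_branch_omegas(cfg, cls_name)

        root_idx = rng.choice(N_SENSE, size=length, p=pi)
        anc_idx = _sample_step(root_idx, cache.kernel(om["internal"], tree.t_internal), rng)
        tips = {
            tree.focal: _sample_step(anc_idx, cache.kernel(om["focal"], tree.t_focal), rng),
            tree.relative_a: _sample_step(anc_idx, cache.kernel(om["relative_a"], tree.t_relative_a), rng),
            tree.relative_b: _sample_step(root_idx, cache.kernel(om["relative_b"], tree.t_relative_b), rng),
        }

        stop_pos = None
        if cls_name == CLASS_INTERNAL_STOP and length >= 3:
            stop_pos = int(rng.integers(1, length - 1))

        row = {
            "gene_id": gene,
            "planted_class": cls_name,
            "n_codons": length,
            "omega_focal": om["focal"],
            "omega_relative_a": om["relative_a"],
            "omega_relative_b": om["relative_b"],
            "omega_internal": om["internal"],
            "parent": "",
            "species": "",
        }
        for sp in tree.species:
            cds = "".join(SENSE_CODONS[i] for i in tips[sp])
            if stop_pos is not None:
                cds = cds[: 3 * stop_pos] + "TAA" + cds[3 * stop_pos + 3 :]
            rid = f"{gene}_{sp}"
            records[sp].append(CodingRecord.from_cds(rid, sp, cds))
            row[f"id_{sp}"] = rid
        truth_rows.append(row)

    # within-species paralogs: duplicate an extant sequence, add divergence
    n_paralogs = int(round(cfg.paralog_rate * cfg.n_genes))
    eligible = [r for r in truth_rows if r["planted_class"] == CLASS_NEUTRAL]
    if n_paralogs > len(eligible):
        n_paralogs = len(eligible)
    chosen = rng.choice(len(eligible), size=n_paralogs, replace=False) if n_paralogs else []
    kernel_par = cache.kernel(cfg.omega_neutral, cfg.paralog_extra_t) if n_paralogs else None
    for k in sorted(int(c) for c in chosen):
        parent_row = eligible[k]
        sp = tree.species[int(rng.integers(0, 3))]
        src = next(r for r in records[sp] if r.id == parent_row[f"id_{sp}"])
        idx = np.array([CODON_INDEX[c] for c in codons_of(src.cds)])
        dup_idx = _sample_step(idx, kernel_par, rng)
        dup_id = f"{parent_row['gene_id']}par_{sp}"
        cds = "".join(SENSE_CODONS[i] for i in dup_idx)
        records[sp].append(CodingRecord.from_cds(dup_id, sp, cds))
        row = {
            "gene_id": f"{parent_row['gene_id']}par",
            "planted_class": CLASS_PARALOG,
            "n_codons": len(idx),
            "omega_focal": cfg.omega_neutral,
            "omega_relative_a": cfg.omega_neutral,
            "omega_relative_b": cfg.omega_neutral,
            "omega_internal": cfg.omega_neutral,
            "parent": parent_row["gene_id"],
            "species": sp,
        }
        for s in tree.species:
            row[f"id_{s}"] = dup_id if s == sp else ""
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_pair_alignment(omega: float, kappa: float, t_total: float, n_codons: int,
                            rng: np.random.Generator):
    """Gap-free codon alignment of two sequences separated by path length
    ``t_total`` under the synonymous-rate-scaled GY94 model (uniform codon
    frequencies). Convenience for estimator validation studies."""
    from .align import CodonAlignment

    model = CodonModel.uniform(kappa=kappa, omega=omega)
    q = synonymous_scaled_rate_matrix(model)
    kernel = transition_kernel(q, model.pi, t_total)
    root = rng.choice(N_SENSE, size=n_codons, p=model.pi)
    tip = _sample_step(root, kernel, rng)
    return CodonAlignment([SENSE_CODONS[i] for i in root], [SENSE_CODONS[i] for i in tip])


def write_study(records: dict, truth, outdir) -> None:
    """Write per-species CDS/protein FASTA and the TSV truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, recs in records.items():
        write_fasta(outdir / f"{sp}.cds.fasta", [(r.id, r.cds) for r in recs])
        write_fasta(outdir / f"{sp}.protein.fasta", [(r.id, r.protein) for r in recs])
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
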