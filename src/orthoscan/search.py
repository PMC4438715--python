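"""All-vs-all protein similarity search.

A Smith-Waterman local aligner (BLOSUM62, affine gaps 11/1) with
Karlin-Altschul E-values stands in for BLASTP at desk scale; externally
computed hit tables in the standard 12-column tabular format can be swapped
in via :func:`orthoscan.sequence_io.read_hit_table`. Only hit ranking and
threshold crossing matter downstream, not bit-compatibility with BLAST.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

KARLIN_ALTSCHUL_LAMBDA = 0.267  # gapped BLOSUM62 defaults
KARLIN_ALTSCHUL_K = 0.041

#: co-optimal alignments examined when applying the deterministic tie-break
_TIE_BREAK_LIMIT = 64


@dataclass
class SimilarityHit:
    """A scored local-alignment match between two proteins."""

    query_id: str
    subject_id: str
    identity_pct: float
    aligned_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    raw_score: float = 0.0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be in [0, 100]")
        if self.aligned_len < 1:
            raise ValueError("aligned_len must be >= 1")


def default_matrix():
    """BLOSUM62 with X scoring -1 against everything (including X)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = m.copy()
    xi = m.alphabet.index("X")
    arr[xi, :] = -1.0
    arr[:, xi] = -1.0
    return arr


_DEFAULT_MATRIX = default_matrix()


def _make_aligner(mode: str, matrix=None, gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix if matrix is not None else _DEFAULT_MATRIX
    # affine gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _expand_alignment(alignment) -> tuple[str, str, tuple[int, int, int, int]]:
    """Gapped row strings and 1-based inclusive coordinates from an alignment.

    In local mode the rows span only the aligned region; in global mode they
    cover both sequences end to end (terminal gaps included).
    """
    ta, tb = alignment.aligned  # aligned blocks of target / query
    coords = (int(ta[0][0]) + 1, int(ta[-1][1]), int(tb[0][0]) + 1, int(tb[-1][1]))
    return str(alignment[0]), str(alignment[1]), coords


def _pick_alignment(alignments):
    """Deterministic tie-break among co-optimal alignments: shortest
    alignment, then smallest query start (first sequence)."""
    best = None
    best_key = None
    for k, aln in enumerate(alignments):
        if k >= _TIE_BREAK_LIMIT:
            break
        length = aln.length
        start = aln.aligned[0][0][0] if len(aln.aligned[0]) else 0
        key = (length, start)
        if best is None or key < best_key:
            best, best_key = aln, key
    return best


def local_align(a: str, b: str, matrix=None, gap_open: int = 11, gap_extend: int = 1):
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns (raw_score, aligned_a, aligned_b, coords) with coords 1-based
    inclusive (qstart, qend, sstart, send). A pair with no positive-scoring
    alignment returns (0.0, "", "", None).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, "", "", None
    aln = _pick_alignment(aligner.align(a, b))
    row_a, row_b, coords = _expand_alignment(aln)
    return float(score), row_a, row_b, coords


def evalue_of(
    raw_score: float,
    query_len: int,
    db_residues: int,
    k: float = KARLIN_ALTSCHUL_K,
    lam: float = KARLIN_ALTSCHUL_LAMBDA,
) -> float:
    """Karlin-Altschul expectation value E = K m n exp(-lambda S)."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("lengths must be positive")
    return k * query_len * db_residues * math.exp(-lam * raw_score)


def bitscore_of(raw_score: float, k: float = KARLIN_ALTSCHUL_K, lam: float = KARLIN_ALTSCHUL_LAMBDA) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2)


def _as_id_seq(records) -> list[tuple[str, str]]:
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            out.append(rec)
        else:
            seq = getattr(rec, "search_protein", None) or getattr(rec, "protein", None) or rec.seq
            out.append((rec.id, seq))
    return out


_TRINITY_GROUP = re.compile(r"^(?P<group>.+?)(?:_seq\d+|_i\d+)$")


def longest_isoforms(records, group_pattern: re.Pattern | str | None = _TRINITY_GROUP):
    """Keep only the longest protein per isoform group.

    Group ids are extracted with ``group_pattern`` (Trinity-style suffixes
    ``_seq<k>``/``_i<k>`` by default); ids that do not match form their own
    group. Ties go to the lexicographically smallest id.
    """
    pairs = _as_id_seq(records)
    if group_pattern is None:
        return list(records)
    pat = re.compile(group_pattern) if isinstance(group_pattern, str) else group_pattern
    by_group: dict = {}
    for rec, (rid, seq) in zip(records, pairs):
        m = pat.match(rid)
        group = m.group("group") if m else rid
        cur = by_group.get(group)
        if cur is None or (len(seq), ) > (len(cur[1]), ) or (len(seq) == len(cur[1]) and rid < cur[0]):
            by_group[group] = (rid, seq, rec)
    kept_ids = {v[0] for v in by_group.values()}
    return [rec for rec, (rid, _) in zip(records, pairs) if rid in kept_ids]


def all_vs_all(
    query_set,
    target_set,
    evalue_cutoff: float = 1e-6,
    matrix=None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[SimilarityHit]:
    """Search every query against every target; keep hits with E <= cutoff.

    Per query, hits are sorted by (ascending E-value, descending bitscore,
    subject id); identity is computed over aligned columns including gaps.
    """
    queries = _as_id_seq(query_set)
    targets = _as_id_seq(target_set)
    if not queries or not targets:
        raise ValueError("query and target sets must be non-empty")
    db_residues = sum(len(s) for _, s in targets)
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)

    hits: list[SimilarityHit] = []
    for qid, qseq in queries:
        if not qseq:
            continue
        per_query = []
        for sid, sseq in targets:
            if not sseq:
                continue
            score = aligner.score(qseq, sseq)
            if score <= 0:
                continue
            ev = evalue_of(score, len(qseq), db_residues)
            if ev > evalue_cutoff:
                continue
            aln = _pick_alignment(aligner.align(qseq, sseq))
            row_a, row_b, coords = _expand_alignment(aln)
            aligned_len = len(row_a)
            identities = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
            mismatches = sum(1 for x, y in zip(row_a, row_b) if x != y and x != "-" and y != "-")
            gap_opens = len(re.findall(r"-+", row_a)) + len(re.findall(r"-+", row_b))
            per_query.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    identity_pct=100.0 * identities / aligned_len,
                    aligned_len=aligned_len,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    qstart=coords[0],
                    qend=coords[1],
                    sstart=coords[2],
                    send=coords[3],
                    evalue=ev,
                    bitscore=bitscore_of(score),
                    raw_score=float(score),
                )
            )
        per_query.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        hits.extend(per_query)
    return hits
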