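"""Codon-aware pairwise alignment.

Ortholog pairs are aligned at the protein level (global Needleman-Wunsch,
affine gaps, end gaps penalized) and the alignment is back-translated onto
the coding sequences, giving column-paired codons on which dN/dS is
estimated. An automated QC step stands in for manual inspection of candidate
alignments: pairs dominated by gaps or containing long runs of mismatching
codons are flagged and barred from positive-selection candidacy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from ._codons import GENETIC_CODE, STOP_CODONS
from .search import _expand_alignment, _make_aligner, _pick_alignment
from .sequence_io import translate_cds

GAP_CODON = "---"


class AlignmentIntegrityError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Column-paired codons for two sequences; gaps are whole codons."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows must have equal length")
        for row in (self.codons_a, self.codons_b):
            for c in row:
                if len(c) != 3:
                    raise ValueError(f"not a codon or gap: {c!r}")

    @staticmethod
    def _is_sense(codon: str) -> bool:
        return codon != GAP_CODON and "N" not in codon and codon not in STOP_CODONS

    @property
    def ungapped_codon_columns(self) -> int:
        """Columns where both entries are sense codons."""
        return sum(
            1 for a, b in zip(self.codons_a, self.codons_b) if self._is_sense(a) and self._is_sense(b)
        )

    @property
    def aligned_len_bp(self) -> int:
        return 3 * self.ungapped_codon_columns

    def sense_columns(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in zip(self.codons_a, self.codons_b)
            if self._is_sense(a) and self._is_sense(b)
        ]


def global_align(a: str, b: str, matrix=None, gap_open: int = 11, gap_extend: int = 1):
    """Optimal global (Needleman-Wunsch) protein alignment with affine gaps.

    Returns (score, aligned_a, aligned_b). Traceback is deterministic: among
    co-optimal alignments the shortest, then the one whose first row starts
    earliest, is chosen.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner("global", matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    aln = _pick_alignment(aligner.align(a, b))
    row_a, row_b, _ = _expand_alignment(aln)
    return float(score), row_a, row_b


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def backtranslate(aligned_a: str, aligned_b: str, cds_a: str, cds_b: str,
                  id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Map an aligned protein pair back onto its coding sequences.

    Each amino-acid column becomes its source codon; protein gaps become the
    codon gap '---'. A terminal stop codon on either CDS is trimmed. The
    ungapped protein must equal the CDS translation, else an integrity error
    naming the offending gene is raised.
    """
    rows = []
    for rid, row, cds in ((id_a, aligned_a, cds_a), (id_b, aligned_b, cds_b)):
        cds = _strip_terminal_stop(cds.upper())
        protein = row.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise AlignmentIntegrityError(
                f"{rid}: CDS length {len(cds)} does not match {len(protein)} aligned residues"
            )
        translated, _ = translate_cds(cds) if cds else ("", False)
        if translated != protein:
            raise AlignmentIntegrityError(f"{rid}: protein row does not match CDS translation")
        codons = []
        k = 0
        for aa in row:
            if aa == "-":
                codons.append(GAP_CODON)
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append(codons)
    return CodonAlignment(codons_a=rows[0], codons_b=rows[1])


class QcResult(NamedTuple):
    passed: bool
    reason: str = ""


def alignment_qc(aln: CodonAlignment, max_gap_frac: float = 0.5, max_mismatch_run: int = 20) -> QcResult:
    """Automated alignment quality check.

    Flags the pair when gap columns exceed ``max_gap_frac`` of all columns or
    when >= ``max_mismatch_run`` consecutive sense-codon columns all mismatch.
    Flagged pairs are excluded from positive-selection candidacy.
    """
    total = len(aln.codons_a)
    if total == 0:
        return QcResult(False, "empty alignment")
    gap_cols = sum(1 for a, b in zip(aln.codons_a, aln.codons_b) if a == GAP_CODON or b == GAP_CODON)
    if gap_cols / total > max_gap_frac:
        return QcResult(False, "gap fraction")
    run = 0
    for a, b in zip(aln.codons_a, aln.codons_b):
        if a != GAP_CODON and b != GAP_CODON and a != b:
            run += 1
            if run >= max_mismatch_run:
                return QcResult(False, "mismatch run")
        else:
            run = 0
    return QcResult(True)
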