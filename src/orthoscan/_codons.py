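"""Shared genetic-code tables and codon bookkeeping.

Everything downstream (simulation, counting estimators, ML fitting) works on
the 61 sense codons of the standard genetic code, indexed lexicographically
over the alphabet ACGT.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_standard = CodonTable.unambiguous_dna_by_id[1]

ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

#: codon -> single-letter amino acid, stops rendered as '*'
GENETIC_CODE = {c: ("*" if c in STOP_CODONS else _standard.forward_table[c]) for c in ALL_CODONS}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a->b is a transition (A<->G or C<->T)."""
    if a == b:
        raise ValueError("not a change")
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def codon_diffs(a: str, b: str) -> list[int]:
    """Positions (0-based) at which two codons differ."""
    return [p for p in range(3) if a[p] != b[p]]


def is_synonymous(a: str, b: str) -> bool:
    """True if two *sense* codons encode the same amino acid."""
    return GENETIC_CODE[a] == GENETIC_CODE[b]


def _single_step_neighbors():
    """All ordered sense-codon pairs differing at exactly one position.

    Returns a list of tuples (i, j, position, transition, nonsynonymous) with
    i, j indices into SENSE_CODONS.
    """
    out = []
    for i, ci in enumerate(SENSE_CODONS):
        for p in range(3):
            for nt in BASES:
                if nt == ci[p]:
                    continue
                cj = ci[:p] + nt + ci[p + 1 :]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                out.append((i, j, p, is_transition(ci[p], nt), not is_synonymous(ci, cj)))
    return out

SINGLE_STEP_NEIGHBORS = _single_step_neighbors()
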