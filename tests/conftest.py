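"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from orthoscan._codons import N_SENSE, SENSE_CODONS
from orthoscan.align import CodonAlignment
from orthoscan.simulate import simulate_pair_alignment  # noqa: F401  (re-export for tests)


def random_codon_alignment(rng: np.random.Generator, n_codons: int) -> CodonAlignment:
    """Uniformly random sense-codon columns (no evolutionary structure)."""
    a = [SENSE_CODONS[i] for i in rng.integers(0, N_SENSE, n_codons)]
    b = [SENSE_CODONS[i] for i in rng.integers(0, N_SENSE, n_codons)]
    return CodonAlignment(a, b)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
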