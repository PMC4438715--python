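"""Sequence I/O, translation, ORF finding and read-quality filtering.

This module is the boundary between on-disk formats (FASTA, FASTQ, 12-column
tabular similarity hits) and the in-memory records used by the rest of the
pipeline. The read filter reproduces whole-read RNA-seq cleaning rules:
a read is discarded if it contains an adapter, if more than 5% of its bases
are N, or if more than 20% of its bases are at or below Q10. All comparisons
are strict ("more than").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

from ._codons import GENETIC_CODE


class FastaParseError(ValueError):
    pass


class HitTableParseError(ValueError):
    pass


class FastaRecord(NamedTuple):
    id: str
    seq: str
    description: str = ""


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence and quality lengths differ")
        if any(q < 0 for q in self.qual):
            raise ValueError(f"read {self.id}: negative quality score")


@dataclass
class CodingRecord:
    """One transcript-derived coding sequence with its translation.

    ``protein`` is the standard-genetic-code translation of ``cds`` (stops as
    '*', codons containing N as 'X'); ``has_internal_stop`` is true when a stop
    occurs before the final codon.
    """

    id: str
    species: str
    cds: str
    protein: str = ""
    has_internal_stop: bool = False
    description: str = ""

    @classmethod
    def from_cds(cls, id: str, species: str, cds: str, description: str = "") -> "CodingRecord":
        protein, internal = translate_cds(cds)
        return cls(id=id, species=species, cds=cds.upper(), protein=protein,
                   has_internal_stop=internal, description=description)

    @property
    def search_protein(self) -> str:
        """Translation with any trailing stop removed, for similarity search."""
        return self.protein.rstrip("*")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[FastaRecord]:
    """Parse a FASTA file into records, preserving order.

    Sequences are uppercased; the header is split into id (first word) and
    description (remainder). Sequence data before any header is a parse error
    naming the line.
    """
    records: list[FastaRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(FastaRecord(header, "".join(chunks).upper(), desc))
                parts = line[1:].split(None, 1)
                header = parts[0] if parts else ""
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"line {lineno}: sequence data before first header")
                chunks.append(line.strip())
    if header is not None:
        records.append(FastaRecord(header, "".join(chunks).upper(), desc))
    return records


def write_fasta(path, records: Iterable, width: int = 60) -> None:
    """Write records (anything with id/seq or id/cds, or (id, seq) pairs)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq, desc = (rec + ("",))[:3]
            else:
                rid = rec.id
                seq = getattr(rec, "seq", None) or getattr(rec, "cds")
                desc = getattr(rec, "description", "")
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

_FASTQ_FORMAT = {33: "fastq", 64: "fastq-illumina"}


def read_fastq(path, encoding_offset: int = 33) -> list[ReadRecord]:
    """Read a 4-line-record FASTQ file (Phred+33 by default, +64 optional)."""
    fmt = _FASTQ_FORMAT[encoding_offset]
    return [
        ReadRecord(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), fmt)
    ]


def write_fastq(path, reads: Iterable[ReadRecord], encoding_offset: int = 33) -> None:
    offset = encoding_offset
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + offset) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


REASON_ADAPTER = "adapter"
REASON_N_FRACTION = "N fraction"
REASON_LOW_QUALITY = "low quality"


def filter_reads(
    reads: Sequence[ReadRecord],
    max_n_frac: float = 0.05,
    q_thresh: int = 10,
    max_lowq_frac: float = 0.20,
    adapters: Sequence[str] = (),
) -> tuple[list[ReadRecord], list[tuple[str, str]]]:
    """Whole-read quality filter.

    A read is removed iff it contains any adapter as an exact substring, OR its
    N fraction exceeds ``max_n_frac``, OR the fraction of bases with quality
    <= ``q_thresh`` exceeds ``max_lowq_frac`` (all strictly "exceeds"). Returns
    (kept reads, removal log of (read id, first triggered reason)).
    """
    adapters = [a.upper() for a in adapters if a]
    kept: list[ReadRecord] = []
    removed: list[tuple[str, str]] = []
    for read in reads:
        n = len(read.seq)
        if n == 0:
            kept.append(read)
            continue
        if any(a in read.seq for a in adapters):
            removed.append((read.id, REASON_ADAPTER))
        elif read.seq.count("N") / n > max_n_frac:
            removed.append((read.id, REASON_N_FRACTION))
        elif sum(1 for q in read.qual if q <= q_thresh) / n > max_lowq_frac:
            removed.append((read.id, REASON_LOW_QUALITY))
        else:
            kept.append(read)
    return kept, removed


# ---------------------------------------------------------------------------
# Translation and ORFs

_VALID_CDS = re.compile(r"^[ACGTN]*$")


def translate_cds(cds: str, frame: int = 0) -> tuple[str, bool]:
    """Standard-genetic-code translation.

    Trailing incomplete codons are dropped; codons containing N translate to
    'X'; stops render as '*'. Returns (protein, has_internal_stop) where an
    internal stop is any '*' before the last translated codon. Characters
    outside {A,C,G,T,N} are rejected.
    """
    seq = cds.upper()
    if not _VALID_CDS.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-IUPAC/unsupported character(s) in CDS: {bad}")
    seq = seq[frame:]
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon after frame offset")
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aas.append("X" if "N" in codon else GENETIC_CODE[codon])
    protein = "".join(aas)
    return protein, "*" in protein[:-1]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def longest_orf(transcript: str, min_len: int = 30) -> str | None:
    """Longest ATG-to-stop open reading frame over all 6 frames.

    The returned CDS includes the stop codon and is reported on its own strand.
    Ties are broken by frame order (+0, +1, +2, -0, -1, -2) then by the 5'-most
    start on that strand. Returns None ("no CDS") if no ORF reaches
    ``min_len`` nucleotides.
    """
    if not transcript:
        raise ValueError("empty transcript")
    best: tuple[int, int, int, str] | None = None  # (-len, frame_rank, start, cds)
    strands = (transcript.upper(), reverse_complement(transcript))
    for strand_i, seq in enumerate(strands):
        for frame in range(3):
            rank = strand_i * 3 + frame
            i = frame
            codons = [(i + 3 * k, seq[i + 3 * k : i + 3 * k + 3]) for k in range((len(seq) - i) // 3)]
            start: int | None = None
            for pos, codon in codons:
                if start is None:
                    if codon == "ATG":
                        start = pos
                elif GENETIC_CODE.get(codon) == "*":
                    cds = seq[start : pos + 3]
                    if len(cds) >= min_len:
                        key = (-len(cds), rank, start, cds)
                        if best is None or key < best:
                            best = key
                    start = None
    return best[3] if best else None


# ---------------------------------------------------------------------------
# Tabular similarity hits (12-column format)

HIT_COLUMNS = (
    "query_id subject_id identity_pct aligned_len mismatches gap_opens "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(path) -> list:
    """Parse 12-column tab-separated similarity hits, preserving row order."""
    from .search import SimilarityHit

    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableParseError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            hits.append(
                SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_pct=float(fields[2]),
                    aligned_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_hit_table(path, hits: Iterable) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(h.aligned_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
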