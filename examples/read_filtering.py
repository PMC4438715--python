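"""Whole-read quality filtering of raw sequencing reads.

Builds a tiny synthetic FASTQ in memory and applies the cleaning rules:
drop reads containing an adapter, reads with more than 5% unknown bases,
and reads with more than 20% of bases at or below Q10.
"""

from orthoscan.sequence_io import ReadRecord, filter_reads

ADAPTER = "AGATCGGAAGAGC"

reads = [
    ReadRecord("clean", "ACGT" * 25, [35] * 100),
    ReadRecord("n_rich", "N" * 6 + "A" * 94, [35] * 100),
    ReadRecord("low_qual", "G" * 100, [8] * 21 + [35] * 79),
    ReadRecord("adapter", "CCC" + ADAPTER + "G" * 84, [35] * 100),
    ReadRecord("boundary", "N" * 5 + "C" * 95, [10] * 20 + [35] * 80),
]

kept, removed = filter_reads(reads, adapters=[ADAPTER])
print(f"kept {len(kept)} of {len(reads)} reads: {[r.id for r in kept]}")
for rid, reason in removed:
    print(f"removed {rid}: {reason}")

# "boundary" survives: exactly 5% N and exactly 20% low-quality bases sit at
# the thresholds, and removal requires strictly exceeding them.
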