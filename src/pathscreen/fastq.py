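"""FASTQ input/output.

Reads are parsed with pysam's C-backed FastxFile; writing is plain buffered
text with a constant Sanger quality (these are synthetic reads, qualities
carry no information).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import pysam

QUAL_CHAR = "I"  # Q40


def read_sequences(path: str) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (qualities ignored)."""
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            yield rec.sequence


def write_fastq(path: str, sequences: Iterable[str], id_prefix: str = "r") -> int:
    """Write sequences as FASTQ with constant quality; returns read count."""
    n = 0
    buf: list[str] = []
    with open(path, "w") as fh:
        for seq in sequences:
            buf.append(f"@{id_prefix}{n}\n{seq}\n+\n{QUAL_CHAR * len(seq)}\n")
            n += 1
            if len(buf) >= 100_000:
                fh.write("".join(buf))
                buf.clear()
        fh.write("".join(buf))
    return n
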