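"""Sequence primitives shared across the pipeline.

Coordinates are 1-based, fully closed intervals everywhere in this package;
conversions to 0-based half-open happen only at the edges (numpy slices,
BED/bedGraph output) and are marked where they occur.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class GenomeSequence:
    """A named nucleotide sequence with a declared topology.

    ``circular=False`` denotes a linear scaffold; ``circular=True`` a closed
    molecule whose origin is an arbitrary cut point.
    """

    name: str
    seq: str
    circular: bool = False
    _arr: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def arr(self) -> np.ndarray:
        if self._arr is None:
            self._arr = as_array(self.seq)
        return self._arr

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for the closed interval [start, end], 1-based.

        For circular sequences the interval may wrap past the end
        (``end > len``), in which case the origin is crossed.
        """
        if start < 1 or start > len(self.seq):
            raise ValueError(f"start {start} outside [1, {len(self.seq)}]")
        if end < start:
            raise ValueError(f"end {end} < start {start}")
        if end <= len(self.seq):
            return self.seq[start - 1 : end]
        if not self.circular:
            raise ValueError(f"end {end} beyond linear sequence of length {len(self.seq)}")
        if end - start + 1 > len(self.seq):
            raise ValueError("interval longer than circular molecule")
        return self.seq[start - 1 :] + self.seq[: end - len(self.seq)]


def read_fasta(path) -> list[GenomeSequence]:
    from Bio import SeqIO

    return [GenomeSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, seqs: list[GenomeSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


@dataclass
class FastqRecord:
    name: str
    seq: str
    qual: str


def write_fastq(path, records: list[FastqRecord]) -> None:
    buf = io.StringIO()
    for r in records:
        buf.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_fastq(path) -> list[FastqRecord]:
    out = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append(FastqRecord(h.strip().lstrip("@"), seq, qual))
    return out
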