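"""Per-mate read alignment against a scaffold.

Two front ends feed the same record types: a built-in seeded mapper, and an
ingester for external SAM/BAM alignments.  The built-in mapper is gapless
(substitution-only), anchors candidate placements with exact 31-mer seeds on
both strands, extends them by vectorised mismatch counting, and keeps every
placement passing the 90%-length / 90%-identity filter used throughout the
structural analysis.  Multi-placement mates set an ambiguity flag on the
pair; downstream, ambiguous pairs contribute to coverage but are excluded
from consistency classification so that repeats cannot fabricate junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqs import GenomeSequence, VALID_BASES, revcomp

logger = logging.getLogger(__name__)


@dataclass
class MateAlignment:
    read_id: str
    mate_index: int  # 1 or 2
    ref_start: int  # 1-based inclusive
    ref_end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    aligned_fraction: float
    identity: float


@dataclass
class PairAlignmentRecord:
    read_id: str
    mate1: MateAlignment | None
    mate2: MateAlignment | None
    ambiguity_flag: bool = False


class ReferenceIndex:
    """Exact k-mer seed index over the forward strand of a reference."""

    def __init__(self, reference: GenomeSequence, k: int = 31):
        if len(reference) == 0:
            raise ValueError("reference is empty")
        self.reference = reference
        self.k = k
        self.arr = reference.arr
        index: dict[bytes, list[int]] = {}
        raw = reference.seq.encode("ascii")
        for i in range(len(raw) - k + 1):
            kmer = raw[i : i + k]
            if b"N" in kmer:
                continue
            index.setdefault(kmer, []).append(i)
        self.index = index


def map_mate(
    read: str,
    index: ReferenceIndex,
    min_len_frac: float = 0.90,
    min_identity: float = 0.90,
    read_id: str = "",
    mate_index: int = 1,
) -> list[MateAlignment]:
    """All placements of one mate passing both thresholds, on both strands.

    Seeds are taken every k bases along the read (plus one flush with the
    read's 3' end); each seed hit implies a gapless candidate placement that
    is scored by mismatch counting over the overlap with the reference.
    Placements clipped by a reference end are allowed as long as the aligned
    span still covers ``min_len_frac`` of the read.
    """
    if len(read) < 31:
        raise ValueError("read shorter than 31 bases")
    if not set(read) <= VALID_BASES:
        bad = sorted(set(read) - VALID_BASES)
        raise ValueError(f"read contains non-ACGTN characters: {bad}")
    k = index.k
    L = len(index.arr)
    rl = len(read)
    out: list[MateAlignment] = []
    for strand, query in (("+", read), ("-", revcomp(read))):
        raw = query.encode("ascii")
        qarr = np.frombuffer(raw, dtype=np.uint8)
        offsets = list(range(0, rl - k + 1, k))
        if offsets[-1] != rl - k:
            offsets.append(rl - k)
        starts: set[int] = set()
        for off in offsets:
            for pos in index.index.get(raw[off : off + k], ()):
                starts.add(pos - off)
        for s in sorted(starts):
            a = max(s, 0)
            b = min(s + rl, L)
            span = b - a
            if span / rl < min_len_frac:
                continue
            qa, qb = a - s, a - s + span
            matches = int(np.count_nonzero(index.arr[a:b] == qarr[qa:qb]))
            identity = matches / span
            if identity < min_identity:
                continue
            out.append(
                MateAlignment(read_id, mate_index, a + 1, b, strand, span / rl, identity)
            )
    return out


def _best(placements: list[MateAlignment]) -> MateAlignment:
    return min(placements, key=lambda p: (-p.identity, p.ref_start))


def pair_up(
    mate1_placements: dict[str, list[MateAlignment]],
    mate2_placements: dict[str, list[MateAlignment]],
) -> list[PairAlignmentRecord]:
    """One record per read pair: best placement per mate (identity, then
    leftmost), ambiguity flagged when either mate has several qualifying
    placements.  Pairs with neither mate placed are dropped."""
    records = []
    for rid in sorted(set(mate1_placements) | set(mate2_placements)):
        p1 = mate1_placements.get(rid, [])
        p2 = mate2_placements.get(rid, [])
        if not p1 and not p2:
            continue
        records.append(
            PairAlignmentRecord(
                rid,
                _best(p1) if p1 else None,
                _best(p2) if p2 else None,
                ambiguity_flag=len(p1) > 1 or len(p2) > 1,
            )
        )
    return records


def map_pairs(
    reads1,
    reads2,
    reference: GenomeSequence,
    min_len_frac: float = 0.90,
    min_identity: float = 0.90,
    k: int = 31,
) -> list[PairAlignmentRecord]:
    """Map two mate streams (``FastqRecord`` lists) and pair them up."""
    index = ReferenceIndex(reference, k=k)
    m1 = {
        r.name: map_mate(r.seq, index, min_len_frac, min_identity, r.name, 1) for r in reads1
    }
    m2 = {
        r.name: map_mate(r.seq, index, min_len_frac, min_identity, r.name, 2) for r in reads2
    }
    m1 = {k_: v for k_, v in m1.items() if v}
    m2 = {k_: v for k_, v in m2.items() if v}
    return pair_up(m1, m2)


def ingest_alignments(
    path,
    min_len_frac: float = 0.90,
    min_identity: float = 0.90,
) -> list[PairAlignmentRecord]:
    """Build pair records from an external SAM/BAM file.

    Primary alignments only; identity from the NM tag when present (otherwise
    the CIGAR match fraction); the same length/identity thresholds as the
    built-in mapper.  Name-unsorted input is handled by buffering; malformed
    records are skipped and counted.
    """
    import pysam

    by_name: dict[str, dict[int, MateAlignment]] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            try:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                qlen = aln.infer_read_length() or aln.query_length
                alen = aln.query_alignment_length
                if not qlen or not alen:
                    continue
                if aln.has_tag("NM"):
                    mismatches = aln.get_tag("NM")
                else:
                    mismatches = 0
                identity = max(0.0, (alen - mismatches) / alen)
                frac = alen / qlen
                if frac < min_len_frac or identity < min_identity:
                    continue
                mate_index = 2 if aln.is_read2 else 1
                rec = MateAlignment(
                    aln.query_name,
                    mate_index,
                    aln.reference_start + 1,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    frac,
                    identity,
                )
                by_name.setdefault(aln.query_name, {})[mate_index] = rec
            except (ValueError, TypeError, KeyError):
                skipped += 1
    if skipped:
        logger.warning("ingest_alignments: skipped %d malformed records", skipped)
    return [
        PairAlignmentRecord(rid, mates.get(1), mates.get(2), ambiguity_flag=False)
        for rid, mates in sorted(by_name.items())
    ]
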