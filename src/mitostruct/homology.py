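"""Thresholded local-similarity scanning: dispersed repeats, plastid-derived
segments (MIPTs), and homology-based gene location.

The engine is a k-mer-anchored, gapless (substitution-only) extender with an
X-drop stop: exact seed matches define a diagonal, extension proceeds
outward scoring +1 per match and a penalty per mismatch, and stops when the
running score falls a fixed amount below its maximum; the hit is trimmed to
the best-scoring endpoints.  Inventory conventions follow the field's usual
reporting: repeats need >=100 bp and >90% identity (strict, matching the
"greater than" convention for repeat inventories), MIPTs >=100 bp and >=80%
identity.  Users with real data needing gapped sensitivity can import
external tabular hits into the same types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqs import GenomeSequence, revcomp

logger = logging.getLogger(__name__)


@dataclass
class SimilarityHit:
    query_start: int
    query_end: int
    query_strand: str
    subject_start: int
    subject_end: int
    subject_strand: str
    length: int
    identity: float


@dataclass
class GeneLocus:
    gene_name: str
    start: int
    end: int
    strand: str
    identity: float
    reference_coverage: float


def _extend(
    q: np.ndarray,
    s: np.ndarray,
    qpos: int,
    spos: int,
    k: int,
    mismatch: int,
    xdrop: int,
) -> tuple[int, int]:
    """Gapless X-drop extension of an exact k-mer anchor.

    Returns the query interval [q_lo, q_hi) of the best-scoring extension;
    the subject interval follows on the same diagonal.
    """
    # right
    score, best, qi = k, k, qpos + k
    best_hi = qi
    si = spos + k
    nq, ns = len(q), len(s)
    while qi < nq and si < ns:
        score += 1 if q[qi] == s[si] else -mismatch
        qi += 1
        si += 1
        if score > best:
            best, best_hi = score, qi
        elif best - score > xdrop:
            break
    # left
    score, best = 0, 0
    qi, si = qpos - 1, spos - 1
    best_lo = qpos
    while qi >= 0 and si >= 0:
        score += 1 if q[qi] == s[si] else -mismatch
        if score > best:
            best, best_lo = score, qi
        elif best - score > xdrop:
            break
        qi -= 1
        si -= 1
    return best_lo, best_hi


def _cross_hits(
    query: GenomeSequence,
    subject: GenomeSequence,
    k: int,
    min_len: int,
    min_identity: float,
    strict_identity: bool,
    mismatch: int = 2,
    xdrop: int = 20,
    self_mode: bool = False,
    subject_strand: str = "+",
) -> list[SimilarityHit]:
    """All qualifying gapless local similarities of query against subject.

    ``self_mode`` restricts to diagonals > 0 (each repeat pair reported once,
    trivial self-diagonal excluded).  Anchors falling inside an already
    extended hit on the same diagonal are skipped; overlapping same-diagonal
    hits are merged afterwards.
    """
    qarr, sarr = query.arr, subject.arr
    index: dict[bytes, list[int]] = {}
    raw_s = subject.seq.encode("ascii")
    for i in range(len(raw_s) - k + 1):
        kmer = raw_s[i : i + k]
        if b"N" not in kmer:
            index.setdefault(kmer, []).append(i)
    raw_q = query.seq.encode("ascii")
    covered: dict[int, list[tuple[int, int]]] = {}
    hits: list[SimilarityHit] = []
    for qpos in range(len(raw_q) - k + 1):
        positions = index.get(raw_q[qpos : qpos + k])
        if not positions:
            continue
        for spos in positions:
            d = spos - qpos
            if self_mode and d <= 0:
                continue
            skip = False
            for lo, hi in covered.get(d, ()):
                if lo <= qpos and qpos + k <= hi:
                    skip = True
                    break
            if skip:
                continue
            q_lo, q_hi = _extend(qarr, sarr, qpos, spos, k, mismatch, xdrop)
            covered.setdefault(d, []).append((q_lo, q_hi))
            length = q_hi - q_lo
            if length < min_len:
                continue
            matches = int(np.count_nonzero(qarr[q_lo:q_hi] == sarr[q_lo + d : q_hi + d]))
            identity = matches / length
            ok = identity > min_identity if strict_identity else identity >= min_identity
            if not ok:
                continue
            hits.append(
                SimilarityHit(
                    q_lo + 1, q_hi, "+", q_lo + d + 1, q_hi + d, subject_strand, length, identity
                )
            )
    return _merge_same_diagonal(hits, qarr, sarr)


def _merge_same_diagonal(
    hits: list[SimilarityHit], qarr: np.ndarray, sarr: np.ndarray
) -> list[SimilarityHit]:
    by_diag: dict[int, list[SimilarityHit]] = {}
    for h in hits:
        by_diag.setdefault(h.subject_start - h.query_start, []).append(h)
    out = []
    for d, group in by_diag.items():
        group.sort(key=lambda h: h.query_start)
        merged = [group[0]]
        for h in group[1:]:
            last = merged[-1]
            if h.query_start <= last.query_end + 1:
                lo, hi = last.query_start, max(last.query_end, h.query_end)
                matches = int(
                    np.count_nonzero(qarr[lo - 1 : hi] == sarr[lo - 1 + d : hi + d])
                )
                merged[-1] = SimilarityHit(
                    lo, hi, "+", lo + d, hi + d, last.subject_strand, hi - lo + 1, matches / (hi - lo + 1)
                )
            else:
                merged.append(h)
        out.extend(merged)
    return out


def _flip_subject(hits: list[SimilarityHit], subject_len: int) -> list[SimilarityHit]:
    """Map hits found against a reverse-complemented subject back to the
    original subject coordinates (strand '-')."""
    out = []
    for h in hits:
        s = subject_len - h.subject_end + 1
        e = subject_len - h.subject_start + 1
        out.append(
            SimilarityHit(h.query_start, h.query_end, "+", s, e, "-", h.length, h.identity)
        )
    return out


def find_repeats(
    genome: GenomeSequence,
    min_len: int = 100,
    min_identity: float = 0.90,
    k: int = 17,
) -> list[SimilarityHit]:
    """Dispersed repeat pairs within one genome, direct and inverted.

    Identity is strict (> min_identity).  Each pair is reported once with
    query_start <= subject_start.
    """
    if len(genome) < 2 * min_len:
        raise ValueError("genome shorter than twice min_len")
    direct = _cross_hits(
        genome, genome, k, min_len, min_identity, strict_identity=True, self_mode=True
    )
    rc = GenomeSequence(genome.name + "_rc", revcomp(genome.seq))
    inverted = _flip_subject(
        _cross_hits(
            genome, rc, k, min_len, min_identity, strict_identity=True, subject_strand="-"
        ),
        len(genome),
    )
    # inverted self-comparison reports each pair twice (and palindromic
    # self-hits once); canonicalise and deduplicate
    seen = set()
    inv_unique = []
    for h in inverted:
        a = (h.query_start, h.query_end)
        b = (h.subject_start, h.subject_end)
        if a == b:
            continue  # a hit on its own reverse complement (palindrome)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        if a > b:
            h = SimilarityHit(b[0], b[1], "+", a[0], a[1], "-", h.length, h.identity)
        inv_unique.append(h)
    return sorted(direct + inv_unique, key=lambda h: (h.query_start, h.subject_start))


def find_mipts(
    genome: GenomeSequence,
    plastome: GenomeSequence,
    min_len: int = 100,
    min_identity: float = 0.80,
    k: int = 12,
) -> list[SimilarityHit]:
    """Plastid-derived segments: genome vs plastome cross-comparison at the
    looser identity floor (inclusive >=).  Hits are on genome coordinates
    with plastome provenance in the subject fields."""
    if len(genome) == 0 or len(plastome) == 0:
        raise ValueError("empty sequence")
    fwd = _cross_hits(genome, plastome, k, min_len, min_identity, strict_identity=False)
    rc = GenomeSequence(plastome.name + "_rc", revcomp(plastome.seq))
    rev = _flip_subject(
        _cross_hits(
            genome, rc, k, min_len, min_identity, strict_identity=False, subject_strand="-"
        ),
        len(plastome),
    )
    return sorted(fwd + rev, key=lambda h: (h.query_start, h.subject_start))


def locate_genes(
    genome: GenomeSequence,
    reference_genes: dict[str, str],
    min_identity: float = 0.70,
    min_ref_cov: float = 0.70,
    k: int = 12,
) -> list[GeneLocus]:
    """Best placement of each reference gene on the genome by local
    similarity; genes falling below either floor are absent (and logged)."""
    if not reference_genes:
        raise ValueError("reference gene set is empty")
    out = []
    for name, seq in reference_genes.items():
        gene = GenomeSequence(name, seq.upper())
        cands = []
        fwd = _cross_hits(
            gene, genome, k, min_len=k, min_identity=min_identity,
            strict_identity=False, mismatch=1, xdrop=40,
        )
        for h in fwd:
            cands.append((h, "+"))
        rc = GenomeSequence(genome.name + "_rc", revcomp(genome.seq))
        for h in _cross_hits(
            gene, rc, k, min_len=k, min_identity=min_identity,
            strict_identity=False, mismatch=1, xdrop=40,
        ):
            flipped = _flip_subject([h], len(genome))[0]
            cands.append((flipped, "-"))
        best = None
        for h, strand in cands:
            cov = (h.query_end - h.query_start + 1) / len(gene)
            if cov < min_ref_cov or h.identity < min_identity:
                continue
            score = h.length * h.identity
            if best is None or score > best[0]:
                best = (score, h, strand, cov)
        if best is None:
            logger.info("gene %s not located above thresholds", name)
            continue
        _, h, strand, cov = best
        out.append(GeneLocus(name, h.subject_start, h.subject_end, strand, h.identity, cov))
    return out


def extract_locus(genome: GenomeSequence, locus: GeneLocus) -> str:
    """Sequence of a located gene, reverse-complemented for '-' strand."""
    seq = genome.fetch(locus.start, locus.end)
    return revcomp(seq) if locus.strand == "-" else seq


def hits_to_tsv(hits: list[SimilarityHit], path) -> None:
    import pandas as pd

    pd.DataFrame([vars(h) for h in hits]).to_csv(path, sep="\t", index=False)


def loci_to_gff3(loci: list[GeneLocus], scaffold_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write(
                f"{scaffold_id}\tmitostruct\tgene\t{l.start}\t{l.end}\t"
                f"{l.identity:.3f}\t{l.strand}\t.\tID={l.gene_name}\n"
            )
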