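"""Per-base depth profiles and coverage-anomaly detection.

Depth spikes mark regions attracting extra reads (typically plastid-derived
segments, MIPTs, that are present again elsewhere at higher copy), and depth
dips mark substoichiometric regions — segments present at reduced copy
number relative to the rest of the molecule population.  Detection is driven
by window medians relative to the genome-wide median, which is robust to the
spikes themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mapping import PairAlignmentRecord
from .seqs import GenomeSequence


@dataclass
class CoverageProfile:
    scaffold_id: str
    depth: np.ndarray  # index 0 is base 1

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.depth)) if len(self.depth) else 0.0

    def region_median(self, start: int, end: int) -> float:
        """Median depth over the closed 1-based interval [start, end]."""
        if start < 1 or end > len(self.depth) or end < start:
            raise ValueError(f"region [{start}, {end}] invalid for length {len(self.depth)}")
        return float(np.median(self.depth[start - 1 : end]))


@dataclass
class AnomalyRegion:
    kind: str  # "spike" | "dip"
    start: int
    end: int
    region_median: float
    ratio_to_genome_median: float


def compute_depth(records: list[PairAlignmentRecord], scaffold: GenomeSequence) -> CoverageProfile:
    """depth[i] = number of mate alignments covering base i (diff-array sum)."""
    L = len(scaffold)
    diff = np.zeros(L + 1, dtype=np.int64)
    for rec in records:
        for mate in (rec.mate1, rec.mate2):
            if mate is None:
                continue
            if mate.ref_start < 1 or mate.ref_end > L:
                raise ValueError(
                    f"alignment [{mate.ref_start}, {mate.ref_end}] outside scaffold of length {L}"
                )
            diff[mate.ref_start - 1] += 1
            diff[mate.ref_end] -= 1
    return CoverageProfile(scaffold.name, np.cumsum(diff[:L]))


def detect_anomalies(
    profile: CoverageProfile,
    window: int = 1000,
    spike_factor: float = 2.0,
    dip_factor: float = 0.6,
    min_len: int = 2000,
) -> list[AnomalyRegion]:
    """Window-median scan for spikes and dips.

    Non-overlapping windows whose median depth deviates beyond the factor
    thresholds are merged into maximal same-kind runs; ``min_len`` applies to
    the merged run span, after which boundaries are refined to the first and
    last base (within the run extended by one window each side) whose depth
    crosses the threshold.
    """
    depth = profile.depth
    L = len(depth)
    if L == 0:
        raise ValueError("empty coverage profile")
    window = min(window, L)
    gmed = float(np.median(depth))
    if gmed == 0:
        return []
    n_win = math.ceil(L / window)
    kinds = []
    for w in range(n_win):
        wmed = float(np.median(depth[w * window : min((w + 1) * window, L)]))
        if wmed > spike_factor * gmed:
            kinds.append("spike")
        elif wmed < dip_factor * gmed:
            kinds.append("dip")
        else:
            kinds.append(None)

    out: list[AnomalyRegion] = []
    w = 0
    while w < n_win:
        kind = kinds[w]
        if kind is None:
            w += 1
            continue
        run_start = w
        while w < n_win and kinds[w] == kind:
            w += 1
        span_start = run_start * window + 1
        span_end = min(w * window, L)
        if span_end - span_start + 1 < min_len:
            continue
        lo = max(span_start - window, 1)
        hi = min(span_end + window, L)
        seg = depth[lo - 1 : hi]
        thr = (spike_factor if kind == "spike" else dip_factor) * gmed
        crossing = seg > thr if kind == "spike" else seg < thr
        idx = np.nonzero(crossing)[0]
        if len(idx) == 0:
            continue
        start = lo + int(idx[0])
        end = lo + int(idx[-1])
        rmed = profile.region_median(start, end)
        out.append(AnomalyRegion(kind, start, end, rmed, rmed / gmed))
    return out


def stoichiometry_ratio(profile: CoverageProfile, start: int, end: int) -> float:
    """Genome median over region median for [start, end]; +inf for a
    zero-median region.  Interpreted as the copy-number fold difference."""
    if end < start:
        raise ValueError("empty region")
    rmed = profile.region_median(start, end)
    gmed = profile.median
    if rmed == 0:
        return math.inf
    return gmed / rmed


def write_bedgraph(profile: CoverageProfile, path) -> None:
    """Run-length-compressed bedGraph (0-based half-open on output)."""
    depth = profile.depth
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        change = np.nonzero(np.diff(depth))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(depth)]])
        for s, e in zip(starts, ends):
            fh.write(f"{profile.scaffold_id}\t{s}\t{e}\t{int(depth[s])}\n")


def write_anomaly_bed(anomalies: list[AnomalyRegion], scaffold_id: str, path) -> None:
    """Anomalies as BED (0-based half-open on output)."""
    with open(path, "w") as fh:
        for a in anomalies:
            fh.write(
                f"{scaffold_id}\t{a.start - 1}\t{a.end}\t{a.kind}\t"
                f"{a.ratio_to_genome_median:.3f}\n"
            )
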