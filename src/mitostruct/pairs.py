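"""Read-pair consistency classification and inconsistent-pair clustering.

A pair from an intact sequencing fragment maps head-to-head (inward-facing,
FR) at roughly the library insert size; pairs violating orientation or
distance are evidence of a structural junction absent from the linear
scaffold representation.  Inconsistent pairs are binned by the 1-kb windows
of their mate start positions, and window pairs accumulating enough support
become candidate junctions.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from .mapping import PairAlignmentRecord

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNRESOLVED = "unresolved"


@dataclass
class PairClassification:
    read_id: str
    status: str
    outer_distance: int | None = None
    orientation: str | None = None  # "head_to_head" | "other"


@dataclass
class InconsistentCluster:
    window_a: int
    window_b: int
    support: int
    members: list[str] = field(default_factory=list)
    bins: list[tuple[int, int]] = field(default_factory=list)


def classify_pair(
    record: PairAlignmentRecord, insert: int = 800, tol: float = 0.5
) -> PairClassification:
    """Classify one pair against the insert model.

    Head-to-head means the leftmost mate on '+' and the rightmost on '-'
    (inward-facing).  The outer distance is the fragment span, rightmost end
    minus leftmost start plus one; consistent requires orientation and
    ``insert*(1-tol) <= outer <= insert*(1+tol)`` (inclusive bounds).  Pairs
    with an unmapped or ambiguously placed mate are unresolved.
    """
    if record.mate1 is None or record.mate2 is None or record.ambiguity_flag:
        return PairClassification(record.read_id, UNRESOLVED)
    left, right = sorted((record.mate1, record.mate2), key=lambda m: (m.ref_start, m.ref_end))
    outer = max(left.ref_end, right.ref_end) - left.ref_start + 1
    head_to_head = left.strand == "+" and right.strand == "-"
    orientation = "head_to_head" if head_to_head else "other"
    lo = insert * (1 - tol)
    hi = insert * (1 + tol)
    status = CONSISTENT if head_to_head and lo <= outer <= hi else INCONSISTENT
    return PairClassification(record.read_id, status, outer, orientation)


def classify_pairs(
    records: list[PairAlignmentRecord], insert: int = 800, tol: float = 0.5
) -> list[PairClassification]:
    return [classify_pair(r, insert, tol) for r in records]


def bin_inconsistent(
    classifications: list[PairClassification],
    records: list[PairAlignmentRecord],
    window: int = 1000,
) -> dict[tuple[int, int], list[str]]:
    """Bin inconsistent pairs into unordered 1-kb window pairs.

    Windows are ``ceil(position/window)`` of each mate's start position.
    Returns window pair -> supporting read ids.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_id = {r.read_id: r for r in records}
    bins: dict[tuple[int, int], list[str]] = defaultdict(list)
    for c in classifications:
        if c.status != INCONSISTENT:
            continue
        rec = by_id[c.read_id]
        w1 = math.ceil(rec.mate1.ref_start / window)
        w2 = math.ceil(rec.mate2.ref_start / window)
        bins[(min(w1, w2), max(w1, w2))].append(c.read_id)
    return dict(bins)


def detect_clusters(
    bins: dict[tuple[int, int], list[str]], min_support: int = 5
) -> list[InconsistentCluster]:
    """Merge adjacent window-pair bins and keep well-supported clusters.

    Bins whose window indices both differ by at most one are merged
    (connected components), support summed over the component; the
    ``min_support`` threshold applies after merging.  Each cluster reports
    the windows of its best-supported bin.
    """
    keys = sorted(bins)
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    by_cell = {k: k for k in keys}
    for (a, b) in keys:
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                nb = (a + da, b + db)
                if nb in by_cell and nb != (a, b):
                    ra, rb = find((a, b)), find(nb)
                    if ra != rb:
                        parent[rb] = ra
    comps: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for k in keys:
        comps[find(k)].append(k)

    clusters = []
    for cells in comps.values():
        members = [rid for c in cells for rid in bins[c]]
        if len(members) < min_support:
            continue
        best = max(cells, key=lambda c: len(bins[c]))
        clusters.append(
            InconsistentCluster(best[0], best[1], len(members), sorted(members), sorted(cells))
        )
    clusters.sort(key=lambda c: (c.window_a, c.window_b))
    return clusters
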