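"""Genome topology inference from coverage segments and junction clusters.

The scaffold is split into coverage-homogeneous segments at anomaly
boundaries; inconsistent-pair clusters become junction edges between
segments.  Three evidence patterns are recognised, mirroring the structures
a paired-end library can support for an organelle assembly:

1. one cluster joining the scaffold's two ends, no depth dip — a single
   circular molecule (a circularized assembly map);
2. one dip segment D with clusters (left end <-> left flank of D) and
   (right end <-> right flank of D) — two circular molecules, [1..D.start-1]
   and [D.end+1..L], interconverting with a linearized form through the
   substoichiometric bridge D;
3. no clusters — a linear molecule.

Anything else is reported as unresolved with the raw edge list; the
inference never guesses.  Copy numbers are assigned from median depth over
each molecule's exclusive intervals, normalised to a maximum of 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .coverage import AnomalyRegion, CoverageProfile
from .pairs import InconsistentCluster

SINGLE_CIRCLE = "single_circle"
CIRCLES_WITH_BRIDGE = "circles_with_bridge"
LINEAR = "linear"
UNRESOLVED = "unresolved"


@dataclass
class Segment:
    start: int
    end: int
    median_depth: float
    kind: str = "normal"  # "normal" | "spike" | "dip"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ClusterEdge:
    segment_a: int  # index into nodes
    segment_b: int
    cluster: InconsistentCluster


@dataclass
class JunctionGraph:
    nodes: list[Segment]
    cluster_edges: list[ClusterEdge]
    window: int = 1000

    @property
    def scaffold_length(self) -> int:
        return self.nodes[-1].end


@dataclass
class MoleculeModel:
    name: str
    topology: str  # "circular" | "linear"
    intervals: list[tuple[int, int, str]]
    relative_copy_number: float | None = None
    note: str | None = None

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.intervals)


@dataclass
class TopologyModel:
    classification: str
    molecules: list[MoleculeModel] = field(default_factory=list)
    evidence: list[InconsistentCluster] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "molecules": [
                {
                    "name": m.name,
                    "topology": m.topology,
                    "intervals": [list(iv) for iv in m.intervals],
                    "length_bp": m.length,
                    "length_kb": round(m.length / 1000),
                    "relative_copy_number": m.relative_copy_number,
                    "note": m.note,
                }
                for m in self.molecules
            ],
            "evidence": [
                {
                    "window_a": c.window_a,
                    "window_b": c.window_b,
                    "support": c.support,
                }
                for c in self.evidence
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def segment_scaffold(
    profile: CoverageProfile, anomalies: list[AnomalyRegion]
) -> list[Segment]:
    """Split [1, L] at anomaly boundaries; annotate each piece's median depth."""
    L = len(profile.depth)
    cuts = sorted(anomalies, key=lambda a: a.start)
    for a, b in zip(cuts, cuts[1:]):
        if b.start <= a.end:
            raise ValueError("overlapping anomaly regions")
    segments = []
    pos = 1
    for a in cuts:
        if a.start > pos:
            segments.append(Segment(pos, a.start - 1, profile.region_median(pos, a.start - 1)))
        segments.append(Segment(a.start, a.end, a.region_median, a.kind))
        pos = a.end + 1
    if pos <= L:
        segments.append(Segment(pos, L, profile.region_median(pos, L)))
    return segments


def build_junction_graph(
    nodes: list[Segment],
    clusters: list[InconsistentCluster],
    window: int = 1000,
) -> JunctionGraph:
    """Attach each cluster as an edge between the segments containing its
    windows (window midpoints; terminal windows fall in the end segments)."""
    L = nodes[-1].end
    n_win = math.ceil(L / window)

    def seg_of(w: int) -> int:
        if w < 1 or w > n_win:
            raise ValueError(f"cluster window {w} beyond scaffold ({n_win} windows)")
        mid = min((w - 1) * window + (window + 1) // 2, L)
        for i, s in enumerate(nodes):
            if s.start <= mid <= s.end:
                return i
        raise AssertionError("segments do not partition the scaffold")

    edges = [ClusterEdge(seg_of(c.window_a), seg_of(c.window_b), c) for c in clusters]
    return JunctionGraph(nodes, edges, window)


def _near(window: int, target_base: int, graph: JunctionGraph, tol_windows: int = 2) -> bool:
    target_window = math.ceil(target_base / graph.window)
    return abs(window - target_window) <= tol_windows


def infer_topology(graph: JunctionGraph, flank_tol_windows: int = 2) -> TopologyModel:
    """Apply the evidence patterns in order; see the module docstring.

    A cluster window counts as a scaffold end / segment flank when it lies
    within ``flank_tol_windows`` windows of the corresponding boundary.
    """
    L = graph.scaffold_length
    dips = [s for s in graph.nodes if s.kind == "dip"]
    edges = graph.cluster_edges

    def windows(c: InconsistentCluster) -> tuple[int, int]:
        return c.window_a, c.window_b

    def is_end_to_end(c: InconsistentCluster) -> bool:
        wa, wb = windows(c)
        return _near(wa, 1, graph, flank_tol_windows) and _near(wb, L, graph, flank_tol_windows)

    # Rule 1: single circle.
    if not dips and len(edges) == 1 and is_end_to_end(edges[0].cluster):
        return TopologyModel(
            SINGLE_CIRCLE,
            [MoleculeModel("circle", "circular", [(1, L, "+")])],
            [edges[0].cluster],
        )

    # Rule 2: two circles bridged by a substoichiometric segment.
    if len(dips) == 1 and len(edges) == 2:
        D = dips[0]
        left = right = None
        for e in edges:
            wa, wb = windows(e.cluster)
            if _near(wa, 1, graph, flank_tol_windows) and _near(
                wb, D.start, graph, flank_tol_windows
            ):
                left = e.cluster
            elif _near(wb, L, graph, flank_tol_windows) and _near(
                wa, D.end, graph, flank_tol_windows
            ):
                right = e.cluster
        if left is not None and right is not None and D.start > 1 and D.end < L:
            return TopologyModel(
                CIRCLES_WITH_BRIDGE,
                [
                    MoleculeModel("circle_A", "circular", [(1, D.start - 1, "+")]),
                    MoleculeModel("circle_B", "circular", [(D.end + 1, L, "+")]),
                    MoleculeModel("bridge", "linear", [(D.start, D.end, "+")]),
                ],
                [left, right],
            )

    # Rule 3: linear.
    if not edges:
        return TopologyModel(LINEAR, [MoleculeModel("scaffold", "linear", [(1, L, "+")])])

    # Rule 4: unresolved.
    return TopologyModel(UNRESOLVED, [], [e.cluster for e in edges])


def assign_copy_numbers(model: TopologyModel, profile: CoverageProfile) -> TopologyModel:
    """Fill relative copy numbers from median depth over exclusive intervals.

    An interval base is exclusive to a molecule when no other molecule's
    intervals contain it; molecules without any exclusive base keep
    ``relative_copy_number=None`` with an explanatory note.  Values are
    normalised so the deepest molecule is 1.0.
    """
    medians: dict[str, float] = {}
    for m in model.molecules:
        others = [
            iv for o in model.molecules if o is not m for iv in o.intervals
        ]
        medians_parts = []
        for s, e, _ in m.intervals:
            cut = [(s, e)]
            for os_, oe, _ in others:
                cut = [
                    piece
                    for (cs, ce) in cut
                    for piece in _subtract((cs, ce), (os_, oe))
                ]
            for cs, ce in cut:
                medians_parts.append((cs, ce))
        if medians_parts:
            import numpy as np

            values = np.concatenate(
                [profile.depth[cs - 1 : ce] for cs, ce in medians_parts]
            )
            medians[m.name] = float(np.median(values))
    if not medians:
        return model
    top = max(medians.values())
    for m in model.molecules:
        if m.name in medians and top > 0:
            m.relative_copy_number = medians[m.name] / top
        elif m.name not in medians:
            m.note = "no exclusive interval; copy number omitted"
    return model


def _subtract(interval: tuple[int, int], other: tuple[int, int]) -> list[tuple[int, int]]:
    s, e = interval
    os_, oe = other
    if oe < s or os_ > e:
        return [(s, e)]
    out = []
    if os_ > s:
        out.append((s, os_ - 1))
    if oe < e:
        out.append((oe + 1, e))
    return out
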