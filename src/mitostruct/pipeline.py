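"""End-to-end structural assessment: reads + scaffold -> topology model."""

from __future__ import annotations

from dataclasses import dataclass

from . import coverage as cov
from . import mapping, pairs, topology
from .seqs import GenomeSequence


@dataclass
class StructuralAssessment:
    records: list[mapping.PairAlignmentRecord]
    profile: cov.CoverageProfile
    anomalies: list[cov.AnomalyRegion]
    classifications: list[pairs.PairClassification]
    clusters: list[pairs.InconsistentCluster]
    model: topology.TopologyModel


def assess_structure(
    scaffold: GenomeSequence,
    reads1,
    reads2,
    insert: int = 800,
    tol: float = 0.5,
    window: int = 1000,
    min_support: int = 5,
    min_len_frac: float = 0.90,
    min_identity: float = 0.90,
    spike_factor: float = 2.0,
    dip_factor: float = 0.6,
    min_anomaly_len: int = 2000,
) -> StructuralAssessment:
    """Map pairs, profile coverage, classify and cluster inconsistent pairs,
    and infer the topology model with copy numbers."""
    records = mapping.map_pairs(reads1, reads2, scaffold, min_len_frac, min_identity)
    profile = cov.compute_depth(records, scaffold)
    anomalies = cov.detect_anomalies(
        profile, window, spike_factor, dip_factor, min_anomaly_len
    )
    classifications = pairs.classify_pairs(records, insert, tol)
    bins = pairs.bin_inconsistent(classifications, records, window)
    clusters = pairs.detect_clusters(bins, min_support)
    segments = topology.segment_scaffold(profile, anomalies)
    graph = topology.build_junction_graph(segments, clusters, window)
    model = topology.infer_topology(graph)
    model = topology.assign_copy_numbers(model, profile)
    return StructuralAssessment(records, profile, anomalies, classifications, clusters, model)
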