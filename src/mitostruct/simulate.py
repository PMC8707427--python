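"""Synthetic genomes, structural isoforms and paired-end read simulation.

This module generates the inputs the rest of the pipeline consumes, with
machine-readable truth tables for every planted feature, emulating a plant
mitogenome sequencing study: genomes of a few hundred kb, dispersed repeats
up to ~500 bp, plastid-derived insertions (MIPTs) of 1-2 kb, and an Illumina
large-insert paired-end library (2 x 125 bp reads, ~800 bp inserts, ~30x
depth).  Structural isoform sets — a single circle, or two circles
interconverting with a linearized form through a substoichiometric bridge —
are expressed as molecules built from oriented scaffold intervals with
relative copy numbers, and reads are drawn from molecules in proportion to
copy number x length.

All coordinates are 1-based closed intervals.  All randomness flows from
explicit integer seeds through ``numpy.random.default_rng``; identical specs
and seeds give byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import FastqRecord, GenomeSequence, revcomp

REPEAT_TRUTH_COLUMNS = ["kind", "feature_id", "start", "end", "partner_start", "partner_end", "identity"]
PAIR_TRUTH_COLUMNS = ["read_id", "molecule", "start", "insert_length", "flipped"]


@dataclass
class PlantedRepeat:
    """A dispersed repeat: the interval at ``source_start`` is copied to
    ``copy_start`` and mutated down to ``identity``."""

    length: int
    identity: float
    source_start: int
    copy_start: int


@dataclass
class PlantedMipt:
    """A plastid-derived segment: ``plastome[donor_start..donor_end]`` is
    written into the genome at ``insert_start`` at the given identity."""

    donor_start: int
    donor_end: int
    insert_start: int
    identity: float

    @property
    def length(self) -> int:
        return self.donor_end - self.donor_start + 1


@dataclass
class GenomeSpec:
    length: int
    gc_fraction: float = 0.45
    seed: int = 0
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    planted_mipts: list[PlantedMipt] = field(default_factory=list)

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        intervals = []
        for r in self.planted_repeats:
            intervals.append(("repeat source", r.source_start, r.source_start + r.length - 1))
            intervals.append(("repeat copy", r.copy_start, r.copy_start + r.length - 1))
        for m in self.planted_mipts:
            intervals.append(("MIPT insertion", m.insert_start, m.insert_start + m.length - 1))
        for label, s, e in intervals:
            if s < 1 or e > self.length:
                raise ValueError(f"{label} [{s}, {e}] outside genome [1, {self.length}]")
        intervals.sort(key=lambda t: t[1])
        for (la, sa, ea), (lb, sb, eb) in zip(intervals, intervals[1:]):
            if sb <= ea:
                raise ValueError(
                    f"planted intervals overlap: {la} [{sa}, {ea}] and {lb} [{sb}, {eb}]"
                )


@dataclass
class MoleculeSpec:
    """One molecule of an isoform set: an ordered list of oriented scaffold
    intervals ``(start, end, strand)`` with a relative copy number."""

    name: str
    topology: str  # "circular" | "linear"
    segments: list[tuple[int, int, str]]
    copy_number: float = 1.0


@dataclass
class IsoformSpec:
    molecules: list[MoleculeSpec]


@dataclass
class Molecule:
    name: str
    topology: str
    segments: list[tuple[int, int, str]]
    copy_number: float
    sequence: GenomeSequence


@dataclass
class LibrarySpec:
    """Paired-end library model: truncated-normal insert sizes, inward-facing
    (FR) mates, uniform substitution errors, constant placeholder qualities."""

    insert_mean: int = 800
    insert_sd: int = 80
    read_length: int = 125
    depth_target: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.depth_target <= 0:
            raise ValueError("depth_target must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, identity: float) -> np.ndarray:
    """Substitute exactly round((1-identity)*len) positions to different bases."""
    out = arr.copy()
    n_mut = int(round((1.0 - identity) * len(arr)))
    if n_mut == 0:
        return out
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in pos:
        choices = bases[bases != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_plastome(length: int = 20000, gc_fraction: float = 0.37, seed: int = 0) -> GenomeSequence:
    """A plastome-like random donor sequence for MIPT planting."""
    rng = np.random.default_rng(seed)
    arr = _random_sequence(rng, length, gc_fraction)
    return GenomeSequence("plastome", arr.tobytes().decode("ascii"), circular=True)


def generate_genome(
    spec: GenomeSpec, plastome: GenomeSequence | None = None
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Generate a random genome with planted repeats and MIPTs.

    Returns the genome and a truth table (one row per planted feature; repeat
    rows carry the partner copy's coordinates, MIPT rows the donor interval).
    """
    spec.validate()
    if spec.planted_mipts and plastome is None:
        raise ValueError("planted_mipts requires a plastome donor sequence")
    rng = np.random.default_rng(spec.seed)
    arr = _random_sequence(rng, spec.length, spec.gc_fraction)

    rows = []
    for i, r in enumerate(spec.planted_repeats):
        src = arr[r.source_start - 1 : r.source_start - 1 + r.length]
        arr[r.copy_start - 1 : r.copy_start - 1 + r.length] = _mutate(rng, src, r.identity)
        rows.append(
            (
                "repeat",
                f"repeat_{i}",
                r.source_start,
                r.source_start + r.length - 1,
                r.copy_start,
                r.copy_start + r.length - 1,
                r.identity,
            )
        )
    for i, m in enumerate(spec.planted_mipts):
        donor = np.frombuffer(
            plastome.fetch(m.donor_start, m.donor_end).encode("ascii"), dtype=np.uint8
        )
        arr[m.insert_start - 1 : m.insert_start - 1 + m.length] = _mutate(rng, donor, m.identity)
        rows.append(
            (
                "mipt",
                f"mipt_{i}",
                m.insert_start,
                m.insert_start + m.length - 1,
                m.donor_start,
                m.donor_end,
                m.identity,
            )
        )
    truth = pd.DataFrame(rows, columns=REPEAT_TRUTH_COLUMNS)
    return GenomeSequence("synthetic_genome", arr.tobytes().decode("ascii")), truth


def build_isoforms(scaffold: GenomeSequence, spec: IsoformSpec) -> list[Molecule]:
    """Materialise molecule sequences from oriented scaffold intervals.

    Circular molecules are flagged so that read sampling wraps the origin.
    Requires every scaffold base to be covered by at least one molecule.
    """
    if not spec.molecules:
        raise ValueError("isoform spec has no molecules")
    cover = np.zeros(len(scaffold) + 1, dtype=bool)
    out = []
    for m in spec.molecules:
        parts = []
        for start, end, strand in m.segments:
            if end < start or end - start + 1 <= 0:
                raise ValueError(f"zero-length or inverted segment ({start}, {end}) in {m.name}")
            if start < 1 or end > len(scaffold):
                raise ValueError(f"segment ({start}, {end}) outside scaffold in {m.name}")
            if m.copy_number <= 0:
                raise ValueError(f"copy_number must be positive in {m.name}")
            piece = scaffold.fetch(start, end)
            parts.append(piece if strand == "+" else revcomp(piece))
            cover[start : end + 1] = True
        seq = GenomeSequence(m.name, "".join(parts), circular=(m.topology == "circular"))
        out.append(Molecule(m.name, m.topology, list(m.segments), m.copy_number, seq))
    if not cover[1:].all():
        first = int(np.argmin(cover[1:])) + 1
        raise ValueError(f"scaffold base {first} is covered by no molecule")
    return out


def two_circle_bridge_spec(
    scaffold_len: int, bridge_start: int, bridge_end: int, ratio: float = 3.0
) -> IsoformSpec:
    """Isoform set for a two-circle genome interconverting with a linearized
    form through a substoichiometric bridge.

    Circle A = [1 .. bridge_start-1], circle B = [bridge_end+1 .. L], both at
    copy ``ratio - 1``; the linearized full-length molecule at copy 1 carries
    the bridge, so exclusive regions sit at ``ratio`` and the bridge at 1 —
    a depth dip by a factor of ``ratio``.
    """
    if not 1 < bridge_start <= bridge_end < scaffold_len:
        raise ValueError("bridge must be internal to the scaffold")
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    return IsoformSpec(
        [
            MoleculeSpec("circle_A", "circular", [(1, bridge_start - 1, "+")], ratio - 1.0),
            MoleculeSpec("circle_B", "circular", [(bridge_end + 1, scaffold_len, "+")], ratio - 1.0),
            MoleculeSpec("linearized", "linear", [(1, scaffold_len, "+")], 1.0),
        ]
    )


def _scaffold_copy_profile(molecules: list[Molecule]) -> np.ndarray:
    """Summed copy number per scaffold base (diff-array over segments)."""
    L = max(end for m in molecules for _, end, _ in m.segments)
    diff = np.zeros(L + 2)
    for m in molecules:
        for start, end, _ in m.segments:
            diff[start] += m.copy_number
            diff[end + 1] -= m.copy_number
    return np.cumsum(diff)[1 : L + 1]


def simulate_pairs(
    molecules: list[Molecule], library: LibrarySpec
) -> tuple[list[FastqRecord], list[FastqRecord], pd.DataFrame]:
    """Draw paired-end reads from a molecule set.

    Inserts are truncated-normal; mates are the two ends of the insert,
    inward-facing, with the sampled strand of the fragment chosen uniformly
    (so mate 1 is the forward end for half the pairs).  The molecule is
    chosen with probability proportional to copy_number x length, and the
    number of pairs is set so that regions at maximal summed copy number
    reach ``depth_target``.  Returns the two mate streams and a truth table
    (molecule, 1-based start on the molecule, insert length, strand flip).
    """
    library.validate()
    rng = np.random.default_rng(library.seed)
    rl = library.read_length
    for m in molecules:
        if len(m.sequence) < 2 * rl:
            raise ValueError(f"molecule {m.name} shorter than two read lengths")
        if not m.sequence.circular and len(m.sequence) < library.insert_mean + 3 * library.insert_sd:
            raise ValueError(
                f"linear molecule {m.name} shorter than insert_mean + 3*insert_sd"
            )

    copy_profile = _scaffold_copy_profile(molecules)
    max_copy = copy_profile.max()
    weights = np.array([m.copy_number * len(m.sequence) for m in molecules], dtype=float)
    effective_bases = weights.sum() / max_copy
    n_pairs = int(round(library.depth_target * effective_bases / (2 * rl)))

    mol_idx = rng.choice(len(molecules), size=n_pairs, p=weights / weights.sum())
    inserts = rng.normal(library.insert_mean, library.insert_sd, size=n_pairs)
    starts = rng.random(n_pairs)
    flips = rng.random(n_pairs) < 0.5

    reads1, reads2, rows = [], [], []
    qual = "I" * rl
    for i in range(n_pairs):
        m = molecules[mol_idx[i]]
        L = len(m.sequence)
        ins = int(round(inserts[i]))
        ins = max(2 * rl, min(ins, L))
        if m.sequence.circular:
            start = int(starts[i] * L) + 1
        else:
            start = int(starts[i] * (L - ins + 1)) + 1
        frag = m.sequence.fetch(start, start + ins - 1)
        fwd = frag[:rl]
        rev = revcomp(frag[-rl:])
        if library.error_rate > 0:
            fwd = _apply_errors(rng, fwd, library.error_rate)
            rev = _apply_errors(rng, rev, library.error_rate)
        rid = f"sim_{i}"
        if flips[i]:
            reads1.append(FastqRecord(rid, rev, qual))
            reads2.append(FastqRecord(rid, fwd, qual))
        else:
            reads1.append(FastqRecord(rid, fwd, qual))
            reads2.append(FastqRecord(rid, rev, qual))
        rows.append((rid, m.name, start, ins, bool(flips[i])))

    truth = pd.DataFrame(rows, columns=PAIR_TRUTH_COLUMNS)
    return reads1, reads2, truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        arr[i] = rng.choice(bases[bases != arr[i]])
    return arr.tobytes().decode("ascii")
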