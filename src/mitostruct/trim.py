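"""Conserved-block trimming of multiple sequence alignments.

Implements the classic conserved-block selection procedure for removing
ambiguously aligned regions before phylogenetic analysis, with the relaxed
parameterisation commonly used for divergent organelle datasets: conserved
and flank thresholds at minimum majority ("half" = floor(n/2)+1 sequences),
up to 8 contiguous nonconserved positions inside a block, minimum block
length 5, and gap positions tolerated in up to half the sequences.

Procedure, for an alignment of n rows:

1. classify each column — gap-disqualified (too many gaps under the b5
   mode) columns are nonconserved; otherwise a column is conserved when its
   modal residue occurs in >= b1 rows and highly conserved when >= b2;
2. reject maximal stretches of more than b3 contiguous nonconserved
   columns, and reject entirely any nonconserved stretch containing a
   gap-disqualified column (gap adjacency rule);
3. trim each candidate block from both ends until the terminal columns are
   highly conserved;
4. reject blocks shorter than b4.

Off-by-one warning: "half" means floor(n/2)+1, the smallest strict
majority — with 10 rows a modal residue in exactly 5 rows is NOT conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAP_CHARS = {"-", "."}
RESIDUES = set("ACGTU")

NONCONSERVED = "nonconserved"
CONSERVED = "conserved"
HIGHLY_CONSERVED = "highly_conserved"


@dataclass
class Msa:
    """A DNA multiple sequence alignment: parallel taxon names and
    equal-length gapped rows (uppercased on construction)."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa: {dup}")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq))
        return cls(taxa, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")

    def take_columns(self, columns: list[int]) -> "Msa":
        """Sub-alignment of the given 1-based original columns, in order."""
        idx = [c - 1 for c in columns]
        return Msa(list(self.taxa), ["".join(r[i] for i in idx) for r in self.rows])


@dataclass
class TrimParams:
    b1: int  # min rows for a conserved position
    b2: int  # min rows for a flank (highly conserved) position
    b3: int = 8  # max contiguous nonconserved positions inside a block
    b4: int = 5  # min block length
    b5: str = "half"  # gap tolerance: "none" | "half" | "all"

    @classmethod
    def relaxed(cls, n_taxa: int) -> "TrimParams":
        """The relaxed setting: b1 = b2 = half (minimum majority), b3 = 8,
        b4 = 5, gaps allowed in up to half the rows."""
        half = n_taxa // 2 + 1
        return cls(b1=half, b2=half, b3=8, b4=5, b5="half")

    def validate(self, n_taxa: int) -> None:
        if not (0 < self.b1 <= self.b2 <= n_taxa):
            raise ValueError(f"need 0 < b1 <= b2 <= n ({self.b1}, {self.b2}, n={n_taxa})")
        if self.b3 < 0:
            raise ValueError("b3 must be >= 0")
        if self.b4 < 2:
            raise ValueError("b4 must be >= 2")
        if self.b5 not in ("none", "half", "all"):
            raise ValueError("b5 must be one of none/half/all")


@dataclass
class BlockSelection:
    kept_columns: list[int]  # 1-based original column indices, increasing
    blocks: list[tuple[int, int]]  # (start, end) closed, original coordinates


def classify_columns(msa: Msa, params: TrimParams) -> tuple[list[str], list[bool]]:
    """Per-column status plus a gap-disqualification flag.

    Ambiguity codes (N, R, Y, ...) are non-gap residues that never count
    toward the modal residue.
    """
    n = msa.n_taxa
    if n == 0 or msa.n_columns == 0:
        raise ValueError("empty alignment")
    params.validate(n)
    statuses, gapflags = [], []
    for j in range(msa.n_columns):
        col = [r[j] for r in msa.rows]
        gaps = sum(c in GAP_CHARS for c in col)
        if params.b5 == "none":
            gap_bad = gaps > 0
        elif params.b5 == "half":
            gap_bad = gaps > n // 2
        else:
            gap_bad = False
        if gap_bad:
            statuses.append(NONCONSERVED)
            gapflags.append(True)
            continue
        gapflags.append(False)
        counts: dict[str, int] = {}
        for c in col:
            if c in RESIDUES:
                counts[c] = counts.get(c, 0) + 1
        modal = max(counts.values(), default=0)
        if modal >= params.b2:
            statuses.append(HIGHLY_CONSERVED)
        elif modal >= params.b1:
            statuses.append(CONSERVED)
        else:
            statuses.append(NONCONSERVED)
    return statuses, gapflags


def select_blocks(
    statuses: list[str], params: TrimParams, gapflags: list[bool] | None = None
) -> BlockSelection:
    """Conserved-block selection over classified columns (module docstring
    steps 2-4).  Returns kept columns in 1-based original coordinates."""
    n_cols = len(statuses)
    if gapflags is None:
        gapflags = [False] * n_cols
    rejected = [False] * n_cols

    j = 0
    while j < n_cols:
        if statuses[j] != NONCONSERVED:
            j += 1
            continue
        start = j
        while j < n_cols and statuses[j] == NONCONSERVED:
            j += 1
        run_len = j - start
        has_gap = any(gapflags[start:j])
        if run_len > params.b3 or has_gap:
            for i in range(start, j):
                rejected[i] = True

    blocks: list[tuple[int, int]] = []
    kept: list[int] = []
    j = 0
    while j < n_cols:
        if rejected[j]:
            j += 1
            continue
        start = j
        while j < n_cols and not rejected[j]:
            j += 1
        end = j - 1
        while start <= end and statuses[start] != HIGHLY_CONSERVED:
            start += 1
        while end >= start and statuses[end] != HIGHLY_CONSERVED:
            end -= 1
        if start > end or end - start + 1 < params.b4:
            continue
        blocks.append((start + 1, end + 1))
        kept.extend(range(start + 1, end + 2))
    return BlockSelection(kept, blocks)


def trim_msa(msa: Msa, params: TrimParams | None = None) -> tuple[Msa, BlockSelection]:
    """Classify, select and extract in one call (params default: relaxed)."""
    if params is None:
        params = TrimParams.relaxed(msa.n_taxa)
    statuses, gapflags = classify_columns(msa, params)
    sel = select_blocks(statuses, params, gapflags)
    return msa.take_columns(sel.kept_columns), sel


def concat_and_trim(
    msas: list[tuple[str, Msa]], params: TrimParams | None = None
) -> tuple[Msa, dict[str, BlockSelection], list[tuple[str, int, int]]]:
    """Trim each gene alignment independently, then concatenate.

    Taxa sets are unioned (order of first appearance); taxa missing from a
    gene are padded with all-gap rows before trimming.  Returns the
    concatenated alignment, the per-gene selections, and a partition table
    of (gene, start, end) in concatenated 1-based coordinates (empty genes
    recorded with start > end).
    """
    if not msas:
        raise ValueError("no alignments given")
    taxa: list[str] = []
    for _, m in msas:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    trimmed: list[tuple[str, Msa, BlockSelection]] = []
    for name, m in msas:
        rows = []
        for t in taxa:
            if t in m.taxa:
                rows.append(m.rows[m.taxa.index(t)])
            else:
                rows.append("-" * m.n_columns)
        padded = Msa(list(taxa), rows)
        p = params if params is not None else TrimParams.relaxed(len(taxa))
        out, sel = trim_msa(padded, p)
        trimmed.append((name, out, sel))
    parts: list[tuple[str, int, int]] = []
    pos = 0
    rows_out = ["" for _ in taxa]
    selections: dict[str, BlockSelection] = {}
    for name, out, sel in trimmed:
        width = out.n_columns
        parts.append((name, pos + 1, pos + width))
        for i in range(len(taxa)):
            rows_out[i] += out.rows[i] if width else ""
        pos += width
        selections[name] = sel
    return Msa(list(taxa), rows_out), selections, parts


def write_partitions(parts: list[tuple[str, int, int]], path) -> None:
    """RAxML-style plain-text partition table (empty genes skipped)."""
    with open(path, "w") as fh:
        for name, start, end in parts:
            if end >= start:
                fh.write(f"DNA, {name} = {start}-{end}\n")
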