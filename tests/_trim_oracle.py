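"""Naive, independent reference implementation of conserved-block trimming.

Written column-by-column from the published procedure description, with a
deliberately different code structure from the package implementation
(status strings + itertools.groupby instead of index scans), to serve as a
dual-route oracle in the tests.
"""

from itertools import groupby

GAPS = "-."


def column_status(column, b1, b2, b5):
    n = len(column)
    gaps = sum(c in GAPS for c in column)
    if b5 == "none":
        allowed = 0
    elif b5 == "half":
        allowed = n // 2
    else:
        allowed = n
    if gaps > allowed:
        return "G"  # gap-disqualified (nonconserved)
    tally = {}
    for c in column:
        if c in "ACGTU":
            tally[c] = tally.get(c, 0) + 1
    modal = max(tally.values()) if tally else 0
    if modal >= b2:
        return "H"
    if modal >= b1:
        return "C"
    return "N"


def kept_columns(rows, b1, b2, b3=8, b4=5, b5="half"):
    """1-based kept column indices for an alignment given as row strings."""
    rows = [r.upper() for r in rows]
    width = len(rows[0])
    status = "".join(
        column_status([r[j] for r in rows], b1, b2, b5) for j in range(width)
    )
    # reject nonconserved stretches longer than b3 or containing a gap column
    rejected = [False] * width
    pos = 0
    for key, grp in groupby(status, key=lambda s: s in "NG"):
        chunk = list(grp)
        if key and (len(chunk) > b3 or "G" in chunk):
            for j in range(pos, pos + len(chunk)):
                rejected[j] = True
        pos += len(chunk)
    # candidate blocks between rejections, trimmed to highly conserved flanks
    kept = []
    pos = 0
    for key, grp in groupby(rejected):
        chunk_len = len(list(grp))
        if not key:
            lo, hi = pos, pos + chunk_len - 1
            while lo <= hi and status[lo] != "H":
                lo += 1
            while hi >= lo and status[hi] != "H":
                hi -= 1
            if lo <= hi and hi - lo + 1 >= b4:
                kept.extend(range(lo + 1, hi + 2))
        pos += chunk_len
    return kept


def random_alignment(rng, n_taxa, width, p_mutate=0.25, p_gap=0.08):
    """A toy DNA alignment: a random master row with per-cell mutations and
    gaps, yielding a mix of conserved and ambiguous regions."""
    bases = "ACGT"
    master = "".join(rng.choice(list(bases)) for _ in range(width))
    rows = []
    for _ in range(n_taxa):
        row = []
        for c in master:
            u = rng.random()
            if u < p_gap:
                row.append("-")
            elif u < p_gap + p_mutate:
                row.append(rng.choice([b for b in bases if b != c]))
            else:
                row.append(c)
        rows.append("".join(row))
    return rows
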