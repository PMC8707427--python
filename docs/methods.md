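# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitostruct`, and what its synthetic-data validation does and does
not establish about real data.

## Coordinates and conventions

All genomic coordinates are 1-based, fully closed intervals. Conversion to
0-based half-open happens only at output boundaries (BED, bedGraph) and is
noted there. Window w over a scaffold covers bases (w−1)·1000+1 … w·1000;
a position p falls in window ⌈p/1000⌉. Reported molecule lengths are exact
integer base-pair counts; rounding to kb happens only in reports.

## Read mapping

The built-in mapper is deliberately minimal: exact 31-mer seeds on both
strands, gapless extension, mismatch counting. A placement qualifies when
the aligned span covers ≥ 90% of the read ("90% length" = aligned span ≥
0.9 × read length, which admits placements clipped by a scaffold end) and
identity over that span is ≥ 90%. Substitution-only alignment suffices
because the companion simulator emits no indels; users with real reads are
expected to supply SAM/BAM from a production mapper through
`ingest_alignments`, which applies the same two thresholds (identity from
the NM tag over the aligned length, primary alignments only).

Seed sensitivity: seeds are taken every 31 bases plus one flush with the
read's 3′ end, so any placement with an exact 31-mer in one of those
windows is found. Reads mutated heavily enough to break every seed window
are missed regardless of identity — irrelevant at the simulator's error
rates (< 1%), and real-data users go through an external mapper anyway.

Multi-placement mates (exact repeats) set an ambiguity flag on the pair.
Ambiguous pairs contribute to coverage but are excluded from consistency
classification: a repeat-induced mis-pick of a placement would otherwise
fabricate junction signal. Best placement per mate is chosen by identity,
ties broken leftmost.

## Pair consistency and clustering

Head-to-head is the standard inward-facing FR geometry: leftmost mate on
'+', rightmost on '−'. The outer distance is the fragment span (rightmost
end − leftmost start + 1), compared against insert·(1 ± tol) with
inclusive bounds (defaults 800 bp, tol 0.5 → 400–1200). Pairs with an
unmapped or ambiguous mate are *unresolved* and carry no junction signal.

Inconsistent pairs are binned by the windows of each mate's start position
(start, not midpoint: the start is what the mapper pins most reliably, and
the choice moves a junction by at most one window). Bins whose window
indices both differ by ≤ 1 are merged into connected components so a
junction straddling a window boundary is not double-reported; the minimum
support of 5 read pairs applies to the component total. With error-free
pairs, inconsistency arises only at true junctions; stray bins from
sequencing error are isolated singletons and never reach the threshold.

## Coverage anomalies

Detection is median-driven throughout: the genome median is robust to the
spikes being sought, and window medians are robust to single-read noise.
Defaults — spike factor 2.0, dip factor 0.6, minimum run 2000 bp — are set
so that the signatures this analysis targets (≈2× spikes over kb-scale
plastid-derived segments; dips to ≈0.4× over a multi-kb bridge) are
detected with margin on both sides. The minimum-length filter applies to
the merged run of flagged 1-kb windows *before* boundary refinement: a
1.7 kb feature spanning two windows is a 2000 bp run and is kept, after
which boundaries are refined to the first/last base crossing the threshold
within the run extended by one window. On step-like profiles this
reproduces boundaries exactly; on sampled profiles the refined boundary
lands inside the insert-length transition zone around the true breakpoint
(typically within a few hundred bp at 30×).

The stoichiometry ratio (genome median / region median) is quantized by
integer per-base depth: at 30× a region at one-fifth copy sits at 6×,
where one depth unit is 17% of the estimate. Parameter-recovery claims are
therefore made about the batch median across seeded replicates; at ratio 3
and 30× individual replicates already land within ±15%.

## Topology inference

Only the two positive evidence patterns described in the README (single
circle; two circles + substoichiometric bridge) are recognised, plus
linear and unresolved fallbacks. Arbitrary breakpoint-graph traversal is
deliberately out of scope: for genomes without large repeats these are the
structures a paired-end library can support, and anything else is reported
unresolved with its raw edge list rather than guessed. A cluster window
counts as a scaffold end or segment flank within a tolerance of 2 windows,
matching the localisation accuracy of insert-size evidence (mates sit up
to ~1 insert from the junction). Copy numbers are median depths over each
molecule's exclusive intervals, normalised to a maximum of 1; molecules
with no exclusive base are annotated rather than assigned.

The two-circle decomposition is exact integer arithmetic on the dip
boundaries: dip at [s, e] on a scaffold of length L gives circles of
s−1 and L−e bp and a bridge of e−s+1 bp.

## Homology scanning

The similarity engine anchors on exact k-mers and extends gaplessly with
+1/match, −2/mismatch scoring and an X-drop of 20 (i.e. extension stops
after a net score drop of 20; hits are trimmed to best-scoring endpoints).
Defaults: k=17 for repeat self-scans (at 90% identity a 100 bp repeat
still contains ~14 exact 17-mers in expectation), k=12 for the 80% MIPT
floor, k=12 with a gentler −1 mismatch penalty and X-drop 40 for gene
location at the 70% floor. Identity is counted over the final hit span.
Repeat identity is strict (> 90%), MIPT identity inclusive (≥ 80%),
following the usual phrasing of each inventory convention.

Boundary accuracy on planted features is typically exact to a few bases;
two effects move it: mutations landing on a planted feature's edge bases
shave the hit inward, and chance matches in the flank can stretch it
outward (any local aligner, including blastn, does the same). Tests allow
single-digit base tolerances accordingly.

Same-diagonal hits are merged (gapless alignment confines one repeat pair
to one diagonal); self-comparison reports each pair once with the leftmost
interval first, and palindromic self-hits are dropped. Counts are
reported as hit pairs; users wanting distinct repeated intervals can
derive them from the interval columns.

## Alignment trimming

The conserved-block procedure is implemented as published for the classic
0.91b behaviour: (1) columns with gaps in more than the allowed number of
rows (b5=half → more than ⌊n/2⌋) are nonconserved; otherwise a column is
conserved when its modal residue count ≥ b1 and highly conserved when ≥
b2; (2) nonconserved stretches longer than b3, or containing a
gap-disqualified column, are rejected; (3) candidate blocks are trimmed
from both ends to highly conserved columns; (4) blocks shorter than b4 are
rejected. "half" is ⌊n/2⌋+1 — the smallest strict majority; an off-by-one
here changes outputs, so it is pinned by test. Ambiguity codes are non-gap
residues that never count toward the modal residue; '-' and '.' both count
as gaps. With b1=b2=half the conserved/highly-conserved distinction
collapses, but both thresholds are implemented separately so stricter
settings work.

The reference binary for this procedure is not distributable with the
package, so equivalence is established by a dual-implementation oracle: an
independent, naive column-by-column implementation (kept in the test
suite) whose outputs on twelve randomized structured toy alignments are
frozen as fixtures, with the small cases verified by hand. Where the
published description is ambiguous (gap-adjacent nonconserved positions),
the rule implemented is the one stated above: a nonconserved stretch
containing any gap-disqualified column is removed entirely.

Batch concatenation unions the taxa sets (padding missing taxa with
all-gap rows before trimming, which under b5=half leaves a gene's columns
eligible as long as gaps stay in the minority), trims each gene
independently, and emits a RAxML-style partition table.

## Synthetic data: what it emulates, and what it does not

The simulator reproduces the statistical structure the analysis assumes:
~hundreds-of-kb genomes, 2 × 125 bp pairs from an 800 bp library at
~30×, planted repeats up to ~500 bp, planted plastid-derived segments of
1–2 kb, and molecule sets with relative copy numbers, including the
two-circle + bridge configuration (circles [1..s−1] and [e+1..L] at copy
r−1 plus a full-length linearized molecule at copy 1, giving the r:1
exclusive-to-bridge depth ratio). Inserts are truncated normal with
sd = 80 bp (10% of the mean; the real library's spread is unknown — the
±50% consistency tolerance suggests a broad distribution, and the value is
configurable). Errors are substitution-only; quality strings are constant
placeholders. Molecules are chosen per pair with probability ∝ copy ×
length, and the pair count is set so regions at maximal summed copy reach
the target depth.

Not emulated: machine-specific error profiles, indels, PCR duplicates,
adapter contamination, GC bias, and organellar-nuclear shared sequence.
Passing tests therefore demonstrate correctness of the inference logic
under the stated read model, not robustness to every artefact of a real
library — which is why the mapping front end accepts external SAM/BAM.

Coverage-spike validation plants an extra molecule spanning the MIPT
interval at additional copy number; this produces the same depth signature
as plastid reads multi-mapping onto the MIPT without requiring
multi-placement counting in the depth computation.

## Problem sizes

Validation runs use 30–100 kb genomes at 20–60×: at these sizes every
signal the pipeline uses (junction support ≈ depth·insert/(2·read length),
window medians, dip contrast) is comfortably above its detection threshold,
and each simulate→map→infer cycle completes in ~1 s, so multi-seed
recovery experiments stay cheap. The worked example runs at the full
366 kb printed coordinates since it is pure arithmetic on a constructed
profile.

## Known limitations

- The built-in mapper is gapless and unsuitable for indel-rich real reads;
  it exists to close the loop on simulated data.
- Junction localisation is window-scale (1 kb); no split-read evidence is
  used, so breakpoints are not base-exact.
- Insert size is a configuration parameter, not re-estimated from data.
- The topology classifier does not enumerate repeat-mediated isoforms;
  genomes with large (> 1 kb) repeats will typically come back unresolved.
- Inferred models describe what the read data support about the assembly,
  not necessarily the in vivo molecule population.
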