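# Methods

## Data model and coordinate conventions

All coordinates are 1-based inclusive on a locus's own axis; BED, bedGraph
and SAM files are converted at the I/O boundary (BED/bedGraph 0-based
half-open, SAM 1-based). A validated junction is stored as the two flanking
coordinates (x, x+1) with the break between them, which avoids committing to
"break after x" versus "break before x+1" — the same convention used in
published breakpoint tables.

A *chromPET* is the pair of 38-bp end tags of one sheared fragment. Tag
pairs are classified as:

* **normal** — both tags uniquely on the same locus, forward/reverse with
  the + tag upstream (FR). Fragment length = outer span.
* **junctional** — tags uniquely on different loci, any orientation.
* **discarded** — a missing, unmapped, multi-mapping, or
  orientation-inconsistent mate.

The FR requirement for normal pairs is a deliberate guard: everted or
same-strand same-locus pairs (chimeras, artifacts) are discarded rather than
allowed to corrupt the fragment-length model. Junctional classification does
not require FR because a junction-spanning fragment's orientation signature
is what identifies which locus donates the 5' side (the + tag sits on the 5'
donor when pairs point inward).

## Fragment-length model

Mean and sample SD (n−1) of normal-chromPET spans, pooled across all samples
of a run (per-sample models are available in the library). Both are rounded
half-up to integer bp because they directly define integer vote-zone widths.
Spans greater than mean + 10 SD of the initial fit are excluded and the
model refit once; the exclusion applies to estimation only. Fewer than two
normal chromPETs is an error unless a fallback model is configured (e.g.
from the library's size-selection target).

## Vote-based localization

Each junctional tag votes on its own locus, anchored at its 5'-most base and
extending in its 3' direction — the direction of the unseen fragment
interior, where the junction must lie (the breakpoint falls between a tag
and its mate). Zone lengths are mean (weight 3) then SD (weight 2) then SD
(weight 1), as inclusive integer intervals clipped to the locus; SD = 0
degenerates to the weight-3 zone alone. Whether the weight-3 zone should
begin at the tag's first or last base is not derivable from first
principles; anchoring at the 5'-most base shifts predictions by at most one
tag length (38 bp), well inside the method's intrinsic error, and makes the
zone contain the junction whenever the fragment is no longer than mean.

Junctional chromPETs are split by fusion orientation and voted separately,
so the two reciprocal junctions give distinct predictions per locus. The
called interval is the maximal run of positions attaining the profile
maximum. Calling thresholds (all CLI-configurable):

* `min_vote = 9` — the maximum must reach at least three overlapping
  weight-3 zones' worth of votes; with fewer than three consistent
  junctional chromPETs there is no call.
* width ≤ mean + 2 SD — a wider flat maximum means the evidence does not
  localize the junction.
* `secondary_frac = 0.8` — a disjoint run reaching 80% of the maximum makes
  the call AMBIGUOUS; exact ties between maximal runs are AMBIGUOUS too,
  never silently resolved to the leftmost.

These thresholds are this package's own operating point: the source method
describes its no-call behavior qualitatively, so the defaults were chosen to
be conservative (a false call requires three independent concordant
fragments) and are exposed rather than hard-coded.

## Junction characterization

**Prediction-to-truth distance** is the nearest-boundary gap: 0 when the
flanking pair (x, x+1) overlaps the called interval [a, b], else x − b
(junction downstream) or a − (x+1) (upstream). This convention reproduces 13
of the 14 printed distances in the validation table the package is tested
against; the remaining cell prints 3 where the convention yields 2, treated
as an upstream off-by-one rather than special-cased. One validated junction
pair in that table (the 102,524-102,525 / 102,526-102,527 pair) implies a
2-bp shared segment under this arithmetic while the accompanying text
describes sequence loss at that locus; the tests record the printed
coordinates as-is. Similarly, the large-offset junction pair
(125,326-125,327 / 149,445-149,446) implies under this arithmetic a ~24-kb
segment present in both derivatives although the source text calls it a
deletion; the package reports what the coordinate arithmetic says and the
simulator round-trip (below) is the normative test.

**Reciprocal classification.** For locus A with c1 = last A base retained in
the A→B fusion and c2 = first A base retained in B→A: consecutive →
balanced; c2 > c1+1 → deletion of c2−c1−1 bases (in neither derivative);
c2 ≤ c1 → duplication of c1−c2+1 bases (in both). Locus B symmetric with
retained sides swapped.

**Microhomology** is the maximal window by which the junction can slide in
both directions while the fused sequence remains producible from both
donors, computed by symmetric base-wise extension and cross-checked in the
tests against brute-force enumeration of all consistent junction
placements. A window spanning an entire input is flagged degenerate.

## The simulator

The generator emulates the structure of the motivating experiment: two
uniformly random loci (defaults 7,000 bp for the captured
breakpoint-cluster-like locus and 175,000 bp for the partner-gene-like
locus), one reciprocal translocation (derivative 1 = A-prefix + B-suffix,
derivative 2 = B-prefix + A-suffix) with optional per-locus deletion or
duplication at the junctions, fragments of length Normal(500, 50) rounded to
integer bp and truncated to [2 × read length, source length] by resampling,
uniform fragment starts, 38-bp reads (read 1 = fragment start, read 2 =
reverse complement of fragment end), and a 4-bp barcode prefixed to both
mates. Fragment sources are drawn from the derivative chromosomes with
probability `tumor_fraction` and from the intact loci otherwise, each pool
weighted by sequence length (uniform shearing of equimolar molecules).
Fragment shape is an assumption: only the 0.5-kb size selection of the
protocol is documented, and a truncated Normal is the standard idealization.

Microhomology of length m is planted by writing one shared m-mer at the four
junction flank sites and then forcing the bases immediately outside each
window to differ between donors, so the detected homology is exactly m.
Configurations whose homology windows would overlap at incompatible offsets
are rejected at validation time.

What the simulator does **not** model: base-call errors are off by default
(a uniform substitution rate is available), base qualities are constant,
there are no indels within reads, no capture-efficiency bias, and no
off-target genomic background. Passing tests therefore demonstrate the
correctness of the pipeline's logic and the statistical behavior of the
voting algorithm under idealized reads; they do not establish robustness to
mapping artifacts of repetitive real genomic sequence, which the
unique-mapping filter only partially addresses.

## Validation experiments and problem sizes

**Localization accuracy** (`validation.breakpoint_recovery_experiment`): 100
replicates, each with fresh random loci, a balanced translocation at a
random position (at least mean + 3 SD from the locus ends), 2,000 read
pairs at tumor fraction 1, full pipeline, distance of the A→B call on the
small locus to the planted junction. Replicates are conditioned on at least
10 junctional chromPETs (re-drawn under a derived seed otherwise), since the
accuracy claim concerns that evidence level; at 2,000 pairs roughly a third
of draws are re-drawn. The acceptance script reports the 90th-percentile
distance, counting a no-call as the small-locus length (7,000 bp, the worst
possible distance) so that missing calls are penalized, not dropped.

**No-call robustness** (`validation.scattered_nocall_experiment`): 10
junctional chromPETs per replicate with uniformly random tag coordinates and
random orientations — the dispersed pattern of cross-sample contamination in
a translocation-negative sample. Tags are scattered over gene-scale loci
(135 kb and 175 kb, the mapping-target scale at which such contamination
disperses in practice); on a locus as small as the 7-kb capture region, ten
scattered 500-bp vote zones would frequently stack into spurious
three-deep clusters, which is a statement about locus size, not about the
caller. All four orientation × locus predictions must be NO_CALL.

**Oracle equivalence**: vote accumulation and argmax calling against a
per-position naive recount (1,000 random instances); microhomology against
brute-force junction-slide enumeration (1,000 instances); barcode assignment
against exhaustive Hamming search over all 4^4 observed barcodes for random
barcode sets of up to 10 entries.

## Known limitations

* Exact full-length matching is deliberate (38-bp tags on two small extracted
  loci); it loses reads with any sequencing error. An optional unambiguous
  1-mismatch rescue exists, and external gapped alignments can be ingested.
* Breakpoints are localized to an interval, not a base: single-base
  resolution requires sequencing across the junction (e.g. junction PCR with
  primers from `primer_targets.bed`).
* Intra-locus structural variants (deletions/inversions within one locus)
  are out of scope; same-locus non-FR pairs are simply discarded.
* The count summary reports both "unique pairs" and "total anchored"
  (normal + junctional) because published count tables do not state whether
  orientation-filtered pairs are included in their totals.
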