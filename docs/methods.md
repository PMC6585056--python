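# Methods

## Coordinate model

All intervals are 0-based, half-open (`[start, end)`), the convention of
the BED inputs the pipeline consumes. Adjacency (`end == start`) is not
overlap. Strand lives on gene models only: for a `+` gene the TSS is the
feature start, for a `−` gene it is `end − 1`, the last covered base. A
gene may carry several TSSs (isoform starts); duplicate gene ids in an
annotation merge their TSSs into one model.

## Enhancer calling

The caller operates on whole peaks, never fragments:

* `intersect_keep(a, b, m)` keeps elements of `a` with their original
  coordinates when they share ≥ `m` bases with at least one *single*
  element of `b` (two abutting `b` elements may not pool their bases).
  `m` defaults to 1 bp and is configurable; no minimum overlap *fraction*
  is imposed.
* `subtract_drop(a, b)` removes an element of `a` entirely on any overlap
  with `b`. Clipping would inflate region counts, and the funnel's
  semantics are counts of regions.

"Annotated TSSs" are expanded to exclusion windows of ±2 kb (default,
configurable) before subtraction: subtracting single bases would remove
almost nothing, and promoter-proximal peaks are exactly what the enhancer
definition must exclude. The two co-occupancy intersections commute (a
test asserts this); their order is fixed only for reproducibility of ids.

Peak-to-TSS distance is measured from the peak midpoint
`floor((start+end)/2)` — unambiguous for wide peaks — and binned into
half-open bins `[0,5 kb)`, `[5,50 kb)`, `[50,500 kb)`, `[500 kb,∞)` with
inclusive lower edges. Peaks on chromosomes without annotated genes fall
in the unbounded bin and are logged.

## TAD linking

A region belongs to the TAD containing its midpoint; it is never assigned
to two TADs, and TADs are validated non-overlapping at load time. A gene
qualifies as a target when it is active and *any* of its TSSs lies inside
the enhancer's TAD (TSS containment, not whole-body containment; activity
is gene-wide, not per-TSS). A TSS sitting exactly on a boundary belongs to
the TAD whose half-open span contains that base. Enhancers outside every
TAD produce no links — there is deliberately no nearest-gene fallback,
because a fallback would silently change the size of the linked-gene set
that downstream expression integration consumes.

Activity is peak overlap, not a signal cutoff: TSS ±1 kb (default) must
overlap an H3K27ac peak by ≥ 1 bp. A signal-threshold definition would
need a normalization model that processed-level peak inputs do not carry.

## Differential-expression integration

`classify_de` partitions genes into up/down/unchanged with inclusive
edges: down iff `q ≤ q_max` and `log2FC ≤ −lfc_min`; up symmetrically.
Defaults are `q_max = 0.05` and per-cell-line `lfc_min` of 0.7 or 0.6.
Duplicate gene ids are an error (silently collapsing them would make
counts irreproducible), and gene identity is exact string match — alias
resolution is dataset-specific and out of scope. Cross-line intersections
(`common_down`) apply each line's own threshold.

## Profile matrices

A bedGraph track is a step function; uncovered positions are 0. For each
region the window `[center − flank, center + flank)` is split into equal
bins (flank 5 kb, bin 50 bp → 200 columns by default; flank must divide
evenly by bin). A bin's value is the length-weighted mean of the step
function over its span, so the computation is exactly linear in the track
and matches a per-base average to floating-point error (< 1e−9 in tests).
Windows truncated by the chromosome start contribute 0 for the missing
bases. "Occupancy" for row ordering is the row mean over the full window
— peak scores are not used — with ties broken by region id so orderings
are deterministic; a reference matrix with identical row ids can impose
its order on other marks for side-by-side heatmaps.

## Cohort statistics

IHC percentages are `100·count/total` rounded half-up to one decimal, the
convention of printed cohort tables; the raw values are returned
alongside. Fisher's exact test uses the hypergeometric null; the
two-sided p sums all tables whose point probability is ≤ the observed one
(with the customary `1+1e−7` tolerance factor), and the default
one-sided "less" alternative tests a *deficit* of double mutants — the
directional mutual-exclusivity claim. The odds ratio is the cross product
`(both·neither)/(a_only·b_only)`; when any cell is zero, 0.5 is added to
every cell (Haldane–Anscombe) and the result is flagged. P-values are
cross-checked in the test suite against a full enumeration of the
hypergeometric support to 1e−12.

## Synthetic data

The generator emulates one processed-level experiment on a 10 Mb toy
chromosome: 20 equal TADs (~500 kb, the scale of mammalian domains), 200
uniformly placed stranded genes of which 40 % are active, 40 true
enhancers and 20 decoys per failure class, all with 600 bp peaks — peak
and domain geometry typical of transcription-factor ChIP-seq and Hi-C at
moderate resolution. True enhancers carry co-centered (±100 bp jitter)
factor/H3K27ac/ATAC peaks; each decoy class violates exactly one calling
criterion, with the promoter-overlapping class centered on active genes'
TSSs so the planted activity flags coincide with what the pipeline
computes. Placement keeps all footprints and TSS exclusion windows
mutually disjoint and keeps inactive promoters more than one activity
window away from any H3K27ac peak, so with default settings the planted
structure is *perfectly separable*: precision = recall = 1.0 end to end.
That is by design — the default dataset is a correctness oracle, not a
difficulty benchmark. Sensitivity is probed separately with `perturb`:
dropping a fraction of enhancer ATAC peaks (recall degrades by exactly
the dropped fraction, since planted items are independent), shifting TAD
boundaries (links whose enhancer and TSS separate are annotated
unrecoverable), or rescaling null genes' q-values toward significance.

Planted downregulation covers *all* enhancer-linked genes, in both
synthetic cell lines, with `log2FC ~ N(−1.5, 0.3)` resampled until ≤ −0.7
and `q ~ U(0, 0.01)`; null genes get `log2FC ~ N(0, 0.2)`, `q ~ U(0, 1)`.
The truncation guarantees planted targets clear every default threshold,
separating correctness tests from borderline-sensitivity tests (which go
through `perturb`). Two lines share the planted targets but have
independent null noise, so cross-line intersections have a known expected
set.

What the generator does **not** emulate: read-level noise, peak-shape and
width variability, signal-dependent peak calling errors, overlapping or
nested TADs, multi-chromosome genomes, correlated expression noise, and
genuinely ambiguous enhancer–promoter geometry. Passing the recovery
suite therefore demonstrates the *logic* of the pipeline is correct under
its stated rules, not that those rules are optimal on real data.

## Numerical and scale choices

* The acceptance script measures recovery on 5 datasets of the default
  size (100 factor peaks, 200 genes, 20 TADs each); the test battery uses
  seeds 1–10. These sizes keep the whole suite in seconds while leaving
  every combinatorial code path exercised.
* Interval oracles run on random instances with chromosome lengths up to
  1 Mb, where per-base boolean masks are exact and cheap.
* Half-up decimal rounding goes through `decimal.Decimal` on the float's
  shortest repr, avoiding binary-float surprises at midpoints.
* Degenerate inputs: empty factor peak set → empty call with a warning
  (not an error); empty link table → all-zero summary; empty profile
  matrix → error on aggregation; zero-total cohort → error.

## Known limitations

The TSS-exclusion width that reproduces any particular published enhancer
count is dataset-specific and must be chosen by the user (it is a single
flag). Linking treats every active same-TAD gene as a target, so linked
gene sets grow with TAD gene density; no distance weighting or contact
frequency is modeled. Fisher's test is pairwise 2×2 only.
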