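# Methods

## Coordinate system

Regions are 0-based half-open intervals `[start, end)` (BED convention);
association records carry 1-based positions in their files and are
converted to 0-based on parse. Regions are drawn in region-file order, not
chromosome order, so the user controls narrative order. The canvas map
divides `1 − gap·(n−1)` canvas units among `n` regions proportionally to
genomic width, giving one shared bp-per-unit factor; the construction makes
the scale equality exact up to floating-point rounding, and the test suite
bounds the relative deviation below 1e-9 (measured ~1e-13). The final
segment edge is pinned to exactly 1.0 to absorb accumulated summation
error.

Point data exactly at a region's right edge is still mapped (closed right
edge) so an index SNP at a boundary is never silently dropped. Intervals
straddling a region edge are clipped, not dropped, preserving base-pair
alignment of what remains. The default inter-region gap is 0.05 canvas
units and is fixed rather than proportional to genomic distance: the gap is
schematic, and a distance-proportional gap would destroy the shared-scale
reading of the figure. One zoom panel per figure; a zoom of a zoom is out
of scope.

## Track encodings

* **Association (SNAP-style).** Height is −log10 p scaled by the track
  y-maximum (by default the ceiling of the data maximum). LD r² to the
  index SNP is binned at edges (0.2, 0.4, 0.6, 0.8) into a five-colour
  blue→red ramp, the de-facto regional-association-plot convention; typed
  variants are circles, imputed squares; records lacking the optional
  columns fall back to a neutral colour and the typed marker. The index
  SNP is the record with r² = 1 (ties broken by largest −log10 p), drawn
  last with a diamond marker and its identifier. Recombination rate is a
  line against a secondary axis normalised to its own maximum.
* **Intensity.** Min–max normalisation into a sequential palette; when all
  values are equal (including a single record) every interval takes the
  palette midpoint — a documented degenerate rule rather than a 0/0.
* **Segmentation.** Abutting same-state segments are merged before
  drawing. States missing from the configured colour table receive
  deterministic fallback colours assigned in sorted state-name order from
  a fixed 20-colour cycle. The legend lists states actually drawn, in
  first-drawn order.
* **Arches.** Semi-ellipses between anchor midpoints. Apex height is
  `arc_height_max · score / score_max` — linear in −log10 p, with
  `score_max` overridable for cross-figure comparability — and colour is a
  sequential ramp at the same normalised score, so height strictly
  increases and darkness non-strictly increases with score (the ramp's
  luminance is monotone; quantisation to 256 levels makes ties possible).
  If every score is zero, arcs take a fixed minimum visible height.
  Interactions with an unmappable anchor are dropped and counted, never
  drawn half-way; any "one anchor in the block" filtering is the user's
  upstream choice.
* **Links.** Two anchor rectangles joined by a segment, stacked into lanes
  by greedy first-fit on x-extents sorted by (start, input order). For
  interval graphs this greedy achieves the chromatic number (maximum
  overlap depth), which the tests verify by brute force.
* **Contact heat map.** The rotated-triangle convention: bin pair (i, j)
  becomes a diamond centred at the canvas midpoint of the two bins at
  height ∝ |i − j|, colour = palette(count/count_max), zero counts in the
  background grey. A square-matrix mode is out of scope. Contact files may
  be upper-triangle or full; symmetric duplicates are summed with a
  warning at parse time, and no symmetric completion is applied.
* **Genes.** Transcript line, exon rectangles, strand arrows along introns
  wide enough to hold them, and the name left of the body (right if the
  label would leave the panel). Row packing is the same greedy first-fit,
  applied to the label + body extent, with label width estimated at 0.008
  canvas units per character.
* **Annotations.** Highlight boxes are translucent full-height rectangles
  on the bottom layer; vertical markers are dashed full-height lines with
  a label; brackets carry a centred label; free text is placed at its
  anchor. Annotations wholly outside the plotted regions are skipped with
  a logged warning.

All renderers are pure functions into glyph lists, and every x coordinate
passes through the same canvas map, which is what carries the cross-track
alignment guarantee; assembly then maps only y (track extent within panel,
panel within page), never x. Ties in any packing are broken by (start,
input order) so identical inputs always produce byte-identical glyph lists.

## Figure assembly

Tracks are stacked top-to-bottom with vertical extents proportional to
their configured heights. Track letters default to a, b, c, … across the
main panel then the zoom panel; explicit letters are preserved and
duplicates rejected. The legend is figure-global (entries deduplicated by
colour/marker/label in first-appearance order) and laid out in rows at the
bottom; an empty legend reserves no space. The zoom panel sits below the
main panel; a translucent trapezoid joins the zoom target's x-extent on
the main panel (computed through the main map, hence exact) to the zoom
panel's full width, with a highlight box over the target so the zoomed
location is always indicated on the full view. Coordinate ticks are placed
at round positions (1/2/5 × 10^k bp, chosen to give about four intervals
per region) and labelled in bp/kb/Mb auto-selected from the region span.
Pages default to 180 × 240 mm; PNG defaults to 300 dpi; both formats are
drawn from the same glyph lists through matplotlib's Agg backend, PDF as
vector output.

## Configuration and CLI

The YAML config is strict: unknown keys are errors, and the fully resolved
configuration (all defaults included) is echoed to the log, so runs are
reproducible from their logs. Parsing is strict by default — the first bad
data line aborts the run with its 1-based line number — with a
`--permissive` flag that drops bad lines with warnings instead. On any
failure, partial outputs are removed. A zoom without its own track list
reuses the main track list; a zoom without an explicit parent index is
matched to the region that contains it.

## Synthetic data generator

`trackfig.fixtures` emulates the structure of a two-locus composite, not
the biology behind it:

* Two 900-kb regions on chr3 and chr8 with synthetic coordinates (no
  genome-assembly dependence), 150 SNPs per region placed uniformly.
* A −log10 p peak of 8 at the index SNP decaying exponentially (30-kb
  length scale) over exponential background noise, capped so the index SNP
  is strictly the regional maximum; r² = exp(−d/40 kb) plus Gaussian noise
  clipped to [0, 1], exactly 1 at the index SNP; ~20 % of variants flagged
  imputed; a smooth recombination background with two hotspots per region.
* A segmentation tiling each region exactly (no gaps or overlaps) with
  states from a six-state Markov chain using ChromHMM-style labels.
* Contact counts over a 40-bin (3-kb bins) window around the index SNP,
  Poisson with mean `120·(1 + |i−j|)^−1`, a planted set of 11 intra-region
  pairs at 4× that mean plus one cross-region pair; the planted pairs are
  emitted as the significant-interactions file with uniform(3, 8) −log10 p
  scores, so every interaction anchor is a bin of the matrix.
* Ten genes with valid BED12 exon structure (first/last blocks flush with
  the transcript ends), including a forced overlapping pair to exercise
  row packing; annotations comprising a 50-kb highlight box, a bracket and
  a vertical marker at the index SNP.

Randomness uses `numpy.random.default_rng` (PCG64) seeded per stream from
the user seed, so fixture sets are byte-identical per seed and portable
across runs. What passing tests on these fixtures show is that the
*geometry and encodings* are correct; they say nothing about statistical
realism of LD structure, recombination maps or chromatin contact decay,
which the generator only caricatures as monotone decay plus noise.

## Numerical choices and problem sizes

Scale equality is asserted at relative error 1e-9, round-trips at 0.5 bp,
cross-track alignment at 1e-9 canvas units. Property suites use 200 random
region sets, 10 000 round-trip positions, 50 zooms, and 100 random packing
instances of ≤ 12 features — sizes at which the brute-force oracles are
exact and instant. Determinism of figure output is asserted structurally on
glyph lists, not on PDF bytes (PDF metadata contains timestamps).

## Known limitations

No indexed or binary inputs (tabix, BigWig, .hic, .cool), no remote URLs,
no genome-build validation or liftover, no LD computation from genotypes
(r² must be precomputed), no Hi-C normalisation (raw counts are plotted
as-is), no SVG or interactive output, single zoom panel, and label-width
estimation is font-metric-free, so extremely long gene names can reserve
more packing space than they visually need.
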