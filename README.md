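# trackfig

Multi-region, multi-scale, multi-track figures of genetic data.

Researchers integrating genome-wide association results with functional
annotation routinely need one publication-ready figure that stacks very
different data types — association p-values, ChromHMM-style chromatin
segmentations, Hi-C interactions and raw contact matrices, gene models,
manual annotations — over one or more genomic loci that may lie megabases
apart or on different chromosomes. Assembling such composites from separate
browser screenshots in an image editor is error-prone precisely where it
matters most: vertical alignment of features across tracks. `trackfig`
builds the whole figure programmatically so that every track is aligned to
the base pair, and writes it as vector PDF and raster PNG.

## The coordinate model

All regions share one horizontal canvas spanning [0, 1]. With regions
*r₁ … rₙ* of genomic widths *wᵢ* (bp) and a fixed inter-region gap *g*
(canvas units), the available width 1 − g(n − 1) is divided among regions
proportionally to *wᵢ*, so every region is drawn at the same scale

&nbsp;&nbsp;&nbsp;&nbsp;bp per canvas unit = Σᵢ wᵢ / (1 − g(n − 1)),

and a position *p* in region *i* maps to
*x = x₀ᵢ + (p − startᵢ)(x₁ᵢ − x₀ᵢ)/wᵢ*. The mapping is bijective on region
interiors (gaps map to nothing), strictly increasing, and identical for
every track — that is the whole alignment guarantee. A zoom panel is simply
a second canvas map built for a sub-region of one parent region; it has a
smaller bp-per-unit factor (magnification) and is tied back to the parent
panel by a connector trapezoid whose upper corners are the zoom target's
endpoints mapped through the *main* panel's map.

Track renderers turn typed records into backend-neutral glyphs (points,
rectangles, arcs, polygons, segments, text) with canvas x and track-local
y ∈ [0, 1]; figure assembly stacks tracks into panels, assigns track
letters a, b, c, …, collects a deduplicated figure-global legend, and only
then hands the glyphs to matplotlib. Interaction arches are semi-ellipses
whose apex height and colour intensity are linear in the interaction score
(−log10 p); contact matrices are drawn as the conventional 45°-rotated
triangle heat field; genes and link blocks are packed into rows by greedy
first-fit, which is optimal for interval graphs.

## Worked example

Generate a complete synthetic input set (two 900-kb loci on chr3 and chr8,
an association peak with an index SNP, LD decay, a segmentation, Hi-C
interactions with a binned contact matrix, genes and annotations) and plot
it:

```sh
trackfig fixtures --out demo --seed 1
trackfig plot --config demo/config.yaml --out demo
```

This writes `demo/figure.pdf` and `demo/figure.png`: six lettered main
tracks (a–f: intensity, arches, links, segmentation, association scatter,
genes) over both loci, plus a zoom panel (tracks g–i: association, contact
heat map, annotations) on the 120-kb window around the index SNP. The same
composition through the library:

```python
from trackfig.cli import parse_config, _resolve_paths
from trackfig.figure import compose_figure
from trackfig.layout import parse_region_file

cfg = parse_config("demo/config.yaml"); _resolve_paths(cfg)
rs = parse_region_file(cfg.region_file.read_text())
c = compose_figure(cfg.figure, rs)
print(f"bp/unit main {c.main.cmap.bp_per_unit:.1f} zoom {c.zoom.cmap.bp_per_unit:.1f}")
print("letters", c.main.letters, c.zoom.letters)
print("connector", c.connector)
```

prints

```
bp/unit main 1894736.8 zoom 120000.0
letters ['a', 'b', 'c', 'd', 'e', 'f'] ['g', 'h', 'i']
connector (0.7308333333333333, 0.7941666666666667, 0.0, 1.0)
```

— both 900-kb regions drawn at 1.89 Mb per canvas unit (the shared scale),
the zoom magnified ~16×, and the connector anchored at the zoom target's
exact main-panel coordinates.

`trackfig fixtures` also accepts `--preset fig1` (intensity + links +
segmentation + association with a zoomed association/segmentation pair) and
`--preset fig2` (arches + annotations over a zoomed raw contact heat map).

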