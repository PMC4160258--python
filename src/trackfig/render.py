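"""Track renderers: typed records + a CanvasMap -> backend-neutral glyphs.

Each renderer is a pure function.  It receives parsed records, the canvas
map of the panel it draws into, and a :class:`TrackSpec`, and returns a
:class:`RenderedTrack` holding a flat glyph list (canvas x in [0, 1],
track-local y in [0, 1]), the track's legend entries, and its axis ranges.
Because every renderer places x through ``CanvasMap.genome_to_canvas``, a
genomic position shown in two different tracks lands on the same canvas x —
the cross-track base-pair alignment guarantee.

Glyph lists are deterministic: identical records and spec produce identical
output, with packing ties broken by (start, input order).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from matplotlib import colormaps
from matplotlib.colors import to_hex

from .io import (
    AssociationRecord,
    ContactBinRecord,
    FeatureAnnotation,
    GeneModel,
    IntensityRecord,
    InteractionRecord,
    SegmentationRecord,
)
from .layout import CanvasMap, GenomicInterval, clip_to_regions

log = logging.getLogger(__name__)

__all__ = [
    "Style",
    "Glyph",
    "TrackSpec",
    "LegendEntry",
    "RenderedTrack",
    "render_association",
    "render_intensity",
    "render_segmentation",
    "render_arcs",
    "render_links",
    "render_heatmap",
    "render_genes",
    "render_annotations",
    "render_track",
    "TRACK_TYPES",
]

TRACK_TYPES = (
    "association",
    "intensity",
    "segmentation",
    "arcs",
    "links",
    "heatmap",
    "genes",
    "annotations",
)

# SNAP-convention 5-colour blue->red ramp for LD r² bins
R2_BIN_EDGES = (0.2, 0.4, 0.6, 0.8)
R2_COLORS = ("#2c7bb6", "#abd9e9", "#ffffbf", "#fdae61", "#d7191c")
NEUTRAL_COLOR = "#808080"
INDEX_SNP_COLOR = "#7b2d8b"
RECOMB_COLOR = "#4dc3ff"
BACKGROUND_COLOR = "#f2f2f2"
HIGHLIGHT_COLOR = "#ffd700"

# estimated width of one character in canvas units, used only to reserve
# horizontal space for labels during row packing
CHAR_WIDTH = 0.008

# deterministic fallback cycle for segmentation states missing a colour
FALLBACK_CYCLE = tuple(to_hex(colormaps["tab20"](i / 19)) for i in range(20))


@dataclass(frozen=True)
class Style:
    """Visual attributes of one glyph; hex colours for determinism."""

    color: str = "#000000"
    fill: Optional[str] = None
    linewidth: float = 1.0
    marker: Optional[str] = None
    fontsize: float = 6.0
    alpha: float = 1.0
    linestyle: str = "solid"


@dataclass(frozen=True)
class Glyph:
    """One drawing primitive in canvas coordinates.

    ``shape`` is one of point, rect, arc, polygon, segment, text.  For a
    rect, x and y are (x0, x1)/(y0, y1); for an arc, x holds the two base
    endpoints and y = (baseline, apex); for text, ``text`` carries the
    string and ``anchor`` the horizontal alignment.
    """

    shape: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    style: Style = Style()
    layer: int = 1
    text: Optional[str] = None
    anchor: str = "center"


@dataclass(frozen=True)
class LegendEntry:
    color: str
    label: str
    marker: Optional[str] = None


@dataclass
class TrackSpec:
    """Per-track parameters (the offline twin of one web-menu panel)."""

    track_type: str
    path: Optional[str] = None
    height: float = 1.0
    letter: Optional[str] = None
    y_label: Optional[str] = None
    palette: str = "Reds"
    # association
    r2_bin_edges: tuple[float, ...] = R2_BIN_EDGES
    r2_colors: tuple[str, ...] = R2_COLORS
    y_max: Optional[float] = None
    # intensity / heatmap normalisation overrides
    vmin: Optional[float] = None
    vmax: Optional[float] = None
    # segmentation
    state_colors: dict = field(default_factory=dict)
    # arcs / links
    arc_height_max: float = 1.0
    min_arc_height: float = 0.05
    score_max: Optional[float] = None
    # heatmap
    bin_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.track_type not in TRACK_TYPES:
            raise ValueError(
                f"unknown track type {self.track_type!r}; expected one of {TRACK_TYPES}"
            )
        if self.height <= 0:
            raise ValueError("track height must be positive")
        if not 0 < self.arc_height_max <= 1:
            raise ValueError("arc_height_max must be in (0, 1]")


@dataclass
class RenderedTrack:
    """A track's glyphs plus its legend and axis metadata."""

    spec: TrackSpec
    glyphs: list[Glyph]
    legend: list[LegendEntry] = field(default_factory=list)
    y_range: Optional[tuple[float, float]] = None
    y_label: Optional[str] = None
    y2_range: Optional[tuple[float, float]] = None
    y2_label: Optional[str] = None
    meta: dict = field(default_factory=dict)


def _palette_hex(name: str, v: float) -> str:
    return to_hex(colormaps[name](min(max(v, 0.0), 1.0)))


def _r2_bin(r2: float, edges: Sequence[float]) -> int:
    """Index of the half-open bin [edge_{k-1}, edge_k) that r2 falls in."""
    for k, e in enumerate(edges):
        if r2 < e:
            return k
    return len(edges)


# --------------------------------------------------------------------------


def render_association(
    recs: Sequence[AssociationRecord], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Regional association (SNAP-style) scatter.

    Point height is -log10 p scaled to [0, 1] by the track y-max; marker
    distinguishes typed from imputed variants; colour encodes the LD r² bin
    to the index SNP; the index SNP itself (r² == 1) is drawn last with a
    distinct marker and its identifier; the recombination rate, when
    present, is a line against a secondary axis.
    """
    mappable = [
        (r, x) for r in recs if (x := m.genome_to_canvas(r.chrom, r.pos)) is not None
    ]
    dropped = len(recs) - len(mappable)
    if dropped:
        log.info("association: %d records outside plotted regions dropped", dropped)

    heights = [r.neg_log10_p for r, _ in mappable]
    y_max = spec.y_max if spec.y_max is not None else max(
        [math.ceil(h) for h in heights] + [1.0]
    )
    any_r2 = any(r.r2 is not None for r, _ in mappable)
    any_typed_flag = any(r.typed is not None for r, _ in mappable)

    index = None
    best = -1.0
    for r, x in mappable:
        if r.r2 is not None and r.r2 >= 1.0 and r.neg_log10_p > best:
            index, best = (r, x), r.neg_log10_p

    glyphs: list[Glyph] = []
    for r, x in mappable:
        if index is not None and r is index[0]:
            continue
        if any_r2 and r.r2 is not None:
            color = spec.r2_colors[_r2_bin(r.r2, spec.r2_bin_edges)]
        else:
            color = NEUTRAL_COLOR
        marker = "o" if (r.typed is None or r.typed) else "s"
        glyphs.append(
            Glyph(
                "point",
                (x,),
                (min(r.neg_log10_p / y_max, 1.0),),
                Style(color=color, fill=color, marker=marker, linewidth=0.3),
                layer=2,
            )
        )

    # recombination-rate overlay on the secondary axis
    recomb_pts = sorted(
        ((x, r.recomb) for r, x in mappable if r.recomb is not None),
        key=lambda t: t[0],
    )
    y2_range = None
    if recomb_pts:
        r_max = max(v for _, v in recomb_pts) or 1.0
        y2_range = (0.0, r_max)
        style = Style(color=RECOMB_COLOR, linewidth=0.8)
        for (xa, va), (xb, vb) in zip(recomb_pts, recomb_pts[1:]):
            glyphs.append(
                Glyph("segment", (xa, xb), (va / r_max, vb / r_max), style, layer=1)
            )

    if index is not None:
        r, x = index
        glyphs.append(
            Glyph(
                "point",
                (x,),
                (min(r.neg_log10_p / y_max, 1.0),),
                Style(color=INDEX_SNP_COLOR, fill=INDEX_SNP_COLOR, marker="D",
                      linewidth=0.3),
                layer=3,
            )
        )
        if r.id:
            glyphs.append(
                Glyph(
                    "text",
                    (x,),
                    (min(r.neg_log10_p / y_max + 0.06, 1.0),),
                    Style(color="#000000", fontsize=6.0),
                    layer=3,
                    text=r.id,
                )
            )

    legend: list[LegendEntry] = []
    if any_r2:
        edges = spec.r2_bin_edges
        labels = [f"r² < {edges[0]:g}"]
        labels += [f"{a:g} ≤ r² < {b:g}" for a, b in zip(edges, edges[1:])]
        labels += [f"r² ≥ {edges[-1]:g}"]
        legend += [
            LegendEntry(c, lab, marker="o") for c, lab in zip(spec.r2_colors, labels)
        ]
        legend.append(LegendEntry(INDEX_SNP_COLOR, "index SNP", marker="D"))
    if any_typed_flag:
        legend.append(LegendEntry("#000000", "typed SNP", marker="o"))
        legend.append(LegendEntry("#000000", "imputed SNP", marker="s"))
    if recomb_pts:
        legend.append(LegendEntry(RECOMB_COLOR, "recombination rate (cM/Mb)"))

    return RenderedTrack(
        spec,
        glyphs,
        legend,
        y_range=(0.0, float(y_max)),
        y_label=spec.y_label or "-log10 p",
        y2_range=y2_range,
        y2_label="recombination rate (cM/Mb)" if recomb_pts else None,
        meta={"dropped": dropped},
    )


def render_intensity(
    recs: Sequence[IntensityRecord], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Full-height rectangles coloured by min-max-normalised value.

    If all values are equal (including a single record), every interval
    takes the palette midpoint.
    """
    vals = [r.value for r in recs]
    vmin = spec.vmin if spec.vmin is not None else (min(vals) if vals else 0.0)
    vmax = spec.vmax if spec.vmax is not None else (max(vals) if vals else 1.0)
    degenerate = vmax == vmin
    glyphs: list[Glyph] = []
    for r in recs:
        frac = 0.5 if degenerate else (r.value - vmin) / (vmax - vmin)
        color = _palette_hex(spec.palette, frac)
        for piece in clip_to_regions(m.regions, r.interval):
            x0 = m.genome_to_canvas(piece.chrom, piece.start)
            x1 = m.genome_to_canvas(piece.chrom, piece.end)
            glyphs.append(
                Glyph("rect", (x0, x1), (0.0, 1.0), Style(color=color, fill=color,
                                                          linewidth=0.0))
            )
    label = spec.y_label or "intensity"
    legend = [
        LegendEntry(_palette_hex(spec.palette, 1.0), f"{label} ({vmin:g}–{vmax:g})",
                    marker="s")
    ] if recs else []
    return RenderedTrack(spec, glyphs, legend, y_label=label)


def _merge_abutting(recs: Sequence[SegmentationRecord]) -> list[SegmentationRecord]:
    out: list[SegmentationRecord] = []
    for r in sorted(recs, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1].chrom == r.chrom and out[-1].end == r.start \
                and out[-1].state == r.state:
            out[-1] = SegmentationRecord(r.chrom, out[-1].start, r.end, r.state)
        else:
            out.append(r)
    return out


def render_segmentation(
    recs: Sequence[SegmentationRecord], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """State-coloured rectangles; abutting same-state segments are merged.

    States absent from the configured colour table get a deterministic
    fallback colour assigned by sorted state-name order.
    """
    merged = _merge_abutting(recs)
    missing = sorted(
        {r.state for r in merged} - set(spec.state_colors), key=str
    )
    fallback = {
        s: FALLBACK_CYCLE[i % len(FALLBACK_CYCLE)] for i, s in enumerate(missing)
    }
    colors = {**fallback, **spec.state_colors}

    glyphs: list[Glyph] = []
    legend: list[LegendEntry] = []
    seen: set[str] = set()
    for r in merged:
        color = colors[r.state]
        pieces = clip_to_regions(m.regions, r.interval)
        for piece in pieces:
            x0 = m.genome_to_canvas(piece.chrom, piece.start)
            x1 = m.genome_to_canvas(piece.chrom, piece.end)
            glyphs.append(
                Glyph("rect", (x0, x1), (0.1, 0.9), Style(color=color, fill=color,
                                                          linewidth=0.0))
            )
        if pieces and r.state not in seen:
            seen.add(r.state)
            legend.append(LegendEntry(color, r.state, marker="s"))
    return RenderedTrack(spec, glyphs, legend, y_label=spec.y_label)


def render_arcs(
    recs: Sequence[InteractionRecord], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Semi-elliptical arches between anchor midpoints.

    Apex height is linear in score (arc_height_max at the track score
    maximum) and colour intensity follows the same normalised score, so
    stronger interactions are taller and darker.  Interactions with an
    unmappable anchor are dropped and counted.  If every score is zero the
    arcs are drawn at a fixed minimum visible height.
    """
    placed: list[tuple[float, float, float]] = []
    dropped = 0
    for r in recs:
        xa = m.genome_to_canvas(r.anchor1.chrom, (r.anchor1.start + r.anchor1.end) / 2)
        xb = m.genome_to_canvas(r.anchor2.chrom, (r.anchor2.start + r.anchor2.end) / 2)
        if xa is None or xb is None:
            dropped += 1
            continue
        placed.append((min(xa, xb), max(xa, xb), r.score))
    if dropped:
        log.info("arcs: %d interactions with unmappable anchors dropped", dropped)

    score_max = spec.score_max if spec.score_max is not None else max(
        (s for _, _, s in placed), default=0.0
    )
    glyphs: list[Glyph] = []
    for x0, x1, s in placed:
        if score_max > 0:
            v = s / score_max
            apex = spec.arc_height_max * v
        else:
            v = 0.0
            apex = spec.min_arc_height
        glyphs.append(
            Glyph(
                "arc",
                (x0, x1),
                (0.0, max(apex, 0.0)),
                Style(color=_palette_hex(spec.palette, v), linewidth=0.9),
            )
        )
    legend = [
        LegendEntry(_palette_hex(spec.palette, 1.0),
                    spec.y_label or "interaction strength (-log10 p)")
    ] if placed else []
    return RenderedTrack(
        spec, glyphs, legend,
        y_range=(0.0, score_max if score_max > 0 else 1.0),
        y_label=spec.y_label, meta={"dropped": dropped},
    )


def _greedy_lanes(extents: Sequence[tuple[float, float]]) -> list[int]:
    """First-fit lane assignment on x-extents sorted by (start, input order).

    Returns the lane index per input extent; two extents in one lane never
    overlap.
    """
    order = sorted(range(len(extents)), key=lambda i: (extents[i][0], i))
    lane_end: list[float] = []
    lanes = [0] * len(extents)
    for i in order:
        x0, x1 = extents[i]
        for lane, end in enumerate(lane_end):
            if x0 >= end:
                lanes[i] = lane
                lane_end[lane] = x1
                break
        else:
            lanes[i] = len(lane_end)
            lane_end.append(x1)
    return lanes


def render_links(
    recs: Sequence[InteractionRecord], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Block-style interaction track: two anchor rectangles joined by a
    horizontal segment, stacked into greedy first-fit lanes so overlapping
    links never share a lane."""
    placed: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    dropped = 0
    for r in recs:
        spans = []
        for anchor in (r.anchor1, r.anchor2):
            pieces = clip_to_regions(m.regions, anchor)
            if not pieces:
                break
            x0 = min(m.genome_to_canvas(p.chrom, p.start) for p in pieces)
            x1 = max(m.genome_to_canvas(p.chrom, p.end) for p in pieces)
            spans.append((x0, x1))
        if len(spans) < 2:
            dropped += 1
            continue
        spans.sort()
        placed.append((spans[0], spans[1], r.score))
    if dropped:
        log.info("links: %d interactions with unmappable anchors dropped", dropped)

    extents = [(a[0], max(a[1], b[1])) for a, b, _ in placed]
    lanes = _greedy_lanes(extents)
    n_lanes = max(lanes, default=-1) + 1
    glyphs: list[Glyph] = []
    for (a, b, score), lane in zip(placed, lanes):
        yc = 1.0 - (lane + 0.5) / max(n_lanes, 1)
        h = 0.3 / max(n_lanes, 1)
        style = Style(color="#b2182b", fill="#b2182b", linewidth=0.0)
        for x0, x1 in (a, b):
            glyphs.append(Glyph("rect", (x0, x1), (yc - h, yc + h), style))
        if b[0] > a[1]:
            glyphs.append(
                Glyph("segment", (a[1], b[0]), (yc, yc),
                      Style(color="#b2182b", linewidth=0.7))
            )
    return RenderedTrack(
        spec, glyphs,
        [LegendEntry("#b2182b", spec.y_label or "significant interaction",
                     marker="s")] if placed else [],
        meta={"lanes": n_lanes, "dropped": dropped},
    )


def render_heatmap(
    recs: Sequence[ContactBinRecord], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Rotated-triangle contact heat field.

    Each bin pair becomes a diamond centred at the canvas midpoint of its two
    bins, at a height proportional to the genomic separation |i - j|; colour
    is the palette at count / count_max, with zero counts in the background
    colour.  Bin pairs whose midpoints fall outside the plotted regions are
    ignored.
    """
    if not recs:
        return RenderedTrack(spec, [], y_label=spec.y_label)
    bin_size = spec.bin_size or recs[0].bin_size
    half = bin_size / m.bp_per_unit / 2.0

    cells: list[tuple[float, float, float]] = []
    for r in recs:
        xi = m.genome_to_canvas(r.chrom1, r.bin1_start + bin_size / 2)
        xj = m.genome_to_canvas(r.chrom2, r.bin2_start + bin_size / 2)
        if xi is None or xj is None:
            continue
        cells.append(((xi + xj) / 2.0, abs(xj - xi) / 2.0, r.count))
    if not cells:
        return RenderedTrack(spec, [], y_label=spec.y_label)

    count_max = spec.vmax if spec.vmax is not None else max(c for _, _, c in cells)
    y_top = max(cy for _, cy, _ in cells) + half
    glyphs: list[Glyph] = []
    for cx, cy, count in cells:
        if count_max > 0 and count > 0:
            color = _palette_hex(spec.palette, count / count_max)
        else:
            color = BACKGROUND_COLOR
        xs = (cx - half, cx, cx + half, cx)
        ys = tuple((v / y_top) for v in (cy, cy - half, cy, cy + half))
        ys = tuple(min(max(v, 0.0), 1.0) for v in ys)
        glyphs.append(
            Glyph("polygon", xs, ys, Style(color=color, fill=color, linewidth=0.0))
        )
    legend = [
        LegendEntry(_palette_hex(spec.palette, 1.0),
                    f"{spec.y_label or 'contact count'} (0–{count_max:g})",
                    marker="s")
    ]
    return RenderedTrack(spec, glyphs, legend, y_label=spec.y_label,
                         meta={"count_max": count_max})


def render_genes(
    models: Sequence[GeneModel], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Gene-model glyphs packed into non-overlapping horizontal rows.

    Each gene draws a thin transcript line, tall exon rectangles, strand
    arrows along introns and its name to the left of the body (or to the
    right when that would leave the panel).  Rows are assigned greedily
    first-fit on the full (label + body) x-extent.
    """
    placed = []
    for g in models:
        body = clip_to_regions(m.regions, GenomicInterval(g.chrom, g.tx_start, g.tx_end))
        if not body:
            continue
        bx0 = min(m.genome_to_canvas(p.chrom, p.start) for p in body)
        bx1 = max(m.genome_to_canvas(p.chrom, p.end) for p in body)
        label_w = (len(g.name) + 1) * CHAR_WIDTH
        if bx0 - label_w >= 0.0:
            ext = (bx0 - label_w, bx1)
            label_x, anchor = bx0 - CHAR_WIDTH * 0.5, "right"
        else:
            ext = (bx0, bx1 + label_w)
            label_x, anchor = bx1 + CHAR_WIDTH * 0.5, "left"
        placed.append((g, body, ext, label_x, anchor))

    lanes = _greedy_lanes([ext for _, _, ext, _, _ in placed])
    n_rows = max(lanes, default=-1) + 1
    glyphs: list[Glyph] = []
    for (g, body, ext, label_x, anchor), row in zip(placed, lanes):
        yc = 1.0 - (row + 0.5) / max(n_rows, 1)
        h = 0.32 / max(n_rows, 1)
        color = "#1a468c"
        for piece in body:
            x0 = m.genome_to_canvas(piece.chrom, piece.start)
            x1 = m.genome_to_canvas(piece.chrom, piece.end)
            glyphs.append(Glyph("segment", (x0, x1), (yc, yc),
                                Style(color=color, linewidth=0.6)))
        for e0, e1 in g.exons:
            for piece in clip_to_regions(m.regions, GenomicInterval(g.chrom, e0, e1)):
                x0 = m.genome_to_canvas(piece.chrom, piece.start)
                x1 = m.genome_to_canvas(piece.chrom, piece.end)
                glyphs.append(
                    Glyph("rect", (x0, x1), (yc - h, yc + h),
                          Style(color=color, fill=color, linewidth=0.0), layer=2)
                )
        arrow = ">" if g.strand == "+" else "<"
        introns = zip(g.exons, g.exons[1:])
        for (_, ie0), (ie1, _) in introns:
            for piece in clip_to_regions(m.regions, GenomicInterval(g.chrom, ie0, max(ie1, ie0 + 1))):
                x0 = m.genome_to_canvas(piece.chrom, piece.start)
                x1 = m.genome_to_canvas(piece.chrom, piece.end)
                if x1 - x0 > 3 * CHAR_WIDTH:
                    glyphs.append(
                        Glyph("text", ((x0 + x1) / 2,), (yc,),
                              Style(color=color, fontsize=5.0), layer=2, text=arrow)
                    )
        glyphs.append(
            Glyph("text", (label_x,), (yc,), Style(color="#000000", fontsize=6.0),
                  layer=2, text=g.name, anchor=anchor)
        )
    return RenderedTrack(spec, glyphs, [], y_label=spec.y_label,
                         meta={"rows": n_rows})


def render_annotations(
    anns: Sequence[FeatureAnnotation], m: CanvasMap, spec: TrackSpec
) -> RenderedTrack:
    """Manual feature annotations: translucent highlight boxes (bottom
    layer), dashed full-height markers with labels, brackets, free text.
    Annotations wholly outside the plotted regions are skipped with a
    warning."""
    glyphs: list[Glyph] = []
    skipped = 0
    for a in anns:
        if a.kind in POINT_KINDS_RENDER:
            x = m.genome_to_canvas(a.target.chrom, a.position)
            if x is None:
                skipped += 1
                log.warning("annotation %r outside plotted regions, skipped", a.label)
                continue
            if a.kind == "vertical-marker":
                glyphs.append(
                    Glyph("segment", (x, x), (0.0, 1.0),
                          Style(color="#333333", linewidth=0.8, linestyle="dashed"),
                          layer=4)
                )
                glyphs.append(
                    Glyph("text", (x,), (0.95,), Style(color="#333333", fontsize=6.0),
                          layer=4, text=a.label)
                )
            else:  # text
                glyphs.append(
                    Glyph("text", (x,), (0.5,), Style(color="#333333", fontsize=6.0),
                          layer=4, text=a.label)
                )
            continue
        pieces = clip_to_regions(m.regions, a.target)
        if not pieces:
            skipped += 1
            log.warning("annotation %r outside plotted regions, skipped", a.label)
            continue
        for piece in pieces:
            x0 = m.genome_to_canvas(piece.chrom, piece.start)
            x1 = m.genome_to_canvas(piece.chrom, piece.end)
            if a.kind == "highlight-box":
                glyphs.append(
                    Glyph("rect", (x0, x1), (0.0, 1.0),
                          Style(color=HIGHLIGHT_COLOR, fill=HIGHLIGHT_COLOR,
                                alpha=0.3, linewidth=0.0), layer=0)
                )
            elif a.kind == "bracket":
                style = Style(color="#333333", linewidth=0.8)
                glyphs.append(Glyph("segment", (x0, x0), (0.55, 0.7), style, layer=4))
                glyphs.append(Glyph("segment", (x0, x1), (0.7, 0.7), style, layer=4))
                glyphs.append(Glyph("segment", (x1, x1), (0.55, 0.7), style, layer=4))
                glyphs.append(
                    Glyph("text", ((x0 + x1) / 2,), (0.82,),
                          Style(color="#333333", fontsize=6.0), layer=4, text=a.label)
                )
    return RenderedTrack(spec, glyphs, [], meta={"skipped": skipped})


POINT_KINDS_RENDER = ("vertical-marker", "text")

_RENDERERS = {
    "association": render_association,
    "intensity": render_intensity,
    "segmentation": render_segmentation,
    "arcs": render_arcs,
    "links": render_links,
    "heatmap": render_heatmap,
    "genes": render_genes,
    "annotations": render_annotations,
}


def render_track(recs, m: CanvasMap, spec: TrackSpec) -> RenderedTrack:
    """Dispatch to the renderer selected by ``spec.track_type``."""
    return _RENDERERS[spec.track_type](recs, m, spec)
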