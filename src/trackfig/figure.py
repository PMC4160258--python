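"""Figure assembly: stack rendered tracks, attach the zoom panel, compose
title / track letters / axes / legend, and emit PDF and PNG.

The composition stage works entirely in abstract coordinates: every track's
glyph y values (track-local [0, 1]) are affinely mapped into the track's
vertical extent within its panel, and panels into the page.  The mapping
never touches glyph x, which is what carries the cross-track base-pair
alignment guarantee through to the page.

The zoom panel sits below the main panel, joined by a translucent trapezoid
from the zoom target's x-extent on the main panel to the zoom panel's full
width, plus a highlight box over the target — so the location of the zoomed
sub-region is always indicated on the full view.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.patches import Polygon as MplPolygon, Rectangle as MplRectangle

import numpy as np

from . import io as tio
from .layout import CanvasMap, RegionSet, ZoomSpec, build_canvas_map, build_zoom_map
from .render import (
    Glyph,
    LegendEntry,
    RenderedTrack,
    Style,
    TrackSpec,
    render_track,
)

log = logging.getLogger(__name__)

__all__ = [
    "FigureSpec",
    "Panel",
    "ComposedFigure",
    "FigureError",
    "stack_tracks",
    "assign_letters",
    "collect_legend",
    "build_legend",
    "attach_zoom",
    "compose_figure",
    "render_figure",
    "region_ticks",
    "load_track_data",
]

VALID_FORMATS = ("pdf", "png")
HIGHLIGHT_COLOR = "#ffd700"
CONNECTOR_COLOR = "#c0c0c0"


class FigureError(ValueError):
    """Invalid figure specification or composition."""


@dataclass
class FigureSpec:
    """Whole-figure parameters."""

    tracks: list[TrackSpec]
    title: str = ""
    zoom: Optional[ZoomSpec] = None
    zoom_tracks: list[TrackSpec] = field(default_factory=list)
    page_size_mm: tuple[float, float] = (180.0, 240.0)
    formats: tuple[str, ...] = ("pdf", "png")
    dpi: int = 300
    gap: float = 0.05

    def validate(self) -> None:
        if not self.tracks:
            raise FigureError("a figure needs at least one main track")
        if self.zoom_tracks and self.zoom is None:
            raise FigureError("zoom_tracks given without a zoom target")
        for f in self.formats:
            if f not in VALID_FORMATS:
                raise FigureError(f"unknown output format {f!r}; expected {VALID_FORMATS}")


@dataclass
class Panel:
    """A stack of rendered tracks sharing one canvas map.

    ``extents[i]`` is track i's (y_bottom, y_top) within the panel's [0, 1]
    vertical span, top-to-bottom in list order; extents partition the span.
    """

    cmap: Optional[CanvasMap]
    tracks: list[RenderedTrack]
    extents: list[tuple[float, float]]
    letters: list[Optional[str]] = field(default_factory=list)


@dataclass
class ComposedFigure:
    spec: FigureSpec
    main: Panel
    zoom: Optional[Panel] = None
    connector: Optional[tuple[float, float, float, float]] = None
    legend: list[LegendEntry] = field(default_factory=list)

    def all_glyphs(self) -> list[Glyph]:
        out: list[Glyph] = []
        for p in (self.main, self.zoom):
            if p is not None:
                for t in p.tracks:
                    out.extend(t.glyphs)
        return out


def stack_tracks(rendered: Sequence[RenderedTrack]) -> Panel:
    """Allocate vertical extents proportional to each track's height, in
    list order from the top of the panel."""
    heights = [t.spec.height for t in rendered]
    if any(h <= 0 for h in heights):
        raise FigureError("track heights must be positive")
    total = sum(heights)
    extents: list[tuple[float, float]] = []
    top = 1.0
    for h in heights:
        frac = h / total
        extents.append((top - frac, top))
        top -= frac
    if extents:
        _, hi = extents[-1]
        extents[-1] = (0.0, hi)
    return Panel(None, list(rendered), extents)


def assign_letters(panels: Sequence[Panel]) -> None:
    """Assign track letters a, b, c, ... across main then zoom panel.

    Explicit letters from the TrackSpec are preserved; duplicates raise.
    """
    auto = iter(string.ascii_lowercase)
    used: set[str] = set()
    explicit = [
        t.spec.letter for p in panels for t in p.tracks if t.spec.letter is not None
    ]
    for letter in explicit:
        if letter in used:
            raise FigureError(f"duplicate track letter {letter!r}")
        used.add(letter)
    for p in panels:
        p.letters = []
        for t in p.tracks:
            if t.spec.letter is not None:
                p.letters.append(t.spec.letter)
            else:
                nxt = next(a for a in auto if a not in used)
                used.add(nxt)
                p.letters.append(nxt)


def collect_legend(panels: Sequence[Panel]) -> list[LegendEntry]:
    """Figure-global legend: entries deduplicated by (colour, marker, label)
    in first-appearance order across tracks."""
    seen: set[tuple] = set()
    out: list[LegendEntry] = []
    for p in panels:
        for t in p.tracks:
            for e in t.legend:
                key = (e.color, e.marker, e.label)
                if key not in seen:
                    seen.add(key)
                    out.append(e)
    return out


def build_legend(entries: Sequence[LegendEntry], max_per_row: int = 3) -> list[Glyph]:
    """Lay the legend out in rows (legend-local [0, 1] coordinates); an
    empty entry list produces no glyphs and reserves no space."""
    if not entries:
        return []
    n_rows = math.ceil(len(entries) / max_per_row)
    glyphs: list[Glyph] = []
    for i, e in enumerate(entries):
        row, col = divmod(i, max_per_row)
        x0 = col / max_per_row
        yc = 1.0 - (row + 0.5) / n_rows
        if e.marker is not None:
            glyphs.append(
                Glyph("point", (x0 + 0.012,), (yc,),
                      Style(color=e.color, fill=e.color, marker=e.marker))
            )
        else:
            glyphs.append(
                Glyph("segment", (x0 + 0.002, x0 + 0.022), (yc, yc),
                      Style(color=e.color, linewidth=1.2))
            )
        glyphs.append(
            Glyph("text", (x0 + 0.03,), (yc,), Style(fontsize=6.0), text=e.label,
                  anchor="left")
        )
    return glyphs


def attach_zoom(
    main: Panel, zoom: Panel, connector: tuple[float, float, float, float]
) -> tuple[Panel, Panel, tuple[float, float, float, float]]:
    """Validate and bundle the main/zoom panel pair with its connector.

    The connector's main-panel anchors must coincide with the zoom target's
    mapped endpoints, which :func:`trackfig.layout.build_zoom_map`
    guarantees by construction.
    """
    xl, xr, zl, zr = connector
    if not (0.0 <= xl < xr <= 1.0) or (zl, zr) != (0.0, 1.0):
        raise FigureError(f"malformed zoom connector {connector}")
    return main, zoom, connector


# --------------------------------------------------------------------------
# axis ticks


def _nice_step(span: float, target_ticks: int = 4) -> float:
    """Largest 1/2/5 x 10^k step giving at least ``target_ticks`` intervals."""
    raw = span / target_ticks
    k = math.floor(math.log10(raw)) if raw > 0 else 0
    for mult in (5, 2, 1):
        step = mult * 10 ** k
        if step <= raw:
            return step
    return 10 ** (k - 1) * 5


def _format_pos(pos: float, unit: str) -> str:
    if unit == "Mb":
        return f"{pos / 1e6:g}"
    if unit == "kb":
        return f"{pos / 1e3:g}"
    return f"{pos:g}"


def region_ticks(cmap: CanvasMap) -> list[tuple[float, str, str]]:
    """Coordinate ticks at round genomic positions (1/2/5 x 10^k bp).

    Returns (canvas_x, label, unit) triples covering every region; the axis
    unit auto-selects bp / kb / Mb from the region span.
    """
    ticks: list[tuple[float, str, str]] = []
    for r, (x0, x1) in zip(cmap.regions, cmap.segments):
        span = r.width
        unit = "Mb" if span >= 1_000_000 else ("kb" if span >= 1_000 else "bp")
        step = _nice_step(span)
        first = math.ceil(r.start / step) * step
        pos = first
        while pos <= r.end:
            x = cmap.genome_to_canvas(r.chrom, pos)
            if x is not None:
                ticks.append((x, _format_pos(pos, unit), unit))
            pos += step
    return ticks


# --------------------------------------------------------------------------
# data loading and full composition


def load_track_data(spec: TrackSpec, permissive: bool = False):
    """Read the track's data file with the parser its type requires."""
    if spec.path is None:
        raise FigureError(f"track of type {spec.track_type!r} has no data path")
    readers = {
        "association": tio.read_association,
        "intensity": tio.read_intensity,
        "segmentation": tio.read_segmentation,
        "arcs": tio.read_interactions,
        "links": tio.read_interactions,
        "genes": tio.read_genes,
        "annotations": tio.read_annotations,
    }
    if spec.track_type == "heatmap":
        if spec.bin_size is None:
            raise FigureError("heatmap track requires bin_size")
        return tio.read_contacts(spec.path, spec.bin_size, permissive)
    return readers[spec.track_type](spec.path, permissive)


def _build_panel(cmap: CanvasMap, specs: Sequence[TrackSpec],
                 permissive: bool) -> Panel:
    rendered = []
    for ts in specs:
        recs = load_track_data(ts, permissive)
        rt = render_track(recs, cmap, ts)
        log.info("track %-12s: %d records -> %d glyphs",
                 ts.track_type, len(recs), len(rt.glyphs))
        rendered.append(rt)
    panel = stack_tracks(rendered)
    panel.cmap = cmap
    return panel


def compose_figure(
    spec: FigureSpec, rs: RegionSet, permissive: bool = False
) -> ComposedFigure:
    """Run the full composition pipeline: canvas map, per-track rendering,
    stacking, zoom panel, letters and figure-global legend."""
    spec.validate()
    cmap = build_canvas_map(rs, gap=spec.gap)
    main = _build_panel(cmap, spec.tracks, permissive)

    zoom_panel = None
    connector = None
    if spec.zoom is not None:
        if spec.zoom.parent_index < 0:
            # infer the containing region
            parent = next(
                (
                    i for i, r in enumerate(rs)
                    if r.chrom == spec.zoom.target.chrom
                    and r.start <= spec.zoom.target.start
                    and spec.zoom.target.end <= r.end
                ),
                None,
            )
            if parent is None:
                raise FigureError("zoom target is not inside any plotted region")
            spec.zoom = ZoomSpec(spec.zoom.target, parent)
        zoom_map, connector = build_zoom_map(cmap, rs, spec.zoom)
        zspecs = spec.zoom_tracks or spec.tracks
        zoom_panel = _build_panel(zoom_map, zspecs, permissive)
        main, zoom_panel, connector = attach_zoom(main, zoom_panel, connector)

    panels = [main] + ([zoom_panel] if zoom_panel else [])
    assign_letters(panels)
    legend = collect_legend(panels)
    return ComposedFigure(spec, main, zoom_panel, connector, legend)


# --------------------------------------------------------------------------
# matplotlib backend


MM_PER_INCH = 25.4

# page margins in figure fraction
_LEFT, _RIGHT = 0.06, 0.97
_TOP = 0.93


def _glyph_artists(ax, g: Glyph, to_fig_x, to_fig_y):
    """Draw one glyph onto ``ax`` (figure-fraction coordinates)."""
    s = g.style
    if g.shape == "point":
        ax.plot(
            [to_fig_x(g.x[0])], [to_fig_y(g.y[0])],
            marker=s.marker or "o", markersize=3.0,
            markerfacecolor=s.fill or s.color, markeredgecolor=s.color,
            markeredgewidth=s.linewidth, linestyle="none", alpha=s.alpha,
            zorder=g.layer + 2,
        )
    elif g.shape == "rect":
        x0, x1 = (to_fig_x(v) for v in g.x)
        y0, y1 = (to_fig_y(v) for v in g.y)
        ax.add_patch(
            MplRectangle((x0, y0), x1 - x0, y1 - y0,
                         facecolor=s.fill or "none",
                         edgecolor=s.color if s.linewidth > 0 else "none",
                         linewidth=s.linewidth, alpha=s.alpha, zorder=g.layer + 2)
        )
    elif g.shape == "arc":
        x0, x1 = g.x
        base, apex = g.y
        t = np.linspace(0.0, np.pi, 64)
        xs = (x0 + x1) / 2 + (x1 - x0) / 2 * np.cos(t)
        ys = base + (apex - base) * np.sin(t)
        ax.plot([to_fig_x(v) for v in xs], [to_fig_y(v) for v in ys],
                color=s.color, linewidth=s.linewidth, alpha=s.alpha,
                zorder=g.layer + 2)
    elif g.shape == "polygon":
        pts = [(to_fig_x(x), to_fig_y(y)) for x, y in zip(g.x, g.y)]
        ax.add_patch(
            MplPolygon(pts, closed=True, facecolor=s.fill or "none",
                       edgecolor=s.color if s.linewidth > 0 else "none",
                       linewidth=s.linewidth, alpha=s.alpha, zorder=g.layer + 2)
        )
    elif g.shape == "segment":
        ax.plot([to_fig_x(v) for v in g.x], [to_fig_y(v) for v in g.y],
                color=s.color, linewidth=s.linewidth, alpha=s.alpha,
                linestyle="--" if s.linestyle == "dashed" else "-",
                zorder=g.layer + 2)
    elif g.shape == "text":
        ha = {"left": "left", "right": "right", "center": "center"}[g.anchor]
        ax.text(to_fig_x(g.x[0]), to_fig_y(g.y[0]), g.text or "",
                fontsize=s.fontsize, color=s.color, ha=ha, va="center",
                alpha=s.alpha, zorder=g.layer + 2)
    else:  # pragma: no cover - closed vocabulary enforced upstream
        raise FigureError(f"unknown glyph shape {g.shape!r}")


def _draw_panel(ax, panel: Panel, rect: tuple[float, float, float, float]) -> None:
    """Draw a panel into the figure-fraction rect (x0, y0, width, height)."""
    px, py, pw, ph = rect

    def fx(x: float) -> float:
        return px + x * pw

    # panel backgrounds per region segment
    for x0, x1 in panel.cmap.segments:
        ax.add_patch(
            MplRectangle((fx(x0), py), (x1 - x0) * pw, ph, facecolor="white",
                         edgecolor="#bbbbbb", linewidth=0.4, zorder=0)
        )
    for (rt, (ey0, ey1)), letter in zip(
        zip(panel.tracks, panel.extents), panel.letters or [None] * len(panel.tracks)
    ):
        def fy(y: float, ey0=ey0, ey1=ey1) -> float:
            return py + (ey0 + y * (ey1 - ey0)) * ph

        for g in sorted(rt.glyphs, key=lambda g: g.layer):
            _glyph_artists(ax, g, fx, fy)
        if letter:
            ax.text(px - 0.03, py + ey1 * ph, letter, fontsize=9,
                    fontweight="bold", ha="left", va="top", zorder=10)
        if rt.y_label:
            ax.text(px - 0.012, py + (ey0 + ey1) / 2 * ph, rt.y_label,
                    fontsize=5, rotation=90, ha="center", va="center", zorder=10)

    # coordinate ticks under the panel
    for x, label, _unit in region_ticks(panel.cmap):
        ax.plot([fx(x), fx(x)], [py - 0.004, py], color="black", linewidth=0.5,
                zorder=5)
        ax.text(fx(x), py - 0.008, label, fontsize=4.5, ha="center", va="top",
                zorder=5)
    # region labels above
    for (x0, x1), r, lab in zip(panel.cmap.segments, panel.cmap.regions,
                                panel.cmap.regions.labels):
        unit = "Mb" if r.width >= 1_000_000 else ("kb" if r.width >= 1_000 else "bp")
        title = lab or f"{r.chrom} ({unit})"
        ax.text(fx((x0 + x1) / 2), py + ph + 0.004, title, fontsize=6,
                ha="center", va="bottom", zorder=5)


def render_figure(
    composed: ComposedFigure, out_dir: str | Path, stem: str = "figure"
) -> list[Path]:
    """Write the composed figure to every requested format.

    PDF output is vector; PNG is rasterised at the configured dpi.  Both
    derive from the same glyph lists.  Returns the written paths.
    """
    spec = composed.spec
    if not spec.formats:
        raise FigureError("no output format requested")
    for f in spec.formats:
        if f not in VALID_FORMATS:
            raise FigureError(f"unknown output format {f!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    w_in = spec.page_size_mm[0] / MM_PER_INCH
    h_in = spec.page_size_mm[1] / MM_PER_INCH
    fig = plt.figure(figsize=(w_in, h_in))
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")

    legend_h = 0.06 if composed.legend else 0.0
    bottom = 0.05 + legend_h
    avail = _TOP - bottom
    if composed.zoom is not None:
        main_rect = (_LEFT, bottom + 0.45 * avail + 0.07 * avail,
                     _RIGHT - _LEFT, 0.48 * avail)
        zoom_rect = (_LEFT, bottom, _RIGHT - _LEFT, 0.45 * avail)
    else:
        main_rect = (_LEFT, bottom, _RIGHT - _LEFT, avail)
        zoom_rect = None

    _draw_panel(ax, composed.main, main_rect)
    if composed.zoom is not None and zoom_rect is not None:
        _draw_panel(ax, composed.zoom, zoom_rect)
        xl, xr, zl, zr = composed.connector
        mx, my, mw, mh = main_rect
        zx, zy, zw, zh = zoom_rect
        # highlight the target on the full view
        ax.add_patch(
            MplRectangle((mx + xl * mw, my), (xr - xl) * mw, mh,
                         facecolor=HIGHLIGHT_COLOR, edgecolor=CONNECTOR_COLOR,
                         linewidth=0.5, alpha=0.25, zorder=9)
        )
        ax.add_patch(
            MplPolygon(
                [
                    (mx + xl * mw, my),
                    (mx + xr * mw, my),
                    (zx + zr * zw, zy + zh),
                    (zx + zl * zw, zy + zh),
                ],
                closed=True, facecolor=CONNECTOR_COLOR, edgecolor="none",
                alpha=0.3, zorder=1,
            )
        )
    if composed.legend:
        lg = build_legend(composed.legend)
        lx, ly, lw, lh = _LEFT, 0.02, _RIGHT - _LEFT, legend_h
        for g in lg:
            _glyph_artists(ax, g, lambda x: lx + x * lw, lambda y: ly + y * lh)
    if spec.title:
        fig.suptitle(spec.title, fontsize=11, y=0.975)

    paths: list[Path] = []
    for fmt in spec.formats:
        path = out_dir / f"{stem}.{fmt}"
        fig.savefig(path, format=fmt, dpi=spec.dpi)
        paths.append(path)
    plt.close(fig)
    return paths
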