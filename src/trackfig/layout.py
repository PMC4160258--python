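"""Genome <-> canvas coordinate machinery.

A figure draws one or more genomic regions — possibly megabases apart or on
different chromosomes — side by side on a shared horizontal canvas spanning
``[0, 1]``.  The defining guarantee is *scale equality*: every region is drawn
at exactly the same number of base pairs per canvas unit, so horizontal
distances are comparable across regions and across tracks.  A zoom panel maps
a sub-region onto its own ``[0, 1]`` canvas at a magnified (smaller bp per
unit) scale, linked back to the parent panel by a connector trapezoid.

All intervals are 0-based half-open ``[start, end)`` (BED convention).
Single-base positions equal to a region's ``end`` are still mapped (closed
right edge for point data) so index SNPs sitting exactly on a boundary are
never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "ZoomSpec",
    "CanvasMap",
    "LayoutError",
    "RegionFileError",
    "parse_region_file",
    "build_canvas_map",
    "clip_to_regions",
    "build_zoom_map",
]

#: Relative tolerance of the cross-region scale-equality guarantee.
SCALE_RTOL = 1e-9


class LayoutError(ValueError):
    """Invalid region geometry or canvas-map parameters."""


class RegionFileError(LayoutError):
    """Malformed region file; message carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise LayoutError("chromosome name must be non-empty")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise LayoutError("interval coordinates must be integers")
        if self.start >= self.end:
            raise LayoutError(
                f"interval start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership with a closed right edge (point data at ``end`` counts)."""
        return chrom == self.chrom and self.start <= pos <= self.end

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if self.chrom != other.chrom:
            return None
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if lo >= hi:
            return None
        return GenomicInterval(self.chrom, lo, hi)


@dataclass(frozen=True)
class RegionSet:
    """Ordered list of plotted regions; list order is left-to-right plot order."""

    regions: tuple[GenomicInterval, ...]
    labels: tuple[Optional[str], ...] = ()

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        labels = tuple(self.labels) if self.labels else (None,) * len(regions)
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "labels", labels)
        if not regions:
            raise LayoutError("a RegionSet needs at least one region")
        if len(labels) != len(regions):
            raise LayoutError("labels must match regions in length")
        for i, a in enumerate(regions):
            for b in regions[i + 1 :]:
                if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                    raise LayoutError(
                        f"regions {a.chrom}:{a.start}-{a.end} and "
                        f"{b.chrom}:{b.start}-{b.end} overlap"
                    )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def total_bp(self) -> int:
        return sum(r.width for r in self.regions)

    def find(self, chrom: str, pos: int) -> Optional[int]:
        """Index of the first region containing (chrom, pos), else None."""
        for i, r in enumerate(self.regions):
            if r.contains(chrom, pos):
                return i
        return None


@dataclass(frozen=True)
class ZoomSpec:
    """A magnified sub-region of one main-panel region."""

    target: GenomicInterval
    parent_index: int

    def validate(self, rs: RegionSet) -> None:
        if not 0 <= self.parent_index < len(rs):
            raise LayoutError(f"zoom parent_index {self.parent_index} out of range")
        parent = rs.regions[self.parent_index]
        t = self.target
        if t.chrom != parent.chrom or t.start < parent.start or t.end > parent.end:
            raise LayoutError(
                f"zoom target {t.chrom}:{t.start}-{t.end} not contained in "
                f"parent region {parent.chrom}:{parent.start}-{parent.end}"
            )
        if t.width >= parent.width:
            raise LayoutError("zoom target must be strictly smaller than its parent region")


@dataclass(frozen=True)
class CanvasMap:
    """Bijective mapping between plotted regions and the [0, 1] canvas.

    ``segments[i]`` is the canvas x-extent of ``regions[i]``; consecutive
    segments are separated by exactly ``gap`` canvas units.  ``bp_per_unit``
    is the single scale factor shared by every region.
    """

    regions: RegionSet
    segments: tuple[tuple[float, float], ...]
    gap: float
    bp_per_unit: float

    def genome_to_canvas(self, chrom: str, pos: int | float) -> Optional[float]:
        """Canvas x of a genomic position, or None if it is not plotted."""
        for (x0, x1), r in zip(self.segments, self.regions):
            if chrom == r.chrom and r.start <= pos <= r.end:
                return x0 + (pos - r.start) * (x1 - x0) / r.width
        return None

    def canvas_to_genome(self, x: float) -> Optional[tuple[str, float]]:
        """Inverse of :meth:`genome_to_canvas`; None inside inter-region gaps."""
        if not 0.0 <= x <= 1.0:
            raise LayoutError(f"canvas coordinate {x} outside [0, 1]")
        for (x0, x1), r in zip(self.segments, self.regions):
            if x0 <= x <= x1:
                return r.chrom, r.start + (x - x0) / (x1 - x0) * r.width
        return None

    def region_segment(self, i: int) -> tuple[float, float]:
        return self.segments[i]


def parse_region_file(source: str | Iterable[str]) -> RegionSet:
    """Parse the region file: tab-delimited chrom, start, end[, label].

    ``source`` may be raw text or an iterable of lines.  Blank lines and
    ``#`` comments are skipped; errors name the 1-based line number.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\r\n") for ln in source]
    regions: list[GenomicInterval] = []
    labels: list[Optional[str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise RegionFileError(f"need at least 3 columns at line {lineno}")
        chrom = cols[0].strip()
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise RegionFileError(f"malformed integer coordinate at line {lineno}") from None
        if start >= end:
            raise RegionFileError(f"start >= end at line {lineno}")
        if not chrom:
            raise RegionFileError(f"empty chromosome name at line {lineno}")
        new = GenomicInterval(chrom, start, end)
        for prev in regions:
            if prev.chrom == new.chrom and prev.start < new.end and new.start < prev.end:
                raise RegionFileError(
                    f"region at line {lineno} overlaps an earlier region on {chrom}"
                )
        regions.append(new)
        labels.append(cols[3].strip() if len(cols) > 3 and cols[3].strip() else None)
    if not regions:
        raise RegionFileError("region file contains no regions")
    return RegionSet(tuple(regions), tuple(labels))


def build_canvas_map(rs: RegionSet, gap: float = 0.05) -> CanvasMap:
    """Lay the regions of ``rs`` onto [0, 1] at one common bp-per-unit scale.

    The canvas width left after ``gap`` units between consecutive regions is
    divided among regions proportionally to their genomic widths, which is
    exactly what makes every region share one scale factor.
    """
    n = len(rs)
    if gap < 0:
        raise LayoutError("gap must be non-negative")
    available = 1.0 - gap * (n - 1)
    if available <= 0:
        raise LayoutError(f"gap {gap} too large for {n} regions")
    total_bp = rs.total_bp
    bp_per_unit = total_bp / available
    segments: list[tuple[float, float]] = []
    x = 0.0
    for r in rs:
        w = r.width / bp_per_unit
        segments.append((x, x + w))
        x += w + gap
    # pin the final edge to exactly 1.0 against accumulated FP error
    x0_last, _ = segments[-1]
    segments[-1] = (x0_last, 1.0) if n > 1 else (0.0, 1.0)
    return CanvasMap(rs, tuple(segments), gap, bp_per_unit)


def clip_to_regions(rs: RegionSet, iv: GenomicInterval) -> list[GenomicInterval]:
    """Intersect ``iv`` with every plotted region, in plot order.

    Features straddling a region edge are truncated rather than dropped so
    that what remains stays base-pair aligned.
    """
    out: list[GenomicInterval] = []
    for r in rs:
        hit = iv.intersect(r)
        if hit is not None:
            out.append(hit)
    return out


def build_zoom_map(
    m: CanvasMap, rs: RegionSet, z: ZoomSpec
) -> tuple[CanvasMap, tuple[float, float, float, float]]:
    """Build the zoom panel's map plus the connector anchor coordinates.

    Returns ``(zoom_map, (main_x_left, main_x_right, zoom_x_left, zoom_x_right))``;
    the first two are the canvas x of the target's endpoints on the *main*
    panel, the last two the zoom panel's full width (0 and 1).  The four
    points define the trapezoid drawn between the panels.
    """
    z.validate(rs)
    zoom_rs = RegionSet((z.target,), (None,))
    zoom_map = build_canvas_map(zoom_rs, gap=0.0)
    xl = m.genome_to_canvas(z.target.chrom, z.target.start)
    xr = m.genome_to_canvas(z.target.chrom, z.target.end)
    assert xl is not None and xr is not None
    return zoom_map, (xl, xr, 0.0, 1.0)
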