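"""Readers and writers for the tab-delimited track-data dialects.

Every dialect is a minimal BED/BEDPE-style superset so files exported from a
genome browser import unmodified:

* association table — ``chrom  pos  pvalue  [typed]  [r2]  [recomb]  [id]``
  (``pos`` is 1-based; ``typed`` is ``T``/``F`` for genotyped vs imputed)
* intensity / segmentation — BED4: ``chrom  start  end  value|state``
* interactions — BEDPE + score:
  ``chrom1  start1  end1  chrom2  start2  end2  score``
* contact bins — ``chrom1  bin1_start  chrom2  bin2_start  count`` with a
  file-level constant bin size
* gene models — BED12
* feature annotations — ``chrom  start  end  kind  label`` with ``kind`` one
  of ``highlight-box``, ``vertical-marker``, ``bracket``, ``text``

All files are tab-delimited UTF-8; ``#`` comment lines and blank lines are
skipped; CRLF and LF line endings are treated identically.  Parse errors
always carry a 1-based line number.  Interval records use 0-based half-open
coordinates; association positions are 1-based in the file and converted to
0-based internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .layout import GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "AssociationRecord",
    "IntensityRecord",
    "SegmentationRecord",
    "InteractionRecord",
    "ContactBinRecord",
    "GeneModel",
    "FeatureAnnotation",
    "read_association",
    "read_intensity",
    "read_segmentation",
    "read_interactions",
    "read_contacts",
    "read_genes",
    "read_annotations",
    "write_association",
    "write_intensity",
    "write_segmentation",
    "write_interactions",
    "write_contacts",
    "write_genes",
    "write_annotations",
]

ANNOTATION_KINDS = ("highlight-box", "vertical-marker", "bracket", "text")
#: kinds anchored to a single base (file interval must satisfy end == start + 1)
POINT_KINDS = ("vertical-marker", "text")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed track-file line; the message names the file and line."""

    def __init__(self, path: object, lineno: int, message: str):
        super().__init__(f"{path}: line {lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# --------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class AssociationRecord:
    """One variant of a regional association (SNAP-style) track.

    ``pos`` is stored 0-based.  ``typed`` distinguishes genotyped from
    imputed variants; ``r2`` is LD with the locus index SNP; ``recomb`` is
    the local recombination rate in cM/Mb.  Optional fields are None when
    the file omits their columns.
    """

    chrom: str
    pos: int
    pvalue: float
    typed: Optional[bool] = None
    r2: Optional[float] = None
    recomb: Optional[float] = None
    id: Optional[str] = None

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.pvalue)


@dataclass(frozen=True)
class IntensityRecord:
    chrom: str
    start: int
    end: int
    value: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SegmentationRecord:
    chrom: str
    start: int
    end: int
    state: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class InteractionRecord:
    """A significant pairwise contact; ``score`` is -log10 p of the interaction."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: float


@dataclass(frozen=True)
class ContactBinRecord:
    """One cell of a binned (raw-count) contact matrix."""

    chrom1: str
    bin1_start: int
    chrom2: str
    bin2_start: int
    count: float
    bin_size: int


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class FeatureAnnotation:
    """A manual annotation: highlight box, vertical marker, bracket or text."""

    target: GenomicInterval
    kind: str
    label: str = ""

    @property
    def position(self) -> int:
        """Anchor base of single-position kinds (0-based)."""
        return self.target.start


# --------------------------------------------------------------------------
# shared line machinery


def _iter_lines(path: PathLike):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_file(path, row_parser, permissive: bool, min_cols: int, what: str):
    out = []
    for lineno, cols in _iter_lines(path):
        try:
            if len(cols) < min_cols:
                raise ValueError(f"expected at least {min_cols} columns, got {len(cols)}")
            rec = row_parser(cols)
        except (ValueError, TypeError) as exc:
            if permissive:
                log.warning("%s: line %d: dropped bad %s record: %s", path, lineno, what, exc)
                continue
            raise ParseError(path, lineno, str(exc)) from None
        if rec is not None:
            out.append(rec)
    return out


def _float(text: str, name: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise ValueError(f"non-numeric {name} {text!r}") from None
    if not math.isfinite(v):
        raise ValueError(f"non-finite {name} {text!r}")
    return v


def _int(text: str, name: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"non-numeric {name} {text!r}") from None


def _bool_flag(text: str) -> bool:
    t = text.strip().upper()
    if t in ("T", "TRUE", "TYPED", "1"):
        return True
    if t in ("F", "FALSE", "IMPUTED", "0"):
        return False
    raise ValueError(f"cannot interpret typed/imputed flag {text!r}")


# --------------------------------------------------------------------------
# readers


def read_association(path: PathLike, permissive: bool = False) -> list[AssociationRecord]:
    """Read an association table; a first line with a non-integer position
    column is taken to be a header and skipped."""
    header_seen = False

    def row(cols: Sequence[str]) -> Optional[AssociationRecord]:
        nonlocal header_seen
        try:
            pos = int(cols[1])
        except ValueError:
            if not header_seen:
                header_seen = True
                return None
            raise ValueError(f"non-numeric position {cols[1]!r}") from None
        header_seen = True
        pvalue = _float(cols[2], "p-value")
        if not 0.0 < pvalue <= 1.0:
            raise ValueError(f"p-value {pvalue} outside (0, 1]")
        typed = _bool_flag(cols[3]) if len(cols) > 3 and cols[3].strip() else None
        r2 = None
        if len(cols) > 4 and cols[4].strip():
            r2 = _float(cols[4], "r2")
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2 {r2} outside [0, 1]")
        recomb = None
        if len(cols) > 5 and cols[5].strip():
            recomb = _float(cols[5], "recombination rate")
            if recomb < 0:
                raise ValueError(f"negative recombination rate {recomb}")
        snp_id = cols[6].strip() if len(cols) > 6 and cols[6].strip() else None
        return AssociationRecord(cols[0], pos - 1, pvalue, typed, r2, recomb, snp_id)

    return _parse_file(path, row, permissive, 3, "association")


def _read_bed4(path, permissive, value_parser, make, what):
    def row(cols):
        start, end = _int(cols[1], "start"), _int(cols[2], "end")
        if start >= end:
            raise ValueError(f"start >= end ({start} >= {end})")
        return make(cols[0], start, end, value_parser(cols[3]))

    return _parse_file(path, row, permissive, 4, what)


def read_intensity(path: PathLike, permissive: bool = False) -> list[IntensityRecord]:
    """BED4 with a numeric value column."""
    return _read_bed4(
        path, permissive, lambda c: _float(c, "value"), IntensityRecord, "intensity"
    )


def read_segmentation(path: PathLike, permissive: bool = False) -> list[SegmentationRecord]:
    """BED4 with a state-label column (e.g. ChromHMM output)."""

    def state(c: str) -> str:
        s = c.strip()
        if not s:
            raise ValueError("empty state label")
        return s

    return _read_bed4(path, permissive, state, SegmentationRecord, "segmentation")


def read_bed_like(path: PathLike, kind: str, permissive: bool = False):
    """Dispatch BED4 parsing by value-column type: 'intensity' or 'segmentation'."""
    if kind == "intensity":
        return read_intensity(path, permissive)
    if kind == "segmentation":
        return read_segmentation(path, permissive)
    raise ValueError(f"unknown BED4 dialect {kind!r}")


def read_interactions(path: PathLike, permissive: bool = False) -> list[InteractionRecord]:
    """BEDPE+score; inter-chromosomal anchor pairs and self-loops are valid."""

    def row(cols):
        a1 = GenomicInterval(cols[0], _int(cols[1], "start1"), _int(cols[2], "end1"))
        a2 = GenomicInterval(cols[3], _int(cols[4], "start2"), _int(cols[5], "end2"))
        score = _float(cols[6], "score")
        if score < 0:
            raise ValueError(f"negative interaction score {score}")
        return InteractionRecord(a1, a2, score)

    return _parse_file(path, row, permissive, 7, "interaction")


def read_contacts(
    path: PathLike, bin_size: int, permissive: bool = False
) -> list[ContactBinRecord]:
    """Binned contact counts; bin starts must sit on the ``bin_size`` grid.

    The file may be upper-triangle or full: the two symmetric orientations of
    a pair are treated as duplicates and summed with a warning.  No symmetric
    completion is applied — the renderer decides how to mirror.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")

    def row(cols):
        b1, b2 = _int(cols[1], "bin1_start"), _int(cols[3], "bin2_start")
        for b in (b1, b2):
            if b % bin_size != 0:
                raise ValueError(f"bin start {b} not aligned to {bin_size} bp grid")
        count = _float(cols[4], "count")
        if count < 0:
            raise ValueError(f"negative contact count {count}")
        return ContactBinRecord(cols[0], b1, cols[2], b2, count, bin_size)

    recs = _parse_file(path, row, permissive, 5, "contact")
    merged: dict[tuple, ContactBinRecord] = {}
    order: list[tuple] = []
    for r in recs:
        key = tuple(sorted(((r.chrom1, r.bin1_start), (r.chrom2, r.bin2_start))))
        if key in merged:
            prev = merged[key]
            log.warning(
                "%s: duplicate symmetric contact pair %s summed (%g + %g)",
                path, key, prev.count, r.count,
            )
            merged[key] = ContactBinRecord(
                prev.chrom1, prev.bin1_start, prev.chrom2, prev.bin2_start,
                prev.count + r.count, bin_size,
            )
        else:
            merged[key] = r
            order.append(key)
    return [merged[k] for k in order]


def read_genes(path: PathLike, permissive: bool = False) -> list[GeneModel]:
    """BED12 gene models; exons are rebuilt from blockSizes/blockStarts."""

    def row(cols):
        if len(cols) < 12:
            raise ValueError(f"BED12 needs 12 columns, got {len(cols)}")
        chrom, name = cols[0], cols[3]
        tx_start, tx_end = _int(cols[1], "txStart"), _int(cols[2], "txEnd")
        if tx_start >= tx_end:
            raise ValueError(f"txStart >= txEnd ({tx_start} >= {tx_end})")
        strand = cols[5]
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        n_blocks = _int(cols[9], "blockCount")
        sizes = [_int(s, "blockSize") for s in cols[10].rstrip(",").split(",") if s]
        starts = [_int(s, "blockStart") for s in cols[11].rstrip(",").split(",") if s]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(
                f"blockCount {n_blocks} does not match listed sizes/starts "
                f"({len(sizes)}/{len(starts)})"
            )
        exons = []
        for off, size in zip(starts, sizes):
            e0, e1 = tx_start + off, tx_start + off + size
            if e0 >= e1:
                raise ValueError("zero-length exon block")
            if e0 < tx_start or e1 > tx_end:
                raise ValueError(f"exon [{e0}, {e1}) outside tx span [{tx_start}, {tx_end})")
            exons.append((e0, e1))
        exons.sort()
        for (s0, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("overlapping exon blocks")
        return GeneModel(name, chrom, tx_start, tx_end, strand, tuple(exons))

    return _parse_file(path, row, permissive, 12, "gene")


def read_annotations(path: PathLike, permissive: bool = False) -> list[FeatureAnnotation]:
    """Manual feature annotations: chrom, start, end, kind, label."""

    def row(cols):
        start, end = _int(cols[1], "start"), _int(cols[2], "end")
        kind = cols[3].strip()
        if kind not in ANNOTATION_KINDS:
            raise ValueError(
                f"unknown annotation kind {kind!r}; expected one of {ANNOTATION_KINDS}"
            )
        label = cols[4] if len(cols) > 4 else ""
        if kind in POINT_KINDS and end != start + 1:
            raise ValueError(f"{kind} annotations must cover exactly one base")
        if not label and kind != "highlight-box":
            raise ValueError(f"{kind} annotations require a label")
        return FeatureAnnotation(GenomicInterval(cols[0], start, end), kind, label)

    return _parse_file(path, row, permissive, 4, "annotation")


# --------------------------------------------------------------------------
# writers (exact inverses of the readers, used for round-trip checks and
# fixture generation)


def _fmt_num(v: float) -> str:
    return repr(v) if isinstance(v, float) else str(v)


def _write(path: PathLike, rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_association(path: PathLike, recs: Iterable[AssociationRecord]) -> None:
    def row(r: AssociationRecord):
        cols = [r.chrom, str(r.pos + 1), _fmt_num(r.pvalue)]
        opt = [
            "" if r.typed is None else ("T" if r.typed else "F"),
            "" if r.r2 is None else _fmt_num(r.r2),
            "" if r.recomb is None else _fmt_num(r.recomb),
            r.id or "",
        ]
        while opt and opt[-1] == "":
            opt.pop()
        return cols + opt

    _write(path, (row(r) for r in recs))


def write_intensity(path: PathLike, recs: Iterable[IntensityRecord]) -> None:
    _write(path, ((r.chrom, str(r.start), str(r.end), _fmt_num(r.value)) for r in recs))


def write_segmentation(path: PathLike, recs: Iterable[SegmentationRecord]) -> None:
    _write(path, ((r.chrom, str(r.start), str(r.end), r.state) for r in recs))


def write_interactions(path: PathLike, recs: Iterable[InteractionRecord]) -> None:
    _write(
        path,
        (
            (
                r.anchor1.chrom, str(r.anchor1.start), str(r.anchor1.end),
                r.anchor2.chrom, str(r.anchor2.start), str(r.anchor2.end),
                _fmt_num(r.score),
            )
            for r in recs
        ),
    )


def write_contacts(path: PathLike, recs: Iterable[ContactBinRecord]) -> None:
    _write(
        path,
        (
            (r.chrom1, str(r.bin1_start), r.chrom2, str(r.bin2_start), _fmt_num(r.count))
            for r in recs
        ),
    )


def write_genes(path: PathLike, recs: Iterable[GeneModel]) -> None:
    def row(g: GeneModel):
        sizes = ",".join(str(e1 - e0) for e0, e1 in g.exons) + ","
        starts = ",".join(str(e0 - g.tx_start) for e0, e1 in g.exons) + ","
        return (
            g.chrom, str(g.tx_start), str(g.tx_end), g.name, "0", g.strand,
            str(g.tx_start), str(g.tx_end), "0,0,0", str(len(g.exons)), sizes, starts,
        )

    _write(path, (row(g) for g in recs))


def write_annotations(path: PathLike, recs: Iterable[FeatureAnnotation]) -> None:
    _write(
        path,
        (
            (a.target.chrom, str(a.target.start), str(a.target.end), a.kind, a.label)
            for a in recs
        ),
    )
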