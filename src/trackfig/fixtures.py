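"""Seeded synthetic input sets exercising every track dialect.

The generator emulates the *structure* of a two-locus regulatory-genomics
composite: two Mb-scale regions on different chromosomes; an association
signal whose index SNP sits in the second region, with LD r² decaying
exponentially away from it and a recombination-rate background; a
ChromHMM-style segmentation tiling each region; a binned contact matrix
around the index SNP with a planted set of enriched bin pairs that double as
the "significant interactions" file (including one pair joining the two
regions); gene models with valid exon structures, some overlapping to
exercise row packing; and manual annotations (an LD-block highlight box and
a marker at the index SNP).

The statistics are deliberately simple — monotone distance decay plus noise,
not a population-genetic or polymer model.  Randomness comes from
``numpy.random.default_rng`` seeded per stream, so a given seed always
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as tio
from .io import (
    AssociationRecord,
    ContactBinRecord,
    FeatureAnnotation,
    GeneModel,
    IntensityRecord,
    InteractionRecord,
    SegmentationRecord,
)
from .layout import GenomicInterval, RegionSet, ZoomSpec

__all__ = [
    "FixtureParams",
    "random_region_set",
    "make_association",
    "make_intensity",
    "make_contacts_and_interactions",
    "make_segmentation_genes_annotations",
    "default_zoom",
    "write_fixture_set",
    "PRESETS",
]

CHROMHMM_STATES = (
    "Active TSS",
    "Enhancer",
    "Transcribed",
    "Repressed",
    "Heterochromatin",
    "Quiescent",
)


@dataclass
class FixtureParams:
    """Knobs of the synthetic data set; defaults emulate a two-locus figure."""

    seed: int = 0
    # (chrom, start, end, label); starts/ends multiples of bin_size
    regions: tuple = (
        ("chr3", 1_200_000, 2_100_000, "locus A (chr3)"),
        ("chr8", 4_800_000, 5_700_000, "locus B (chr8)"),
    )
    n_snps: int = 150  # per region
    index_chrom: str = "chr8"
    index_pos: int = 5_250_000
    index_snp_id: str = "rs9900132"  # synthetic identifier
    peak_neg_log10_p: float = 8.0
    signal_decay_bp: float = 30_000.0
    r2_decay_bp: float = 40_000.0
    imputed_frac: float = 0.2
    n_states: int = 6
    mean_segment_bp: float = 6_000.0
    bin_size: int = 3_000
    contact_base: float = 120.0
    contact_decay: float = 1.0
    enrichment: float = 4.0
    n_interactions: int = 12
    contact_window_bins: int = 40
    n_genes: int = 10
    max_exons: int = 8
    zoom_half_width_bp: int = 60_000

    def region_set(self) -> RegionSet:
        ivs = tuple(GenomicInterval(c, s, e) for c, s, e, _ in self.regions)
        labels = tuple(lab for _, _, _, lab in self.regions)
        return RegionSet(ivs, labels)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def random_region_set(
    rng: np.random.Generator,
    n_regions: Optional[int] = None,
    width_range: tuple[int, int] = (1_000, 10_000_000),
) -> RegionSet:
    """A random non-overlapping RegionSet (1-5 regions, each on its own
    chromosome) for property tests of the coordinate machinery."""
    n = int(n_regions if n_regions is not None else rng.integers(1, 6))
    regions = []
    for k in range(n):
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        start = int(rng.integers(0, 10_000_000))
        regions.append(GenomicInterval(f"chr{k + 1}", start, start + width))
    return RegionSet(tuple(regions))


def default_zoom(p: FixtureParams) -> ZoomSpec:
    """Zoom window centred on the index SNP, aligned to the contact grid."""
    half = p.zoom_half_width_bp
    target = GenomicInterval(p.index_chrom, p.index_pos - half, p.index_pos + half)
    parent = next(
        i for i, (c, s, e, _) in enumerate(p.regions)
        if c == target.chrom and s <= target.start and target.end <= e
    )
    return ZoomSpec(target, parent)


def make_association(p: FixtureParams) -> list[AssociationRecord]:
    """SNPs uniform over the regions; a -log10 p peak at the index SNP
    decaying with distance over background noise; r² = exp(-d / decay) with
    noise, clipped to [0, 1]; the index SNP gets r² = 1, the named id, and
    the maximum -log10 p of its region."""
    rng = p._rng(1)
    out: list[AssociationRecord] = []
    for chrom, start, end, _ in p.regions:
        pos = np.sort(rng.choice(np.arange(start, end), size=p.n_snps, replace=False))
        is_index_region = chrom == p.index_chrom
        if is_index_region:
            pos = np.unique(np.append(pos, p.index_pos))
        noise = rng.exponential(0.4, size=pos.size)
        if is_index_region:
            d = np.abs(pos - p.index_pos)
            nlp = p.peak_neg_log10_p * np.exp(-d / p.signal_decay_bp) + noise
            # keep the index SNP strictly on top
            nlp = np.where(d > 0, np.minimum(nlp, p.peak_neg_log10_p - 0.2), nlp)
            nlp[d == 0] = p.peak_neg_log10_p
            r2 = np.clip(np.exp(-d / p.r2_decay_bp) + rng.normal(0, 0.05, pos.size), 0, 1)
            r2[d == 0] = 1.0
            r2 = np.where((d > 0) & (r2 >= 1.0), 0.999, r2)
        else:
            nlp = noise
            r2 = np.clip(np.abs(rng.normal(0, 0.03, pos.size)), 0, 1)
        typed = rng.random(pos.size) >= p.imputed_frac
        # smooth recombination background with two hotspots per region
        hot = rng.uniform(start, end, size=2)
        amp = rng.uniform(25, 55, size=2)
        recomb = 1.5 + sum(
            a * np.exp(-((pos - h) ** 2) / (2 * 4_000.0 ** 2))
            for a, h in zip(amp, hot)
        )
        for k in range(pos.size):
            at_index = is_index_region and pos[k] == p.index_pos
            pv = float(f"{10.0 ** -float(nlp[k]):.6g}")
            pv = min(max(pv, 1e-300), 1.0)
            out.append(
                AssociationRecord(
                    chrom,
                    int(pos[k]),
                    pv,
                    typed=True if at_index else bool(typed[k]),
                    r2=1.0 if at_index else round(float(r2[k]), 4),
                    recomb=round(float(recomb[k]), 3),
                    id=p.index_snp_id if at_index else None,
                )
            )
    return out


def make_intensity(
    p: FixtureParams, assoc: Optional[list[AssociationRecord]] = None,
    window_bp: int = 15_000,
) -> list[IntensityRecord]:
    """Windowed maximum of the association -log10 p, as a colour-intensity
    summary of the same signal."""
    if assoc is None:
        assoc = make_association(p)
    out: list[IntensityRecord] = []
    for chrom, start, end, _ in p.regions:
        snps = [(a.pos, a.neg_log10_p) for a in assoc if a.chrom == chrom]
        w0 = start
        while w0 < end:
            w1 = min(w0 + window_bp, end)
            vals = [v for pos, v in snps if w0 <= pos < w1]
            out.append(
                IntensityRecord(chrom, w0, w1, round(max(vals, default=0.0), 4))
            )
            w0 = w1
    return out


def make_contacts_and_interactions(
    p: FixtureParams,
) -> tuple[list[ContactBinRecord], list[InteractionRecord]]:
    """Contact counts with expected value ``contact_base * (1 + |i-j|)^-decay``
    in a bin window around the index SNP, plus a planted enriched pair set.

    The planted pairs (expected count ``enrichment`` times background at the
    same separation) are emitted as the significant-interactions list with
    synthetic -log10 p scores; one planted pair joins the two regions.
    """
    rng = p._rng(2)
    bs = p.bin_size
    chrom = p.index_chrom
    region = next(r for r in p.regions if r[0] == chrom)
    index_bin = (p.index_pos - region[1]) // bs * bs + region[1]
    w = p.contact_window_bins
    first = index_bin - (w // 2) * bs
    first = max(first, region[1])
    bins = [first + k * bs for k in range(w)]

    # planted intra-region pairs: one anchor at the index bin
    offsets = rng.choice(np.arange(3, w // 2), size=p.n_interactions - 1, replace=False)
    planted = {(index_bin, index_bin + int(o) * bs) for o in offsets}
    planted = {(min(a, b), max(a, b)) for a, b in planted}

    contacts: list[ContactBinRecord] = []
    for i, bi in enumerate(bins):
        for j in range(i, w):
            bj = bins[j]
            lam = p.contact_base * (1.0 + (j - i)) ** (-p.contact_decay)
            if (min(bi, bj), max(bi, bj)) in planted:
                lam *= p.enrichment
            count = int(rng.poisson(lam))
            contacts.append(ContactBinRecord(chrom, bi, chrom, bj, count, bs))

    # one planted pair joining the two regions
    other = next(r for r in p.regions if r[0] != chrom)
    cross_bin = (other[1] + other[2]) // 2 // bs * bs
    cross_count = int(rng.poisson(p.contact_base * 0.1 * p.enrichment))
    contacts.append(
        ContactBinRecord(other[0], cross_bin, chrom, index_bin, cross_count, bs)
    )

    interactions: list[InteractionRecord] = []
    scores = np.round(rng.uniform(3.0, 8.0, size=p.n_interactions), 3)
    for (a, b), s in zip(sorted(planted), scores):
        interactions.append(
            InteractionRecord(
                GenomicInterval(chrom, a, a + bs),
                GenomicInterval(chrom, b, b + bs),
                float(s),
            )
        )
    interactions.append(
        InteractionRecord(
            GenomicInterval(other[0], cross_bin, cross_bin + bs),
            GenomicInterval(chrom, index_bin, index_bin + bs),
            float(scores[-1]),
        )
    )
    return contacts, interactions


def _markov_states(rng: np.random.Generator, n: int, states: tuple) -> list[str]:
    out = [states[int(rng.integers(len(states)))]]
    for _ in range(n - 1):
        prev = states.index(out[-1])
        nxt = int(rng.integers(len(states) - 1))
        if nxt >= prev:
            nxt += 1
        out.append(states[nxt])
    return out


def make_segmentation_genes_annotations(
    p: FixtureParams,
) -> tuple[list[SegmentationRecord], list[GeneModel], list[FeatureAnnotation]]:
    """Segmentation tiling each region exactly; genes with valid exon
    structure (at least two mutually overlapping in the first region);
    an LD-block highlight box and an index-SNP marker."""
    rng = p._rng(3)
    states = CHROMHMM_STATES[: p.n_states]

    segs: list[SegmentationRecord] = []
    for chrom, start, end, _ in p.regions:
        edges = [start]
        while edges[-1] < end:
            step = max(600, int(round(rng.exponential(p.mean_segment_bp) / 200)) * 200)
            edges.append(min(edges[-1] + step, end))
        labels = _markov_states(rng, len(edges) - 1, states)
        segs += [
            SegmentationRecord(chrom, a, b, s)
            for a, b, s in zip(edges, edges[1:], labels)
        ]

    genes: list[GeneModel] = []
    per_region = max(1, p.n_genes // len(p.regions))
    gi = 0
    for ridx, (chrom, start, end, _) in enumerate(p.regions):
        for k in range(per_region):
            span = int(rng.integers(20_000, 120_000))
            tx0 = int(rng.integers(start, end - span))
            genes.append(_random_gene(rng, f"SYNG{gi + 1}", chrom, tx0, tx0 + span, p))
            gi += 1
        if ridx == 0:
            # force an overlapping pair to exercise row packing
            g = genes[-per_region]
            shift = max(1, (g.tx_end - g.tx_start) // 3)
            tx0 = min(g.tx_start + shift, end - 20_000)
            tx1 = min(tx0 + (g.tx_end - g.tx_start), end)
            genes.append(_random_gene(rng, f"SYNG{gi + 1}", chrom, tx0, tx1, p))
            gi += 1

    half = 25_000
    anns = [
        FeatureAnnotation(
            GenomicInterval(p.index_chrom, p.index_pos - half, p.index_pos + half),
            "highlight-box", "",
        ),
        FeatureAnnotation(
            GenomicInterval(p.index_chrom, p.index_pos, p.index_pos + 1),
            "vertical-marker", p.index_snp_id,
        ),
        FeatureAnnotation(
            GenomicInterval(p.index_chrom, p.index_pos - half, p.index_pos + half),
            "bracket", "LD block",
        ),
    ]
    return segs, genes, anns


def _random_gene(rng, name, chrom, tx0, tx1, p: FixtureParams) -> GeneModel:
    span = tx1 - tx0
    n_exons = int(rng.integers(2, p.max_exons + 1))
    cuts = np.sort(rng.choice(np.arange(1, span - 1), size=2 * n_exons - 2,
                              replace=False))
    offsets = np.concatenate([[0], cuts, [span]])
    exons = tuple(
        (tx0 + int(offsets[2 * k]), tx0 + int(offsets[2 * k + 1]))
        for k in range(n_exons)
    )
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(name, chrom, tx0, tx1, strand, exons)


# --------------------------------------------------------------------------
# on-disk fixture sets and ready-to-run configs


def _track(ttype, path, **kw):
    return {"type": ttype, "path": path, **kw}


def _preset_tracks(preset: str, p: FixtureParams) -> tuple[list, list]:
    assoc = _track("association", "association.tsv", height=1.6,
                   y_label="-log10 p")
    inten = _track("intensity", "intensity.bed", height=0.5,
                   y_label="GWAS signal")
    seg = _track("segmentation", "segmentation.bed", height=0.5)
    arcs = _track("arcs", "interactions.bedpe", height=1.2)
    links = _track("links", "interactions.bedpe", height=0.8)
    genes = _track("genes", "genes.bed12", height=0.9)
    heat = _track("heatmap", "contacts.tsv", bin_size=p.bin_size, height=1.4,
                  y_label="Hi-C reads")
    anno = _track("annotations", "annotations.tsv", height=0.4)
    if preset == "fig1":
        return [inten, links, seg, assoc], [assoc, seg]
    if preset == "fig2":
        return [arcs, anno], [heat, anno]
    # default: six main tracks (letters a-f) and a three-track zoom
    return [inten, arcs, links, seg, assoc, genes], [assoc, heat, anno]


PRESETS = ("default", "fig1", "fig2")


def write_fixture_set(
    out_dir: str | Path, params: Optional[FixtureParams] = None,
    preset: str = "default",
) -> dict[str, Path]:
    """Write the full synthetic input set plus a ready-to-run YAML config.

    Returns a name -> path mapping; ``paths['config']`` can be fed straight
    to ``trackfig plot --config``.
    """
    p = params or FixtureParams()
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rs = p.region_set()
    with open(out / "regions.tsv", "w", encoding="utf-8") as fh:
        for iv, lab in zip(rs.regions, rs.labels):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab or ''}\n")

    assoc = make_association(p)
    tio.write_association(out / "association.tsv", assoc)
    tio.write_intensity(out / "intensity.bed", make_intensity(p, assoc))
    contacts, interactions = make_contacts_and_interactions(p)
    tio.write_contacts(out / "contacts.tsv", contacts)
    tio.write_interactions(out / "interactions.bedpe", interactions)
    segs, genes, anns = make_segmentation_genes_annotations(p)
    tio.write_segmentation(out / "segmentation.bed", segs)
    tio.write_genes(out / "genes.bed12", genes)
    tio.write_annotations(out / "annotations.tsv", anns)

    zoom = default_zoom(p)
    main_tracks, zoom_tracks = _preset_tracks(preset, p)
    config = {
        "title": "Synthetic two-locus composite",
        "region_file": "regions.tsv",
        "gap": 0.05,
        "formats": ["pdf", "png"],
        "dpi": 150,
        "tracks": main_tracks,
        "zoom": {
            "chrom": zoom.target.chrom,
            "start": zoom.target.start,
            "end": zoom.target.end,
            "tracks": zoom_tracks,
        },
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False, allow_unicode=True)

    paths = {
        "config": cfg_path,
        "regions": out / "regions.tsv",
        "association": out / "association.tsv",
        "intensity": out / "intensity.bed",
        "contacts": out / "contacts.tsv",
        "interactions": out / "interactions.bedpe",
        "segmentation": out / "segmentation.bed",
        "genes": out / "genes.bed12",
        "annotations": out / "annotations.tsv",
    }
    return paths
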