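"""Track renderers: height/colour encodings, greedy packing against
brute-force oracles, cross-track alignment and determinism."""

import numpy as np
import pytest
from matplotlib.colors import to_rgb

from trackfig.io import (
    AssociationRecord,
    ContactBinRecord,
    FeatureAnnotation,
    GeneModel,
    IntensityRecord,
    InteractionRecord,
    SegmentationRecord,
)
from trackfig.layout import (
    GenomicInterval,
    RegionSet,
    build_canvas_map,
)
from trackfig.render import (
    R2_BIN_EDGES,
    TrackSpec,
    _greedy_lanes,
    _r2_bin,
    render_annotations,
    render_arcs,
    render_association,
    render_genes,
    render_heatmap,
    render_intensity,
    render_links,
    render_segmentation,
)


def _luminance(hex_color: str) -> float:
    r, g, b = to_rgb(hex_color)
    return 0.299 * r + 0.587 * g + 0.114 * b


@pytest.fixture
def big_map():
    rs = RegionSet(
        (GenomicInterval("chr3", 0, 100_000), GenomicInterval("chr8", 0, 100_000))
    )
    return build_canvas_map(rs, gap=0.1)


class TestAssociation:
    def test_point_height_is_neg_log10_p_over_ymax(self, big_map):
        recs = [AssociationRecord("chr3", 500, 0.001)]
        rt = render_association(recs, big_map, TrackSpec("association", y_max=6.0))
        (pt,) = [g for g in rt.glyphs if g.shape == "point"]
        assert pt.y[0] == pytest.approx(3.0 / 6.0)

    def test_pvalue_one_sits_on_the_axis(self, big_map):
        recs = [AssociationRecord("chr3", 500, 1.0)]
        rt = render_association(recs, big_map, TrackSpec("association"))
        (pt,) = [g for g in rt.glyphs if g.shape == "point"]
        assert pt.y[0] == 0.0

    def test_r2_bin_lookup_matches_brute_force(self):
        """Configured-bin lookup equals counting how many edges lie at or
        below the value."""
        rng = np.random.default_rng(3)
        for r2 in list(rng.random(200)) + [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            brute = sum(1 for e in R2_BIN_EDGES if r2 >= e)
            assert _r2_bin(r2, R2_BIN_EDGES) == brute

    def test_top_bin_colour_for_high_r2(self, big_map):
        recs = [
            AssociationRecord("chr3", 500, 0.01, typed=True, r2=0.85),
            AssociationRecord("chr3", 600, 0.01, typed=True, r2=0.05),
        ]
        spec = TrackSpec("association")
        rt = render_association(recs, big_map, spec)
        pts = [g for g in rt.glyphs if g.shape == "point"]
        assert pts[0].style.color == spec.r2_colors[-1]
        assert pts[1].style.color == spec.r2_colors[0]

    def test_typed_and_imputed_markers_differ(self, big_map):
        recs = [
            AssociationRecord("chr3", 500, 0.01, typed=True),
            AssociationRecord("chr3", 600, 0.01, typed=False),
        ]
        rt = render_association(recs, big_map, TrackSpec("association"))
        markers = {g.style.marker for g in rt.glyphs if g.shape == "point"}
        assert len(markers) == 2

    def test_index_snp_drawn_last_with_label(self, big_map):
        recs = [
            AssociationRecord("chr3", 500, 1e-8, typed=True, r2=1.0, id="rsINDEX"),
            AssociationRecord("chr3", 600, 0.01, typed=True, r2=0.5),
        ]
        rt = render_association(recs, big_map, TrackSpec("association"))
        pts = [g for g in rt.glyphs if g.shape == "point"]
        assert pts[-1].layer > pts[0].layer
        assert pts[-1].style.marker == "D"
        labels = [g.text for g in rt.glyphs if g.shape == "text"]
        assert "rsINDEX" in labels

    def test_recombination_line_on_secondary_axis(self, big_map):
        recs = [
            AssociationRecord("chr3", 100, 0.5, recomb=10.0),
            AssociationRecord("chr3", 5000, 0.5, recomb=40.0),
        ]
        rt = render_association(recs, big_map, TrackSpec("association"))
        segs = [g for g in rt.glyphs if g.shape == "segment"]
        assert len(segs) == 1
        assert rt.y2_range == (0.0, 40.0)
        assert segs[0].y == pytest.approx((10 / 40, 1.0))

    def test_records_outside_regions_produce_no_glyphs(self, big_map):
        recs = [AssociationRecord("chr9", 500, 0.001)]
        rt = render_association(recs, big_map, TrackSpec("association"))
        assert rt.glyphs == []


class TestIntensity:
    def test_min_max_normalisation(self, big_map):
        recs = [
            IntensityRecord("chr3", 0, 100, v) for v in (0.0, 5.0, 10.0)
        ]
        spec = TrackSpec("intensity", palette="Greys")
        rt = render_intensity(recs, big_map, spec)
        lums = [_luminance(g.style.fill) for g in rt.glyphs]
        # darker fill for larger value; midpoint strictly between
        assert lums[0] > lums[1] > lums[2]

    def test_interval_clipped_at_region_edge(self, big_map):
        recs = [IntensityRecord("chr3", 90_000, 150_000, 1.0)]
        rt = render_intensity(recs, big_map, TrackSpec("intensity"))
        (rect,) = rt.glyphs
        assert rect.x[1] == pytest.approx(big_map.segments[0][1])

    def test_single_record_takes_palette_midpoint(self, big_map):
        recs = [IntensityRecord("chr3", 0, 100, 7.0)]
        spec = TrackSpec("intensity")
        rt = render_intensity(recs, big_map, spec)
        from trackfig.render import _palette_hex

        assert rt.glyphs[0].style.fill == _palette_hex(spec.palette, 0.5)


class TestSegmentation:
    def test_abutting_same_state_merged(self, big_map):
        recs = [
            SegmentationRecord("chr3", 0, 3000, "Enh"),
            SegmentationRecord("chr3", 3000, 6000, "Enh"),
        ]
        rt = render_segmentation(recs, big_map, TrackSpec("segmentation"))
        assert len(rt.glyphs) == 1
        assert rt.glyphs[0].x[1] == pytest.approx(
            big_map.genome_to_canvas("chr3", 6000)
        )

    def test_one_legend_entry_per_state_present(self, big_map):
        recs = [
            SegmentationRecord("chr3", 0, 1000, "A"),
            SegmentationRecord("chr3", 2000, 3000, "B"),
            SegmentationRecord("chr3", 4000, 5000, "C"),
            SegmentationRecord("chr3", 6000, 7000, "A"),
        ]
        rt = render_segmentation(recs, big_map, TrackSpec("segmentation"))
        assert len(rt.legend) == 3

    def test_fallback_colours_deterministic(self, big_map):
        recs = [
            SegmentationRecord("chr3", 0, 1000, "Zed"),
            SegmentationRecord("chr3", 2000, 3000, "Alpha"),
        ]
        a = render_segmentation(recs, big_map, TrackSpec("segmentation"))
        b = render_segmentation(recs, big_map, TrackSpec("segmentation"))
        assert a.glyphs == b.glyphs
        # colours assigned by sorted state-name order, not record order
        colour = {e.label: e.color for e in a.legend}
        assert colour["Alpha"] != colour["Zed"]


class TestArcs:
    def _recs(self, scores, chrom="chr3"):
        return [
            InteractionRecord(
                GenomicInterval(chrom, 1000 * (i + 1), 1000 * (i + 1) + 100),
                GenomicInterval(chrom, 50_000 + 1000 * i, 50_000 + 1000 * i + 100),
                s,
            )
            for i, s in enumerate(scores)
        ]

    def test_apex_linear_in_score(self, big_map):
        rt = render_arcs(self._recs([2.0, 4.0]), big_map,
                         TrackSpec("arcs", arc_height_max=1.0))
        assert [g.y[1] for g in rt.glyphs] == pytest.approx([0.5, 1.0])

    def test_monotone_height_and_colour_intensity(self, big_map):
        """Brute-force over all pairs: higher score implies strictly higher
        apex and a colour at least as dark."""
        rng = np.random.default_rng(17)
        scores = list(np.round(rng.uniform(0.1, 9.0, 30), 3))
        rt = render_arcs(self._recs(scores), big_map, TrackSpec("arcs"))
        apexes = [g.y[1] for g in rt.glyphs]
        darkness = [1.0 - _luminance(g.style.color) for g in rt.glyphs]
        for i in range(len(scores)):
            for j in range(len(scores)):
                if scores[i] > scores[j]:
                    assert apexes[i] > apexes[j]
                    assert darkness[i] >= darkness[j]

    def test_cross_region_arc_spans_the_gap(self, big_map):
        rec = InteractionRecord(
            GenomicInterval("chr3", 90_000, 90_100),
            GenomicInterval("chr8", 1_000, 1_100),
            3.0,
        )
        rt = render_arcs([rec], big_map, TrackSpec("arcs"))
        (g,) = rt.glyphs
        gap_lo, gap_hi = big_map.segments[0][1], big_map.segments[1][0]
        assert g.x[0] < gap_lo < gap_hi < g.x[1]

    def test_all_zero_scores_use_minimum_visible_height(self, big_map):
        rt = render_arcs(self._recs([0.0, 0.0]), big_map,
                         TrackSpec("arcs", min_arc_height=0.07))
        assert [g.y[1] for g in rt.glyphs] == [0.07, 0.07]

    def test_unmappable_anchor_drops_interaction(self, big_map):
        rec = InteractionRecord(
            GenomicInterval("chr3", 1000, 1100),
            GenomicInterval("chrX", 1000, 1100),
            3.0,
        )
        rt = render_arcs([rec], big_map, TrackSpec("arcs"))
        assert rt.glyphs == []
        assert rt.meta["dropped"] == 1


def _max_overlap_depth(extents):
    """Brute-force chromatic number of an interval graph = max clique."""
    events = []
    for x0, x1 in extents:
        events += [(x0, 1), (x1, -1)]
    depth = best = 0
    for _, d in sorted(events, key=lambda e: (e[0], e[1])):
        depth += d
        best = max(best, depth)
    return best


class TestLinks:
    def _rec(self, a0, a1, b0, b1, chrom="chr3"):
        return InteractionRecord(
            GenomicInterval(chrom, a0, a1), GenomicInterval(chrom, b0, b1), 1.0
        )

    def test_disjoint_links_share_lane_zero(self, big_map):
        recs = [self._rec(0, 100, 5_000, 5_100), self._rec(50_000, 50_100, 60_000, 60_100)]
        rt = render_links(recs, big_map, TrackSpec("links"))
        assert rt.meta["lanes"] == 1

    def test_mutually_overlapping_links_get_distinct_lanes(self, big_map):
        recs = [
            self._rec(0, 100, 50_000, 50_100),
            self._rec(1_000, 1_100, 51_000, 51_100),
            self._rec(2_000, 2_100, 52_000, 52_100),
        ]
        rt = render_links(recs, big_map, TrackSpec("links"))
        assert rt.meta["lanes"] == 3

    def test_cross_region_connector_spans_gap(self, big_map):
        rec = InteractionRecord(
            GenomicInterval("chr3", 90_000, 90_100),
            GenomicInterval("chr8", 1_000, 1_100),
            1.0,
        )
        rt = render_links([rec], big_map, TrackSpec("links"))
        seg = [g for g in rt.glyphs if g.shape == "segment"]
        gap_lo, gap_hi = big_map.segments[0][1], big_map.segments[1][0]
        assert seg and seg[0].x[0] <= gap_lo and seg[0].x[1] >= gap_hi

    def test_greedy_lane_assignment_is_valid_and_optimal(self):
        """On 100 seeded random instances, no two overlapping extents share
        a lane (checked over all pairs) and the lane count equals the
        brute-force maximum overlap depth."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(1, 13))
            extents = []
            for _ in range(n):
                x0 = float(rng.uniform(0, 0.9))
                extents.append((x0, x0 + float(rng.uniform(0.01, 0.4))))
            lanes = _greedy_lanes(extents)
            for i in range(n):
                for j in range(i + 1, n):
                    if lanes[i] == lanes[j]:
                        (a0, a1), (b0, b1) = extents[i], extents[j]
                        assert a1 <= b0 or b1 <= a0
            assert max(lanes) + 1 == _max_overlap_depth(extents)


class TestHeatmap:
    def _recs(self, triples, chrom="chr3", bs=1000):
        return [
            ContactBinRecord(chrom, a, chrom, b, c, bs) for a, b, c in triples
        ]

    def test_diagonal_diamond_sits_on_the_axis(self, big_map):
        rt = render_heatmap(
            self._recs([(5000, 5000, 10)]), big_map,
            TrackSpec("heatmap", bin_size=1000),
        )
        (g,) = rt.glyphs
        assert min(g.y) == 0.0

    def test_counts_normalised_to_palette_and_background(self, big_map):
        from trackfig.render import BACKGROUND_COLOR, _palette_hex

        spec = TrackSpec("heatmap", bin_size=1000)
        rt = render_heatmap(
            self._recs([(5000, 9000, 0), (5000, 20_000, 10)]), big_map, spec
        )
        assert rt.glyphs[0].style.fill == BACKGROUND_COLOR
        assert rt.glyphs[1].style.fill == _palette_hex(spec.palette, 1.0)

    def test_diamond_height_proportional_to_bin_separation(self, big_map):
        spec = TrackSpec("heatmap", bin_size=1000)
        rt = render_heatmap(
            self._recs([(5000, 10_000, 1), (5000, 30_000, 1)]), big_map, spec
        )
        c0 = (max(rt.glyphs[0].y) + min(rt.glyphs[0].y)) / 2
        c1 = (max(rt.glyphs[1].y) + min(rt.glyphs[1].y)) / 2
        assert c1 / c0 == pytest.approx(25_000 / 5_000, rel=1e-6)

    def test_out_of_region_bins_ignored(self, big_map):
        rt = render_heatmap(
            self._recs([(5000, 5000, 3)], chrom="chrX"), big_map,
            TrackSpec("heatmap", bin_size=1000),
        )
        assert rt.glyphs == []


class TestGenes:
    def _gene(self, name, tx0, tx1, chrom="chr3", strand="+"):
        third = (tx1 - tx0) // 3
        return GeneModel(
            name, chrom, tx0, tx1, strand,
            ((tx0, tx0 + third), (tx1 - third, tx1)),
        )

    def test_non_overlapping_genes_share_one_row(self, big_map):
        genes = [self._gene("A", 20_000, 30_000), self._gene("B", 60_000, 70_000)]
        rt = render_genes(genes, big_map, TrackSpec("genes"))
        assert rt.meta["rows"] == 1

    def test_pairwise_overlapping_genes_get_three_rows(self, big_map):
        genes = [
            self._gene("A", 20_000, 60_000),
            self._gene("B", 25_000, 65_000),
            self._gene("C", 30_000, 70_000),
        ]
        rt = render_genes(genes, big_map, TrackSpec("genes"))
        assert rt.meta["rows"] == 3

    def test_row_packing_never_overlaps_and_is_optimal(self):
        """100 seeded random gene sets: exhaustive pairwise no-overlap check
        within each row, and row count equals the brute-force lower bound
        (maximum overlap depth of the packed extents)."""
        rs = RegionSet((GenomicInterval("chr3", 0, 1_000_000),))
        m = build_canvas_map(rs)
        rng = np.random.default_rng(31)
        from trackfig.render import CHAR_WIDTH

        for _ in range(100):
            n = int(rng.integers(1, 13))
            genes = []
            for k in range(n):
                tx0 = int(rng.integers(0, 900_000))
                tx1 = tx0 + int(rng.integers(10_000, 100_000))
                genes.append(self._gene(f"G{k}", tx0, min(tx1, 1_000_000)))
            rt = render_genes(genes, m, TrackSpec("genes"))
            extents = []
            for g in genes:
                bx0 = m.genome_to_canvas("chr3", g.tx_start)
                bx1 = m.genome_to_canvas("chr3", g.tx_end)
                lw = (len(g.name) + 1) * CHAR_WIDTH
                extents.append((bx0 - lw, bx1) if bx0 - lw >= 0 else (bx0, bx1 + lw))
            from trackfig.render import _greedy_lanes

            lanes = _greedy_lanes(extents)
            for i in range(n):
                for j in range(i + 1, n):
                    if lanes[i] == lanes[j]:
                        (a0, a1), (b0, b1) = extents[i], extents[j]
                        assert a1 <= b0 or b1 <= a0
            assert rt.meta["rows"] == _max_overlap_depth(extents)

    def test_clipped_gene_keeps_its_name_inside_the_panel(self, big_map):
        g = self._gene("EDGE", 90_000, 150_000)
        rt = render_genes([g], big_map, TrackSpec("genes"))
        (name,) = [t for t in rt.glyphs if t.shape == "text" and t.text == "EDGE"]
        assert 0.0 <= name.x[0] <= 1.0
        rects = [r for r in rt.glyphs if r.shape == "rect"]
        assert all(r.x[1] <= big_map.segments[0][1] + 1e-12 for r in rects)


class TestAnnotations:
    def test_highlight_box_translucent_bottom_layer(self, big_map):
        anns = [
            FeatureAnnotation(GenomicInterval("chr3", 10_000, 20_000), "highlight-box")
        ]
        rt = render_annotations(anns, big_map, TrackSpec("annotations"))
        (g,) = rt.glyphs
        assert g.layer == 0
        assert g.style.alpha < 1.0
        assert g.y == (0.0, 1.0)

    def test_vertical_marker_with_label(self, big_map):
        anns = [
            FeatureAnnotation(GenomicInterval("chr3", 5000, 5001),
                              "vertical-marker", "rsX")
        ]
        rt = render_annotations(anns, big_map, TrackSpec("annotations"))
        shapes = {g.shape for g in rt.glyphs}
        assert shapes == {"segment", "text"}
        seg = next(g for g in rt.glyphs if g.shape == "segment")
        assert seg.style.linestyle == "dashed"
        assert seg.x[0] == seg.x[1] == big_map.genome_to_canvas("chr3", 5000)

    def test_bracket_has_centred_label(self, big_map):
        anns = [
            FeatureAnnotation(GenomicInterval("chr3", 10_000, 20_000), "bracket", "LD")
        ]
        rt = render_annotations(anns, big_map, TrackSpec("annotations"))
        text = next(g for g in rt.glyphs if g.shape == "text")
        mid = (big_map.genome_to_canvas("chr3", 10_000)
               + big_map.genome_to_canvas("chr3", 20_000)) / 2
        assert text.x[0] == pytest.approx(mid)

    def test_outside_annotation_skipped_with_warning(self, big_map, caplog):
        import logging

        anns = [
            FeatureAnnotation(GenomicInterval("chrX", 5000, 5001),
                              "vertical-marker", "gone")
        ]
        with caplog.at_level(logging.WARNING):
            rt = render_annotations(anns, big_map, TrackSpec("annotations"))
        assert rt.glyphs == []
        assert rt.meta["skipped"] == 1
        assert "gone" in caplog.text


class TestCrossTrackProperties:
    def test_same_position_aligns_across_tracks(self, big_map):
        """A genomic position drawn by two different renderers lands on the
        same canvas x to < 1e-9 canvas units."""
        pos = 42_137
        assoc = render_association(
            [AssociationRecord("chr3", pos, 0.01)], big_map, TrackSpec("association")
        )
        ann = render_annotations(
            [FeatureAnnotation(GenomicInterval("chr3", pos, pos + 1),
                               "vertical-marker", "x")],
            big_map, TrackSpec("annotations"),
        )
        x_assoc = assoc.glyphs[0].x[0]
        x_ann = next(g for g in ann.glyphs if g.shape == "segment").x[0]
        assert abs(x_assoc - x_ann) < 1e-9

    def test_renderers_are_deterministic(self, big_map):
        recs = [
            AssociationRecord("chr3", 100 * i, 10.0 ** -(i % 8 + 0.5), typed=bool(i % 2),
                              r2=(i % 10) / 10)
            for i in range(1, 50)
        ]
        a = render_association(recs, big_map, TrackSpec("association"))
        b = render_association(recs, big_map, TrackSpec("association"))
        assert a.glyphs == b.glyphs
        assert a.legend == b.legend

    def test_glyphs_confined_to_segments_except_gap_crossers(self, big_map):
        recs = [
            SegmentationRecord("chr3", 0, 50_000, "A"),
            SegmentationRecord("chr8", 50_000, 100_000, "B"),
        ]
        rt = render_segmentation(recs, big_map, TrackSpec("segmentation"))
        seg_spans = big_map.segments
        for g in rt.glyphs:
            assert any(s0 - 1e-12 <= min(g.x) and max(g.x) <= s1 + 1e-12
                       for s0, s1 in seg_spans)
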