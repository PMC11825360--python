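"""Image geometry, ACT palette and rendering."""

import numpy as np
import pysam
import pytest

from svcompare.encoding import (ACT_PALETTE, BACKGROUND_COLOR,
                                SKELETON_COLOR, TRACK_HEIGHTS,
                                ImageGeometry, MappingConditionCounts,
                                act_color, encode_one_to_n, encode_pair,
                                min_detectable_af, render_act,
                                sketch_structure)
from svcompare.loci import discover_loci
from svcompare.signatures import extract_series
from svcompare.training import series_from_components
from svcompare.simulate import ComponentSpec


class TestPalette:
    def test_forward_color_is_the_published_triple(self):
        assert act_color("forward") == (135, 206, 255)

    @pytest.mark.parametrize("condition,expected", [
        ("reversed", (135, 106, 255)),          # second channel - 100
        ("duplicated", (135, 206, 155)),        # third channel - 100
        ("reverse_duplicated", (135, 106, 155)),  # both subtractions
    ])
    def test_derived_colors_follow_subtract_100_rule(self, condition,
                                                     expected):
        assert act_color(condition) == expected

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            act_color("chimeric")


class TestGeometry:
    @pytest.mark.parametrize("size,track,af", [(256, 25, 0.04),
                                               (512, 50, 0.02),
                                               (1024, 100, 0.01)])
    def test_track_height_and_af_floor_table(self, size, track, af):
        g = ImageGeometry(image_size=size, chrom="chr1", win_start=0,
                          win_end=10_000)
        assert g.track_height == TRACK_HEIGHTS[size] == track
        assert g.min_detectable_af == pytest.approx(af)
        assert min_detectable_af(size) == pytest.approx(af)

    def test_unsupported_size_rejected(self):
        with pytest.raises(ValueError):
            ImageGeometry(image_size=300, chrom="chr1", win_start=0,
                          win_end=1000)

    @pytest.mark.parametrize("win", [(1000, 3000), (0, 50_000), (500, 900)])
    def test_pixel_reference_roundtrip_within_one_pixel(self, win):
        g = ImageGeometry(image_size=512, chrom="chr1", win_start=win[0],
                          win_end=win[1])
        rng = np.random.default_rng(1)
        for pos in rng.integers(win[0], win[1], 50):
            err = abs(g.pos_of(g.x_of(int(pos))) - int(pos))
            assert err <= g.bp_per_pixel + 1

    def test_geometry_json_roundtrip(self):
        g = ImageGeometry(image_size=256, chrom="chr1", win_start=100,
                          win_end=5000, read_axis=(10, 4800))
        g2 = ImageGeometry.from_json(g.to_json())
        assert g2 == g


class TestRenderAct:
    def _geom(self, size=512):
        return ImageGeometry(image_size=size, chrom="chr1", win_start=0,
                             win_end=5000)

    def _render(self, counts, norm, size=512):
        g = self._geom(size)
        pixels = np.zeros((size, size, 3), dtype=np.uint8)
        render_act(MappingConditionCounts(counts=counts, norm=norm), g,
                   "case", pixels)
        return g, pixels

    def test_single_condition_saturates_track(self):
        counts = np.zeros((4, 5000), dtype=np.int32)
        counts[0] = 20
        g, px = self._render(counts, norm=20)
        col = px[:, 100]
        track = col[g.image_size - g.track_height:]
        assert (track == ACT_PALETTE["forward"]).all(axis=1).sum() == g.track_height

    def test_mixed_conditions_stack_proportionally(self):
        counts = np.zeros((4, 5000), dtype=np.int32)
        counts[0] = 10  # forward
        counts[1] = 10  # reversed
        g, px = self._render(counts, norm=20)
        T = g.track_height
        track = px[g.image_size - T:, 100]
        n_fwd = (track == ACT_PALETTE["forward"]).all(axis=1).sum()
        n_rev = (track == ACT_PALETTE["reversed"]).all(axis=1).sum()
        assert n_fwd == n_rev == T // 2
        # stacking order: forward sits at the inner (upper) edge of the
        # bottom track
        assert tuple(track[0]) == ACT_PALETTE["forward"]

    def test_zero_coverage_leaves_empty_columns(self):
        counts = np.zeros((4, 5000), dtype=np.int32)
        _, px = self._render(counts, norm=1)
        assert (px == 0).all()


class TestSketch:
    def test_empty_series_rejected(self):
        from svcompare.signatures import SymbolSeries
        with pytest.raises(ValueError):
            sketch_structure(SymbolSeries(read_name="r"), 0, 1000, "chr1")

    def test_deletion_read_sketches_two_diagonals_with_gap(self):
        comps = [ComponentSpec("DEL", 5000, 6000)]
        series = series_from_components(comps, 1000, 10_000, chrom="chr1")
        elems = sketch_structure(series, 1000, 10_000, "chr1")
        kinds = [e.kind for e in elems]
        assert kinds == ["M", "M"]
        assert not elems[0].aberrant
        assert elems[1].ref_start - elems[0].ref_end == 1000

    def test_inversion_read_sketches_antidiagonal(self):
        comps = [ComponentSpec("INV", 5000, 6000)]
        series = series_from_components(comps, 1000, 10_000, chrom="chr1")
        elems = sketch_structure(series, 1000, 10_000, "chr1")
        assert [e.kind for e in elems] == ["M", "V", "M"]
        assert elems[1].aberrant

    def test_unmapped_insertion_leaves_vertical_gap_element(self):
        comps = [ComponentSpec("INS", 5000, 5000, seq="ACGT" * 100)]
        series = series_from_components(comps, 1000, 10_000, chrom="chr1")
        elems = sketch_structure(series, 1000, 10_000, "chr1")
        i = [e for e in elems if e.kind == "I"]
        assert len(i) == 1
        assert i[0].aberrant
        assert i[0].read_end - i[0].read_start == 400


@pytest.fixture(scope="module")
def panel_loci(panel_scenario):
    with pysam.AlignmentFile(panel_scenario.bams["case"]) as bam:
        series = extract_series(bam, "chrS", 0, panel_scenario.ref_len)
    return discover_loci(series, min_support=10)


class TestEncodePair:
    def _encode(self, scen, locus, size=512):
        with pysam.AlignmentFile(scen.bams["case"]) as case, \
                pysam.AlignmentFile(scen.bams["control"]) as ctrl, \
                pysam.FastaFile(scen.ref_path) as ref:
            return encode_pair(locus, case, ctrl, image_size=size,
                               ref_fasta=ref)

    def test_rendered_colors_come_only_from_the_fixed_palette(
            self, panel_scenario, panel_loci):
        img = self._encode(panel_scenario, panel_loci[0])
        colors = {tuple(c) for c in img.pixels.reshape(-1, 3)}
        allowed = (set(map(tuple, ACT_PALETTE.values()))
                   | {BACKGROUND_COLOR, SKELETON_COLOR})
        assert colors <= allowed

    def test_case_only_deletion_contrasts_with_full_control_track(
            self, panel_scenario, panel_loci):
        # panel controls carry no variant: the control track stays full
        # height over the gap while the case track shows the deficit
        locus = next(l for l in panel_loci
                     if l.consensus_signature == "MM")
        img = self._encode(panel_scenario, locus)
        g = img.geometry
        S, T = g.image_size, g.track_height
        mid = S // 2

        def act_height(col, track):
            rows = img.pixels[:T, col] if track == "control" \
                else img.pixels[S - T:, col]
            return (rows != 0).any(axis=1).sum()

        assert act_height(mid, "control") >= T - 3
        assert act_height(mid, "case") <= T * 0.75

    def test_insertion_locus_renders_vertical_tracks_beside_gap(
            self, panel_scenario, panel_loci):
        locus = next(l for l in panel_loci
                     if l.consensus_signature == "MIM")
        img = self._encode(panel_scenario, locus)
        g = img.geometry
        assert g.insertion_tracks
        tr = g.insertion_tracks[0]
        case_cols = img.pixels[tr.y0:tr.y1, tr.x:tr.x + g.track_height]
        fwd = (case_cols == ACT_PALETTE["forward"]).all(axis=2)
        assert fwd.any()  # case carriers produce a right-side bar

    def test_encoding_is_deterministic(self, panel_scenario, panel_loci):
        a = self._encode(panel_scenario, panel_loci[0])
        b = self._encode(panel_scenario, panel_loci[0])
        assert np.array_equal(a.pixels, b.pixels)

    def test_deletion_deficit_tracks_allele_fraction(self, panel_scenario,
                                                     panel_loci):
        # AF 0.5 deletion: case ACT height over the gap ~ (1-f) of track
        for locus in panel_loci:
            if locus.consensus_signature != "MM":
                continue
            img = self._encode(panel_scenario, locus)
            g = img.geometry
            S, T = g.image_size, g.track_height
            mid = S // 2
            rows = img.pixels[S - T:, mid]
            h = (rows != 0).any(axis=1).sum()
            f = 1 - h / T
            assert f == pytest.approx(0.5, abs=1 / T + 0.12) or \
                f == pytest.approx(1.0, abs=1 / T + 0.12)

    def test_zero_case_coverage_is_an_error(self, panel_scenario, panel_loci,
                                            tmp_path, sam_header):
        empty = tmp_path / "empty.bam"
        hdr = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chrS", "LN": panel_scenario.ref_len}]})
        with pysam.AlignmentFile(empty, "wb", header=hdr):
            pass
        pysam.index(str(empty))
        locus = panel_loci[0]
        rep_series = locus.dominant_cluster().reads[0]
        with pysam.AlignmentFile(empty) as case, \
                pysam.AlignmentFile(panel_scenario.bams["control"]) as ctrl:
            with pytest.raises(ValueError, match="coverage"):
                encode_pair(locus, case, ctrl, representative=rep_series)

    def test_zero_control_coverage_flags_low_confidence(
            self, panel_scenario, panel_loci, tmp_path):
        empty = tmp_path / "empty2.bam"
        hdr = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chrS", "LN": panel_scenario.ref_len}]})
        with pysam.AlignmentFile(empty, "wb", header=hdr):
            pass
        pysam.index(str(empty))
        with pysam.AlignmentFile(panel_scenario.bams["case"]) as case, \
                pysam.AlignmentFile(empty) as ctrl:
            img = encode_pair(panel_loci[0], case, ctrl)
        assert img.low_confidence
        track = img.pixels[:img.geometry.track_height].reshape(-1, 3)
        for color in ACT_PALETTE.values():
            assert not (track == color).all(axis=1).any()


class TestOneToN:
    def test_n_controls_give_n_images_with_identical_case_content(
            self, panel_scenario, panel_loci):
        locus = panel_loci[0]
        with pysam.AlignmentFile(panel_scenario.bams["case"]) as case, \
                pysam.AlignmentFile(panel_scenario.bams["control"]) as ctrl:
            imgs = encode_one_to_n(locus, case, [ctrl, ctrl, ctrl])
            assert len(imgs) == 3
            S, T = imgs[0].geometry.image_size, imgs[0].geometry.track_height
            for img in imgs[1:]:
                assert np.array_equal(img.pixels[T:], imgs[0].pixels[T:])

            single = encode_one_to_n(locus, case, [ctrl])
            pair = encode_pair(locus, case, ctrl)
            assert np.array_equal(single[0].pixels, pair.pixels)

    def test_empty_control_list_rejected(self, panel_scenario, panel_loci):
        with pysam.AlignmentFile(panel_scenario.bams["case"]) as case:
            with pytest.raises(ValueError):
                encode_one_to_n(panel_loci[0], case, [])
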