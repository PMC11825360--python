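"""Mask decoding, genotyping, comparison categories and trio metrics."""

import numpy as np
import pytest

from svcompare.encoding import ImageGeometry, InsertionTrack
from svcompare.interpret import (GERMLINE, NEW_ALLELE, NEW_BREAKPOINT,
                                 NEW_COMPONENT, SVCall, SVComponent,
                                 af_to_genotype, call_de_novo, call_somatic,
                                 compare_component, join_components,
                                 mask_to_components, mendelian_consistency,
                                 twin_discordancy)
from svcompare.masks import DEL, REF, SegmentationMask, TruthComponent, \
    make_truth_mask


def geom(size=512, win=(10_000, 20_000)):
    return ImageGeometry(image_size=size, chrom="chr1", win_start=win[0],
                         win_end=win[1])


def blank_mask(g):
    S, T = g.image_size, g.track_height
    labels = np.zeros((S, S), dtype=np.uint8)
    labels[:T] = REF
    labels[S - T:] = REF
    return labels


class TestMaskToComponents:
    def test_full_height_region_decodes_af_one_and_span(self):
        g = geom()
        labels = blank_mask(g)
        x0, x1 = g.x_of(12_000), g.x_of(13_000)
        labels[g.image_size - g.track_height:, x0:x1] = DEL
        comps = mask_to_components(SegmentationMask(labels=labels), g)
        assert len(comps) == 1
        c = comps[0]
        assert (c.component_type, c.track) == ("DEL", "case")
        assert c.allele_fraction == 1.0
        assert abs(c.ref_start - 12_000) <= 2 * g.bp_per_pixel
        assert abs(c.ref_end - 13_000) <= 2 * g.bp_per_pixel

    def test_half_height_region_decodes_af_half(self):
        g = geom(512)  # track 50 px
        labels = blank_mask(g)
        x0, x1 = g.x_of(12_000), g.x_of(13_000)
        labels[g.image_size - 25:, x0:x1] = DEL  # 25 of 50 px
        comps = mask_to_components(SegmentationMask(labels=labels), g)
        assert comps[0].allele_fraction == pytest.approx(0.5)

    def test_one_pixel_band_in_100px_track_decodes_af_001(self):
        g = geom(1024)  # track 100 px
        labels = blank_mask(g)
        x0, x1 = g.x_of(12_000), g.x_of(13_000)
        labels[g.image_size - 1:, x0:x1] = DEL
        comps = mask_to_components(SegmentationMask(labels=labels), g)
        assert comps[0].allele_fraction == pytest.approx(0.01)

    def test_two_disjoint_regions_make_two_components(self):
        g = geom()
        labels = blank_mask(g)
        S, T = g.image_size, g.track_height
        labels[S - T:, g.x_of(11_000):g.x_of(12_000)] = DEL
        labels[S - T:, g.x_of(15_000):g.x_of(16_000)] = DEL
        comps = mask_to_components(SegmentationMask(labels=labels), g)
        # independent connected-component check: two far-apart blocks
        assert len(comps) == 2
        assert comps[0].ref_end < comps[1].ref_start

    def test_empty_mask_decodes_nothing(self):
        g = geom()
        comps = mask_to_components(
            SegmentationMask(labels=blank_mask(g)), g)
        assert comps == []

    def test_insertion_track_width_decodes_af(self):
        g = geom(512)
        g.insertion_tracks.append(InsertionTrack(ref_pos=15_000,
                                                 x=g.x_of(15_000),
                                                 y0=200, y1=240,
                                                 kind_hint="INS"))
        labels = blank_mask(g)
        tr = g.insertion_tracks[0]
        from svcompare.masks import INS
        labels[200:240, tr.x:tr.x + 25] = INS  # 25 of 50 px wide
        comps = mask_to_components(SegmentationMask(labels=labels), g)
        assert len(comps) == 1
        assert comps[0].component_type == "INS"
        assert comps[0].allele_fraction == pytest.approx(0.5)
        assert comps[0].insertion_length is not None


class TestGenotyping:
    @pytest.mark.parametrize("af,gt", [(1.0, "1/1"), (0.5, "0/1"),
                                       (0.0, "0/0"), (0.24, "0/0"),
                                       (0.25, "0/1"), (0.75, "1/1")])
    def test_af_bands(self, af, gt):
        assert af_to_genotype(af) == gt

    @pytest.mark.parametrize("af", [-0.1, 1.5])
    def test_out_of_range_rejected(self, af):
        with pytest.raises(ValueError):
            af_to_genotype(af)

    def test_genotype_monotone_in_af(self):
        order = {"0/0": 0, "0/1": 1, "1/1": 2}
        gts = [order[af_to_genotype(af)] for af in np.linspace(0, 1, 101)]
        assert gts == sorted(gts)

    @pytest.mark.parametrize("track", [25, 50, 100])
    def test_af_floor_is_never_homozygous(self, track):
        assert af_to_genotype(1 / track) != "1/1"


def _comp(ctype="DEL", start=12_000, end=13_000, af=0.5, track="case"):
    return SVComponent(component_type=ctype, chrom="chr1", ref_start=start,
                       ref_end=end, allele_fraction=af, track=track)


class TestCompareComponent:
    BP_TOL, AF_TOL = 100, 0.1

    def _cmp(self, case, controls):
        return compare_component(case, controls, self.BP_TOL, self.AF_TOL)

    def test_empty_control_is_new_component(self):
        e = self._cmp(_comp(), [])
        assert e.category == NEW_COMPONENT
        assert e.genotype_control == "0/0"

    def test_same_span_same_af_is_germline(self):
        e = self._cmp(_comp(af=0.5), [_comp(af=0.5, track="control")])
        assert e.category == GERMLINE

    def test_same_span_different_af_is_new_allele(self):
        e = self._cmp(_comp(af=1.0), [_comp(af=0.5, track="control")])
        assert e.category == NEW_ALLELE
        assert (e.genotype_case, e.genotype_control) == ("1/1", "0/1")

    def test_shifted_span_is_new_breakpoint(self):
        ctrl = _comp(start=12_400, end=13_400, af=0.5, track="control")
        e = self._cmp(_comp(af=0.5), [ctrl])
        assert e.category == NEW_BREAKPOINT

    def test_precedence_breakpoint_beats_allele(self):
        # both breakpoints and AF differ: New breakpoint wins
        ctrl = _comp(start=12_400, end=13_400, af=1.0, track="control")
        e = self._cmp(_comp(af=0.5), [ctrl])
        assert e.category == NEW_BREAKPOINT

    def test_different_type_is_new_component(self):
        e = self._cmp(_comp(), [_comp(ctype="INV", track="control")])
        assert e.category == NEW_COMPONENT

    def test_exactly_one_category_assigned(self):
        for ctrl in ([], [_comp(track="control")],
                     [_comp(af=1.0, track="control")],
                     [_comp(start=12_500, end=13_500, track="control")]):
            e = self._cmp(_comp(), ctrl)
            assert e.category in (GERMLINE, NEW_COMPONENT, NEW_BREAKPOINT,
                                  NEW_ALLELE)


class TestJoinComponents:
    def test_single_component_is_ssv_type(self):
        assert join_components([_comp("DEL")]) == "DEL"

    def test_two_components_joined_in_reference_order(self):
        comps = [_comp("INV", 13_000, 14_000), _comp("DEL", 12_000, 13_000)]
        assert join_components(comps) == "DEL+INV"

    def test_insertion_sorts_before_deletion_at_same_breakpoint(self):
        ins = SVComponent("INS", "chr1", 12_000, 12_001, 0.5, "case",
                          insertion_length=500)
        d = _comp("DEL", 12_000, 13_000)
        assert join_components([d, ins]) == "INS+DEL"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            join_components([])


def _call_with_categories(categories_by_control, support=15, af=0.5):
    comps = [_comp(af=af)]
    call = SVCall(chrom="chr1", ref_start=12_000, ref_end=13_000,
                  joined_type="DEL", components=comps, support=support,
                  allele_fraction=af)
    from svcompare.interpret import ComparisonEntry
    for name, cats in categories_by_control.items():
        call.comparisons[name] = [
            ComparisonEntry(c, "0/1", "0/0", name) for c in cats]
    return call


class TestDeNovoRule:
    def test_new_component_vs_both_parents_is_de_novo(self):
        call = _call_with_categories({"father": [NEW_COMPONENT],
                                      "mother": [NEW_COMPONENT]})
        assert call_de_novo(call)

    def test_germline_vs_one_parent_is_not(self):
        call = _call_with_categories({"father": [NEW_COMPONENT],
                                      "mother": [GERMLINE]})
        assert not call_de_novo(call)

    def test_new_allele_vs_one_parent_is_not(self):
        call = _call_with_categories({"father": [NEW_ALLELE],
                                      "mother": [NEW_COMPONENT]})
        assert not call_de_novo(call)

    def test_single_control_rejected(self):
        call = _call_with_categories({"father": [NEW_COMPONENT]})
        with pytest.raises(ValueError):
            call_de_novo(call)


class TestSomaticRule:
    def test_tumor_only_component_above_floors_is_somatic(self):
        call = _call_with_categories({"normal": [NEW_COMPONENT]},
                                     support=3, af=0.05)
        assert call_somatic(call, min_support=2, min_af=0.01)

    def test_af_below_floor_is_not_callable(self):
        call = _call_with_categories({"normal": [NEW_COMPONENT]},
                                     support=3, af=0.005)
        assert not call_somatic(call, min_support=2, min_af=0.01)

    def test_germline_in_normal_is_not_somatic(self):
        call = _call_with_categories({"normal": [GERMLINE]},
                                     support=30, af=0.5)
        assert not call_somatic(call)

    def test_support_floor_enforced(self):
        call = _call_with_categories({"normal": [NEW_COMPONENT]},
                                     support=1, af=0.05)
        assert not call_somatic(call, min_support=2)


class TestTrioMetrics:
    def test_het_child_from_hom_parents_consistent(self):
        assert mendelian_consistency([("0/1", "1/1", "0/0")]) == 1.0

    def test_hom_child_needs_alt_from_both(self):
        assert mendelian_consistency([("1/1", "0/0", "0/1")]) == 0.0

    def test_rate_is_fractional(self):
        records = [("0/1", "0/1", "0/0"), ("0/1", "0/0", "0/1"),
                   ("1/1", "0/1", "0/1"), ("1/1", "0/0", "0/0")]
        assert mendelian_consistency(records) == 0.75

    def test_identical_twins_have_zero_discordancy(self):
        assert twin_discordancy([("0/1", "0/1")] * 50) == 0.0

    def test_one_in_hundred_differs(self):
        records = [("0/1", "0/1")] * 99 + [("0/1", "1/1")]
        assert twin_discordancy(records) == pytest.approx(0.01)

    def test_het_vs_hom_counts_as_discordant(self):
        assert twin_discordancy([("0/1", "1/1")]) == 1.0


class TestRoundtrip:
    """Truth -> mask -> components recovers the truth up to quantisation."""

    @pytest.mark.parametrize("size", [256, 512, 1024])
    @pytest.mark.parametrize("af", [0.1, 0.5, 1.0])
    def test_deletion_roundtrip(self, size, af):
        from svcompare.loci import CandidateLocus
        from svcompare.encoding import build_geometry, EncodedImage
        from svcompare.simulate import ComponentSpec
        from svcompare.training import series_from_components

        if af < 1 / {256: 25, 512: 50, 1024: 100}[size]:
            pytest.skip("below representable floor")
        comps = [ComponentSpec("DEL", 50_000, 51_000)]
        series = series_from_components(comps, 45_000, 56_000, chrom="chr1")
        locus = CandidateLocus(chrom="chr1", ref_start=50_000, ref_end=51_000)
        g, elems = build_geometry(locus, series, size)
        img = EncodedImage(pixels=np.zeros((size, size, 3), np.uint8),
                           geometry=g, skeleton=elems)
        mask = make_truth_mask(img, [TruthComponent("DEL", 50_000, 51_000,
                                                    af=af)], [])
        comps_out = [c for c in mask_to_components(mask, g)
                     if c.track == "case"]
        assert len(comps_out) == 1
        c = comps_out[0]
        assert c.component_type == "DEL"
        assert abs(c.allele_fraction - af) <= 1 / g.track_height
        assert abs(c.ref_start - 50_000) <= g.bp_per_pixel + 1
        assert abs(c.ref_end - 51_000) <= g.bp_per_pixel + 1
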