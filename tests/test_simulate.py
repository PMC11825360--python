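"""Simulator: references, haplotypes, fabricated alignments, scoring."""

import numpy as np
import pysam
import pytest

from svcompare.signatures import extract_series
from svcompare.simulate import (ComponentSpec, TruthVariant, build_haplotype,
                                csv_subcomponent_accuracy, score_calls,
                                simulate_reference, synthesize_alignments)


class TestReference:
    def test_same_seed_same_sequence(self):
        assert simulate_reference(10_000, seed=1) == \
            simulate_reference(10_000, seed=1)

    def test_different_seed_differs(self):
        assert simulate_reference(10_000, seed=1) != \
            simulate_reference(10_000, seed=2)

    def test_gc_content_near_half(self):
        seq = simulate_reference(1_000_000, seed=3)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02


class TestHaplotypes:
    def _ref(self, n=50_000, seed=0):
        seq = simulate_reference(n, seed)
        return seq, np.frombuffer(seq.encode(), dtype=np.uint8)

    def test_deletion_shortens_haplotype(self):
        seq, arr = self._ref()
        hap = build_haplotype(len(seq), arr, [ComponentSpec("DEL", 10_000,
                                                            11_000)])
        assert hap.length == len(seq) - 1000

    def test_insertion_lengthens_haplotype(self):
        seq, arr = self._ref()
        hap = build_haplotype(len(seq), arr,
                              [ComponentSpec("INS", 10_000, 10_000,
                                             seq="A" * 700)])
        assert hap.length == len(seq) + 700

    def test_duplication_adds_one_copy(self):
        seq, arr = self._ref()
        hap = build_haplotype(len(seq), arr, [ComponentSpec("DUP", 10_000,
                                                            10_400)])
        assert hap.length == len(seq) + 400

    def test_complex_variant_applies_all_edits(self):
        seq, arr = self._ref()
        hap = build_haplotype(len(seq), arr,
                              [ComponentSpec("INV", 10_000, 10_500),
                               ComponentSpec("DEL", 10_500, 11_200)])
        assert hap.length == len(seq) - 700

    def test_overlapping_components_rejected(self):
        seq, arr = self._ref()
        with pytest.raises(ValueError, match="overlap"):
            build_haplotype(len(seq), arr,
                            [ComponentSpec("DEL", 10_000, 11_000),
                             ComponentSpec("INV", 10_500, 11_500)])


@pytest.fixture(scope="module")
def het_del_bam(tmp_path_factory):
    seq = simulate_reference(60_000, seed=7)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    haps = [build_haplotype(len(seq), arr,
                            [ComponentSpec("DEL", 30_000, 31_000)]),
            build_haplotype(len(seq), arr, [])]
    bam = tmp_path_factory.mktemp("sim") / "het.bam"
    meta = synthesize_alignments("chrS", seq, haps, coverage=40,
                                 out_bam=bam, read_length=12_000,
                                 af_mode="binomial", seed=5)
    return bam, meta


class TestSynthesizedAlignments:
    def test_carrier_fraction_binomial_around_af(self, het_del_bam):
        _, meta = het_del_bam
        carriers = sum(m.hap == 0 for m in meta)
        n = len(meta)
        sigma = np.sqrt(n * 0.25)
        assert abs(carriers - 0.5 * n) <= 3 * sigma

    def test_signature_recovery_on_perfect_reads(self, het_del_bam):
        bam, _ = het_del_bam
        with pysam.AlignmentFile(bam) as fh:
            series = extract_series(fh, "chrS", 0, 60_000)
        spanning = [s for s in series
                    if s.ref_extent and s.ref_extent[1] < 29_500
                    and s.ref_extent[2] > 31_500]
        carriers = [s for s in spanning if "h0" in s.read_name]
        assert carriers
        good = sum(s.signature == "MM" for s in carriers)
        assert good / len(carriers) >= 0.99
        normals = [s for s in spanning if "h1" in s.read_name]
        assert all(s.signature == "M" for s in normals)

    def test_same_seed_reproduces_reads(self, tmp_path):
        seq = simulate_reference(30_000, seed=1)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        haps = [build_haplotype(len(seq), arr, [])]
        m1 = synthesize_alignments("chrS", seq, haps, 10,
                                   tmp_path / "a.bam", read_length=8000,
                                   seed=3)
        m2 = synthesize_alignments("chrS", seq, haps, 10,
                                   tmp_path / "b.bam", read_length=8000,
                                   seed=3)
        assert [(m.name, m.ext_lo, m.ext_hi) for m in m1] == \
            [(m.name, m.ext_lo, m.ext_hi) for m in m2]

    def test_hifi_like_errors_leave_signatures_intact(self, tmp_path):
        seq = simulate_reference(40_000, seed=11)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        haps = [build_haplotype(len(seq), arr,
                                [ComponentSpec("DEL", 20_000, 20_800)])]
        bam = tmp_path / "err.bam"
        synthesize_alignments("chrS", seq, haps, coverage=20, out_bam=bam,
                              read_length=12_000,
                              error_profile="hifi_like", seed=9)
        with pysam.AlignmentFile(bam) as fh:
            series = extract_series(fh, "chrS", 0, 40_000)
        spanning = [s for s in series
                    if s.ref_extent and s.ref_extent[1] < 19_500
                    and s.ref_extent[2] > 21_300]
        assert spanning
        good = sum(s.signature == "MM" for s in spanning)
        assert good / len(spanning) >= 0.99


def _tv(vid, comps, stratum=""):
    return TruthVariant(variant_id=vid, chrom="chrS", components=comps,
                        stratum=stratum)


class _FakeCall:
    def __init__(self, chrom, start, end, joined_type):
        self.chrom, self.ref_start, self.ref_end = chrom, start, end
        self.joined_type = joined_type


class TestScoring:
    def _truth(self):
        return [_tv("v0", [ComponentSpec("DEL", 10_000, 11_000)]),
                _tv("v1", [ComponentSpec("INV", 50_000, 51_000),
                           ComponentSpec("DEL", 51_000, 51_700)])]

    def test_perfect_calls_score_f1_one(self):
        calls = [_FakeCall("chrS", 10_000, 11_000, "DEL"),
                 _FakeCall("chrS", 50_000, 51_700, "INV+DEL")]
        res = score_calls(calls, self._truth())
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_empty_calls_zero_recall(self):
        res = score_calls([], self._truth())
        assert res.recall == 0.0

    def test_half_matched_uses_harmonic_mean(self):
        calls = [_FakeCall("chrS", 10_000, 11_000, "DEL"),
                 _FakeCall("chrS", 200_000, 201_000, "DEL")]
        res = score_calls(calls, self._truth())
        assert res.precision == 0.5
        assert res.recall == 0.5
        assert res.f1 == pytest.approx(2 * 0.25 / 1.0)

    def test_breakpoint_tolerance_enforced(self):
        calls = [_FakeCall("chrS", 11_000, 12_000, "DEL")]  # 1 kb off
        res = score_calls(calls, self._truth(), bp_tol=500)
        assert res.recall == 0.0

    def test_subcomponent_accuracy_flags_missing_component(self):
        truth = self._truth()
        good = _FakeCall("chrS", 50_000, 51_700, "INV+DEL")
        partial = _FakeCall("chrS", 50_000, 51_700, "DEL")
        assert csv_subcomponent_accuracy([(good, truth[1])]) == 1.0
        assert csv_subcomponent_accuracy([(partial, truth[1])]) == 0.0

    def test_subcomponent_accuracy_arithmetic(self):
        truth = self._truth()
        pairs = [(_FakeCall("chrS", 50_000, 51_700, "INV+DEL"), truth[1])] * 3
        pairs += [(_FakeCall("chrS", 50_000, 51_700, "INV"), truth[1])]
        assert csv_subcomponent_accuracy(pairs) == 0.75
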