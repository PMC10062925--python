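import math

import numpy as np
import pysam
import pytest

from methylhet.alignment_io import (
    attach_methylation_tag,
    parse_methylation_calls,
    stream_methyl_reads,
)
from methylhet.simulate import (
    LocusConfig,
    analytic_measures,
    build_reference,
    iid_epiallele_probs,
    mixture_epiallele_probs,
    simulate_alignments,
    trim_calls_3prime,
    trim_read_3prime,
)

from conftest import make_segment

HALF_HALF = mixture_epiallele_probs(4, {0b0000: 0.5, 0b1111: 0.5})


def locus(positions=(100, 104, 108, 112), probs=HALF_HALF, depth=50,
          read_length=30, chrom="chr1", call_error=0.0):
    return LocusConfig(chrom=chrom, cpg_positions=tuple(positions),
                       epiallele_probs=tuple(probs), depth=depth,
                       read_length=read_length, call_error=call_error)


class TestLocusConfig:
    def test_probability_vector_validated(self):
        with pytest.raises(ValueError):
            locus(probs=(0.5,) * 4)
        with pytest.raises(ValueError):
            locus(probs=tuple([2.0] + [0.0] * 15))

    def test_cpg_spacing_validated(self):
        with pytest.raises(ValueError):
            locus(positions=(100, 101, 104, 108))


class TestAnalyticMeasures:
    def test_two_complementary_patterns(self):
        gt = analytic_measures(HALF_HALF, positions=(100, 104, 108, 112))
        assert gt.pdr == 0.0
        assert gt.pm == (0.5,)
        assert gt.me == (0.25,)
        assert gt.fdrp == pytest.approx(0.5)
        assert gt.qfdrp == pytest.approx(0.5)
        assert gt.mhl == pytest.approx(0.5)
        assert gt.lpmd == 0.0

    def test_single_fully_methylated_pattern(self):
        probs = mixture_epiallele_probs(4, {0b1111: 1.0})
        gt = analytic_measures(probs)
        assert (gt.pdr, gt.lpmd, gt.fdrp, gt.qfdrp) == (0.0, 0.0, 0.0, 0.0)
        assert gt.pm == (0.0,) and gt.me == (0.0,)
        assert gt.mhl == 1.0

    def test_single_fully_unmethylated_pattern(self):
        probs = mixture_epiallele_probs(4, {0b0000: 1.0})
        assert analytic_measures(probs).mhl == 0.0

    def test_uniform_sixteen(self):
        gt = analytic_measures([1 / 16] * 16)
        assert gt.pm == (pytest.approx(0.9375),)
        assert gt.me == (pytest.approx(1.0),)
        assert gt.pdr == pytest.approx(14 / 16)

    def test_iid_lpmd_is_2theta_1_minus_theta(self):
        theta = 0.3
        gt = analytic_measures(iid_epiallele_probs(5, theta),
                               positions=(0, 4, 8, 12, 16))
        assert gt.lpmd == pytest.approx(2 * theta * (1 - theta))

    def test_lpmd_respects_distance_window(self):
        gt = analytic_measures(HALF_HALF, positions=(0, 20, 40, 60))
        assert gt.lpmd is None

    def test_invalid_probs_raise(self):
        with pytest.raises(ValueError):
            analytic_measures([0.5, 0.6])
        with pytest.raises(ValueError):
            analytic_measures([0.5, 0.5, 0.0])  # not a power of two


class TestSimulateAlignments:
    def test_deterministic_output(self, tmp_path):
        cfgs = [locus(depth=20)]
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        simulate_alignments(cfgs, seed=11, sam_path=str(p1), reverse_fraction=0.5)
        simulate_alignments(cfgs, seed=11, sam_path=str(p2), reverse_fraction=0.5)
        assert p1.read_bytes() == p2.read_bytes()

    def test_depth_zero_header_only(self, tmp_path):
        path = tmp_path / "empty.sam"
        simulate_alignments([locus(depth=0)], seed=0, sam_path=str(path))
        with pysam.AlignmentFile(str(path)) as af:
            assert list(af) == []

    def test_output_is_sorted_and_parseable(self, tmp_path):
        cfgs = [locus(), locus(positions=(500, 502, 504, 510), chrom="chr2")]
        path = tmp_path / "sim.sam"
        simulate_alignments(cfgs, seed=3, sam_path=str(path), reverse_fraction=0.3)
        reads = list(stream_methyl_reads(str(path)))
        assert len(reads) == 100

    def test_overlapping_loci_rejected(self, tmp_path):
        cfgs = [locus(), locus(positions=(110, 114, 118, 122))]
        with pytest.raises(ValueError, match="overlap"):
            simulate_alignments(cfgs, seed=0, sam_path=str(tmp_path / "x.sam"))

    def test_empirical_pattern_frequencies(self, tmp_path):
        cfg = locus(probs=[1 / 16] * 16, depth=160, read_length=20)
        path = tmp_path / "sim.sam"
        simulate_alignments([cfg], seed=5, sam_path=str(path))
        counts = np.zeros(16)
        for r in stream_methyl_reads(str(path)):
            assert r.positions == cfg.cpg_positions
            pattern = sum(1 << i for i, (_, s) in enumerate(r.calls) if s)
            counts[pattern] += 1
        p = counts / counts.sum()
        se = math.sqrt((1 / 16) * (15 / 16) / 160)
        assert np.all(np.abs(p - 1 / 16) < 3.5 * se)

    def test_strand_collapse_same_coordinates(self, tmp_path):
        cfg = locus(depth=60, read_length=30)
        path = tmp_path / "sim.sam"
        simulate_alignments([cfg], seed=2, sam_path=str(path), reverse_fraction=0.5)
        for r in stream_methyl_reads(str(path)):
            assert set(r.positions) <= set(cfg.cpg_positions)

    def test_ground_truth_matches_analytic(self, tmp_path):
        cfg = locus()
        truths = simulate_alignments([cfg], seed=0,
                                     sam_path=str(tmp_path / "s.sam"))
        assert truths[0] == analytic_measures(cfg.epiallele_probs,
                                              cfg.cpg_positions)


class TestTagRoundTrip:
    @pytest.mark.parametrize("reverse_fraction", [0.0, 1.0, 0.5])
    def test_simulate_strip_tag_parse(self, tmp_path, reverse_fraction):
        cfgs = [locus(depth=30, call_error=0.1)]
        ref = build_reference(cfgs, seed=1)
        sim_path = tmp_path / "sim.sam"
        simulate_alignments(cfgs, seed=1, sam_path=str(sim_path),
                            reverse_fraction=reverse_fraction, reference=ref)
        with pysam.AlignmentFile(str(sim_path)) as af:
            for seg in af:
                truth = parse_methylation_calls(seg)
                seg.set_tag("XM", None)
                retagged = attach_methylation_tag(seg, ref)
                assert retagged is not None
                assert parse_methylation_calls(retagged).calls == truth.calls


class TestTrim:
    def _call_offsets(self, xm):
        return [i for i, c in enumerate(xm) if c in "Zz"]

    def test_forward_trim_drops_right_calls(self, header):
        xm = list("." * 50)
        xm[10] = "Z"
        xm[40] = "z"
        seg = make_segment(header, pos=100, cigar="50M", xm="".join(xm))
        assert trim_read_3prime(seg, 25)
        assert seg.query_length == 25
        assert self._call_offsets(seg.get_tag("XM")) == [10]
        assert seg.reference_start == 100

    def test_identity_at_full_length(self, header):
        seg = make_segment(header, pos=100, cigar="50M", xm="Z" + "." * 49)
        before = seg.to_string()
        assert trim_read_3prime(seg, 50)
        assert seg.to_string() == before

    def test_reverse_trim_advances_pos(self, header):
        xm = list("." * 50)
        xm[5] = "Z"
        xm[45] = "z"
        seg = make_segment(header, pos=100, cigar="50M", xm="".join(xm), flag=0x10)
        assert trim_read_3prime(seg, 25)
        assert seg.reference_start == 125
        assert seg.query_length == 25
        # only the reference-right call (query offset 45 -> new offset 20) survives
        assert self._call_offsets(seg.get_tag("XM")) == [20]

    def test_too_short_read_counts_warning(self, tmp_path, header):
        from conftest import write_sam

        seg = make_segment(header, pos=100, cigar="20M", xm="Z" + "." * 19)
        path = write_sam(tmp_path / "in.sam", [seg])
        warnings = trim_calls_3prime(path, [25],
                                     {25: str(tmp_path / "out25.sam")})
        assert warnings == {25: 1}
        with pysam.AlignmentFile(str(tmp_path / "out25.sam")) as af:
            assert next(iter(af)).query_length == 20

    def test_trimming_never_creates_calls(self, tmp_path):
        cfgs = [locus(depth=40, read_length=40), ]
        sim_path = tmp_path / "sim.sam"
        simulate_alignments(cfgs, seed=4, sam_path=str(sim_path),
                            reverse_fraction=0.5)
        out = {25: str(tmp_path / "t25.sam")}
        trim_calls_3prime(str(sim_path), [25], out)

        def calls_by_name(path):
            by_name = {}
            with pysam.AlignmentFile(path) as af:
                for seg in af:
                    mr = parse_methylation_calls(seg)
                    if mr is not None:
                        by_name[seg.query_name] = set(mr.calls)
            return by_name

        original = calls_by_name(str(sim_path))
        for name, calls in calls_by_name(out[25]).items():
            assert calls <= original[name]

    def test_trimmed_output_remains_sorted(self, tmp_path):
        cfgs = [locus(depth=40, read_length=40)]
        sim_path = tmp_path / "sim.sam"
        simulate_alignments(cfgs, seed=4, sam_path=str(sim_path),
                            reverse_fraction=0.5)
        out = {20: str(tmp_path / "t20.sam")}
        trim_calls_3prime(str(sim_path), [20], out)
        list(stream_methyl_reads(out[20]))  # raises if unsorted
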