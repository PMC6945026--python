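import numpy as np
import pytest

import repeatdepth as rd
from repeatdepth.coverage import GCBiasProfile

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"


def write_sam(tmp_path, body, name="t.sam"):
    path = tmp_path / name
    path.write_text(SAM_HEADER + body)
    return path


def sam_line(qname, flag, pos_1based, seq="A" * 75, mapq=60):
    return (
        f"{qname}\t{flag}\tchr1\t{pos_1based}\t{mapq}\t{len(seq)}M\t*\t0\t0\t{seq}\t"
        + "I" * len(seq)
        + "\n"
    )


class TestReadAlignments:
    def test_empty_file(self, tmp_path):
        aln = rd.read_alignments(write_sam(tmp_path, ""))
        assert len(aln) == 0

    def test_unmapped_records_excluded(self, tmp_path):
        body = sam_line("a", 0, 100) + sam_line("b", 4, 0)
        aln = rd.read_alignments(write_sam(tmp_path, body))
        assert len(aln) == 1
        assert aln.start[0] == 99  # SAM is 1-based

    def test_each_mate_is_one_record(self, tmp_path):
        body = sam_line("p", 99, 100) + sam_line("p", 147, 300)
        aln = rd.read_alignments(write_sam(tmp_path, body))
        assert len(aln) == 2
        assert list(aln.is_reverse) == [False, True]

    def test_malformed_record_raises(self, tmp_path):
        path = write_sam(tmp_path, "badline\twith\ttoo\tfew\tfields\n")
        with pytest.raises(ValueError, match="malformed SAM"):
            rd.read_alignments(path)


def _tiny_ref(**kwargs):
    return rd.ReferenceModel(
        genome_length=kwargs.get("genome_length", 10_000),
        repeat_region=rd.GenomicRegion("chr1", 1_000, 2_000),
        repeat_unit_length=kwargs.get("unit_length", 1_000),
    )


def _table(starts, ends=None, reverse=None):
    starts = np.asarray(starts, dtype=np.int64)
    ends = starts + 75 if ends is None else np.asarray(ends, dtype=np.int64)
    n = len(starts)
    return rd.AlignmentTable(
        ref_names=["chr1"],
        ref_id=np.zeros(n, dtype=np.int32),
        start=starts,
        end=ends,
        is_reverse=np.zeros(n, dtype=bool) if reverse is None else np.asarray(reverse),
    )


class TestCountRegions:
    def test_single_base_overlap_counts(self):
        ref = _tiny_ref()
        # spans [926,1001) and [1999,2074): each overlaps by exactly 1 base
        aln = _table([926, 1999])
        counts = rd.count_regions(aln, ref, regions=[ref.repeat_region])
        assert counts.region_counts[ref.repeat_region] == 2
        # one base earlier / at the end boundary: no overlap
        aln2 = _table([925, 2000])
        counts2 = rd.count_regions(aln2, ref, regions=[ref.repeat_region])
        assert counts2.region_counts[ref.repeat_region] == 0

    def test_counting_rules_differ_at_edges(self):
        ref = _tiny_ref()
        # forward record straddling the region start: overlap yes, start no,
        # anchor (=start) no
        aln = _table([950], reverse=[False])
        region = [ref.repeat_region]
        assert rd.count_regions(aln, ref, region, "overlap").region_counts[ref.repeat_region] == 1
        assert rd.count_regions(aln, ref, region, "start").region_counts[ref.repeat_region] == 0
        # reverse record in the same place: anchor = end-1 = 1024, inside
        alnr = _table([950], reverse=[True])
        assert rd.count_regions(alnr, ref, region, "anchor").region_counts[ref.repeat_region] == 1

    def test_unknown_sequence_errors(self):
        ref = rd.ReferenceModel(
            genome_length=10_000,
            repeat_region=rd.GenomicRegion("chrX", 0, 100),
            repeat_unit_length=100,
        )
        with pytest.raises(KeyError):
            rd.count_regions(_table([10]), ref)


class TestEstimateRR:
    def test_identity_when_share_matches_length_ratio(self):
        ref = _tiny_ref()  # L/G = 0.1
        counts = rd.CountSummary(total_mapped=1000, region_counts={ref.repeat_region: 100})
        assert rd.estimate_rr(counts, ref).value == pytest.approx(1.0)

    def test_printed_formula_hand_value(self):
        """10,000 repeat records of 1,000,000 at the worm constants."""
        ref = rd.celegans_reference()
        counts = rd.CountSummary(
            total_mapped=1_000_000, region_counts={ref.repeat_region: 10_000}
        )
        est = rd.estimate_rr(counts, ref)
        assert est.value == pytest.approx(139.3443, abs=1e-4)

    def test_scale_invariance(self):
        ref = _tiny_ref()
        a = rd.estimate_rr(
            rd.CountSummary(1000, {ref.repeat_region: 70}), ref
        ).value
        b = rd.estimate_rr(
            rd.CountSummary(2000, {ref.repeat_region: 140}), ref
        ).value
        assert a == b

    def test_no_mapped_records_errors(self):
        ref = _tiny_ref()
        with pytest.raises(ValueError, match="no mapped"):
            rd.estimate_rr(rd.CountSummary(0, {ref.repeat_region: 0}), ref)

    def test_zero_repeat_count_warns(self):
        ref = _tiny_ref()
        with pytest.warns(UserWarning, match="copy number reported as 0"):
            est = rd.estimate_rr(rd.CountSummary(10, {ref.repeat_region: 0}), ref)
        assert est.value == 0.0


def test_rr_matches_straight_line_sam_recount(tmp_path, toy_reference):
    """Oracle equivalence: the pipeline's RR equals a brute-force recount of
    the raw SAM with independently written counting code."""
    cfg = rd.SimConfig(
        seed=21,
        true_copy_number=10,
        genome_length=500_000,
        repeat_unit_length=5_000,
        n_read_pairs=2_000,
    )
    sim = rd.simulate_reads(toy_reference, cfg)
    path = tmp_path / "sim.sam"
    sim.write_sam(path)

    # independent recount: plain text parsing, no package code
    rs, re_ = toy_reference.repeat_region.start, toy_reference.repeat_region.end
    n_tot = 0
    n_rep = 0
    for line in open(path):
        if line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & 0x4:
            continue
        n_tot += 1
        start = int(fields[3]) - 1
        end = start + len(fields[9])
        if start < re_ and end > rs:
            n_rep += 1
    oracle = n_rep * toy_reference.genome_length / (n_tot * toy_reference.repeat_unit_length)

    aln = rd.read_alignments(path)
    counts = rd.count_regions(aln, toy_reference, regions=[toy_reference.repeat_region])
    assert rd.estimate_rr(counts, toy_reference).value == pytest.approx(oracle, rel=1e-12)


class TestGCProfile:
    def test_uniform_reads_give_flat_profile(self, default_reference):
        cfg = rd.SimConfig(seed=30, true_copy_number=100, n_read_pairs=100_000)
        sim = rd.simulate_reads(default_reference, cfg)
        prof = rd.fit_gc_profile(sim.alignments, default_reference)
        rates = prof.rate[np.isfinite(prof.rate) & (prof.eligible > 20_000)]
        assert rates.std() / rates.mean() < 0.1

    def test_zero_reads_all_rates_zero(self, default_reference):
        empty = _table([])
        empty.ref_names = [default_reference.repeat_region.name]
        with pytest.warns(UserWarning, match="no background anchors"):
            prof = rd.fit_gc_profile(empty, default_reference)
        assert np.nansum(prof.rate) == 0

    def test_biased_profile_tracks_acceptance_weight(self, default_reference):
        """Fitted per-bin rates reproduce the simulator's Gaussian acceptance
        function up to a constant on well-populated bins."""
        cfg = rd.SimConfig(
            seed=31, true_copy_number=100, n_read_pairs=400_000, gc_bias_mode="unimodal"
        )
        sim = rd.simulate_reads(default_reference, cfg)
        prof = rd.fit_gc_profile(sim.alignments, default_reference)
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        good = np.isfinite(prof.rate) & (prof.eligible > 50_000)
        w = np.exp(-((centers[good] - 0.5) ** 2) / (2 * 0.1**2))
        ratio = prof.rate[good] / w
        assert np.max(np.abs(ratio / np.median(ratio) - 1)) < 0.10


class TestEstimateGCC:
    def test_flat_profile_equals_anchor_rr_exactly(self, toy_reference, toy_simulation):
        prof = rd.fit_gc_profile(toy_simulation.alignments, toy_reference)
        flat = GCBiasProfile(
            window=prof.window,
            bin_edges=prof.bin_edges,
            rate=np.where(np.isfinite(prof.rate), 0.013, np.nan),
            eligible=prof.eligible,
        )
        gcc = rd.estimate_gcc(toy_simulation.alignments, toy_reference, flat)
        counts = rd.count_regions(
            toy_simulation.alignments,
            toy_reference,
            regions=[toy_reference.repeat_region],
            counting="anchor",
        )
        rr = rd.estimate_rr(counts, toy_reference)
        assert gcc.value == rr.value

    def test_matched_gc_composition_gcc_close_to_rr(self, default_reference):
        cfg = rd.SimConfig(
            seed=33, true_copy_number=100, n_read_pairs=300_000, repeat_gc=0.50
        )
        ref = rd.build_reference(cfg)
        sim = rd.simulate_reads(ref, cfg)
        prof = rd.fit_gc_profile(sim.alignments, ref)
        gcc = rd.estimate_gcc(sim.alignments, ref, prof)
        counts = rd.count_regions(sim.alignments, ref, regions=[ref.repeat_region], counting="anchor")
        rr = rd.estimate_rr(counts, ref)
        assert gcc.value == pytest.approx(rr.value, rel=0.02)

    def test_monotone_in_copy_number(self, default_reference):
        values = []
        for c in (50, 100, 200):
            cfg = rd.SimConfig(seed=34, true_copy_number=c, n_read_pairs=100_000)
            sim = rd.simulate_reads(default_reference, cfg)
            counts = rd.count_regions(
                sim.alignments, default_reference, regions=[default_reference.repeat_region]
            )
            values.append(rd.estimate_rr(counts, default_reference).value)
        assert values[0] < values[1] < values[2]


class TestControlAudit:
    def test_uniform_simulation_mean_near_one(self, default_reference):
        cfg = rd.SimConfig(seed=36, true_copy_number=10, n_read_pairs=300_000)
        sim = rd.simulate_reads(default_reference, cfg)
        _, mean = rd.estimate_control_regions(sim.alignments, default_reference)
        assert mean == pytest.approx(1.0, abs=0.15)

    def test_global_overcount_shows_in_audit(self, default_reference):
        """Doubling every record (a global count distortion) doubles the
        audit mean, demonstrating its diagnostic use."""
        cfg = rd.SimConfig(seed=37, true_copy_number=10, n_read_pairs=100_000)
        sim = rd.simulate_reads(default_reference, cfg)
        aln = sim.alignments
        doubled = rd.AlignmentTable(
            ref_names=aln.ref_names,
            ref_id=np.concatenate([aln.ref_id, aln.ref_id]),
            start=np.concatenate([aln.start, aln.start]),
            end=np.concatenate([aln.end, aln.end]),
            is_reverse=np.concatenate([aln.is_reverse, aln.is_reverse]),
        )
        # doubling both numerator and denominator leaves ratios unchanged ...
        _, mean_doubled = rd.estimate_control_regions(doubled, default_reference)
        assert mean_doubled == pytest.approx(1.0, abs=0.15)
        # ... but inflating only region counts (half the records dropped from
        # the total) shifts the audit away from 1
        half = aln.subset(np.arange(len(aln)) % 2 == 0)
        inflated = rd.CountSummary(
            total_mapped=len(half),
            region_counts={
                r: rd.count_regions(aln, default_reference, [r], "anchor").region_counts[r]
                for r in default_reference.control_regions
            },
        )
        ests = [
            rd.estimate_rr(inflated, default_reference, region=r, unit_length=r.length).value
            for r in default_reference.control_regions
        ]
        assert np.mean(ests) == pytest.approx(2.0, abs=0.3)

    def test_empty_region_list(self):
        ref = _tiny_ref()
        ests, mean = rd.estimate_control_regions(_table([10]), ref)
        assert ests == [] and np.isnan(mean)


class TestDownsampling:
    def test_fraction_one_reproduces_full_estimate(self, toy_reference, toy_simulation):
        out = rd.downsample_estimates(
            toy_simulation.alignments, 1.0, 3, 0, toy_reference, method="rr"
        )
        assert out["estimates"] == [out["full_estimate"]] * 3
        assert out["max_percent_deviation"] == 0.0

    def test_spread_shrinks_with_fraction(self, toy_reference, toy_simulation):
        low = rd.downsample_estimates(
            toy_simulation.alignments, 0.05, 8, 1, toy_reference, method="rr"
        )
        high = rd.downsample_estimates(
            toy_simulation.alignments, 0.5, 8, 1, toy_reference, method="rr"
        )
        assert high["cv_percent"] < low["cv_percent"]

    @pytest.mark.parametrize("kwargs", [{"n_reps": 0}, {"fraction": 0.0}, {"fraction": 1.5}])
    def test_invalid_arguments(self, toy_reference, toy_simulation, kwargs):
        args = {"fraction": 0.5, "n_reps": 2}
        args.update(kwargs)
        with pytest.raises(ValueError):
            rd.downsample_estimates(
                toy_simulation.alignments, args["fraction"], args["n_reps"], 0, toy_reference
            )
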