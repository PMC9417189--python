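import itertools

import numpy as np
import pytest

from duocall.caller_io import DepthTrack, PopulationFrequencyTable, SomaticCall
from duocall.consensus_filter import (
    FilterConfig,
    FilterReason,
    apply_population_filter,
    apply_record_filters,
    apply_site_filters,
    attrition_summary,
    intersect_callsets,
    merge_outcomes,
    run_cascade,
    subtract_germline,
)
from duocall.errors import InputError
from duocall.reference_context import GenomicInterval, HomopolymerRun, IntervalSet

CFG = FilterConfig()


def make_call(
    pos1=100,
    ref="C",
    alt="T",
    caller="A",
    sample="S1",
    filter_status="PASS",
    qual=30.0,
    alt_depth=20,
    total_depth=50,
    normal_depth=40,
    contig="c1",
):
    return SomaticCall(
        sample_id=sample,
        caller_id=caller,
        contig=contig,
        pos1=pos1,
        ref_allele=ref,
        alt_allele=alt,
        filter_status=filter_status,
        qual_score=qual,
        tumor_alt_depth=alt_depth,
        tumor_total_depth=total_depth,
        normal_depth=normal_depth,
    )


class TestRecordFilters:
    def test_inclusive_boundaries_pass(self):
        # quality >= 10 and at least 4 supporting reads both pass at the boundary
        out = apply_record_filters(make_call(qual=10.0, alt_depth=4), CFG)
        assert out.passed

    def test_qual_below_threshold(self):
        out = apply_record_filters(make_call(qual=9.9, alt_depth=4), CFG)
        assert out.reasons == {FilterReason.FAIL_QUAL}

    def test_multi_reason(self):
        out = apply_record_filters(
            make_call(filter_status="LowEVS", qual=50, alt_depth=3), CFG
        )
        assert out.reasons == {FilterReason.FAIL_FILTER_FIELD, FilterReason.FAIL_ALT_READS}

    def test_snv_only_mode(self):
        cfg = FilterConfig(snv_only=True)
        indel = make_call(ref="CA", alt="C")
        assert FilterReason.FAIL_NON_SNV in apply_record_filters(indel, cfg).reasons
        assert apply_record_filters(make_call(), cfg).passed

    def test_require_pass_off(self):
        cfg = FilterConfig(require_pass=False)
        assert apply_record_filters(make_call(filter_status="LowEVS"), cfg).passed


class TestSiteFilters:
    RUNS = [HomopolymerRun("c1", 10, 13, "A")]
    REPEATS = IntervalSet([GenomicInterval("c1", 200, 300)])

    def test_boundary_normal_depth_passes(self):
        track = DepthTrack([("c1", 0, 1000, 10)])
        out = apply_site_filters(make_call(pos1=100), self.RUNS, self.REPEATS, track, CFG)
        assert out.passed

    def test_low_normal_depth(self):
        track = DepthTrack([("c1", 0, 1000, 9)])
        out = apply_site_filters(make_call(pos1=100), self.RUNS, self.REPEATS, track, CFG)
        assert out.reasons == {FilterReason.FAIL_NORMAL_COVERAGE}

    def test_homopolymer_adjacent_one_nt(self):
        track = DepthTrack([("c1", 0, 1000, 50)])
        out = apply_site_filters(make_call(pos1=9), self.RUNS, self.REPEATS, track, CFG)
        assert out.reasons == {FilterReason.FAIL_HOMOPOLYMER}

    def test_repeat_membership(self):
        track = DepthTrack([("c1", 0, 1000, 50)])
        out = apply_site_filters(make_call(pos1=250), self.RUNS, self.REPEATS, track, CFG)
        assert out.reasons == {FilterReason.FAIL_REPEAT}

    def test_track_wins_over_vcf_normal_depth(self):
        track = DepthTrack([("c1", 0, 1000, 5)])
        call = make_call(pos1=100, normal_depth=50)
        out = apply_site_filters(call, self.RUNS, self.REPEATS, track, CFG)
        assert FilterReason.FAIL_NORMAL_COVERAGE in out.reasons

    def test_vcf_normal_depth_fallback(self):
        out = apply_site_filters(make_call(pos1=100, normal_depth=50), self.RUNS, self.REPEATS, None, CFG)
        assert out.passed


class TestPopulationFilter:
    def test_maf_above_threshold_fails(self):
        freqs = PopulationFrequencyTable({("c1", 100, "C", "T"): 0.002})
        out = apply_population_filter(make_call(), freqs, CFG)
        assert out.reasons == {FilterReason.FAIL_POPULATION_MAF}

    def test_maf_exactly_at_threshold_passes(self):
        freqs = PopulationFrequencyTable({("c1", 100, "C", "T"): 0.001})
        assert apply_population_filter(make_call(), freqs, CFG).passed

    def test_absent_record_passes(self):
        freqs = PopulationFrequencyTable({})
        assert apply_population_filter(make_call(), freqs, CFG).passed

    def test_allele_aware_default(self):
        freqs = PopulationFrequencyTable({("c1", 100, "C", "G"): 0.5})
        assert apply_population_filter(make_call(alt="T"), freqs, CFG).passed

    def test_position_only_mode(self):
        freqs = PopulationFrequencyTable({("c1", 100, "C", "G"): 0.5})
        cfg = FilterConfig(population_match_allele=False)
        out = apply_population_filter(make_call(alt="T"), freqs, cfg)
        assert out.reasons == {FilterReason.FAIL_POPULATION_MAF}


class TestGermlineSubtraction:
    def test_match_fails(self):
        calls = [make_call()]
        out = subtract_germline(calls, {("c1", 100, "C", "T")})
        assert out[0].reasons == {FilterReason.FAIL_GERMLINE_MATCH}

    def test_empty_set_all_pass(self):
        assert all(o.passed for o in subtract_germline([make_call()], set()))

    def test_allele_level_matching(self):
        out = subtract_germline([make_call(alt="T")], {("c1", 100, "C", "G")})
        assert out[0].passed


def _random_calls(rng, n, sample="S1", caller="A"):
    calls = []
    for i in range(n):
        total = int(rng.integers(5, 80))
        calls.append(
            make_call(
                pos1=int(rng.integers(1, 2000)),
                caller=caller,
                sample=sample,
                filter_status="PASS" if rng.uniform() < 0.8 else "LowEVS",
                qual=float(rng.uniform(0, 40)),
                alt_depth=int(rng.integers(0, total + 1)),
                total_depth=total,
                normal_depth=int(rng.integers(0, 40)),
            )
        )
    return calls


def _random_context(rng):
    runs = [HomopolymerRun("c1", int(s), int(s) + 4, "A") for s in rng.integers(1, 1900, 10)]
    repeats = IntervalSet(
        [GenomicInterval("c1", int(s), int(s) + 50) for s in rng.integers(0, 1900, 8)]
    )
    freqs = PopulationFrequencyTable(
        {("c1", int(p), "C", "T"): float(rng.uniform(0, 0.01)) for p in rng.integers(1, 2000, 60)}
    )
    germline = {("c1", int(p), "C", "T") for p in rng.integers(1, 2000, 40)}
    return runs, repeats, freqs, germline


class TestRunCascade:
    def test_all_passing(self):
        calls = [make_call(pos1=p) for p in (5, 6, 7, 8, 9)]
        track = DepthTrack([("c1", 0, 2000, 50)])
        survivors, audit = run_cascade(
            calls, runs=[], repeats=IntervalSet(), depth_track=track,
            freqs=None, germline_keys=None, cfg=CFG,
        )
        assert survivors == calls
        assert all(o.passed for o in audit)

    def test_single_failure_removed(self):
        calls = [make_call(pos1=5), make_call(pos1=6, qual=1.0)]
        track = DepthTrack([("c1", 0, 2000, 50)])
        survivors, audit = run_cascade(
            calls, runs=[], repeats=IntervalSet(), depth_track=track,
            freqs=None, germline_keys=None, cfg=CFG,
        )
        assert [c.pos1 for c in survivors] == [5]
        assert audit[1].reasons == {FilterReason.FAIL_QUAL}

    def test_verdict_equals_conjunction_of_predicates(self):
        rng = np.random.default_rng(42)
        runs, repeats, freqs, germline = _random_context(rng)
        calls = _random_calls(rng, 60)
        track = DepthTrack([("c1", 0, 2000, 12)])
        survivors, audit = run_cascade(
            calls, runs=runs, repeats=repeats, depth_track=track,
            freqs=freqs, germline_keys=germline, cfg=CFG,
        )
        for call, outcome in zip(calls, audit):
            independent = set(apply_record_filters(call, CFG).reasons)
            independent |= set(apply_site_filters(call, runs, repeats, track, CFG).reasons)
            independent |= set(apply_population_filter(call, freqs, CFG).reasons)
            independent |= set(subtract_germline([call], germline)[0].reasons)
            assert set(outcome.reasons) == independent
            assert (call in survivors) == (not independent)

    def test_order_independence_all_orders(self):
        """Survivors are identical under every sequential predicate ordering."""
        rng = np.random.default_rng(7)
        runs, repeats, freqs, germline = _random_context(rng)
        calls = _random_calls(rng, 20)
        track = DepthTrack([("c1", 0, 2000, 12)])
        predicates = [
            lambda c: apply_record_filters(c, CFG).passed,
            lambda c: apply_site_filters(c, runs, repeats, track, CFG).passed,
            lambda c: apply_population_filter(c, freqs, CFG).passed,
            lambda c: subtract_germline([c], germline)[0].passed,
        ]
        survivors, _ = run_cascade(
            calls, runs=runs, repeats=repeats, depth_track=track,
            freqs=freqs, germline_keys=germline, cfg=CFG,
        )
        expected_keys = [id(c) for c in survivors]
        for order in itertools.permutations(predicates):
            remaining = list(calls)
            for pred in order:
                remaining = [c for c in remaining if pred(c)]
            assert [id(c) for c in remaining] == expected_keys

    def test_monotonicity_of_thresholds(self):
        rng = np.random.default_rng(123)
        runs, repeats, freqs, germline = _random_context(rng)
        calls = _random_calls(rng, 80)
        track = DepthTrack([("c1", 0, 2000, 15)])

        def survivor_keys(cfg):
            survivors, _ = run_cascade(
                calls, runs=runs, repeats=repeats, depth_track=track,
                freqs=freqs, germline_keys=germline, cfg=cfg,
            )
            return {id(c) for c in survivors}

        base = survivor_keys(CFG)
        tighter = [
            FilterConfig(min_qual=20),
            FilterConfig(min_alt_reads=8),
            FilterConfig(min_normal_depth=14),
            FilterConfig(max_population_maf=0.0001),
        ]
        for cfg in tighter:
            assert survivor_keys(cfg) <= base


class TestIntersect:
    def test_identity(self):
        a = [make_call(pos1=p, caller="A") for p in (1, 2, 3)]
        b = [make_call(pos1=p, caller="B") for p in (1, 2, 3)]
        consensus = intersect_callsets(a, b)
        assert [v.pos1 for v in consensus] == [1, 2, 3]

    def test_disjoint(self):
        a = [make_call(pos1=1, caller="A")]
        b = [make_call(pos1=2, caller="B")]
        assert intersect_callsets(a, b) == []

    def test_partial_overlap(self):
        a = [make_call(pos1=p, caller="A") for p in (1, 2)]
        b = [make_call(pos1=p, caller="B") for p in (2, 3)]
        assert [v.pos1 for v in intersect_callsets(a, b)] == [2]

    def test_subset_and_symmetry_properties(self):
        rng = np.random.default_rng(5)
        pos_a = set(map(int, rng.choice(500, 40, replace=False)))
        pos_b = set(map(int, rng.choice(500, 40, replace=False)))
        a = [make_call(pos1=p + 1, caller="A") for p in sorted(pos_a)]
        b = [make_call(pos1=p + 1, caller="B") for p in sorted(pos_b)]
        ab = intersect_callsets(a, b)
        assert len(ab) <= min(len(a), len(b))
        keys_a = {c.key for c in a}
        keys_b = {c.key for c in b}
        assert all(v.key in keys_a and v.key in keys_b for v in ab)
        # symmetric in reported keys (evidence roles swap)
        ba = intersect_callsets(b, a, af_source="B")
        assert [v.key for v in ab] == [v.key for v in ba]

    def test_af_from_source_a(self):
        a = [make_call(pos1=1, caller="A", alt_depth=20, total_depth=50)]
        b = [make_call(pos1=1, caller="B", alt_depth=5, total_depth=40)]
        (v,) = intersect_callsets(a, b)
        assert v.allele_fraction == pytest.approx(0.4)

    def test_af_fallback_when_source_lacks_depth(self):
        a = [make_call(pos1=1, caller="A", alt_depth=0, total_depth=0)]
        b = [make_call(pos1=1, caller="B", alt_depth=10, total_depth=40)]
        (v,) = intersect_callsets(a, b)
        assert v.allele_fraction == pytest.approx(0.25)

    def test_duplicate_key_rejected(self):
        a = [make_call(pos1=1, caller="A"), make_call(pos1=1, caller="A")]
        with pytest.raises(InputError, match="duplicate"):
            intersect_callsets(a, [])

    def test_mixed_samples_rejected(self):
        a = [make_call(pos1=1, sample="S1")]
        b = [make_call(pos1=1, sample="S2", caller="B")]
        with pytest.raises(InputError, match="samples"):
            intersect_callsets(a, b)

    def test_sorted_output(self):
        a = [make_call(pos1=p, caller="A") for p in (30, 2, 500)]
        b = [make_call(pos1=p, caller="B") for p in (500, 30, 2)]
        assert [v.pos1 for v in intersect_callsets(a, b)] == [2, 30, 500]


class TestAttrition:
    def test_counts(self):
        o1 = apply_record_filters(make_call(qual=1.0, alt_depth=1), CFG)
        o2 = apply_record_filters(make_call(), CFG)
        summary = attrition_summary([o1, o2])
        assert summary["n_in"] == 2
        assert summary["n_out"] == 1
        assert summary["FAIL_QUAL"] == 1
        assert summary["FAIL_ALT_READS"] == 1

    def test_merge_requires_same_call(self):
        with pytest.raises(InputError):
            merge_outcomes(
                apply_record_filters(make_call(pos1=1), CFG),
                apply_record_filters(make_call(pos1=2), CFG),
            )
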