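import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herscan.event_detection import (
    CandidateRun,
    CentromereRelation,
    ChromosomeModel,
    Direction,
    Event,
    EventType,
    Inheritance,
    MarkerCall,
    Region,
    annotate_centromere,
    assign_parent_of_origin,
    breakpoint_interval,
    classify_inheritance,
    detect_aneuploidy,
    find_aberrant_runs,
    match_reciprocal,
    reciprocal_overlap,
)
from herscan.genotyping import Dosage
from herscan.probe_annotation import HomoeologyBlock, Orientation

# shorthand dosage symbols for call vectors
L1, L2 = Dosage.LOSS_P1, Dosage.LOSS_P2
G1, G2 = Dosage.GAIN_P1, Dosage.GAIN_P2
BAL, UNK = Dosage.BALANCED, Dosage.UNKNOWN


def calls_from(dosages, chrom="A1", spacing=1000):
    return [
        MarkerCall(f"p{i:04d}", chrom, (i + 1) * spacing, d)
        for i, d in enumerate(dosages)
    ]


class TestFindAberrantRuns:
    def test_two_consecutive_insufficient(self):
        assert find_aberrant_runs(calls_from([L1, L1, BAL, BAL, BAL])) == []

    def test_three_consecutive(self):
        runs = find_aberrant_runs(calls_from([L1, L1, L1]))
        assert len(runs) == 1
        assert runs[0].n_support_loci == 3
        assert runs[0].direction is Direction.LOSS
        assert runs[0].parent_of_origin == "parent1"

    def test_interior_unknown_bridged(self):
        vec = [L1] * 6 + [UNK] + [L1] * 6
        runs = find_aberrant_runs(calls_from(vec))
        assert len(runs) == 1
        assert runs[0].n_support_loci == 12

    def test_conflicting_call_breaks(self):
        vec = [L1, L1, L1, G1, L1, L1, L1]
        runs = find_aberrant_runs(calls_from(vec))
        assert [(r.direction, r.n_support_loci) for r in runs] == [
            (Direction.LOSS, 3), (Direction.LOSS, 3)]

    def test_parent_attribution_separates_runs(self):
        vec = [L1, L1, L1, L2, L2, L2]
        runs = find_aberrant_runs(calls_from(vec))
        assert {r.parent_of_origin for r in runs} == {"parent1", "parent2"}

    def test_unsorted_input_rejected(self):
        calls = calls_from([L1, L1, L1])[::-1]
        with pytest.raises(ValueError):
            find_aberrant_runs(calls)

    def test_trailing_unknowns_not_included(self):
        vec = [L1, L1, L1, UNK, UNK]
        (run,) = find_aberrant_runs(calls_from(vec))
        assert run.last_position == 3000


# ---------------------------------------------------------------------------
# brute-force oracle for run finding: window-validity predicate + scan
# ---------------------------------------------------------------------------

def _key(d):
    return {L1: (Direction.LOSS, "parent1"), L2: (Direction.LOSS, "parent2"),
            G1: (Direction.GAIN, "parent1"),
            G2: (Direction.GAIN, "parent2")}.get(d)


def _valid(vec, i, j, key, gap_tol):
    if _key(vec[j]) != key:
        return False
    unknowns = 0
    for k in range(i, j + 1):
        if _key(vec[k]) == key:
            continue
        if vec[k] is UNK:
            unknowns += 1
        else:
            return False
    return unknowns <= gap_tol


def oracle_runs(vec, min_run=3, gap_tol=1):
    out = []
    i = 0
    while i < len(vec):
        key = _key(vec[i])
        if key is None:
            i += 1
            continue
        j_best = None
        for j in range(len(vec) - 1, i - 1, -1):
            if _valid(vec, i, j, key, gap_tol):
                j_best = j
                break
        support = sum(1 for k in range(i, j_best + 1) if _key(vec[k]) == key)
        if support >= min_run:
            out.append((i, j_best, support, key))
            i = j_best + 1
        else:
            i += 1
    return out


def impl_runs(vec, min_run=3, gap_tol=1):
    runs = find_aberrant_runs(calls_from(vec), min_run=min_run,
                              gap_tolerance=gap_tol)
    return [
        (r.first_position // 1000 - 1, r.last_position // 1000 - 1,
         r.n_support_loci, (r.direction, r.parent_of_origin))
        for r in runs
    ]


SYMBOLS_3 = (L1, BAL, UNK)
SYMBOLS_4 = (G1, L1, BAL, UNK)


class TestRunOracle:
    @pytest.mark.parametrize("length", range(1, 8))
    def test_exhaustive_four_symbols(self, length):
        for vec in itertools.product(SYMBOLS_4, repeat=length):
            assert impl_runs(list(vec)) == oracle_runs(list(vec)), vec

    @pytest.mark.parametrize("min_run,gap_tol", [(3, 1), (3, 0), (2, 2)])
    def test_exhaustive_three_symbols_length_9(self, min_run, gap_tol):
        for length in (8, 9):
            for vec in itertools.product(SYMBOLS_3, repeat=length):
                v = list(vec)
                assert impl_runs(v, min_run, gap_tol) == \
                    oracle_runs(v, min_run, gap_tol), vec

    @given(st.lists(st.sampled_from(SYMBOLS_4), min_size=1, max_size=12))
    @settings(max_examples=500, deadline=None)
    def test_random_length_12(self, vec):
        assert impl_runs(vec) == oracle_runs(vec)


def block(a_chrom="A1", c_chrom="C1", length=40_000_000):
    return HomoeologyBlock(
        f"blk_{a_chrom}_{c_chrom}", (a_chrom, 1, length), (c_chrom, 1, length),
        Orientation.SAME, 100,
    )


def run(chrom, direction, start, end, parent="parent1", n=10, ind="I1"):
    return CandidateRun(ind, chrom, direction, parent, start, end, n)


class TestMatchReciprocal:
    def test_reciprocal_pairing(self):
        runs = [run("C1", Direction.LOSS, 100_000, 5_000_000),
                run("A1", Direction.GAIN, 100_000, 5_000_000)]
        events = match_reciprocal(runs, [block()])
        assert len(events) == 1
        assert events[0].type is EventType.HER
        assert events[0].gain_region.chromosome == "A1"
        assert events[0].loss_region.chromosome == "C1"

    def test_unpaired_loss_is_deletion(self):
        events = match_reciprocal([run("C1", Direction.LOSS, 1, 5_000_000)],
                                  [block()])
        assert [e.type for e in events] == [EventType.DELETION]

    def test_unpaired_gain_is_duplication(self):
        events = match_reciprocal([run("A1", Direction.GAIN, 1, 5_000_000)],
                                  [block()])
        assert [e.type for e in events] == [EventType.DUPLICATION]

    def test_different_parents_do_not_pair(self):
        runs = [run("C1", Direction.LOSS, 1, 5_000_000, parent="parent1"),
                run("A1", Direction.GAIN, 1, 5_000_000, parent="parent2")]
        events = match_reciprocal(runs, [block()])
        assert {e.type for e in events} == {EventType.DELETION,
                                            EventType.DUPLICATION}

    def test_no_projection_overlap_no_pair(self):
        runs = [run("C1", Direction.LOSS, 1, 2_000_000),
                run("A1", Direction.GAIN, 30_000_000, 39_000_000)]
        events = match_reciprocal(runs, [block()])
        assert {e.type for e in events} == {EventType.DELETION,
                                            EventType.DUPLICATION}

    def test_each_run_pairs_at_most_once(self):
        runs = [run("C1", Direction.LOSS, 1, 5_000_000),
                run("A1", Direction.GAIN, 1, 3_000_000),
                run("A1", Direction.GAIN, 3_500_000, 5_000_000)]
        events = match_reciprocal(runs, [block()])
        types = sorted(e.type.value for e in events)
        assert types == ["HeR", "duplication"]


class TestDetectAneuploidy:
    def test_whole_chromosome_gain(self):
        r = run("A8", Direction.GAIN, 1, 21_000_000, n=100)
        events, rest = detect_aneuploidy([r], {"A8": 100})
        assert rest == []
        assert events[0].type is EventType.ANEUPLOID_GAIN

    def test_partial_run_stays_segmental(self):
        r = run("C1", Direction.LOSS, 1, 16_000_000, n=40)
        events, rest = detect_aneuploidy([r], {"C1": 100})
        assert events == [] and rest == [r]

    def test_fragmented_whole_chromosome_merges(self):
        frags = [run("A8", Direction.GAIN, 1, 10_000_000, n=48),
                 run("A8", Direction.GAIN, 10_500_000, 21_000_000, n=48)]
        events, rest = detect_aneuploidy(frags, {"A8": 100})
        assert rest == []
        assert events[0].type is EventType.ANEUPLOID_GAIN
        assert events[0].gain_region.n_support_loci == 96

    def test_two_aneuploidies_one_individual(self):
        runs = [run("A7", Direction.GAIN, 1, 25_000_000, n=100),
                run("C6", Direction.GAIN, 1, 40_000_000, n=100)]
        events, rest = detect_aneuploidy(runs, {"A7": 100, "C6": 100})
        assert len(events) == 2 and rest == []


def event(ind, chrom="A1", start=1, end=10_000_000, etype=EventType.DELETION,
          parent="parent1"):
    return Event(
        event_id=f"e_{ind}", individual_id=ind, type=etype,
        loss_region=Region(chrom, start, end, 10), parent_of_origin=parent,
    )


class TestClassifyInheritance:
    def test_single_carrier_de_novo(self):
        e = event("I1")
        pop = [e] + [event(f"I{i}", chrom="C5") for i in range(2, 5)]
        assert classify_inheritance(e, pop, 48) is Inheritance.DE_NOVO

    def test_subset_carriers_segregating(self):
        pop = [event(f"I{i}") for i in range(10)]
        assert classify_inheritance(pop[0], pop, 48) is Inheritance.SEGREGATING

    def test_all_carriers_fixed(self):
        pop = [event(f"I{i}") for i in range(48)]
        assert classify_inheritance(pop[0], pop, 48) is Inheritance.FIXED

    def test_partial_overlap_below_half_not_same(self):
        a = event("I1", start=1, end=10_000_000)
        b = event("I2", start=9_000_000, end=30_000_000)
        assert classify_inheritance(a, [a, b], 48) is Inheritance.DE_NOVO

    def test_population_too_small(self):
        e = event("I1")
        assert classify_inheritance(e, [e], 1) is Inheritance.UNCLASSIFIED

    def test_reciprocal_overlap(self):
        assert reciprocal_overlap((1, 100), (51, 150)) == pytest.approx(0.5)
        assert reciprocal_overlap((1, 10), (20, 30)) == 0.0


class TestAssignParentOfOrigin:
    def test_resolves_labels(self):
        e = event("I1", parent="parent2")
        out = assign_parent_of_origin(e, "Daichousen", "Rainbow")
        assert out.parent_of_origin == "Rainbow"

    def test_unknown_label_passthrough(self):
        e = event("I1", parent="somebody")
        assert assign_parent_of_origin(e).parent_of_origin == "somebody"


class TestBreakpointInterval:
    MODELS = {"A1": ChromosomeModel("A1", 21_700_000,
                                    (10_000_000, 10_400_000))}

    def test_flanking_marker_interval(self):
        e = event("I1", start=500_000, end=1_000_000)
        positions = {"A1": [400_000, 500_000, 750_000, 1_000_000, 1_000_172]}
        out = breakpoint_interval(e, positions, self.MODELS)
        assert out.breakpoint_intervals == ((400_000, 500_000),
                                            (1_000_000, 1_000_172))
        left, right = out.breakpoint_intervals
        assert right[1] - right[0] == 172

    def test_truncated_at_chromosome_end(self):
        e = event("I1", start=20_000_000, end=21_500_000)
        positions = {"A1": [19_000_000, 20_000_000, 21_500_000]}
        out = breakpoint_interval(e, positions, self.MODELS)
        assert out.breakpoint_intervals[1] == (21_500_000, 21_700_000)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_maps_match_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(int(p) for p in
                           rng.choice(np.arange(1, 21_700_000, 1000), 200,
                                      replace=False))
        lo, hi = sorted(rng.choice(positions, 2, replace=False))
        e = event("I1", start=int(lo), end=int(hi))
        out = breakpoint_interval(e, {"A1": positions}, self.MODELS)

        # independent linear scan
        before = None
        for p in positions:
            if p < lo:
                before = p
        after = None
        for p in reversed(positions):
            if p > hi:
                after = p
        expected_left = (before, lo) if before is not None else (1, lo)
        expected_right = (hi, after) if after is not None else (hi, 21_700_000)
        assert out.breakpoint_intervals == (expected_left, expected_right)


class TestAnnotateCentromere:
    MODELS = {"A1": ChromosomeModel("A1", 30_000_000,
                                    (14_800_000, 15_200_000))}

    def test_spans(self):
        e = event("I1", start=10_000_000, end=20_000_000)
        out = annotate_centromere(e, self.MODELS)
        assert out.centromere_relation is CentromereRelation.SPANS

    def test_breakpoint_near_centromere(self):
        e = event("I1", start=1, end=14_400_000)  # 0.4 Mb from the edge
        out = annotate_centromere(e, self.MODELS)
        assert out.centromere_relation is \
            CentromereRelation.BREAKPOINT_AT_CENTROMERE

    def test_far_terminal_region_none(self):
        e = event("I1", start=1, end=5_000_000)
        out = annotate_centromere(e, self.MODELS)
        assert out.centromere_relation is CentromereRelation.NONE

    def test_spans_takes_precedence(self):
        e = event("I1", start=14_000_000, end=16_000_000)
        out = annotate_centromere(e, self.MODELS)
        assert out.centromere_relation is CentromereRelation.SPANS
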