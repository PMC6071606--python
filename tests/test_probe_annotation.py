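import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herscan.probe_annotation import (
    GenomeHit,
    Orientation,
    ProbeLocus,
    Specificity,
    Subgenome,
    assign_homoeologous_locus,
    build_homoeology_map,
    classify_specificity,
    project_interval,
)


def hit(probe="p1", chrom="A1", pos=1000, identity=0.95):
    return GenomeHit(probe, Subgenome(chrom[0]), chrom, pos, identity)


class TestClassifySpecificity:
    def test_a_specific(self):
        hits = [hit(chrom="A1", identity=0.95), hit(chrom="C1", identity=0.80)]
        assert classify_specificity(hits) is Specificity.A_SPECIFIC

    def test_dual(self):
        hits = [hit(chrom="A1", identity=0.95), hit(chrom="C1", identity=0.92)]
        assert classify_specificity(hits) is Specificity.DUAL

    def test_single_low_hit_unassigned(self):
        assert classify_specificity([hit(chrom="A1", identity=0.88)]) \
            is Specificity.UNASSIGNED

    def test_empty_is_unassigned(self):
        assert classify_specificity([]) is Specificity.UNASSIGNED

    def test_tie_at_threshold_does_not_exceed(self):
        # identity exactly at the threshold counts as not exceeding it
        hits = [hit(chrom="A1", identity=0.90), hit(chrom="C1", identity=0.50)]
        assert classify_specificity(hits) is Specificity.UNASSIGNED

    def test_best_hit_per_subgenome_wins(self):
        hits = [hit(chrom="A1", identity=0.5), hit(chrom="A2", identity=0.95)]
        assert classify_specificity(hits) is Specificity.A_SPECIFIC

    def test_malformed_identity_rejected(self):
        with pytest.raises(ValueError):
            hit(identity=1.2)

    @given(
        a=st.floats(0, 1), c=st.floats(0, 1),
        lo=st.floats(0.5, 0.99), hi=st.floats(0.5, 0.99),
    )
    def test_threshold_monotonicity(self, a, c, lo, hi):
        """Raising the specificity threshold never converts unassigned to
        specific."""
        lo, hi = min(lo, hi), max(lo, hi)
        hits = [hit(chrom="A1", identity=a), hit(chrom="C1", identity=c)]
        low = classify_specificity(hits, high_thresh=lo)
        high = classify_specificity(hits, high_thresh=hi)
        if low is Specificity.UNASSIGNED:
            assert high is Specificity.UNASSIGNED


class TestAssignHomoeologousLocus:
    def test_partner_above_threshold(self):
        hits = [hit(chrom="A1", pos=100, identity=0.95),
                hit(chrom="C1", pos=1_500_000, identity=0.60)]
        locus = assign_homoeologous_locus(hits)
        assert locus.specificity is Specificity.A_SPECIFIC
        assert locus.primary_locus == ("A1", 100)
        assert locus.homoeologous_locus == ("C1", 1_500_000)

    def test_partner_below_threshold_absent(self):
        hits = [hit(chrom="A1", identity=0.95), hit(chrom="C1", identity=0.40)]
        assert assign_homoeologous_locus(hits).homoeologous_locus is None

    def test_unassigned_has_no_loci(self):
        locus = assign_homoeologous_locus([hit(chrom="A1", identity=0.5)])
        assert locus.primary_locus is None
        assert locus.homoeologous_locus is None

    def test_dual_probe_excluded(self):
        hits = [hit(chrom="A1", identity=0.95), hit(chrom="C1", identity=0.95)]
        locus = assign_homoeologous_locus(hits)
        assert locus.specificity is Specificity.DUAL
        assert not locus.is_informative

    @given(min_id=st.floats(0.3, 0.9))
    def test_min_identity_monotonicity(self, min_id):
        """Raising the homoeology threshold never adds partner loci."""
        hits = [hit(chrom="A1", identity=0.95), hit(chrom="C1", identity=0.55)]
        base = assign_homoeologous_locus(hits, min_identity=0.3)
        raised = assign_homoeologous_locus(hits, min_identity=min_id)
        if base.homoeologous_locus is None:
            assert raised.homoeologous_locus is None


def make_locus(probe, chrom, pos, pchrom, ppos):
    return ProbeLocus(probe, Specificity.A_SPECIFIC if chrom[0] == "A"
                      else Specificity.C_SPECIFIC,
                      (chrom, pos), (pchrom, ppos))


def collinear_loci(n=100, chrom="A1", pchrom="C1", step=50_000, start=1,
                   partner_start=1, direction=1):
    return [
        make_locus(f"{chrom}_{i:04d}", chrom, start + i * step, pchrom,
                   partner_start + direction * i * step)
        for i in range(n)
    ]


class TestBuildHomoeologyMap:
    def test_collinear_single_block(self):
        blocks = build_homoeology_map(collinear_loci(100))
        assert len(blocks) == 1
        b = blocks[0]
        assert b.a_interval[0] == "A1" and b.c_interval[0] == "C1"
        assert b.orientation is Orientation.SAME
        assert b.n_probes == 100

    def test_inverted_block(self):
        loci = collinear_loci(50, partner_start=10_000_000, direction=-1)
        (block,) = build_homoeology_map(loci)
        assert block.orientation is Orientation.INVERTED

    def test_split_partner_chromosome(self):
        """Two primary chromosomes pairing to opposite halves of one
        partner produce two blocks sharing that partner chromosome."""
        a9 = collinear_loci(40, chrom="A9", pchrom="C9", partner_start=1)
        a10 = collinear_loci(40, chrom="A10", pchrom="C9",
                             partner_start=20_000_000)
        blocks = build_homoeology_map(a9 + a10)
        assert len(blocks) == 2
        assert {b.a_interval[0] for b in blocks} == {"A9", "A10"}
        assert all(b.c_interval[0] == "C9" for b in blocks)

    def test_min_block_probes_filters_short_runs(self):
        assert build_homoeology_map(collinear_loci(4), min_block_probes=5) == []

    def test_gap_breaks_block(self):
        loci = collinear_loci(10)
        far = [make_locus("far", "A1", 50_000_000, "C1", 50_000_000)]
        blocks = build_homoeology_map(loci + far, max_gap=2_000_000)
        assert len(blocks) == 1 and blocks[0].n_probes == 10

    def test_empty_input(self):
        assert build_homoeology_map([]) == []


# ---------------------------------------------------------------------------
# brute-force oracle: greedy longest-valid-window segmentation, stated
# declaratively (window validity predicate + left-to-right scan)
# ---------------------------------------------------------------------------

def _window_valid(group, i, j, max_gap):
    sub = group[i:j + 1]
    if len({loc.homoeologous_locus[0] for loc in sub}) != 1:
        return False
    partner = [loc.homoeologous_locus[1] for loc in sub]
    primary = [loc.primary_locus[1] for loc in sub]
    for a, b in zip(primary, primary[1:]):
        if b - a > max_gap:
            return False
    for a, b in zip(partner, partner[1:]):
        if abs(b - a) > max_gap:
            return False
    nondecr = all(b >= a for a, b in zip(partner, partner[1:]))
    nonincr = all(b <= a for a, b in zip(partner, partner[1:]))
    return nondecr or nonincr


def oracle_blocks(loci, min_block_probes, max_gap):
    """Independent enumeration of maximal monotone runs."""
    anchored = [l for l in loci
                if l.primary_locus is not None and l.homoeologous_locus is not None]
    by_chrom = {}
    for loc in anchored:
        by_chrom.setdefault(loc.primary_locus[0], []).append(loc)
    out = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom],
                       key=lambda l: (l.primary_locus[1], l.probe_id))
        i = 0
        while i < len(group):
            j_best = i
            for j in range(len(group) - 1, i - 1, -1):
                if _window_valid(group, i, j, max_gap):
                    j_best = j
                    break
            if j_best - i + 1 >= min_block_probes:
                out.append(tuple(loc.probe_id for loc in group[i:j_best + 1]))
            i = j_best + 1
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_toy_maps(self, seed):
        """Planted blocks plus shuffled probes: block memberships equal the
        brute-force segmentation."""
        rng = np.random.default_rng(seed)
        loci = []
        pid = 0
        for b in range(5):
            chrom = f"A{b + 1}"
            pchrom = f"C{(b % 3) + 1}"
            direction = 1 if rng.random() < 0.5 else -1
            start = int(rng.integers(1, 5_000_000))
            pstart = int(rng.integers(1, 30_000_000))
            for i in range(int(rng.integers(8, 40))):
                pos = start + i * int(rng.integers(10_000, 200_000))
                ppos = pstart + direction * i * int(rng.integers(10_000, 200_000))
                loci.append(make_locus(f"p{pid:05d}", chrom, pos, pchrom,
                                       max(ppos, 1)))
                pid += 1
        # ~2% shuffled probes with random partner positions
        for _ in range(max(1, len(loci) // 50)):
            k = int(rng.integers(len(loci)))
            src = loci[k]
            loci[k] = make_locus(src.probe_id, src.primary_locus[0],
                                 src.primary_locus[1], "C9",
                                 int(rng.integers(1, 50_000_000)))
        got = build_homoeology_map(loci, min_block_probes=5, max_gap=2_000_000)
        expected = oracle_blocks(loci, min_block_probes=5, max_gap=2_000_000)
        assert [b.probe_ids for b in got] == expected

    @given(
        partner=st.lists(st.integers(1, 30), min_size=1, max_size=40),
        min_probes=st.integers(1, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_small_maps_match_oracle(self, partner, min_probes):
        loci = [
            make_locus(f"p{i:03d}", "A1", (i + 1) * 10, "C1", p * 10)
            for i, p in enumerate(partner)
        ]
        got = build_homoeology_map(loci, min_block_probes=min_probes,
                                   max_gap=10**9)
        expected = oracle_blocks(loci, min_block_probes=min_probes,
                                 max_gap=10**9)
        assert [b.probe_ids for b in got] == expected

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        loci = [
            make_locus(f"p{i:04d}", "A1", (i + 1) * 1000, "C1",
                       int(rng.integers(1, 10**6)))
            for i in range(200)
        ]
        blocks = build_homoeology_map(loci, min_block_probes=3, max_gap=10**9)
        seen = [p for b in blocks for p in b.probe_ids]
        assert len(seen) == len(set(seen))
        # blocks on the same chromosome pair do not overlap on primary interval
        ivs = sorted(
            (b.a_interval[1], b.a_interval[2]) for b in blocks
        )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 < s2


class TestProjectInterval:
    def test_same_orientation_midpoint(self, tiny_map):
        block = next(b for b in tiny_map.blocks if b.a_interval[0] == "A1")
        a_len = block.a_interval[2]
        c_len = block.c_interval[2]
        proj = project_interval(block, "A1", 1, a_len)
        assert proj[0] == "C1"
        assert proj[1] == 1 and proj[2] == c_len

    def test_disjoint_returns_none(self, tiny_map):
        block = next(b for b in tiny_map.blocks if b.a_interval[0] == "A9")
        # C9 bottom half is outside the A9 block's C interval
        assert project_interval(block, "C9", 55_000_000, 56_000_000) is None

    def test_inverted_orientation_flips(self):
        from herscan.probe_annotation import HomoeologyBlock
        block = HomoeologyBlock("b", ("A1", 1, 1000), ("C1", 1, 1000),
                                Orientation.INVERTED, 10)
        proj = project_interval(block, "A1", 1, 100)
        assert proj[0] == "C1"
        assert proj[1] == 901 and proj[2] == 1000
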