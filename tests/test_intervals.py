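"""Seed thresholds, run extension, interruption tolerance, exports."""

import numpy as np
import pytest

from xpgwas.intervals import (
    Interval,
    IntervalParams,
    detect_intervals,
    enumerate_intervals_bruteforce,
    find_seeds,
    interval_summary,
    is_seed,
    report_interval_variants,
    write_intervals_bed,
)
from xpgwas.stitch import StitchPlan, stitch_scaffolds

from conftest import make_afe


def records_from_matching_afe(afe_values, start=1000, step=100, other_afe=None,
                              depth=55):
    """AFe record track with the given matching-pool (pool A) AFe series.

    By default the other pool mirrors so qualifying sites have delta ~1.
    """
    records = []
    for i, a in enumerate(afe_values):
        b = other_afe[i] if other_afe is not None else 1.0 - a
        records.append(make_afe(start + i * step, a, b,
                                depth_a=depth, depth_b=depth))
    return records


class TestSeedThreshold:
    @pytest.mark.parametrize("coverage,expected", [
        (100, 0.89),
        (200, 0.895),
        (50, 0.88),
    ])
    def test_values(self, coverage, expected):
        from xpgwas.intervals import seed_threshold
        assert seed_threshold(coverage) == pytest.approx(expected)

    def test_limit_is_p(self):
        from xpgwas.intervals import seed_threshold
        assert seed_threshold(1e12) == pytest.approx(0.9, abs=1e-9)

    def test_nonpositive_coverage_rejected(self):
        from xpgwas.intervals import seed_threshold
        with pytest.raises(ValueError):
            seed_threshold(0)


class TestFindSeeds:
    def test_qualifying_and_divergent_is_seed(self):
        rec = make_afe(100, 0.05, 1.0, depth_a=50, depth_b=50)  # C=100, X=0.89
        assert is_seed(rec, IntervalParams())

    def test_qualifying_but_not_divergent(self):
        rec = make_afe(100, 0.05, 0.5, depth_a=50, depth_b=50)  # delta 0.45
        assert not is_seed(rec, IntervalParams())

    def test_no_delta_no_seeds(self):
        records = records_from_matching_afe([0.0, 0.05, 0.1],
                                            other_afe=[0.0, 0.05, 0.1])
        assert find_seeds(records) == []

    def test_x_disabled_when_error_zero(self):
        rec = make_afe(100, 0.05, 0.96, depth_a=5, depth_b=5)  # C=10
        # with E=0.01: X = 0.9 - 1/10 = ... wait 100*0.01/10 = 0.1 -> X=0.8
        assert is_seed(rec, IntervalParams())
        strict = IntervalParams(error_rate=0.0)  # flat delta >= P rule
        assert is_seed(rec, strict)
        low = make_afe(100, 0.05, 0.88, depth_a=5, depth_b=5)  # delta 0.83
        assert is_seed(low, IntervalParams())      # 0.83 >= X=0.8
        assert not is_seed(low, strict)            # 0.83 < 0.9


class TestDetectIntervals:
    def test_pure_run(self):
        records = records_from_matching_afe([0.0, 0.05, 0.0])
        (iv,) = detect_intervals(records)
        assert (iv.start, iv.end, iv.n_variants) == (1000, 1200, 3)

    def test_single_interruption_absorbed(self):
        records = records_from_matching_afe([0.0, 0.0, 0.5, 0.0, 0.0])
        (iv,) = detect_intervals(records)
        assert (iv.start, iv.end) == (1000, 1400)
        assert iv.member_sites == (1000, 1100, 1300, 1400)  # interrupter out

    def test_double_interruption_splits(self):
        records = records_from_matching_afe([0.0, 0.0, 0.5, 0.5, 0.0, 0.0])
        intervals = detect_intervals(records)
        assert [(iv.start, iv.end) for iv in intervals] == \
            [(1000, 1100), (1400, 1500)]

    def test_interruption_at_edge_not_absorbed(self):
        records = records_from_matching_afe([0.5, 0.0, 0.0, 0.5])
        (iv,) = detect_intervals(records)
        assert (iv.start, iv.end) == (1100, 1200)

    def test_run_without_seed_not_reported(self):
        # qualifying but non-divergent run: no seed, no interval
        records = records_from_matching_afe([0.0, 0.05, 0.0],
                                            other_afe=[0.2, 0.2, 0.2])
        assert detect_intervals(records) == []

    def test_min_variants_discards_singletons(self):
        records = records_from_matching_afe([0.5, 0.0, 0.5])
        assert detect_intervals(records) == []
        singleton_ok = IntervalParams(min_variants=1)
        (iv,) = detect_intervals(records, singleton_ok)
        assert iv.n_variants == 1

    def test_qualifying_threshold_inclusive(self):
        records = records_from_matching_afe([0.1, 0.0, 0.1])
        (iv,) = detect_intervals(records)
        assert iv.n_variants == 3

    def test_chromosomes_independent(self):
        a = records_from_matching_afe([0.0, 0.0])
        b = [make_afe(p, 0.0, 1.0, chrom="chr2") for p in (1000, 1100)]
        intervals = detect_intervals(a + b)
        assert [iv.chrom for iv in intervals] == ["chr1", "chr2"]

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(5)
        records = records_from_matching_afe(rng.uniform(0, 0.3, 60))
        first = detect_intervals(records)
        again = detect_intervals(records)
        assert first == again

    def test_never_spans_spacer_with_liftover(self):
        sequences = {"s1": "A" * 2000, "s2": "C" * 2000}
        plan = StitchPlan(groups=(("super1", ("s1", "s2")),), spacer_len=550)
        _, table = stitch_scaffolds(sequences, plan)
        # qualifying run straddling the junction at super coordinates
        records = [make_afe(p, 0.0, 1.0, chrom="super1")
                   for p in (1900, 1950, 2600, 2650)]  # s1: <=2000, s2: >2550
        merged = detect_intervals(records)
        split = detect_intervals(records, liftover=table)
        assert len(merged) == 1
        assert [(iv.start, iv.end) for iv in split] == \
            [(1900, 1950), (2600, 2650)]


class TestOracleEquivalence:
    def random_records(self, rng, n):
        """Random AFe track with plenty of near-qualifying structure."""
        match = np.where(rng.random(n) < 0.55,
                         rng.uniform(0, 0.12, n), rng.uniform(0.1, 1.0, n))
        other = np.where(rng.random(n) < 0.5,
                         rng.uniform(0.85, 1.0, n), rng.random(n))
        depth = rng.integers(20, 120, size=(n, 2))
        return [
            make_afe(1000 + 37 * i, float(match[i]), float(other[i]),
                     depth_a=int(depth[i, 0]), depth_b=int(depth[i, 1]))
            for i in range(n)
        ]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_enumeration(self, seed):
        """Seed extension equals exhaustive maximal-tolerant-run enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 400))
        records = self.random_records(rng, n)
        params = IntervalParams(max_interruption=int(rng.integers(0, 3)) or 1)
        fast = detect_intervals(records, params)
        slow = enumerate_intervals_bruteforce(records, params)
        assert [(iv.start, iv.end, iv.member_sites) for iv in fast] == \
            [(iv.start, iv.end, iv.member_sites) for iv in slow]

    def test_intervals_disjoint_and_sorted(self):
        rng = np.random.default_rng(99)
        records = self.random_records(rng, 300)
        intervals = detect_intervals(records)
        for a, b in zip(intervals, intervals[1:]):
            assert a.end < b.start


class TestReporting:
    def test_all_saturated_reported(self):
        records = records_from_matching_afe([0.0, 0.0, 0.0])
        (iv,) = detect_intervals(records)
        assert len(report_interval_variants(iv, records)) == 3

    def test_absorbed_interrupter_excluded(self):
        records = records_from_matching_afe([0.0, 0.0, 0.5, 0.0, 0.0],
                                            other_afe=[1.0, 1.0, 0.8, 1.0, 1.0])
        (iv,) = detect_intervals(records)
        reported = report_interval_variants(iv, records)
        assert iv.start <= 1200 <= iv.end           # inside the span
        assert 1200 not in [r.pos for r in reported]  # delta 0.3 < 0.9

    def test_containment(self):
        rng = np.random.default_rng(3)
        match = rng.uniform(0, 0.2, 50)
        records = records_from_matching_afe(match)
        for iv in detect_intervals(records):
            for rec in report_interval_variants(iv, records):
                assert iv.start <= rec.pos <= iv.end


class TestSummaryAndExports:
    def test_mean_length(self):
        intervals = [
            Interval("chr1", 1, 1000, 1, (1, 1000)),
            Interval("chr1", 2000, 4999, 2000, (2000, 4999)),
        ]
        summary = interval_summary(intervals)
        assert summary["count"] == 2
        assert summary["mean_length"] == pytest.approx(2000.0)

    def test_empty_summary_flagged(self):
        summary = interval_summary([])
        assert summary["count"] == 0 and summary["mean_length"] is None

    def test_bed_is_zero_based_half_open(self, tmp_path):
        iv = Interval("chr1", 1000, 1200, 1000, (1000, 1100, 1200))
        path = tmp_path / "iv.bed"
        write_intervals_bed([iv], path)
        chrom, start, end, name = path.read_text().split()
        assert (chrom, int(start), int(end)) == ("chr1", 999, 1200)
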