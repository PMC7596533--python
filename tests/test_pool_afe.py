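"""VCF parsing, hard filtering, AFe computation and coverage banding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xpgwas.pool_afe import (
    FilterParams,
    PoolSample,
    PooledVariant,
    compute_afe,
    compute_afe_table,
    coverage_band_filter,
    hard_filter,
    mean_informative_depth,
    read_afe_tsv,
    read_pooled_vcf,
    write_afe_tsv,
)

from conftest import (
    FILTER_FIXTURE_LINES,
    FILTER_FIXTURE_SURVIVOR_POS,
    POOLS,
    VCF_HEADER,
    make_afe,
    vcf_line,
)


def make_variant(pos=100, ref="A", alts=("T",), a=(30, 0, 30, 99, True),
                 b=(0, 30, 30, 99, True), info=None):
    def sample(spec):
        ref_count, alt_count, dp, gq, genotyped = spec
        return PoolSample(ref_count=ref_count, alt_count=alt_count,
                          depth=dp, gq=gq, genotyped=genotyped)
    return PooledVariant(chrom="chr1", pos=pos, ref_allele=ref,
                         alt_alleles=alts,
                         samples={POOLS[0]: sample(a), POOLS[1]: sample(b)},
                         info=info or {})


class TestReadPooledVcf:
    def test_count_and_order(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + vcf_line(300) + vcf_line(100) + vcf_line(200))
        variants = read_pooled_vcf(path, POOLS)
        assert [v.pos for v in variants] == [100, 200, 300]

    def test_missing_genotype_flagged(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + vcf_line(100, b="./.:0,30:30:99"))
        (v,) = read_pooled_vcf(path, POOLS)
        assert not v.samples["THCVA"].genotyped
        assert v.samples["CBDA"].genotyped

    def test_missing_sample_rejected(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + vcf_line(100))
        with pytest.raises(ValueError, match="otherpool"):
            read_pooled_vcf(path, ("CBDA", "otherpool"))

    def test_variant_class(self):
        assert make_variant(ref="A", alts=("T",)).variant_class == "SNP"
        assert make_variant(ref="A", alts=("AT",)).variant_class == "InDel"
        assert make_variant(ref="AC", alts=("A",)).variant_class == "InDel"


class TestHardFilter:
    def test_designed_fixture_survivors(self, filter_fixture_vcf):
        """Each removal rule fires exactly where designed; tallies conserve."""
        variants = read_pooled_vcf(filter_fixture_vcf, POOLS)
        survivors, tally = hard_filter(variants)
        assert [v.pos for v in survivors] == FILTER_FIXTURE_SURVIVOR_POS
        expected = {fate for _, fate in FILTER_FIXTURE_LINES}
        for fate in expected:
            assert tally[fate] == sum(
                1 for _, f in FILTER_FIXTURE_LINES if f == fate)
        assert sum(tally.values()) == len(variants)

    @pytest.mark.parametrize("variant,reason", [
        (make_variant(a=(14, 0, 14, 99, True)), "DP"),
        (make_variant(b=(0, 30, 30, 19, True)), "GQ"),
        (make_variant(alts=("T", "G")), "multiallelic"),
        (make_variant(a=(30, 0, 30, 99, False)), "missing_genotype"),
    ])
    def test_single_rule(self, variant, reason):
        survivors, tally = hard_filter([variant])
        assert survivors == []
        assert tally[reason] == 1

    def test_boundaries_inclusive(self):
        ok = make_variant(a=(15, 0, 15, 20, True), b=(0, 15, 15, 20, True))
        survivors, _ = hard_filter([ok])
        assert survivors == [ok]

    def test_site_annotation_filter(self):
        params = FilterParams(site_filters={"QD": ("<", 2.0)})
        bad = make_variant(info={"QD": 1.5})
        absent = make_variant(pos=200)  # no annotation: not failed by it
        survivors, tally = hard_filter([bad, absent], params)
        assert survivors == [absent]
        assert tally["site_filter"] == 1

    def test_empty_input(self):
        survivors, tally = hard_filter([])
        assert survivors == [] and tally["pass"] == 0

    @given(st.integers(0, 30), st.integers(0, 50), st.data())
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_thresholds(self, min_dp, min_gq, data):
        """Raising min_dp or min_gq never enlarges the survivor set."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        variants = [
            make_variant(pos=int(p),
                         a=(int(rng.integers(0, 40)), 0,
                            int(rng.integers(0, 40)), int(rng.integers(0, 60)), True),
                         b=(0, int(rng.integers(0, 40)),
                            int(rng.integers(0, 40)), int(rng.integers(0, 60)), True))
            for p in range(100, 2100, 100)
        ]
        loose, _ = hard_filter(variants, FilterParams(min_dp=min_dp, min_gq=min_gq))
        strict, _ = hard_filter(
            variants, FilterParams(min_dp=min_dp + 5, min_gq=min_gq + 5))
        assert set(id(v) for v in strict) <= set(id(v) for v in loose)


class TestComputeAfe:
    @pytest.mark.parametrize("a,b,exp_a,exp_b", [
        ((30, 0), (0, 30), 0.0, 1.0),    # all-ref pool -> 0, all-alt -> 1
        ((25, 25), (25, 25), 0.5, 0.5),
        ((10, 30), (40, 10), 0.75, 0.2),
    ])
    def test_values(self, a, b, exp_a, exp_b):
        v = make_variant(a=(*a, sum(a), 99, True), b=(*b, sum(b), 99, True))
        rec = compute_afe(v, POOLS)
        assert rec.afe_a == pytest.approx(exp_a)
        assert rec.afe_b == pytest.approx(exp_b)
        assert rec.delta == pytest.approx(abs(exp_a - exp_b))
        assert rec.coverage == sum(a) + sum(b)

    def test_zero_informative_reads_skipped(self):
        v = make_variant(a=(0, 0, 10, 99, True))
        assert compute_afe(v, POOLS) is None

    def test_multiallelic_rejected(self):
        with pytest.raises(ValueError):
            compute_afe(make_variant(alts=("T", "G")), POOLS)

    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_matches_per_read_tally(self, ra, aa, rb, ab):
        """AFe equals a brute-force per-read tally on random count tables."""
        if ra + aa == 0 or rb + ab == 0:
            return
        v = make_variant(a=(ra, aa, ra + aa, 99, True),
                         b=(rb, ab, rb + ab, 99, True))
        rec = compute_afe(v, POOLS)
        # oracle: count read-by-read
        reads_a = ["alt"] * aa + ["ref"] * ra
        reads_b = ["alt"] * ab + ["ref"] * rb
        assert rec.afe_a == pytest.approx(
            sum(r == "alt" for r in reads_a) / len(reads_a))
        assert rec.afe_b == pytest.approx(
            sum(r == "alt" for r in reads_b) / len(reads_b))
        assert 0 <= rec.afe_a <= 1 and 0 <= rec.afe_b <= 1
        assert 0 <= rec.delta <= 1

    def test_order_invariance(self):
        variants = [make_variant(pos=p) for p in (300, 100, 200)]
        fwd = compute_afe_table(variants, POOLS)
        rev = compute_afe_table(list(reversed(variants)), POOLS)
        assert sorted((r.chrom, r.pos, r.afe_a) for r in fwd) == \
            sorted((r.chrom, r.pos, r.afe_a) for r in rev)


class TestCoverageBand:
    def test_boundaries(self):
        """37 < 0.75*50 removed; 125 = 2.5*50 kept (inclusive)."""
        records = [
            make_afe(100, 0.0, 1.0, depth_a=37, depth_b=50),
            make_afe(200, 0.0, 1.0, depth_a=125, depth_b=50),
            make_afe(300, 0.0, 1.0, depth_a=50, depth_b=50),
        ]
        kept = coverage_band_filter(records, mean_depths=(50.0, 50.0))
        assert [r.pos for r in kept] == [200, 300]

    def test_uniform_depth_all_survive(self):
        records = [make_afe(p, 0.2, 0.3, depth_a=60, depth_b=60)
                   for p in range(100, 1100, 100)]
        assert coverage_band_filter(records) == records

    def test_combined_mode(self):
        params = FilterParams(coverage_band_mode="combined")
        records = [make_afe(100, 0.0, 1.0, depth_a=10, depth_b=110),
                   make_afe(200, 0.0, 1.0, depth_a=60, depth_b=60)]
        kept = coverage_band_filter(records, mean_depths=(60.0, 60.0),
                                    params=params)
        # combined coverage 120 within [90, 300] for both records
        assert [r.pos for r in kept] == [100, 200]

    def test_mean_depth_estimated_from_records(self):
        records = [make_afe(p, 0.0, 1.0, depth_a=d, depth_b=55)
                   for p, d in [(100, 50), (200, 55), (300, 60), (400, 500)]]
        mean_a, mean_b = mean_informative_depth(records)
        kept = coverage_band_filter(records)
        assert mean_b == pytest.approx(55.0)
        assert 400 not in [r.pos for r in kept]  # 500 >> 2.5 * mean


def test_afe_tsv_round_trip(tmp_path):
    records = [make_afe(100, 0.1, 0.9), make_afe(200, 0.0, 1.0, depth_a=40)]
    path = tmp_path / "afe.tsv"
    write_afe_tsv(records, path)
    assert read_afe_tsv(path) == records
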