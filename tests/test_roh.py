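import numpy as np
import pandas as pd
import pytest

from rohscape import (
    LengthClassScheme,
    RohParams,
    RohSet,
    classify_lengths,
    detect_roh,
    detect_roh_individual,
    roh_summary,
    segment_length_mb,
)
from rohscape.roh import SEGMENT_COLUMNS, brute_force_roh, chrom_counts_and_coverage

from conftest import make_dataset, random_positions

RELAXED = RohParams(
    window_snps=10,
    min_snps_in_roh=10,
    min_length_bp=100_000,
    max_missing_in_roh=2,
    max_het_in_roh=0,
    max_gap_bp=1_000_000,
)


def _segments_equal(a, b):
    key = lambda s: (s.chrom, s.start_bp, s.end_bp, s.n_snps)
    return sorted(map(key, a)) == sorted(map(key, b))


class TestDetect:
    def test_all_het_yields_nothing(self):
        ds = make_dataset(np.ones((1, 200), dtype=np.int8), {"1": list(range(10**6, 201 * 10**6, 10**6))})
        assert detect_roh_individual(ds.calls[0], ds.snps, RohParams()) == []

    def test_fully_homozygous_single_segment(self):
        bps = [50_000 * (j + 1) for j in range(200)]  # 10 Mb chromosome, even spacing
        ds = make_dataset(np.zeros((1, 200), dtype=np.int8), {"1": bps})
        segs = detect_roh_individual(ds.calls[0], ds.snps, RohParams())
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp, segs[0].n_snps) == (bps[0], bps[-1], 200)

    def test_chromosome_shorter_than_window_silent(self):
        ds = make_dataset(np.zeros((1, 10), dtype=np.int8))
        assert detect_roh_individual(ds.calls[0], ds.snps, RohParams(window_snps=50)) == []

    def test_unsorted_map_errors(self):
        ds = make_dataset(np.zeros((1, 3), dtype=np.int8))
        snps = ds.snps.copy()
        snps.loc[1, "bp"] = 10**9
        with pytest.raises(ValueError, match="sorted"):
            detect_roh_individual(ds.calls[0], snps, RohParams(window_snps=2, min_snps_in_roh=2))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_genotypes(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        g = rng.choice([0, 1, 2, -1], size=n, p=[0.55, 0.12, 0.28, 0.05]).astype(np.int8)
        bp1 = np.array(random_positions(rng, n // 2, 30_000_000))
        bp2 = np.array(random_positions(rng, n - n // 2, 30_000_000))
        ds = make_dataset(g[None, :], {"1": bp1.tolist(), "2": bp2.tolist()})
        fast = detect_roh_individual(ds.calls[0], ds.snps, RELAXED)
        slow = brute_force_roh(ds.calls[0], ds.snps, RELAXED)
        assert _segments_equal(fast, slow)

    def test_monotonic_in_thresholds(self):
        rng = np.random.default_rng(77)
        g = rng.choice([0, 1, 2], size=600, p=[0.6, 0.08, 0.32]).astype(np.int8)
        bp = np.array(random_positions(rng, 600, 40_000_000))
        ds = make_dataset(g[None, :], {"1": bp.tolist()})
        base = len(detect_roh_individual(ds.calls[0], ds.snps, RELAXED))
        stricter_len = RohParams(**{**RELAXED.__dict__, "min_length_bp": 1_000_000})
        stricter_snps = RohParams(**{**RELAXED.__dict__, "min_snps_in_roh": 30})
        assert len(detect_roh_individual(ds.calls[0], ds.snps, stricter_len)) <= base
        assert len(detect_roh_individual(ds.calls[0], ds.snps, stricter_snps)) <= base

    def test_segments_disjoint_and_within_chromosome(self):
        rng = np.random.default_rng(13)
        g = rng.choice([0, 1, 2], size=400, p=[0.7, 0.05, 0.25]).astype(np.int8)
        bp1 = np.array(random_positions(rng, 200, 20_000_000))
        bp2 = np.array(random_positions(rng, 200, 20_000_000))
        ds = make_dataset(g[None, :], {"1": bp1.tolist(), "2": bp2.tolist()})
        segs = detect_roh_individual(ds.calls[0], ds.snps, RELAXED)
        by_chrom: dict[str, list] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, ss in by_chrom.items():
            ss.sort(key=lambda s: s.start_bp)
            for a, b in zip(ss, ss[1:]):
                assert a.end_bp < b.start_bp

    def test_identical_individuals_identical_calls(self):
        ds = make_dataset(np.zeros((2, 60), dtype=np.int8), {"1": [10**5 * (j + 1) for j in range(60)]})
        roh = detect_roh(ds, RELAXED)
        s1 = roh.for_sample("s1").drop(columns="sample_id").reset_index(drop=True)
        s2 = roh.for_sample("s2").drop(columns="sample_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)


class TestClassify:
    def test_boundary_left_closed(self):
        scheme = LengthClassScheme()
        assert scheme.classify(5.0) == "5-10"
        assert scheme.classify(4.999) == "0-5"
        assert scheme.classify(41.0) == ">40"

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"s{i}", "P", "1", 0, int(rng.uniform(1, 60) * 1e6), 50, 0) for i in range(40)
        ]
        segs = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
        segs["length_bp"] = segs["end_bp"] - segs["start_bp"]
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(40)], "population": "P"})
        table = classify_lengths(RohSet(segs, samples))
        assert table.loc["Total", "Total"] == 40
        assert table.drop(index="Total")["Total"].sum() == 40

    def test_empty_set_all_zero(self):
        samples = pd.DataFrame({"sample_id": ["a"], "population": ["P"]})
        table = classify_lengths(RohSet(pd.DataFrame(), samples))
        assert (table["Total"] == 0).all()


class TestSummary:
    def test_single_individual_single_segment(self):
        segs = pd.DataFrame(
            [("s1", "P", "1", 1_000_000, 3_000_000, 60, 2_000_000)], columns=SEGMENT_COLUMNS
        )
        samples = pd.DataFrame({"sample_id": ["s1"], "population": ["P"]})
        summ = roh_summary(RohSet(segs, samples))
        row = summ[summ["population"] == "P"].iloc[0]
        assert row["mean_roh_per_individual"] == 1.0
        assert row["mean_length_mb"] == 2.0

    def test_zero_roh_individuals_counted_in_mean(self):
        segs = pd.DataFrame(
            [("s1", "P", "1", 1_000_000, 3_000_000, 60, 2_000_000)], columns=SEGMENT_COLUMNS
        )
        samples = pd.DataFrame({"sample_id": ["s1", "s2"], "population": ["P", "P"]})
        summ = roh_summary(RohSet(segs, samples))
        assert summ[summ["population"] == "P"].iloc[0]["mean_roh_per_individual"] == 0.5


class TestChromTable:
    def test_no_segments_zero(self):
        ds = make_dataset(np.ones((2, 20), dtype=np.int8))
        table = chrom_counts_and_coverage(RohSet(pd.DataFrame(), ds.samples), ds)
        assert (table["n_segments"] == 0).all() and (table["coverage"] == 0).all()

    def test_full_span_coverage_one(self):
        ds = make_dataset(np.zeros((1, 20), dtype=np.int8))
        first, last = int(ds.snps["bp"].min()), int(ds.snps["bp"].max())
        segs = pd.DataFrame(
            [("s1", "POP", "1", first, last, 20, last - first)], columns=SEGMENT_COLUMNS
        )
        table = chrom_counts_and_coverage(RohSet(segs, ds.samples), ds)
        row = table[(table["chrom"] == "1") & (table["population"] == "POP")].iloc[0]
        assert row["coverage"] == pytest.approx(1.0)

    def test_matches_interval_accumulation_oracle(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(
            np.zeros((3, 40), dtype=np.int8),
            {"1": [10**6 * (j + 1) for j in range(20)], "2": [10**6 * (j + 1) for j in range(20)]},
        )
        rows = []
        for i in range(3):
            for _ in range(rng.integers(0, 4)):
                c = rng.choice(["1", "2"])
                a, b = sorted(rng.integers(1_000_000, 20_000_000, size=2).tolist())
                if a < b:
                    rows.append((f"s{i + 1}", "POP", c, a, b, 10, b - a))
        segs = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
        table = chrom_counts_and_coverage(RohSet(segs, ds.samples), ds)
        spans = {c: 19_000_000 for c in ("1", "2")}
        for chrom in ("1", "2"):
            total = sum(r[6] for r in rows if r[2] == chrom)
            exp = total / (spans[chrom] * 3)
            got = table[(table["chrom"] == chrom) & (table["population"] == "POP")].iloc[0]["coverage"]
            assert got == pytest.approx(exp)


class TestLengthArithmetic:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (39467151, 137516937, 98.05),
            (60187788, 67883046, 7.70),
            (0 + 1, 1_000_001, 1.00),
        ],
    )
    def test_reported_mb(self, start, end, expected):
        assert segment_length_mb(start, end) == expected

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            segment_length_mb(100, 100)
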