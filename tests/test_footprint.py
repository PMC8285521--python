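"""Binomial detection power and callable-footprint arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csccqc.footprint import (
    CoverageProfile,
    callable_footprint,
    effective_coverage,
    prob_both_alleles_sampled,
    prob_detect_het,
)


def binom_pmf(k, n):
    return math.comb(n, k) * 0.5**n


class TestAllelePower:
    @pytest.mark.parametrize("n, expected", [
        (6, 0.96875),           # the 6x reference threshold
        (1, 0.0),               # one read samples one allele
        (10, 1.0 - 2.0 * 0.5**10),
    ])
    def test_known_values(self, n, expected):
        assert prob_both_alleles_sampled(n) == pytest.approx(expected, abs=1e-12)

    def test_matches_binomial_enumeration(self):
        # P(1 <= X <= n-1) for X ~ Binomial(n, 1/2), summed directly
        for n in range(1, 30):
            interior = sum(binom_pmf(k, n) for k in range(1, n))
            assert prob_both_alleles_sampled(n) == pytest.approx(interior, abs=1e-12)

    def test_strictly_increasing_to_one(self):
        # strictly increasing until float resolution saturates the limit
        vals = [prob_both_alleles_sampled(n) for n in range(1, 53)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert prob_both_alleles_sampled(60) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_zero_reads(self):
        with pytest.raises(ValueError):
            prob_both_alleles_sampled(0)


class TestEffectiveCoverage:
    def test_low_purity_worked_example(self):
        assert effective_coverage(100, 0.08) == pytest.approx(8.0, abs=1e-9)

    def test_pure_tumor_identity(self):
        assert effective_coverage(37.5, 1.0) == 37.5

    def test_zero_depth(self):
        assert effective_coverage(0, 0.5) == 0.0

    @pytest.mark.parametrize("rho", [0.0, -0.1, 1.5])
    def test_rejects_bad_cellularity(self, rho):
        with pytest.raises(ValueError):
            effective_coverage(10, rho)


class TestHetDetection:
    def test_eightfold_four_reads(self):
        # tail sum of Binomial(8, 1/2) from 4: (70+56+28+8+1)/256
        oracle = sum(binom_pmf(k, 8) for k in range(4, 9))
        p = prob_detect_het(8, 4)
        assert p == pytest.approx(163 / 256, abs=1e-12)
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p >= 0.5  # detection succeeds more than half the time

    def test_unreachable_threshold(self):
        assert prob_detect_het(3, 4) == 0.0

    def test_no_reads_required(self):
        assert prob_detect_het(8, 0) == 1.0

    def test_half_to_even_rounding(self):
        # 8.5 rounds to 8, 9.5 rounds to 10
        assert prob_detect_het(8.5, 4) == prob_detect_het(8, 4)
        assert prob_detect_het(9.5, 4) == prob_detect_het(10, 4)

    @settings(max_examples=50, deadline=None)
    @given(depth=st.integers(1, 200), min_alt=st.integers(1, 10))
    def test_monotone_in_depth_and_threshold(self, depth, min_alt):
        assert prob_detect_het(depth + 1, min_alt) >= prob_detect_het(depth, min_alt)
        assert prob_detect_het(depth, min_alt + 1) <= prob_detect_het(depth, min_alt)


def profile(rows, territory, role="tumor", sample_id="S"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
    return CoverageProfile(sample_id, role, df, territory)


class TestCallableFootprint:
    def test_uniform_tracks_fully_callable(self):
        ref = profile([("chr1", 0, 1_000_000, 30)], 1_000_000, "reference")
        tum = profile([("chr1", 0, 1_000_000, 100)], 1_000_000)
        rep = callable_footprint(ref, tum, 0.5)
        assert rep.sample_footprint_bp == 1_000_000
        assert rep.fraction_callable == 1.0

    def test_low_purity_zeroes_tumor_footprint(self):
        ref = profile([("chr1", 0, 1_000_000, 30)], 1_000_000, "reference")
        tum = profile([("chr1", 0, 1_000_000, 100)], 1_000_000)
        rep = callable_footprint(ref, tum, 0.05)  # effective 5x < 8x
        assert rep.tumor_footprint_bp == 0
        assert rep.sample_footprint_bp == 0
        assert rep.fraction_callable == 0.0

    def test_piecewise_track_counted_base_by_base(self):
        # 1 Mb territory; exactly 600 kb passes both thresholds
        ref_rows = [("chr1", 0, 700_000, 30), ("chr1", 700_000, 1_000_000, 2)]
        tum_rows = [("chr1", 0, 100_000, 5),       # eff 2.5: fails
                    ("chr1", 100_000, 700_000, 40),  # eff 20: passes
                    ("chr1", 700_000, 1_000_000, 40)]
        ref = profile(ref_rows, 1_000_000, "reference")
        tum = profile(tum_rows, 1_000_000)
        rep = callable_footprint(ref, tum, 0.5)
        # brute-force per-base count at 1 kb resolution
        base = np.arange(0, 1_000_000, 1000)
        ref_depth = np.where(base < 700_000, 30, 2)
        tum_depth = np.where(base < 100_000, 5, 40)
        ref_bp = 1000 * int((ref_depth >= 6).sum())
        tum_bp = 1000 * int((tum_depth * 0.5 >= 8).sum())
        assert rep.reference_footprint_bp == ref_bp == 700_000
        assert rep.tumor_footprint_bp == tum_bp == 900_000
        assert rep.sample_footprint_bp == min(ref_bp, tum_bp)
        # the overlapping-passing region is only 600 kb
        rep_int = callable_footprint(ref, tum, 0.5, intersection=True)
        assert rep_int.sample_footprint_bp == 600_000

    def test_scalar_min_bounds_intersection(self, rng):
        territory = 100_000
        for _ in range(20):
            edges = np.sort(rng.choice(np.arange(1, 100), 6, replace=False)) * 1000
            edges = np.concatenate([[0], edges, [territory]])
            rows_r = [("chr1", int(a), int(b), int(rng.integers(0, 40)))
                      for a, b in zip(edges[:-1], edges[1:])]
            rows_t = [("chr1", int(a), int(b), int(rng.integers(0, 40)))
                      for a, b in zip(edges[:-1], edges[1:])]
            ref = profile(rows_r, territory, "reference")
            tum = profile(rows_t, territory)
            scalar = callable_footprint(ref, tum, 0.6)
            inter = callable_footprint(ref, tum, 0.6, intersection=True)
            assert scalar.sample_footprint_bp >= inter.sample_footprint_bp

    def test_invariant_under_repartition(self):
        ref = profile([("chr1", 0, 1_000_000, 30)], 1_000_000, "reference")
        tum_whole = profile([("chr1", 0, 1_000_000, 50)], 1_000_000)
        tum_split = profile(
            [("chr1", i, i + 100_000, 50) for i in range(0, 1_000_000, 100_000)],
            1_000_000)
        for intersection in (False, True):
            a = callable_footprint(ref, tum_whole, 0.5, intersection=intersection)
            b = callable_footprint(ref, tum_split, 0.5, intersection=intersection)
            assert a.sample_footprint_bp == b.sample_footprint_bp
            assert a.fraction_callable == b.fraction_callable

    def test_mismatched_territories_rejected(self):
        ref = profile([("chr1", 0, 1000, 30)], 1000, "reference")
        tum = profile([("chr1", 0, 1000, 30)], 2000)
        with pytest.raises(ValueError):
            callable_footprint(ref, tum, 0.5)
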