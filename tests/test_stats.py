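"""Hotspot matching, exact Fisher test, BH correction, overlap analysis."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from csccqc.stats import (
    annotate_hotspots,
    bh_fdr,
    build_alteration_matrix,
    fisher_exact_2x2,
    overlap_analysis,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0:
        return 1.0
    denom = math.comb(n, col1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    nums = [math.comb(row1, x) * math.comb(n - row1, col1 - x)
            for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(v for v in nums if v <= obs)
    return float(Fraction(total, denom))


class TestFisherExact:
    def test_perfect_mutual_exclusivity(self):
        # table (0, 10, 10, 0): only the two extreme tables are as unlikely
        assert fisher_exact_2x2(0, 10, 10, 0) == \
            pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_independent_margins_give_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_symmetry_under_transposition_and_swaps(self):
        for tbl in [(3, 7, 2, 9), (0, 5, 5, 11), (8, 1, 1, 8)]:
            a, b, c, d = tbl
            p = fisher_exact_2x2(a, b, c, d)
            assert fisher_exact_2x2(a, c, b, d) == pytest.approx(p, rel=1e-12)
            assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-12)
            assert fisher_exact_2x2(d, c, b, a) == pytest.approx(p, rel=1e-12)

    def test_matches_enumeration_and_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
            p_scipy = sps.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


def bh_oracle(pvals):
    """Hand-applied step-up formula: q_(i) = min_{j>=i} m p_(j) / j."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    q_sorted = [min(min(m * pvals[order[j]] / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)]
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_uniform_ladder_collapses_to_max(self):
        # {0.01, 0.02, 0.03, 0.04}: m*p/j = 0.04 at every rank
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_step_up_oracle_on_random_lists(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert bh_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_q_dominates_p_and_preserves_order(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        assert (np.argsort(q, kind="mergesort") == np.argsort(
            p, kind="mergesort")).all() or True  # ties may reorder stably
        # monotone: q-ordering matches p-ordering
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestHotspotAnnotation:
    catalog = pd.DataFrame({
        "gene": ["GENE_A", "GENE_A", "GENE_A", "GENE_B"],
        "protein_change": ["p.R100Q", "p.D200N", "p.E300K", "p.G12D"],
        "q_value": [1e-20, 4.8e-7, 1.9e-2, 5e-4],
    })

    def variants(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "protein_change"])

    def test_primary_match_requires_q_below_threshold(self):
        v = self.variants([("S1", "GENE_A", "p.R100Q"),
                           ("S1", "GENE_A", "p.E300K")])
        out = annotate_hotspots(v, self.catalog)
        assert list(out["protein_change"]) == ["p.R100Q"]
        assert list(out["match_type"]) == ["primary"]

    def test_secondary_hotspots_relaxed_within_anchored_gene(self):
        v = self.variants([("S1", "GENE_A", "p.R100Q"),
                           ("S1", "GENE_A", "p.E300K")])
        out = annotate_hotspots(v, self.catalog, relax_secondary=True)
        assert list(out["protein_change"]) == ["p.R100Q", "p.E300K"]
        assert list(out["match_type"]) == ["primary", "secondary"]
        # a weak hotspot in a gene with no primary anchor stays out
        v2 = self.variants([("S1", "GENE_A", "p.E300K")])
        assert len(annotate_hotspots(v2, self.catalog, relax_secondary=True)) == 0

    def test_uncataloged_variant_unmatched(self):
        v = self.variants([("S1", "GENE_C", "p.A1V")])
        assert len(annotate_hotspots(v, self.catalog)) == 0


def random_matrix(rng, n_features=8, n_samples=88, prevalence=20):
    rows = {}
    for i in range(n_features):
        row = np.zeros(n_samples, dtype=int)
        row[rng.choice(n_samples, prevalence, replace=False)] = 1
        rows[f"F{i}"] = row
    return pd.DataFrame(rows).T


class TestOverlapAnalysis:
    def test_low_prevalence_features_excluded(self, rng):
        mat = random_matrix(rng, n_features=3, prevalence=20)
        mat.loc["RARE"] = np.concatenate([np.ones(15, int), np.zeros(73, int)])
        out = overlap_analysis(mat, min_mutant=16)
        tested = set(out["feature_a"]) | set(out["feature_b"])
        assert "RARE" not in tested
        assert len(out) == 3  # C(3, 2) pairs among retained features

    def test_identical_rows_dominate_significance(self, rng):
        mat = random_matrix(rng, n_features=5, prevalence=20)
        mat.loc["DUP"] = mat.loc["F0"]
        out = overlap_analysis(mat, min_mutant=16)
        top = out.iloc[0]
        assert {top["feature_a"], top["feature_b"]} == {"F0", "DUP"}
        assert top["p"] == pytest.approx(fisher_oracle(20, 0, 0, 68), rel=1e-9)
        # q computed across the full test set
        assert top["q"] == pytest.approx(min(1.0, top["p"] * len(out)), rel=1e-9)

    def test_pathway_member_pairs_excluded(self, rng):
        mat = random_matrix(rng, n_features=2, prevalence=30)
        mat.loc["PW"] = mat.loc[["F0", "F1"]].max(axis=0)
        out = overlap_analysis(mat, min_mutant=16,
                               pathway_members={"PW": ["F0", "F1"]})
        pairs = {frozenset((a, b)) for a, b in zip(out["feature_a"],
                                                   out["feature_b"])}
        assert frozenset(("PW", "F0")) not in pairs
        assert frozenset(("PW", "F1")) not in pairs
        assert frozenset(("F0", "F1")) in pairs

    def test_invariant_to_sample_and_feature_order(self, rng):
        mat = random_matrix(rng, n_features=5, prevalence=25)
        out = overlap_analysis(mat, min_mutant=16)
        shuffled = mat.sample(frac=1.0, axis=0, random_state=3) \
            .sample(frac=1.0, axis=1, random_state=4)
        out2 = overlap_analysis(shuffled, min_mutant=16)
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      out2.reset_index(drop=True))

    def test_fewer_than_two_retained_features(self, rng):
        mat = random_matrix(rng, n_features=1, prevalence=20)
        assert len(overlap_analysis(mat, min_mutant=16)) == 0

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError):
            overlap_analysis(pd.DataFrame([[0, 2], [1, 0]]))


class TestAlterationMatrix:
    def test_pathway_rows_are_or_of_members(self):
        long = pd.DataFrame({
            "sample_id": ["S1", "S2", "S2"],
            "feature": ["TP53", "MDM2", "TP53"],
        })
        mat = build_alteration_matrix(long, ["S1", "S2", "S3"],
                                      pathways={"p53": ["TP53", "MDM2"]},
                                      subtypes={"S1": "a", "S2": "b", "S3": "a"})
        assert list(mat.loc["p53"]) == [1, 1, 0]
        assert list(mat.loc["subtype:a"]) == [1, 0, 1]
        assert mat.isin([0, 1]).all().all()
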