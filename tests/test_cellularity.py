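"""Tumor-purity estimators: exact inversions, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from csccqc.cellularity import (
    cellularity_from_cnloh_ai,
    cellularity_from_deletion_ai,
    cellularity_from_median_maf,
    cellularity_from_modal_maf,
    estimate_cellularity,
    pooled_minor_fraction,
)
from csccqc.simulate import simulate_clonal_read_counts, simulate_het_snp_counts


def snp_frame(pairs, label):
    return pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, len(pairs) + 1),
        "a_reads": [a for a, _ in pairs], "b_reads": [b for _, b in pairs],
        "region_label": label,
    })


def exact_f_frame(f, label, total=60_000):
    """One pooled SNP set whose minor fraction is exactly f."""
    minor = int(round(f * total))
    return snp_frame([(total - minor, minor)], label)


def grid_invert(f, model):
    """Brute-force inversion of a mixture model f(rho) on a fine rho grid."""
    grid = np.linspace(0.0, 1.0, 2_000_001)
    return grid[np.argmin(np.abs(model(grid) - f))]


class TestAllelicImbalance:
    @pytest.mark.parametrize("f, expected", [
        (0.0, 1.0),    # no reads from the lost allele: pure tumor
        (0.5, 0.0),    # balanced alleles: no tumor
        (1 / 3, 0.5),
    ])
    def test_deletion_inversion(self, f, expected):
        est = cellularity_from_deletion_ai(exact_f_frame(f, "deletion"))
        assert est.rho == pytest.approx(expected, abs=1e-9)
        oracle = grid_invert(f, lambda r: (1 - r) / (2 - r))
        assert est.rho == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("f, expected", [
        (0.0, 1.0), (0.5, 0.0), (0.25, 0.5),
    ])
    def test_cnloh_inversion(self, f, expected):
        est = cellularity_from_cnloh_ai(exact_f_frame(f, "cnLOH"))
        assert est.rho == pytest.approx(expected, abs=1e-9)
        oracle = grid_invert(f, lambda r: (1 - r) / 2)
        assert est.rho == pytest.approx(oracle, abs=1e-6)

    def test_inversions_match_grid_oracle_across_f(self):
        for f in np.linspace(0.01, 0.49, 25):
            del_est = cellularity_from_deletion_ai(exact_f_frame(f, "deletion"))
            assert del_est.rho == pytest.approx(
                grid_invert(f, lambda r: (1 - r) / (2 - r)), abs=1e-6)
            loh_est = cellularity_from_cnloh_ai(exact_f_frame(f, "cnLOH"))
            assert loh_est.rho == pytest.approx(
                grid_invert(f, lambda r: (1 - r) / 2), abs=1e-6)

    def test_rho_always_within_unit_interval(self, rng):
        # per-SNP minor pooling keeps f <= 0.5, so estimates stay in [0, 1]
        for _ in range(50):
            pairs = list(zip(rng.integers(0, 100, 20), rng.integers(1, 100, 20)))
            for fn, label in ((cellularity_from_deletion_ai, "deletion"),
                              (cellularity_from_cnloh_ai, "cnLOH")):
                est = fn(snp_frame(pairs, label))
                assert 0.0 <= est.rho <= 1.0

    def test_invariant_to_order_and_allele_swap(self, rng):
        snps = simulate_het_snp_counts(0.6, "deletion", 400, 60, rng)
        base = cellularity_from_deletion_ai(snps).rho
        shuffled = snps.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert cellularity_from_deletion_ai(shuffled).rho == base
        swapped = snps.rename(columns={"a_reads": "b_reads", "b_reads": "a_reads"})
        assert cellularity_from_deletion_ai(swapped).rho == base

    def test_rejects_empty_or_mislabeled(self):
        with pytest.raises(ValueError):
            cellularity_from_deletion_ai(snp_frame([], "deletion"))
        with pytest.raises(ValueError):
            cellularity_from_deletion_ai(exact_f_frame(0.2, "cnLOH"))


class TestModalMaf:
    def test_doubling_rule_on_degenerate_data(self):
        est = cellularity_from_modal_maf([0.25] * 100)
        assert est.rho == pytest.approx(0.5, abs=1e-12)
        est = cellularity_from_modal_maf([0.5] * 100)
        assert est.rho == pytest.approx(1.0, abs=1e-12)

    def test_mode_of_clonal_subclonal_mixture(self, rng):
        # 80% clonal around MAF 0.30, 20% subclonal around 0.10: the mode
        # sits at 0.30 so rho ~ 0.6
        mafs = np.concatenate([
            rng.normal(0.30, 0.03, 400), rng.normal(0.10, 0.02, 100)])
        mafs = np.clip(mafs, 0.01, 0.59)
        est = cellularity_from_modal_maf(mafs)
        assert est.rho == pytest.approx(0.6, abs=0.05)
        # agreement with an exhaustive fine-grid mode of the same KDE target
        from scipy.stats import gaussian_kde
        grid = np.linspace(0.001, 0.6, 60_000)
        oracle_mode = grid[np.argmax(gaussian_kde(mafs, bw_method="silverman")(grid))]
        assert est.rho == pytest.approx(2 * oracle_mode, abs=0.01)

    def test_too_few_mutations_raises(self):
        with pytest.raises(ValueError):
            cellularity_from_modal_maf([0.3] * 10, min_mutations=50)


class TestMedianMaf:
    def test_female_doubles_autosomal_median(self):
        est = cellularity_from_median_maf([0.2, 0.2, 0.25, 0.15], sex="female")
        assert est.rho == pytest.approx(0.4, abs=1e-12)

    def test_male_sex_chromosome_not_doubled(self):
        est = cellularity_from_median_maf([], [0.45, 0.45, 0.45], sex="male")
        assert est.rho == pytest.approx(0.45, abs=1e-12)

    def test_male_count_weighted_combination(self):
        # 90 autosomal MAFs with median 0.25 (-> 0.5) and 10 sex-chromosome
        # MAFs with median 0.5 (-> 0.5): weighted mean 0.5
        est = cellularity_from_median_maf([0.25] * 90, [0.5] * 10, sex="male")
        assert est.rho == pytest.approx(0.5, abs=1e-12)
        assert est.n_support == 100
        # asymmetric case, computed by hand: (90*0.4 + 10*0.3)/100 = 0.39
        est = cellularity_from_median_maf([0.2] * 90, [0.3] * 10, sex="male")
        assert est.rho == pytest.approx(0.39, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cellularity_from_median_maf([], [], sex="female")


class TestEstimatorSelection:
    def test_priority_prefers_deletion_ai(self, rng):
        snps = pd.concat([
            simulate_het_snp_counts(0.7, "deletion", 100, 60, rng),
            simulate_het_snp_counts(0.7, "neutral", 100, 60, rng),
        ], ignore_index=True)
        alt, ref = simulate_clonal_read_counts(0.7, 300, 60, rng)
        mafs = alt / (alt + ref)
        selected, estimates = estimate_cellularity(snps, mafs, sex="female")
        assert selected.method == "deletion_AI"
        assert {e.method for e in estimates} >= {"deletion_AI", "modal_MAF",
                                                 "median_MAF"}

    def test_modal_chosen_without_cn_events(self, rng):
        alt, ref = simulate_clonal_read_counts(0.6, 500, 80, rng)
        mafs = alt / (alt + ref)
        selected, _ = estimate_cellularity(None, mafs, sex="female")
        assert selected.method == "modal_MAF"

    def test_methods_agree_on_simulated_sample(self, rng):
        rho = 0.7
        snps = pd.concat([
            simulate_het_snp_counts(rho, "deletion", 1000, 60, rng),
            simulate_het_snp_counts(rho, "cnLOH", 1000, 60, rng),
        ], ignore_index=True)
        alt, ref = simulate_clonal_read_counts(rho, 300, 60, rng)
        mafs = alt / (alt + ref)
        _, estimates = estimate_cellularity(snps, mafs, sex="female")
        assert len(estimates) == 4
        for est in estimates:
            assert est.rho == pytest.approx(rho, abs=0.05), est.method

    def test_no_method_applicable(self):
        with pytest.raises(ValueError):
            estimate_cellularity(None, [], sex="female")

    def test_pooled_fraction_requires_reads(self):
        with pytest.raises(ValueError):
            pooled_minor_fraction(np.array([0]), np.array([0]))
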