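"""Simulator statistics match their generative model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gametophase.simdata import (
    ConfigurationError,
    SimConfig,
    simulate_coverage_table,
    simulate_donor,
    simulate_long_reads,
    simulate_meiosis,
    simulate_phenotypes,
    simulate_sperm_calls,
)


class TestDonor:
    def test_site_count_and_order(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=10_000_000, het_density=1e-4, seed=0)
        sites, _ = simulate_donor(cfg)
        assert len(sites) == 1_000
        assert (np.diff(sites["pos"]) > 0).all()
        assert (sites["allele_a"] != sites["allele_b"]).all()

    def test_same_seed_reproduces_site_table(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=1_000_000, seed=7)
        a, _ = simulate_donor(cfg)
        b, _ = simulate_donor(cfg)
        pd.testing.assert_frame_equal(a, b)
        c, _ = simulate_donor(SimConfig(n_chromosomes=2, chrom_length_bp=1_000_000, seed=8))
        assert not a["pos"].equals(c["pos"])

    def test_study_density_gives_study_scale_site_count(self):
        # ~1 het site per 478 bp on a 20-Mb scaled chromosome
        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=20_000_000, het_density=1 / 478, seed=0)
        sites, _ = simulate_donor(cfg)
        # 2.4 Gb at this density carries ~5 million sites; per-Mb rate matches
        assert sites.shape[0] == pytest.approx(20e6 / 478, rel=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(het_density=0.0),
            dict(chrom_length_bp=0),
            dict(dropout_rate=1.5),
            dict(qtl_position=("chrX", 100)),
            dict(read_length_bp=2_000_000, chrom_length_bp=1_000_000),
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestMeiosis:
    def test_obligate_crossover_forces_at_least_one(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=1_000_000, n_sperm=1_000,
            mean_crossovers_per_chrom=1.0, obligate_crossover=True, seed=3,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        assert all(len(xo["chr1"]) >= 1 for xo in truth.crossovers)

    def test_crossover_count_mean_within_three_standard_errors(self):
        mean = 1.3
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=1_000_000, n_sperm=10_000,
            mean_crossovers_per_chrom=mean, seed=4,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        counts = np.array([len(xo["chr1"]) for xo in truth.crossovers])
        se = np.sqrt(mean / len(counts))  # Poisson variance == mean
        assert abs(counts.mean() - mean) < 3 * se

    def test_genome_wide_mean_matches_study_scale(self):
        # 18 crossovers spread over 19 autosomes, 102 sperm
        cfg = SimConfig(seed=5)
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        per_sperm = [sum(len(x) for x in xo.values()) for xo in truth.crossovers]
        se = np.sqrt(18.0 / len(per_sperm))
        assert np.mean(per_sperm) == pytest.approx(18.0, abs=3 * se)

    def test_origin_tracks_switch_exactly_at_crossovers(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=2_000_000, n_sperm=30,
            mean_crossovers_per_chrom=2.0, seed=6,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        pos = truth.sites["pos"].to_numpy()
        for s in range(cfg.n_sperm):
            xs = truth.crossovers[s]["chr1"]
            assert (np.diff(xs) > 0).all()
            expect = (truth.start_phase[s, 0] + np.searchsorted(xs, pos)) % 2
            np.testing.assert_array_equal(truth.origins[s], expect)


class TestSpermCalls:
    def test_noiseless_limit_reproduces_truth(self):
        cfg = SimConfig(
            n_chromosomes=2, chrom_length_bp=1_000_000, n_sperm=20,
            dropout_rate=0.0, genotype_error_rate=0.0, seed=7,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        m = simulate_sperm_calls(truth, cfg)
        np.testing.assert_array_equal(m.calls, truth.truth_codes())

    def test_dropout_and_error_rates_are_binomial(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=10_000_000, het_density=1e-3,
            n_sperm=20, dropout_rate=0.5, genotype_error_rate=0.01, seed=8,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        m = simulate_sperm_calls(truth, cfg)
        observed = m.calls != -1
        per_sperm = observed.mean(axis=0)  # 10,000 sites each
        assert ((per_sperm > 0.47) & (per_sperm < 0.53)).all()
        codes = truth.truth_codes()
        err = (m.calls[observed] != codes[observed]).mean()
        n_obs = observed.sum()
        assert err == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / n_obs))

    def test_observed_calls_are_site_alleles(self, small_sim):
        _, _, m = small_sim
        assert set(np.unique(m.calls)) <= {-1, 0, 1}

    def test_per_sperm_coverage_range_widens_spread(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=5_000_000, n_sperm=40,
            per_sperm_coverage_range=(0.18, 0.68), seed=9,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        m = simulate_sperm_calls(truth, cfg)
        frac = (m.calls != -1).mean(axis=0)
        assert frac.min() < 0.3 and frac.max() > 0.55


class TestLongReads:
    def test_read_count_follows_depth(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=1_500_000, read_depth=4.0,
            read_length_bp=15_000, n_sperm=2, seed=10,
        )
        _, truth = simulate_donor(cfg)
        reads = simulate_long_reads(truth, cfg)
        assert len(reads) == round(4.0 * 1_500_000 / 15_000)
        assert all(len(r.sequence) == 15_000 for r in reads)

    def test_read_alleles_match_source_haplotype(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=500_000, read_depth=2.0,
            read_length_bp=20_000, n_sperm=2, seed=11,
        )
        _, truth = simulate_donor(cfg)
        hap_seqs = {h: truth.chromosome_sequence("chr1", h) for h in (0, 1)}
        for r in simulate_long_reads(truth, cfg):
            assert r.sequence == hap_seqs[r.haplotype][r.start - 1 : r.start - 1 + 20_000]


class TestPhenotypes:
    def test_tertile_grades_are_balanced(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=500_000, n_sperm=100, seed=12)
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        pheno = simulate_phenotypes(truth, cfg)
        counts = pheno["grade"].value_counts()
        assert set(counts.index) == {1, 2, 3}
        assert counts.max() - counts.min() <= 1
        # grade 1 holds the best (highest) latent values
        assert pheno.groupby("grade")["latent"].mean().is_monotonic_decreasing

    def test_planted_effect_appears_in_latent_scale(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=2_000_000, n_sperm=2_000,
            qtl_position=("chr1", 1_000_000), qtl_effect=2.0, seed=13,
        )
        _, truth = simulate_donor(cfg)
        simulate_meiosis(truth, cfg)
        pheno = simulate_phenotypes(truth, cfg)
        g = np.array([truth.origin_at(s, "chr1", 1_000_000) for s in range(cfg.n_sperm)])
        diff = pheno["latent"][g == 1].mean() - pheno["latent"][g == 0].mean()
        assert diff == pytest.approx(2.0, abs=0.2)

    def test_null_effect_gives_no_association(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_chromosomes=1, chrom_length_bp=1_000_000, n_sperm=150,
                qtl_position=("chr1", 500_000), qtl_effect=0.0, seed=100 + seed,
            )
            _, truth = simulate_donor(cfg)
            simulate_meiosis(truth, cfg)
            pheno = simulate_phenotypes(truth, cfg)
            g = np.array([truth.origin_at(s, "chr1", 500_000) for s in range(cfg.n_sperm)])
            table = pd.crosstab(pheno["grade"], g)
            _, p, _, _ = stats.chi2_contingency(table)
            hits += p >= 0.05
        assert hits >= 18  # >=90% of null seeds non-significant


def test_coverage_table_separates_sexes():
    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=500_000, n_sperm=80, seed=14)
    _, truth = simulate_donor(cfg)
    simulate_meiosis(truth, cfg)
    cov = simulate_coverage_table(truth)
    is_y = truth.sex == "Y"
    assert (cov["y_cov"][is_y] > 0.5).all() and (cov["y_cov"][~is_y] < 0.2).all()
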