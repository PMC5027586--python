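import dataclasses

import numpy as np
import pytest

from groseqtk.simulate import (
    CHIP_CONDITIONS,
    GRO_CONDITIONS,
    GeneTruth,
    IntergenicEnhancerTruth,
    IntragenicEnhancerTruth,
    SimConfig,
    TFSite,
    TruthSet,
    generate_truth,
    simulate_chip_coverage,
    simulate_groseq,
)

from oracles import validate_truth


def tiny_truth(genes=(), inter=(), intra=(), tf=None, k4=(), **cfg_kwargs):
    cfg = SimConfig(
        n_chromosomes=1,
        chrom_length=200_000,
        n_genes=0,
        n_intergenic_enhancers=0,
        n_intragenic_enhancers=0,
        n_tf_extra_sites=0,
        seed=0,
        **cfg_kwargs,
    )
    return TruthSet(
        config=cfg,
        genes=list(genes),
        intergenic_enhancers=list(inter),
        intragenic_enhancers=list(intra),
        h3k4me2=list(k4),
        tf_sites=tf or {},
    )


def gene(start=50_000, end=70_000, strand="+", fc2=0.0, fc05=0.0, density=0.5, ratio=1.0):
    return GeneTruth(
        gene_id="g0",
        chrom="chr1",
        strand=strand,
        start=start,
        end=end,
        base_density=density,
        log2fc={"t0.5": fc05, "t2": fc2},
        pausing_ratio=ratio,
    )


class TestGenerateTruth:
    def test_counts_pass_through(self):
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_length=1_000_000,
            n_genes=10,
            n_intergenic_enhancers=0,
            n_intragenic_enhancers=0,
            n_tf_extra_sites=5,
            seed=1,
        )
        truth = generate_truth(cfg)
        assert len(truth.genes) == 10
        assert truth.intergenic_enhancers == []

    def test_determinism(self):
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_length=1_000_000,
            n_genes=15,
            n_intergenic_enhancers=4,
            n_intragenic_enhancers=4,
            n_tf_extra_sites=5,
            seed=3,
        )
        a, b = generate_truth(cfg), generate_truth(dataclasses.replace(cfg))
        assert a == b

    def test_intragenic_invariants_brute_force(self):
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_length=1_000_000,
            n_genes=20,
            n_intergenic_enhancers=0,
            n_intragenic_enhancers=5,
            n_tf_extra_sites=5,
            seed=2,
        )
        truth = generate_truth(cfg)
        assert len(truth.intragenic_enhancers) == 5
        assert validate_truth(truth) == []

    def test_full_truth_satisfies_invariants(self, small_truth):
        assert validate_truth(small_truth) == []

    def test_placement_failure_is_loud(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=300_000, n_genes=50, seed=1,
            n_intergenic_enhancers=0, n_intragenic_enhancers=0, n_tf_extra_sites=0,
        )
        with pytest.raises(ValueError, match="cannot place"):
            generate_truth(cfg)

    def test_too_many_enhancers_is_loud(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=1_000_000, n_genes=10,
            n_intergenic_enhancers=100, n_intragenic_enhancers=0,
            n_tf_extra_sites=0, seed=1,
        )
        with pytest.raises(ValueError, match="clearance"):
            generate_truth(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_genes_up=1.2).validate()
        with pytest.raises(ValueError):
            SimConfig(gene_length_range=(500, 2000)).validate()

    def test_regulated_fractions_honored(self):
        cfg = SimConfig(
            n_chromosomes=2, chrom_length=3_000_000, n_genes=100,
            frac_genes_up=0.2, frac_genes_down=0.1, early_fraction=1.0,
            n_intergenic_enhancers=0, n_intragenic_enhancers=0,
            n_tf_extra_sites=0, seed=4,
        )
        truth = generate_truth(cfg)
        n_up = sum(g.log2fc["t2"] > 0 for g in truth.genes)
        n_down = sum(g.log2fc["t2"] < 0 for g in truth.genes)
        assert n_up == 20 and n_down == 10


class TestSimulateGroseq:
    def test_support_of_emission_model(self):
        truth = tiny_truth(genes=[gene()], background_density=0.0)
        cov = simulate_groseq(truth, "vehicle", 1)
        plus, minus = cov.chroms["chr1"]
        bw = truth.config.bin_width
        assert minus.sum() == 0
        assert plus[: 50_000 // bw].sum() == 0
        assert plus[70_000 // bw :].sum() == 0
        assert plus[50_000 // bw : 70_000 // bw].sum() > 0

    def test_unknown_condition_rejected(self):
        truth = tiny_truth()
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_groseq(truth, "t4", 1)

    def test_determinism(self):
        truth = tiny_truth(genes=[gene()])
        a = simulate_groseq(truth, "t2", 1)
        b = simulate_groseq(truth, "t2", 1)
        np.testing.assert_array_equal(a.chroms["chr1"][0], b.chroms["chr1"][0])

    def test_total_tags_conservation(self):
        truth = tiny_truth(genes=[gene()])
        cov = simulate_groseq(truth, "vehicle", 1)
        plus, minus = cov.chroms["chr1"]
        assert cov.total_tags == int(plus.sum() + minus.sum())

    def test_fold_change_monte_carlo(self):
        truth = tiny_truth(genes=[gene(fc2=1.0, density=1.0)], background_density=0.0)
        bw = truth.config.bin_width
        sl = slice(50_000 // bw, 70_000 // bw)
        means = {}
        for cond in ("vehicle", "t2"):
            tags = [
                simulate_groseq(truth, cond, rep).chroms["chr1"][0][sl].mean()
                for rep in range(60)
            ]
            means[cond] = np.mean(tags)
        ratio = means["t2"] / means["vehicle"]
        assert 1.8 <= ratio <= 2.2

    def test_pausing_ratio_monte_carlo(self):
        truth = tiny_truth(
            genes=[gene(density=1.0, ratio=10.0)], background_density=0.0
        )
        bw = truth.config.bin_width
        prom = slice((50_000 - 50) // bw, (50_000 + 250) // bw)
        body = slice((50_000 + 250) // bw, 70_000 // bw)
        ratios = []
        for rep in range(60):
            plus = simulate_groseq(truth, "vehicle", rep).chroms["chr1"][0]
            ratios.append(plus[prom].mean() / plus[body].mean())
        assert 8.0 <= float(np.mean(ratios)) <= 12.0

    def test_enhancer_emission_strands(self):
        inter = IntergenicEnhancerTruth(
            id="e0", chrom="chr1", center=100_000,
            plus_span=(100_200, 100_500), minus_span=(99_500, 99_800),
            density=1.0, log2fc={"t0.5": 0.0, "t2": 0.0},
        )
        truth = tiny_truth(inter=[inter], background_density=0.0)
        cov = simulate_groseq(truth, "vehicle", 1)
        plus, minus = cov.chroms["chr1"]
        bw = truth.config.bin_width
        assert plus[100_200 // bw : 100_500 // bw].sum() > 0
        assert minus[99_500 // bw : 99_800 // bw].sum() > 0
        assert plus[99_500 // bw : 99_800 // bw].sum() == 0

    def test_intragenic_emits_antisense(self):
        host = gene(density=0.0)  # silent host isolates the enhancer signal
        intra = IntragenicEnhancerTruth(
            id="i0", host_gene="g0", chrom="chr1", start=60_000, end=60_300,
            strand="-", density=1.0, log2fc={"t0.5": 0.0, "t2": 0.0},
        )
        truth = tiny_truth(genes=[host], intra=[intra], background_density=0.0)
        cov = simulate_groseq(truth, "vehicle", 1)
        plus, minus = cov.chroms["chr1"]
        bw = truth.config.bin_width
        assert minus[60_000 // bw : 60_300 // bw].sum() > 0
        assert plus.sum() == 0


class TestSimulateChip:
    def site(self, conditions=CHIP_CONDITIONS):
        return TFSite(chrom="chr1", start=100_000, end=100_400, conditions=tuple(conditions))

    def test_unknown_factor_rejected(self):
        truth = tiny_truth(tf={"AR": []})
        with pytest.raises(ValueError, match="unknown factor"):
            simulate_chip_coverage(truth, "FOXA1", "t2", 1)

    def test_factor_without_sites_matches_control(self):
        truth = tiny_truth(tf={"AR": []})
        t = simulate_chip_coverage(truth, "AR", "t2", 1)
        c = simulate_chip_coverage(truth, "AR", "t2", 1, control=True)
        ratio = t.chroms["chr1"][0].mean() / c.chroms["chr1"][0].mean()
        assert 0.8 <= ratio <= 1.25

    def test_enrichment_monte_carlo(self):
        truth = tiny_truth(tf={"AR": [self.site()]}, chip_enrichment=8.0)
        bw = truth.config.bin_width
        sl = slice(100_000 // bw, 100_400 // bw)
        t_means, c_means = [], []
        for rep in range(60):
            t_means.append(simulate_chip_coverage(truth, "AR", "t2", rep).chroms["chr1"][0][sl].mean())
            c_means.append(
                simulate_chip_coverage(truth, "AR", "t2", rep, control=True).chroms["chr1"][0][sl].mean()
            )
        ratio = np.mean(t_means) / np.mean(c_means)
        assert 6.0 <= ratio <= 10.0

    def test_site_inactive_in_condition_is_background(self):
        truth = tiny_truth(tf={"AR": [self.site(conditions=("t2",))]})
        bw = truth.config.bin_width
        sl = slice(100_000 // bw, 100_400 // bw)
        t = simulate_chip_coverage(truth, "AR", "t0.5", 1)
        c = simulate_chip_coverage(truth, "AR", "t0.5", 1, control=True)
        ratio = t.chroms["chr1"][0][sl].mean() / c.chroms["chr1"][0][sl].mean()
        assert 0.5 <= ratio <= 1.5

    def test_deterministic_under_fixed_seed(self):
        truth = tiny_truth(tf={"AR": [self.site()]})
        a = simulate_chip_coverage(truth, "AR", "t2", 1)
        b = simulate_chip_coverage(truth, "AR", "t2", 1)
        np.testing.assert_array_equal(a.chroms["chr1"][0], b.chroms["chr1"][0])

    def test_unstranded(self):
        truth = tiny_truth(tf={"AR": []})
        cov = simulate_chip_coverage(truth, "AR", "t2", 1)
        assert not cov.stranded
        assert cov.chroms["chr1"][0] is cov.chroms["chr1"][1]
        assert cov.total_tags == int(cov.chroms["chr1"][0].sum())


class TestConditions:
    def test_condition_sets(self):
        assert GRO_CONDITIONS == ("vehicle", "t0.5", "t2")
        assert CHIP_CONDITIONS == ("vehicle", "t0.5", "t2", "t4")
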