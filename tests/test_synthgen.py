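import numpy as np
import pytest

from balsel.diversity import diversity_summary, divergence
from balsel.genealogy import four_gamete_screen
from balsel.neutrality import tajimas_d
from balsel.regionio import read_bed, read_haplotype_fasta
from balsel.synthgen import (
    BalancedRegionSpec,
    ThinningSpec,
    generate_balanced_region,
    generate_neutral_region,
    generate_reference_panel,
    thin_singletons,
    write_region_bundle,
)


class TestNeutralRegion:
    def test_no_recombination_passes_four_gamete(self):
        aln, _ = generate_neutral_region(n=40, L=2000, theta=10.0, seed=7)
        assert four_gamete_screen(aln).compatible

    def test_divergence_matches_two_lineage_clock(self):
        # mean fixed-difference rate ~ 2 mu t over replicates
        mu, t_years, gen = 2.7e-8, 6e6, 25.0
        expected = 2 * mu * (t_years / gen)
        rates = []
        for seed in range(300):
            _, og = generate_neutral_region(
                n=8, L=1000, mu=mu, seed=seed,
                outgroup_split_years=t_years, generation_years=gen)
            rates.append(divergence(og).d_raw)
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - expected) < 3 * se

    def test_same_seed_identical(self):
        a1, og1 = generate_neutral_region(n=10, L=500, theta=5.0, seed=42)
        a2, og2 = generate_neutral_region(n=10, L=500, theta=5.0, seed=42)
        assert np.array_equal(a1.haplotypes, a2.haplotypes)
        assert np.array_equal(a1.positions, a2.positions)
        assert np.array_equal(og1.site_class, og2.site_class)


class TestReferencePanelGeneration:
    def test_window_count_and_shape(self):
        alns = generate_reference_panel(count=25, window_bp=1000, n=10,
                                        seed=3)
        assert len(alns) == 25
        assert all(a.L == 1000 and a.n == 10 for a in alns)

    def test_fixed_theta_reduces_between_window_variance(self):
        fixed = generate_reference_panel(count=60, window_bp=2000, n=20,
                                         theta_mean=2e-3, fixed_theta=True,
                                         seed=5)
        spread = generate_reference_panel(count=60, window_bp=2000, n=20,
                                          theta_mean=2e-3, theta_sigma=1.0,
                                          seed=5)
        var_fixed = np.var([diversity_summary(a).theta_w for a in fixed])
        var_spread = np.var([diversity_summary(a).theta_w for a in spread])
        assert var_fixed < var_spread

    def test_minimum_count_enforced(self):
        with pytest.raises(ValueError):
            generate_reference_panel(count=5)


class TestBalancedRegion:
    def test_truth_tmrca_is_split_when_clades_are_shallower(self):
        spec = BalancedRegionSpec(seed=11)
        _, truth = generate_balanced_region(spec)
        if max(truth["clade_tmrcas_gen"]) <= 5e6 / 25:
            assert truth["tmrca_gen"] == 5e6 / 25
        assert truth["tmrca_years"] == truth["tmrca_gen"] * 25

    def test_two_balanced_clades_push_tajimas_d_positive(self):
        positive = sum(
            tajimas_d(generate_balanced_region(
                BalancedRegionSpec(seed=s))[0]) > 0
            for s in range(60))
        assert positive / 60 >= 0.8

    def test_three_clade_private_rare_clade_keeps_d_unremarkable(self):
        # deepest clade private to EAS at low frequency: diversity is high
        # but the SFS is not shifted to intermediate frequencies
        d_values, theta_ratio = [], []
        for seed in range(40):
            spec = BalancedRegionSpec(
                n={"EAS": 40}, clade_count=3,
                split_times_years=(2.8e6, 6e6),
                clade_frequencies={"EAS": (0.80, 0.15, 0.05)},
                seed=seed)
            aln, _ = generate_balanced_region(spec)
            summ = diversity_summary(aln)
            d_values.append(tajimas_d(aln))
            theta_ratio.append(summ.theta_w)
        assert np.median(d_values) < 1.0  # not the two-clade skew
        # still an extreme theta_w relative to the neutral expectation
        assert np.median(theta_ratio) > 4 * 2.5e-8 * 2 * 10_000

    def test_empty_clade_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            generate_balanced_region(BalancedRegionSpec(
                n={"CEU": 2}, clade_frequencies={"CEU": (1.0, 0.0)},
                seed=0))

    def test_clade_labels_cover_sample(self):
        spec = BalancedRegionSpec(
            n={"CEU": 20, "YRI": 20},
            clade_frequencies={"CEU": (0.5, 0.5), "YRI": (0.25, 0.75)},
            seed=9)
        aln, truth = generate_balanced_region(spec)
        assert len(truth["clade_labels"]) == aln.n == 40


class TestThinning:
    def _singleton_heavy(self, seed=0):
        aln, _ = generate_neutral_region(n=20, L=2000, theta=15.0, seed=seed)
        return aln

    def test_identity_at_zero(self):
        aln = self._singleton_heavy()
        out = thin_singletons(aln, ThinningSpec(0.0, seed=1))
        assert np.array_equal(out.haplotypes, aln.haplotypes)

    def test_full_thinning_removes_all_singletons(self):
        aln = self._singleton_heavy()
        out = thin_singletons(aln, ThinningSpec(1.0, seed=1))
        assert diversity_summary(out).eta_s == 0

    def test_binomial_retention_rate(self):
        kept = total = 0
        for seed in range(60):
            aln = self._singleton_heavy(seed)
            n_singletons = sum(
                1 for j in range(aln.m)
                if (np.bincount(aln.haplotypes[:, j]) == 1).any())
            out = thin_singletons(aln, ThinningSpec(0.5, seed=seed))
            total += n_singletons
            kept += n_singletons - (aln.m - out.m)
        p_hat = kept / total
        se = np.sqrt(0.25 / total)
        assert abs(p_hat - 0.5) < 3 * se


class TestBundleRoundTrip:
    def test_outputs_readable_by_the_io_layer(self, tmp_path):
        aln, og = generate_neutral_region(n=10, L=800, theta=6.0, seed=2)
        paths = write_region_bundle(aln, tmp_path, og=og,
                                    truth={"tmrca_gen": 1.0})
        again = read_haplotype_fasta(paths["fasta"], paths["pop_map"])
        assert np.array_equal(again.haplotypes, aln.haplotypes)
        assert np.array_equal(again.positions, aln.positions)
        regions = read_bed(paths["bed"])
        assert regions[0].length == 800
        assert paths["truth"].exists() and paths["outgroup"].exists()
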