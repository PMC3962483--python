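"""Generator contracts: determinism, Mendelian legality, sweep and admixture
structure, microsatellite/morphometric control parameters."""

import numpy as np
import pytest

from medpopgen.containers import MISSING
from medpopgen.diversity import inbreeding_coefficient
from medpopgen.selection import ehh
from medpopgen.simulate import (
    ScenarioSpec,
    SimConfig,
    inject_sweep,
    simulate_admixture,
    simulate_bottleneck_population,
    simulate_inbred_line,
    simulate_microsatellites,
    simulate_morphometrics,
    simulate_neutral_population,
    simulate_trios,
)
from medpopgen.variant_io import mendel_check, read_vcf, write_vcf


class TestConfigValidation:
    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, sequence_length=0)
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_haplotypes=7)
        with pytest.raises(ValueError):
            SimConfig(seed=1, mutation_rate=-1e-8)
        with pytest.raises(ValueError):
            ScenarioSpec(kind="sweeep")
        with pytest.raises(ValueError):
            ScenarioSpec(kind="admixture", admixture_fraction=1.5)


class TestNeutralPopulation:
    def test_zero_mutation_rate_zero_sites(self):
        haps = simulate_neutral_population(
            SimConfig(seed=1, sequence_length=10_000, n_haplotypes=4,
                      mutation_rate=0.0))
        assert haps.n_sites == 0

    def test_seed_determinism(self):
        cfg = SimConfig(seed=99, sequence_length=50_000, n_haplotypes=8)
        assert simulate_neutral_population(cfg) == simulate_neutral_population(cfg)
        other = simulate_neutral_population(
            SimConfig(seed=100, sequence_length=50_000, n_haplotypes=8))
        assert other != simulate_neutral_population(cfg)

    def test_ancestral_recorded_and_positions_increasing(self, wild_population):
        assert wild_population.known_ancestral().all()
        assert np.all(np.diff(wild_population.positions) > 0)

    def test_vcf_round_trip_lossless(self, wild_population, tmp_path):
        path = tmp_path / "sim.vcf"
        write_vcf(wild_population, path)
        assert read_vcf(path, phased=True) == wild_population

    def test_duplicated_lineage_zero_heterozygosity(self):
        haps = simulate_neutral_population(
            SimConfig(seed=3, sequence_length=50_000, n_haplotypes=2))
        dup = haps.haplotypes.copy()
        dup[1] = dup[0]
        assert (dup[0] == dup[1]).all()
        pi = (dup[0] != dup[1]).mean() if dup.shape[1] else 0.0
        assert pi == 0.0

    def test_bottleneck_reduces_diversity(self):
        cfg = SimConfig(seed=5, sequence_length=200_000, n_haplotypes=16)
        spec = ScenarioSpec(kind="bottleneck", bottleneck_time=100,
                            bottleneck_size_ratio=0.01)
        neutral = [simulate_neutral_population(
            SimConfig(seed=50 + s, sequence_length=200_000, n_haplotypes=16)
        ).n_sites for s in range(5)]
        squeezed = [simulate_bottleneck_population(
            SimConfig(seed=70 + s, sequence_length=200_000, n_haplotypes=16), spec
        ).n_sites for s in range(5)]
        assert np.mean(squeezed) < np.mean(neutral)


class TestTrios:
    @pytest.fixture(scope="class")
    def founders(self):
        yield simulate_neutral_population(
            SimConfig(seed=7, sequence_length=150_000, n_haplotypes=16)
        ).to_genotype_table()

    def test_forced_transmission(self, founders):
        table, ped = simulate_trios(founders, 4, 2.5e-8, seed=1)
        hom = ((founders.genotypes[0] == founders.genotypes[0][:, [0]]).all(1)
               & (founders.genotypes[1] == founders.genotypes[0]).all(1)
               & (founders.genotypes[1][:, 0] == founders.genotypes[1][:, 1]))
        child = table.genotypes[table.sample_index("child0")]
        assert (child[hom] == founders.genotypes[0][hom]).all()

    def test_zero_recombination_transmits_whole_haplotypes(self, founders):
        table, _ = simulate_trios(founders, 1, 0.0, seed=2)
        child = table.genotypes[table.sample_index("child0")]
        father = founders.genotypes[0]
        mother = founders.genotypes[1]
        assert any(np.array_equal(child[:, 0], father[:, k]) for k in (0, 1))
        assert any(np.array_equal(child[:, 1], mother[:, k]) for k in (0, 1))

    def test_zero_mendelian_errors_by_construction(self, founders):
        table, ped = simulate_trios(founders, 4, 2.5e-8, seed=3)
        assert mendel_check(table, ped).total == 0

    def test_odd_founder_count_rejected(self, founders):
        odd = founders.take_samples(founders.samples[:3])
        with pytest.raises(ValueError, match="odd"):
            simulate_trios(odd, 1, 0.0, seed=1)

    def test_determinism(self, founders):
        a, _ = simulate_trios(founders, 2, 2.5e-8, seed=5)
        b, _ = simulate_trios(founders, 2, 2.5e-8, seed=5)
        assert a == b


class TestInjectSweep:
    def test_full_sweep_monomorphic_derived(self, wild_population):
        spec = ScenarioSpec(kind="sweep", sweep_position=150_000, sweep_frequency=1.0)
        swept = inject_sweep(wild_population, spec, seed=1)
        core = int(np.nonzero(swept.positions == 150_000)[0][0])
        assert swept.haplotypes[:, core].all()

    def test_half_frequency_rounding(self):
        haps = simulate_neutral_population(
            SimConfig(seed=9, sequence_length=100_000, n_haplotypes=20))
        spec = ScenarioSpec(kind="sweep", sweep_position=50_000, sweep_frequency=0.5)
        swept = inject_sweep(haps, spec, seed=2)
        core = int(np.nonzero(swept.positions == 50_000)[0][0])
        assert swept.haplotypes[:, core].sum() == 10

    def test_incompatible_frequency_rejected(self):
        haps = simulate_neutral_population(
            SimConfig(seed=9, sequence_length=50_000, n_haplotypes=20))
        spec = ScenarioSpec(kind="sweep", sweep_position=1000, sweep_frequency=0.01)
        with pytest.raises(ValueError, match="carriers"):
            inject_sweep(haps, spec, seed=1)

    def test_carrier_ehh_exceeds_noncarrier_ehh_at_10kb(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            haps = simulate_neutral_population(
                SimConfig(seed=500 + seed, sequence_length=300_000, n_haplotypes=48))
            spec = ScenarioSpec(kind="sweep", sweep_position=150_000,
                                sweep_frequency=0.5)
            swept = inject_sweep(haps, spec, seed=seed)
            core = int(np.nonzero(swept.positions == 150_000)[0][0])
            carriers = ehh(swept, core, "derived")
            others = ehh(swept, core, "ancestral")
            mean_c = (carriers.at_distance(10_000, "left")
                      + carriers.at_distance(10_000, "right")) / 2
            mean_o = (others.at_distance(10_000, "left")
                      + others.at_distance(10_000, "right")) / 2
            wins += mean_c > mean_o
        assert wins >= int(0.9 * n_seeds)


class TestAdmixture:
    def test_outgroup_fixed_ancestral(self):
        cfg = SimConfig(seed=11, sequence_length=100_000, n_haplotypes=8)
        panels = simulate_admixture(cfg, f=0.1)
        assert (panels["O"].haplotypes == 0).all()
        positions = panels["P1"].positions
        for label in ("P2", "P3", "O"):
            assert np.array_equal(panels[label].positions, positions)

    def test_f_one_aligns_p2_with_p3(self):
        from medpopgen.introgression import (QuartetData, QuartetSpec,
                                             d_statistic, site_patterns)
        cfg = SimConfig(seed=12, sequence_length=300_000, n_haplotypes=8)
        panels = simulate_admixture(cfg, f=1.0)
        data = QuartetData.from_haplotype_sets(panels)
        res = d_statistic(site_patterns(data, QuartetSpec("P1", "P2", "P3", "O")),
                          block_size_bp=50_000)
        assert res.d > 0.2

    def test_invalid_fraction_rejected(self):
        cfg = SimConfig(seed=1, sequence_length=10_000, n_haplotypes=4)
        with pytest.raises(ValueError):
            simulate_admixture(cfg, f=1.2)

    def test_determinism(self):
        cfg = SimConfig(seed=13, sequence_length=50_000, n_haplotypes=4)
        a = simulate_admixture(cfg, f=0.05)
        b = simulate_admixture(cfg, f=0.05)
        assert all(a[k] == b[k] for k in a)


class TestInbredLine:
    @pytest.fixture(scope="class")
    def founder(self):
        yield simulate_neutral_population(
            SimConfig(seed=17, sequence_length=200_000, n_haplotypes=4)
        ).to_genotype_table()

    def test_zero_generations_identity(self, founder):
        out = simulate_inbred_line(founder, 0, seed=1)
        assert out == founder

    def test_homozygous_founder_stays_homozygous(self, founder):
        # an already-isogenic pair: both individuals identical homozygotes
        hom = founder.genotypes.copy()
        hom[:, :, 1] = hom[:, :, 0]
        hom[1] = hom[0]
        from conftest import make_table
        founder_hom = make_table(hom, positions=founder.positions)
        out = simulate_inbred_line(founder_hom, 5, seed=2)
        assert not out.het_mask().any()

    def test_heterozygosity_declines(self, founder):
        h = []
        for g in (1, 4, 10):
            vals = [simulate_inbred_line(founder, g, seed=s).het_mask().mean()
                    for s in range(15)]
            h.append(np.mean(vals))
        assert h[0] > h[1] > h[2]


class TestMicrosatsAndMorphs:
    def test_hwe_table_f_near_zero(self):
        vals = [inbreeding_coefficient(
            simulate_microsatellites(9, 105, 12, target_F=0.0, seed=s)).mean
            for s in range(30)]
        assert abs(np.mean(vals)) < 0.05

    def test_morphometrics_columns_and_shapes(self):
        table = simulate_morphometrics(["a", "b"], 10, trait_h2=0.3, seed=1)
        assert list(table.columns) == ["strain", "L1", "L2", "L3", "L4",
                                       "D1", "D2", "D3", "D4", "D5"]
        assert len(table) == 20
        assert (table["L4"] > 0).all() and (table["D5"] > 0).all()

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            simulate_morphometrics(["a"], 5, trait_h2=1.5, seed=1)


class TestCoalescentCalibration:
    """Distributional checks of the neutral simulator against closed-form
    coalescent expectations."""

    @pytest.fixture(scope="class")
    def replicates(self):
        cfgs = [SimConfig(seed=100_000 + s, sequence_length=50_000,
                          n_haplotypes=10, recombination_rate=0.0)
                for s in range(200)]
        yield [simulate_neutral_population(c) for c in cfgs]

    def test_watterson_segregating_sites(self, replicates):
        """Observed S matches theta * sum(1/i) within 3 sampling SDs of the
        200-replicate mean."""
        n = 10
        theta = 4 * 15_000 * 2.5e-8 * 50_000
        expected = theta * sum(1 / i for i in range(1, n))
        s_obs = np.array([h.n_sites for h in replicates], float)
        se_mean = s_obs.std(ddof=1) / np.sqrt(len(s_obs))
        assert abs(s_obs.mean() - expected) < 3 * se_mean

    def test_folded_sfs_matches_coalescent_expectation(self, replicates):
        """Replicate-mean folded site-frequency spectrum vs the coalescent
        expectation E[eta_i] = theta (1/i + 1/(n-i)) / (1 + [i == n-i]).

        Sites within a replicate share genealogy, so the chi-square uses the
        across-replicate sampling covariance of the class counts (a
        Hotelling-type statistic against the chi-square reference), not a
        Poisson approximation.
        """
        from scipy import stats
        n = 10
        theta = 4 * 15_000 * 2.5e-8 * 50_000
        n_classes = n // 2
        per_rep = np.zeros((len(replicates), n_classes))
        for r, h in enumerate(replicates):
            derived = h.haplotypes.sum(axis=0)
            folded = np.minimum(derived, n - derived)
            for i in range(1, n_classes + 1):
                per_rep[r, i - 1] = (folded == i).sum()
        expect = theta * np.array([(1 / i + 1 / (n - i)) / (1 + (i == n - i))
                                   for i in range(1, n_classes + 1)])
        R = len(replicates)
        diff = per_rep.mean(axis=0) - expect
        cov = np.cov(per_rep, rowvar=False) / R
        t2 = float(diff @ np.linalg.solve(cov, diff))
        p = stats.chi2.sf(t2, df=n_classes)
        assert p > 0.01

    def test_sib_mating_heterozygosity_decay_rate(self):
        """Mean heterozygosity after g brother-sister generations tracks
        H0 * lambda^g with lambda = (1 + sqrt(5))/4 within 10%.

        The founder pair mates first (unrelated; F1 heterozygosity equals
        H0), so g sib-matings correspond to g + 1 simulated generations.
        """
        founder = simulate_neutral_population(
            SimConfig(seed=77, sequence_length=200_000, n_haplotypes=4)
        ).to_genotype_table()
        h0 = founder.het_mask().mean()
        lam = (1 + np.sqrt(5)) / 4
        for g in (2, 4, 6):
            hets = [simulate_inbred_line(founder, g + 1, seed=s).het_mask().mean()
                    for s in range(500)]
            ratio = np.mean(hets) / (h0 * lam**g)
            assert 0.9 < ratio < 1.1, (g, ratio)

    def test_mean_d_monotone_in_admixture_fraction(self):
        from medpopgen.introgression import (QuartetData, QuartetSpec,
                                             d_statistic, site_patterns)
        spec = QuartetSpec("P1", "P2", "P3", "O")
        means = []
        for f in (0.0, 0.05, 0.1, 0.2):
            ds = []
            for seed in range(12):
                cfg = SimConfig(seed=200_000 + seed, sequence_length=300_000,
                                n_haplotypes=8)
                panels = simulate_admixture(cfg, f=f, seed=300_000 + seed)
                data = QuartetData.from_haplotype_sets(panels)
                res = d_statistic(site_patterns(data, spec),
                                  block_size_bp=100_000, n_blocks_min=100)
                ds.append(res.d)
            means.append(np.mean(ds))
        assert abs(means[0]) < 0.05
        assert means[0] < means[1] < means[2] < means[3]
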