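"""Wright-Fisher simulator: determinism, neutral expectations, demography."""

import numpy as np
import pytest

from whalepop.diversity_stats import tajimas_d, watterson_theta
from whalepop.sfs_demography import fsfs_from_genotypes, neutral_folded_expectation
from whalepop.wf_simulator import (
    DemographicScenario,
    SimulationConfig,
    WrightFisherPopulation,
    sample_fsfs,
    scenario_library,
    simulate,
)


def small_cfg(**kw):
    defaults = dict(
        n_diploid_initial=60,
        genome_elements=(40_000,),
        mu=2e-5,
        rec=1e-6,
        burnin_generations=600,
        sample_size=12,
        seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def const_scenario(n, g=5):
    return DemographicScenario("const", epochs=[(0, (n,)), (g, (n,))])


class TestScenario:
    def test_offsets_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DemographicScenario("bad", epochs=[(5, (10,)), (5, (10,))])

    def test_migration_bounds(self):
        with pytest.raises(ValueError, match="migration"):
            DemographicScenario(
                "bad", epochs=[(0, (10, 10)), (5, (10, 10))], migration=[0.9, 0.9]
            )

    def test_sizes_at(self):
        sc = DemographicScenario(
            "b", epochs=[(0, (100,)), (10, (20,)), (15, (100,))]
        )
        assert sc.sizes_at(5) == ((100,), 0.0)
        assert sc.sizes_at(11) == ((20,), 0.0)
        assert sc.sizes_at(15) == ((20,), 0.0)  # epoch starts after its offset
        assert sc.duration == 15

    def test_epochs_in_years(self):
        sc = DemographicScenario("b", epochs=[(0, (100,)), (30, (100,))])
        years = sc.epochs_in_years()
        assert years[0][0] == pytest.approx(30 * 25.9)


class TestSimulate:
    def test_no_mutation_stays_monomorphic(self):
        cfg = small_cfg(mu=0.0, burnin_generations=50)
        gm = simulate(cfg, const_scenario(60))
        assert gm.n_sites == 0

    def test_determinism(self):
        cfg = small_cfg(burnin_generations=100)
        a = simulate(cfg, const_scenario(60))
        b = simulate(cfg, const_scenario(60))
        assert a.equals(b)

    def test_sample_size_checked(self):
        cfg = small_cfg(sample_size=100)
        with pytest.raises(ValueError, match="sample_size"):
            simulate(cfg, const_scenario(60))

    def test_positions_within_elements(self):
        cfg = small_cfg(genome_elements=(10_000, 10_000), burnin_generations=200)
        gm = simulate(cfg, const_scenario(60))
        assert set(np.unique(gm.chrom_ids)) <= {"elem1", "elem2"}
        assert gm.positions.min() >= 1
        assert gm.positions.max() <= 10_000

    def test_watterson_theta_near_equilibrium(self):
        """Seeded neutral runs: mean Watterson theta within 15% of 4*N*mu,
        rec=0 (single genealogy per replicate)."""
        thetas = []
        for k in range(12):
            cfg = SimulationConfig(
                n_diploid_initial=100, genome_elements=(100_000,), mu=2e-6,
                rec=0.0, burnin_generations=1000, sample_size=15, seed=100 + k,
            )
            gm = simulate(cfg, const_scenario(100, g=2))
            S = int(gm.is_segregating().sum())
            thetas.append(watterson_theta(S, 30, 100_000))
        assert float(np.mean(thetas)) == pytest.approx(4 * 100 * 2e-6, rel=0.15)


class TestPopulationState:
    def test_martingale_mean_frequency(self):
        """Under pure drift the allele frequency is a martingale."""
        cfg = small_cfg(mu=0.0, rec=0.0)
        finals = []
        for k in range(200):
            rng = np.random.default_rng(1000 + k)
            n = 30
            haps = np.zeros((2 * n, 1), dtype=np.uint8)
            haps[: n, 0] = 1  # frequency 0.5
            pop = WrightFisherPopulation(
                cfg, deme_sizes=[n], rng=rng, haplotypes=haps, positions=np.array([10])
            )
            pop.run(15)
            f = pop.allele_frequencies()
            finals.append(float(f[0]) if f.size else round(float(pop.haps[0, 0])))
        assert float(np.mean(finals)) == pytest.approx(0.5, abs=0.05)

    def test_heterozygosity_decay(self):
        """E[H_t] = H_0 (1 - 1/(2N))^t under drift without mutation."""
        cfg = small_cfg(mu=0.0, rec=0.0)
        n, t = 25, 30
        hets = []
        rng_master = np.random.default_rng(77)
        for k in range(150):
            rng = np.random.default_rng(2000 + k)
            haps = (rng_master.random((2 * n, 40)) < 0.5).astype(np.uint8)
            pop = WrightFisherPopulation(
                cfg, deme_sizes=[n], rng=rng,
                haplotypes=haps, positions=np.arange(40) * 100,
            )
            h0 = pop.mean_heterozygosity()
            pop.run(t)
            hets.append(pop.mean_heterozygosity() / h0)
        expected = (1 - 1 / (2 * n)) ** t
        assert float(np.mean(hets)) == pytest.approx(expected, rel=0.1)


class TestScenarioLibrary:
    def test_families_present(self):
        lib = scenario_library(n_base=1000, horizon_generations=30)
        names = {s.name for s in lib}
        assert {"constant", "gradual_decline", "bottleneck_80",
                "bottleneck_80_migration", "constant_migration"} <= names

    def test_bottleneck_severity(self):
        lib = {s.name: s for s in scenario_library(n_base=1000)}
        b80 = lib["bottleneck_80"]
        assert b80.epochs[-1][1][0] == 200  # 80% reduction
        assert b80.duration == 30

    def test_years_conversion(self):
        lib = {s.name: s for s in scenario_library(n_base=1000)}
        years = dict((round(y), s) for y, s in lib["bottleneck_80"].epochs_in_years())
        # drop 5 generations before sampling = ~130 years at 25.9 y/gen
        assert round(5 * 25.9) in years

    def test_all_scenarios_valid_and_simulable(self):
        for sc in scenario_library(n_base=40, horizon_generations=10, bottleneck_duration=3):
            cfg = small_cfg(
                n_diploid_initial=40, burnin_generations=40, sample_size=5,
                genome_elements=(5_000,), mu=1e-4,
            )
            gm = simulate(cfg, sc)
            assert gm.n_individuals == 5


class TestSampleFsfs:
    def test_single_replicate_equals_simulate(self):
        cfg = small_cfg(burnin_generations=300)
        sc = const_scenario(60)
        mean_sfs, spectra = sample_fsfs(cfg, sc, n_replicates=1, seed=cfg.seed)
        direct = fsfs_from_genotypes(
            simulate(SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed}), sc)
        )
        np.testing.assert_array_equal(mean_sfs.counts, direct.counts)

    def test_neutral_shape(self):
        """Averaged neutral fSFS tracks the closed-form 1/i + 1/(2n-i) shape."""
        cfg = SimulationConfig(
            n_diploid_initial=80, genome_elements=(60_000,), mu=1e-5,
            rec=1e-6, burnin_generations=800, sample_size=10, seed=5,
        )
        mean_sfs, _ = sample_fsfs(cfg, const_scenario(80, g=2), n_replicates=12, seed=50)
        props = mean_sfs.counts / mean_sfs.counts.sum()
        expected = neutral_folded_expectation(20)
        assert np.abs(props - expected).max() < 0.05

    def test_bottleneck_shifts_spectrum_toward_intermediate(self):
        """A recent severe bottleneck pushes Tajima's D positive relative to a
        constant-size run on the same scale."""
        base = dict(
            n_diploid_initial=80, genome_elements=(60_000,), mu=1e-5,
            rec=1e-6, burnin_generations=800, sample_size=10,
        )
        d_const, d_bot = [], []
        bot = DemographicScenario(
            "bot", epochs=[(0, (80,)), (10, (16,)), (25, (16,))]
        )
        for k in range(6):
            gm_c = simulate(SimulationConfig(**base, seed=300 + k), const_scenario(80, g=25))
            gm_b = simulate(SimulationConfig(**base, seed=300 + k), bot)
            d_const.append(tajimas_d(gm_c))
            d_bot.append(tajimas_d(gm_b))
        assert float(np.mean(d_bot)) > float(np.mean(d_const))


def test_scenario_file_roundtrip(tmp_path):
    from whalepop.wf_simulator import load_scenario, save_scenario

    sc = DemographicScenario(
        "bottleneck", epochs=[(0, (100, 50)), (10, (20, 50)), (15, (20, 50))],
        migration=[0.0, 0.05, 0.05],
    )
    path = tmp_path / "scenario.json"
    save_scenario(sc, str(path))
    back = load_scenario(str(path))
    assert back.name == sc.name
    assert back.epochs == [(0, (100, 50)), (10, (20, 50)), (15, (20, 50))]
    assert back.migration == sc.migration
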