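"""Forward Wright-Fisher load simulator: accounting, equilibria, scenarios."""

from dataclasses import replace

import numpy as np
import pytest

from nimrescue import loadsim as lsim
from nimrescue.loadsim import (DFE, ForwardSimulator, GenomeConfig, SimPopulation,
                               calibrate_dfe, run_decline_and_split,
                               run_rescue_scenario)


def manual_population(sim, hap_ids, n_individuals=None):
    """Build a population directly from per-haplotype id lists."""
    haps = [np.array(sorted(h), dtype=np.int64) for h in hap_ids]
    sexes = np.zeros(len(haps) // 2, dtype=np.int64)
    sexes[1::2] = 1
    return SimPopulation.from_haplotype_list(haps, sexes)


class TestGenomeConfig:
    def test_exome_and_mutation_budget(self):
        cfg = GenomeConfig()
        assert cfg.exome_bp == 13_500_000
        assert cfg.n_genes == 9000
        assert cfg.u_deleterious / cfg.u_neutral == pytest.approx(1.5)  # 3:2

    def test_rescaling_preserves_products(self):
        cfg = GenomeConfig()
        s = cfg.rescaled(5.0)
        assert s.mu_deleterious == pytest.approx(5 * cfg.mu_deleterious)
        assert s.recomb_between_genes == pytest.approx(5 * cfg.recomb_between_genes)


class TestLoadAccounting:
    def test_homozygous_site_closed_form(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=0)
        mid = int(sim.table.append(np.array([0.1]), np.array([0.5]), np.array([0]))[0])
        pop = manual_population(sim, [[mid], [mid]])
        lin = sim.metrics(pop, scale="linear")
        assert lin.realized_le == pytest.approx(0.1)
        assert lin.total_le == pytest.approx(0.1)
        assert lin.masked_le == pytest.approx(0.0)
        assert lin.mean_fitness == pytest.approx(0.9)
        log = sim.metrics(pop, scale="log")
        assert log.realized_le == pytest.approx(-np.log(0.9))
        assert log.masked_le == pytest.approx(0.0)

    def test_heterozygous_recessive_site_is_masked(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=0)
        mid = int(sim.table.append(np.array([0.1]), np.array([0.0]), np.array([0]))[0])
        pop = manual_population(sim, [[mid], []])
        lin = sim.metrics(pop, scale="linear")
        assert lin.realized_le == pytest.approx(0.0)
        assert lin.masked_le == pytest.approx(0.1)
        log = sim.metrics(pop, scale="log")
        assert log.realized_le == pytest.approx(0.0)
        assert log.masked_le == pytest.approx(-np.log(0.9))
        assert log.mean_fitness == pytest.approx(1.0)

    def test_identity_and_direct_summation_oracle(self):
        # random small population checked against a pure-python oracle
        rng = np.random.default_rng(3)
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=3)
        n_mut = 40
        s = np.round(rng.uniform(0, 0.3, n_mut), 3)
        h = np.round(rng.uniform(0, 0.5, n_mut), 3)
        ids = sim.table.append(s, h, rng.integers(0, 9000, n_mut))
        haps = [rng.choice(ids, size=rng.integers(0, 15), replace=False)
                for _ in range(10)]
        pop = manual_population(sim, haps)
        m = sim.metrics(pop, per_individual=True)
        for i in range(pop.n):
            a = set(haps[2 * i].tolist())
            b = set(haps[2 * i + 1].tolist())
            hom, het = a & b, a ^ b
            realized = sum(s[v] for v in hom) + sum(h[v] * s[v] for v in het)
            total = sum(s[v] for v in hom) + sum(s[v] for v in het)
            row = m.per_individual.iloc[i]
            assert row["realized_le"] == pytest.approx(realized)
            assert row["total_le"] == pytest.approx(total)
            assert row["masked_le"] == pytest.approx(total - realized)

    def test_mutation_free_population(self):
        cfg = replace(GenomeConfig(), mu_deleterious=0.0, mu_neutral=0.0)
        sim = ForwardSimulator(cfg, DFE(), seed=4)
        pop = sim.init_population(20, neutral_init=False)
        pop = sim.run(pop, 5)
        m = sim.metrics(pop)
        assert m.total_le == 0.0 and m.mean_fitness == 1.0 and m.pi == 0.0


class TestPi:
    def test_two_haplotypes_closed_form(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=5)
        ids = sim.table.append(np.zeros(27), np.full(27, 0.5),
                               np.arange(27, dtype=np.int64))
        pop = manual_population(sim, [list(ids), []])
        assert sim.pi(pop) == pytest.approx(2e-6)

    def test_monomorphic_and_validation(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=6)
        pop = manual_population(sim, [[], [], [], []])
        assert sim.pi(pop) == 0.0
        single = manual_population(sim, [[], []])
        assert sim.pi(single) == 0.0
        with pytest.raises(ValueError):
            sim.pi(SimPopulation(flat=np.empty(0, np.int64),
                                 offsets=np.zeros(2, np.int64),
                                 sexes=np.zeros(0, np.int64)))

    def test_coalescent_initialization_matches_neutral_theory(self):
        n = 80
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=7)
        pop = sim.init_population(n, neutral_init=True)
        assert sim.pi(pop) == pytest.approx(4 * n * 1.6e-8, rel=0.25)


class TestDynamics:
    def test_mutation_input_ratio_three_to_two(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=8)
        pop = sim.init_population(80, neutral_init=False)
        sim.run(pop, 200)
        assert sim.mutation_input_ratio == pytest.approx(1.5, abs=0.1)

    def test_doubling_mutation_rate_scales_masked_load(self):
        def masked(mu_factor, seed):
            cfg = replace(GenomeConfig(),
                          mu_deleterious=GenomeConfig().mu_deleterious * mu_factor)
            sim = ForwardSimulator(cfg, DFE(scale=4.0), seed=seed)
            pop = sim.init_population(60, neutral_init=False)
            pop = sim.run(pop, 500)
            return sim.metrics(pop).masked_le

        base = np.mean([masked(1, s) for s in (20, 21, 22)])
        double = np.mean([masked(2, s) for s in (23, 24, 25)])
        assert 1.4 <= double / base <= 2.7

    def test_fixed_mutations_become_drift_load(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(scale=4.0), seed=9)
        pop = sim.init_population(12, neutral_init=False)
        pop = sim.run(pop, 400, prune_interval=20)
        # tiny population: fixation certain; pruned load is recorded
        assert pop.drift_load_le >= 0.0
        uniq, counts = np.unique(pop.flat, return_counts=True)
        assert (counts < len(pop.offsets) - 1).all()   # no fixed ids remain

    def test_population_schedule_validation(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(), seed=10)
        pop = sim.init_population(10, neutral_init=False)
        with pytest.raises(ValueError, match="N >= 2"):
            sim.step(pop, n_offspring=1)


@pytest.fixture(scope="module")
def split_runs():
    """Reduced-scale burn-in -> decline and captive split, several seeds."""
    runs = []
    for seed in range(6):
        sim = ForwardSimulator(GenomeConfig(), DFE(scale=6.0), seed=700 + seed)
        pop = sim.init_population(100, neutral_init=False)
        pop = sim.run(pop, 800)
        wild, captive = run_decline_and_split(
            sim, pop, wild_schedule=[int(x) for x in np.linspace(100, 40, 16)],
            captive_n=12, captive_generations=16)
        runs.append((sim, wild, captive))
    return runs


class TestScenarios:
    @staticmethod
    def _lethal_copies_per_individual(sim, pop):
        if pop.flat.size == 0:
            return 0.0
        uniq, counts = np.unique(pop.flat, return_counts=True)
        lethal = sim.table.s[uniq] >= 1.0
        return float(counts[lethal].sum()) / pop.n

    def test_captive_line_loses_diversity(self, split_runs):
        pi_w = [sim.pi(w) for sim, w, c in split_runs]
        pi_c = [sim.pi(c) for sim, w, c in split_runs]
        assert np.mean(pi_c) < np.mean(pi_w)

    def test_captive_line_purges_lethals(self, split_runs):
        lw = [self._lethal_copies_per_individual(sim, w) for sim, w, c in split_runs]
        lc = [self._lethal_copies_per_individual(sim, c) for sim, w, c in split_runs]
        assert np.mean(lc) < np.mean(lw)

    def test_zero_separation_is_indistinguishable(self):
        sim = ForwardSimulator(GenomeConfig(), DFE(scale=6.0), seed=30)
        pop = sim.init_population(80, neutral_init=False)
        pop = sim.run(pop, 600)
        captive = sim.sample_founders(pop, 30, label="captive")
        mw = sim.metrics(pop).masked_le
        mc = sim.metrics(captive).masked_le
        assert mc == pytest.approx(mw, rel=0.35)

    def test_rescue_scenario_bookkeeping(self, split_runs):
        sim, wild, captive = split_runs[0]
        ts = run_rescue_scenario(sim, wild.copy(), captive.copy(), k_released=2,
                                 horizon=4)
        assert list(ts["generation"]) == [0, 1, 2, 3, 4]
        assert (ts["k"] == 2).all()
        assert np.allclose(ts["masked_le"] + ts["realized_le"], ts["total_le"])
        with pytest.raises(ValueError, match="captive population"):
            run_rescue_scenario(sim, wild.copy(), captive.copy(),
                                k_released=captive.n + 1)

    def test_short_burnin_warns(self):
        with pytest.warns(UserWarning, match="10N"):
            lsim.run_burnin(GenomeConfig(), DFE(), n_ancestral=30,
                            selection_generations=50, seed=1, neutral_init=False)


class TestCalibration:
    def test_zero_target_returns_neutral_dfe(self):
        res = calibrate_dfe(target_masked_le=0.0, n_cal=10, seed=0)
        assert res.dfe.scale == 0.0
        rng = np.random.default_rng(0)
        s, h = res.dfe.draw(rng, 100)
        assert (s == 0).all()

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_dfe(target_masked_le=-1.0)

    def test_dfe_draw_structure(self):
        rng = np.random.default_rng(1)
        s, h = DFE(lethal_fraction=0.5).draw(rng, 2000)
        lethal = s == 1.0
        assert 0.4 < lethal.mean() < 0.6
        assert np.allclose(h[lethal], 0.02)
        nl = ~lethal
        assert np.allclose(h[nl], 0.5 / (1 + 7071.0 * s[nl]))
        assert (s >= 0).all() and (h <= 0.5).all()
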