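"""Initialization, the generation loop, replicate protocol, determinism."""

import numpy as np
import pytest

import plastisim.simulation as sim
from plastisim.demography import (
    DispersalPattern,
    LifeHistoryOrder,
    LifeHistorySpec,
)
from plastisim.environment import GradientSpec, TemporalPattern, TemporalSpec
from plastisim.genetics import LocusConfig
from plastisim.simulation import (
    SimConfig,
    initialize,
    run_generation,
    run_replicate,
    run_replicates,
)


def tiny_config(**over):
    defaults = dict(
        grad=GradientSpec(n_demes=5),
        life=LifeHistorySpec(dispersal_rate=0.2, carrying_capacity=20),
        n_generations=30,
        n_replicates=2,
        base_seed=3,
        report_window=10,
    )
    defaults.update(over)
    return SimConfig(**defaults)


class TestInitialize:
    def test_default_metapopulation_size(self, rng):
        cfg = SimConfig(n_generations=10)
        pop, _ = initialize(cfg, rng)
        assert pop.size == 50 * 100
        assert np.bincount(pop.deme).tolist() == [100] * 50

    def test_instability_starts_at_zero(self, rng):
        cfg = SimConfig(n_generations=10)
        pop, _ = initialize(cfg, rng)
        assert np.all(pop.instability == 0)

    def test_initial_alleles_discrete_uniform(self, rng):
        cfg = SimConfig(
            grad=GradientSpec(n_demes=1),
            life=LifeHistorySpec(dispersal_rate=0.0, carrying_capacity=100_000),
            n_generations=10,
        )
        pop, _ = initialize(cfg, rng)
        assert set(np.unique(pop.plastic)) == {-2.0, -1.0, 0.0, 1.0, 2.0}
        # per-allele variance 2 -> var of the 10-allele sum is 20
        sum_p = pop.plastic.sum(axis=1)
        se = np.sqrt(20 / pop.size)
        assert abs(sum_p.mean()) < 3 * se

    def test_phenotypes_unset_before_development(self, rng):
        pop, _ = initialize(tiny_config(), rng)
        assert np.all(np.isnan(pop.phenotype))


class TestConfigValidation:
    def test_single_deme_forbids_dispersal(self):
        with pytest.raises(ValueError):
            SimConfig(
                grad=GradientSpec(n_demes=1),
                life=LifeHistorySpec(dispersal_rate=0.3),
            )

    def test_pleiotropic_mode_forbids_instability_loci(self):
        with pytest.raises(ValueError):
            LocusConfig(pleiotropic=True, has_instability=True)

    def test_from_dict_round_trip(self):
        cfg = tiny_config()
        assert SimConfig.from_dict(cfg.to_dict()) == cfg

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            SimConfig.from_dict({"not_a_key": 1})

    def test_tau_entry_conventions(self):
        cfg = SimConfig.from_dict(
            {"n_demes": 50, "pattern": "p1_selection_only", "tau_percent": 10}
        )
        assert cfg.temporal.tau == pytest.approx(1.96)
        cfg = SimConfig.from_dict(
            {
                "n_demes": 1,
                "dispersal_rate": 0,
                "pattern": "p4_development_carries_over",
                "tau_over_sigma": 1.5,
            }
        )
        assert cfg.temporal.tau == pytest.approx(3.0)


class TestGenerationLoop:
    def test_individuals_stay_on_the_gradient(self, rng):
        cfg = tiny_config(
            life=LifeHistorySpec(
                dispersal_pattern=DispersalPattern.STEPPING_STONE,
                dispersal_rate=0.8,
                carrying_capacity=20,
            )
        )
        rngs = sim._rng_streams(0)
        pop, env = initialize(cfg, rngs["init"])
        for _ in range(10):
            pop, env = run_generation(pop, env, cfg, rngs)
            assert pop.deme.min() >= 0
            assert pop.deme.max() < cfg.grad.n_demes
            occupied = np.bincount(pop.deme, minlength=5)
            assert set(occupied[occupied > 0]) == {20}

    def test_neutral_generation_preserves_allele_values(self, rng):
        # no mutation, no selection mortality, no dispersal: offspring
        # alleles are resampled from, hence a subset of, the parental pool
        cfg = tiny_config(
            life=LifeHistorySpec(
                dispersal_rate=0.0, sigma=1e9, carrying_capacity=20
            ),
            mutation_rate=0.0,
        )
        rngs = sim._rng_streams(1)
        pop, env = initialize(cfg, rngs["init"])
        before = [set(pop.plastic[pop.deme == d].ravel()) for d in range(5)]
        pop, env = run_generation(pop, env, cfg, rngs)
        for d in range(5):
            after = set(pop.plastic[pop.deme == d].ravel())
            assert after <= before[d]

    def test_drift_only_run_keeps_population_full(self):
        cfg = tiny_config(
            life=LifeHistorySpec(
                dispersal_rate=0.0, sigma=1e9, carrying_capacity=20
            ),
            n_generations=20,
        )
        res = run_replicate(cfg, seed=5)
        assert not res.extinct
        assert res.series["population_size"][-1] == 100


class TestPleiotropicVariant:
    def test_run_reports_realized_noise_sd(self):
        cfg = SimConfig.from_dict(
            {
                "n_demes": 5,
                "carrying_capacity": 20,
                "dispersal_rate": 0.2,
                "mode": "pleiotropic",
                "pleiotropy_strength": 1.6,
                "n_generations": 25,
                "n_replicates": 1,
                "base_seed": 2,
                "report_window": 5,
            }
        )
        assert cfg.loci.pleiotropic and not cfg.loci.has_instability
        res = run_replicate(cfg, 2)
        assert not res.extinct
        assert res.mean_instability is not None
        assert res.mean_instability >= 0
        # noise sd is proportional to |sum P|: strength 0 gives exactly 0
        cfg0 = SimConfig.from_dict(
            {**cfg.to_dict(), "pleiotropy_strength": 0.0}
        )
        res0 = run_replicate(cfg0, 2)
        assert res0.mean_instability == 0.0


class TestReplicateProtocol:
    def test_same_seed_bit_identical(self):
        cfg = tiny_config()
        a = run_replicate(cfg, seed=42)
        b = run_replicate(cfg, seed=42)
        assert a.mean_plasticity == b.mean_plasticity
        assert a.mean_instability == b.mean_instability
        for key in a.series:
            assert np.array_equal(
                a.series[key], b.series[key], equal_nan=True
            )

    def test_benign_config_all_replicates_succeed(self):
        cfg = tiny_config(
            life=LifeHistorySpec(
                dispersal_rate=0.0, sigma=1e9, carrying_capacity=10
            ),
            n_generations=10,
            n_replicates=3,
        )
        results = run_replicates(cfg)
        assert len(results) == 3
        assert not any(r.extinct for r in results)

    def test_forced_extinction_caps_at_max_attempts(self, monkeypatch):
        # survival-zero stub: every attempt goes extinct immediately
        def kill_all(pop, theta, sigma, rng):
            return pop.subset(np.zeros(pop.size, dtype=bool))

        monkeypatch.setattr(sim, "select", kill_all)
        cfg = tiny_config(n_replicates=2)
        results = run_replicates(cfg)
        assert len(results) == cfg.max_attempts == 60
        assert all(r.extinct for r in results)
        assert all(r.mean_plasticity is None for r in results)

    def test_attempt_seeds_are_base_seed_plus_index(self, monkeypatch):
        def kill_all(pop, theta, sigma, rng):
            return pop.subset(np.zeros(pop.size, dtype=bool))

        monkeypatch.setattr(sim, "select", kill_all)
        cfg = tiny_config(base_seed=100, max_attempts=60)
        results = run_replicates(cfg)
        assert [r.seed for r in results[:5]] == [100, 101, 102, 103, 104]
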