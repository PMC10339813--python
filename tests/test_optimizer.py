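"""Swarm mechanics, Pareto archive, mutation operators and full runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psiselect.optimizer import (
    OptimizerConfig,
    ParetoArchive,
    Particle,
    decode,
    dominates,
    gdm_mutate,
    pso_step,
    run,
)


class TestDominates:
    def test_strictly_better_everywhere(self):
        assert dominates((0.1, 0.1, 0.1, 0.1), (0.2, 0.2, 0.2, 0.2))

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates((0.3, 0.3), (0.3, 0.3))

    def test_incomparable_pair(self):
        assert not dominates((0.1, 0.3), (0.3, 0.1))
        assert not dominates((0.3, 0.1), (0.1, 0.3))

    def test_weak_improvement_suffices(self):
        assert dominates((0.1, 0.2), (0.1, 0.3))


class TestDecode:
    def test_threshold_is_strict(self):
        np.testing.assert_array_equal(decode(np.array([0.6, 0.4, 0.51])), [1, 0, 1])
        np.testing.assert_array_equal(decode(np.full(4, 0.5)), [0, 0, 0, 0])

    def test_14_bit_particle_selects_nb_sw_gic(self):
        """The mask 01000000010001 picks the 2nd, 10th and 14th features,
        i.e. NB, SW and GIC in the canonical order."""
        from psiselect.graph_features import FEATURE_NAMES

        bits = np.array([0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1])
        position = np.where(bits == 1, 0.9, 0.1)
        mask = decode(position)
        np.testing.assert_array_equal(mask, bits)
        assert [FEATURE_NAMES[i] for i in np.flatnonzero(mask)] == ["NB", "SW", "GIC"]


class TestPsoStep:
    cfg = OptimizerConfig(seed=0)

    def test_converged_particle_is_stationary(self):
        pos = np.array([0.3, 0.7])
        p = Particle(pos.copy(), np.zeros(2), pos.copy(), np.array([0.1, 0.1]))
        out = pso_step(p, pos.copy(), self.cfg, np.random.default_rng(1))
        np.testing.assert_allclose(out.position, pos)
        np.testing.assert_allclose(out.velocity, 0.0)

    def test_cognitive_only_update_pulls_toward_pbest(self):
        cfg = OptimizerConfig(w=0.0, c1=2.0, c2=0.0, seed=0)
        pos = np.array([0.2, 0.8])
        pbest = np.array([0.6, 0.4])
        p = Particle(pos.copy(), np.zeros(2), pbest, np.array([0.1, 0.1]))
        out = pso_step(p, pos.copy(), cfg, np.random.default_rng(2))
        moved = out.position - pos
        pull = pbest - pos
        assert np.all(np.sign(moved[pull != 0]) == np.sign(pull[pull != 0]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_position_stays_in_unit_cube(self, seed):
        rng = np.random.default_rng(seed)
        p = Particle(rng.random(5), rng.uniform(-1, 1, 5), rng.random(5),
                     rng.random(2))
        out = pso_step(p, rng.random(5), OptimizerConfig(seed=0), rng)
        assert np.all(out.position >= 0.0) and np.all(out.position <= 1.0)
        assert np.all(np.abs(out.velocity) <= 0.5 + 1e-12)


class TestGdmMutate:
    def test_coincident_attractors_leave_position_unchanged(self):
        cfg = OptimizerConfig(seed=0)
        pos = np.array([0.4, 0.6])
        p = Particle(pos.copy(), np.zeros(2), pos.copy(), np.array([0.1]))
        out = gdm_mutate(p, pos.copy(), cfg, np.random.default_rng(3))
        np.testing.assert_allclose(out.position, pos)

    def test_zero_gaussian_draws_are_identity(self):
        class ZeroRng:
            def standard_normal(self, n):
                return np.zeros(n)

        cfg = OptimizerConfig(seed=0)
        p = Particle(np.array([0.3]), np.zeros(1), np.array([0.9]), np.array([0.1]))
        out = gdm_mutate(p, np.array([0.1]), cfg, ZeroRng())
        np.testing.assert_allclose(out.position, [0.3])

    def test_perturbation_moments_match_closed_form(self):
        """Over many draws the perturbation mean is 0 and its variance is
        p1^2 (L*-L)^2 + p2^2 (L_rand-L)^2 (independent unit normals)."""
        cfg = OptimizerConfig(seed=0)
        L, Lstar, Lrand = 0.5, 0.55, 0.45
        p = Particle(np.array([L]), np.zeros(1), np.array([Lstar]), np.array([0.1]))
        rng = np.random.default_rng(4)
        deltas = np.array([
            gdm_mutate(p, np.array([Lrand]), cfg, rng).position[0] - L
            for _ in range(10_000)
        ])
        expected_var = 0.25 * (Lstar - L) ** 2 + 0.25 * (Lrand - L) ** 2
        assert abs(deltas.mean()) < 3 * np.sqrt(expected_var / 10_000)
        assert deltas.var() == pytest.approx(expected_var, rel=0.1)

    def test_literal_mode_drops_current_position(self):
        cfg = OptimizerConfig(gdm_mode="literal", seed=0)

        class OneRng:
            def standard_normal(self, n):
                return np.ones(n)

        p = Particle(np.array([0.5]), np.zeros(1), np.array([0.7]), np.array([0.1]))
        out = gdm_mutate(p, np.array([0.9]), cfg, OneRng())
        # 0.5*1*(0.7-0.5) + 0.5*1*(0.9-0.5) = 0.3
        np.testing.assert_allclose(out.position, [0.3])


class TestParetoArchive:
    def test_first_candidate_always_enters(self):
        arch = ParetoArchive(10)
        assert arch.add(np.array([0.5]), np.array([1.0, 2.0]))
        assert len(arch) == 1

    def test_dominated_candidate_rejected(self):
        arch = ParetoArchive(10)
        arch.add(np.array([0.1]), np.array([0.1, 0.1]))
        assert not arch.add(np.array([0.2]), np.array([0.2, 0.2]))
        assert len(arch) == 1

    def test_dominating_candidate_evicts(self):
        arch = ParetoArchive(10)
        arch.add(np.array([0.2]), np.array([0.2, 0.2]))
        arch.add(np.array([0.3]), np.array([0.3, 0.1]))
        arch.add(np.array([0.1]), np.array([0.1, 0.05]))
        objs = arch.objectives
        assert len(arch) == 1
        np.testing.assert_array_equal(objs[0], [0.1, 0.05])

    def test_duplicate_objectives_rejected(self):
        arch = ParetoArchive(10)
        arch.add(np.array([0.1]), np.array([0.5, 0.5]))
        assert not arch.add(np.array([0.9]), np.array([0.5, 0.5]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mutual_nondominance_invariant(self, seed):
        rng = np.random.default_rng(seed)
        arch = ParetoArchive(8)
        for _ in range(60):
            arch.add(rng.random(2), rng.random(3))
        objs = arch.objectives
        assert len(arch) <= 8
        for i in range(len(arch)):
            for j in range(len(arch)):
                if i != j:
                    assert not dominates(objs[i], objs[j])

    def test_capacity_pruning_keeps_spread(self):
        """When a non-dominated candidate arrives at capacity, size stays at
        capacity and the extreme points survive."""
        arch = ParetoArchive(5)
        f1 = np.linspace(0, 1, 9)
        for v in f1:
            arch.add(np.array([v]), np.array([v, 1.0 - v]))
        assert len(arch) == 5
        objs = arch.objectives
        assert objs[:, 0].min() == 0.0 and objs[:, 0].max() == 1.0


class _Schaffer:
    """Schaffer N.1: f = (x^2, (x-2)^2) on x in [-4, 4]; front at x in [0, 2]."""

    dimension = 1
    n_objectives = 2

    def evaluate(self, u):
        x = -4.0 + 8.0 * float(u[0])
        return np.array([x**2, (x - 2.0) ** 2])

    def front(self, n=200):
        x = np.linspace(0, 2, n)
        return np.column_stack([x**2, (x - 2.0) ** 2])


class TestRun:
    def test_schaffer_front_found(self):
        from psiselect.benchmarks import igd

        prob = _Schaffer()
        res = run("mopso_gdm", prob, OptimizerConfig(seed=3))
        assert igd(res.final_objectives, prob.front()) < 0.05

    @pytest.mark.parametrize("alg", ["mopso_gdm", "mopso", "mopso_m", "nsga2"])
    def test_same_seed_reproduces_archive(self, alg):
        prob = _Schaffer()
        cfg = OptimizerConfig(n_particles=10, n_iterations=10, seed=7)
        a = run(alg, prob, cfg)
        b = run(alg, prob, cfg)
        assert np.array_equal(a.final_objectives, b.final_objectives)
        for p, q in zip(a.archive.positions, b.archive.positions):
            np.testing.assert_array_equal(p, q)

    def test_zero_mutation_rate_reduces_gdm_to_plain_mopso(self):
        prob = _Schaffer()
        cfg = OptimizerConfig(n_particles=12, n_iterations=15, mutation_rate=0.0, seed=5)
        a = run("mopso_gdm", prob, cfg)
        b = run("mopso", prob, cfg)
        assert np.array_equal(a.final_objectives, b.final_objectives)
        for h1, h2 in zip(a.history, b.history):
            np.testing.assert_array_equal(h1["archive_objectives"], h2["archive_objectives"])

    def test_distinct_count_monotone_over_iterations(self):
        prob = _Schaffer()
        res = run("mopso_gdm", prob, OptimizerConfig(n_particles=8, n_iterations=12, seed=1))
        counts = [h["n_distinct"] for h in res.history]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_archive_mutually_nondominated_each_iteration(self):
        prob = _Schaffer()
        res = run("mopso", prob, OptimizerConfig(n_particles=8, n_iterations=10, seed=2))
        for h in res.history:
            objs = h["archive_objectives"]
            for i in range(len(objs)):
                for j in range(len(objs)):
                    if i != j:
                        assert not dominates(objs[i], objs[j])

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            run("simulated_annealing", _Schaffer(), OptimizerConfig())
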