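"""Composite fitness counting, L2 penalty, and replicate evaluation."""

import numpy as np
import pytest

import morphonca as m
from morphonca.engine import Trajectory


def traj_from_typemaps(typemaps, grid):
    """Build a trajectory carrying given type maps (states set to match)."""
    typemaps = np.asarray(typemaps)
    states = np.full(typemaps.shape + (grid.state_dim,), -3.0)
    states[..., grid.n_types :] = 0.0
    rows, cols = np.indices(typemaps.shape[1:])
    for k in range(typemaps.shape[0]):
        states[k][rows, cols, typemaps[k]] = 3.0
    gates = np.zeros((typemaps.shape[0] - 1,) + typemaps.shape[1:], dtype=bool)
    return Trajectory(states=states, typemaps=typemaps, gate_mask=gates, pd=0.0, grid=grid)


def brute_force_counts(typemaps, target):
    """Hand-rolled recount of n_G / n_T / n_S from their definitions."""
    typemaps = np.asarray(typemaps)
    n_g = int((typemaps[-1] == target).sum())
    n_t = sum(
        int(np.array_equal(typemaps[k], target)) for k in range(1, typemaps.shape[0])
    )
    n_s = 0
    for k in range(typemaps.shape[0] - 1):
        if np.array_equal(typemaps[k + 1], typemaps[k]) and not np.array_equal(
            typemaps[k], target
        ):
            n_s += 1
    return n_g, n_t, n_s


class TestFitnessScore:
    def test_perfect_trajectory_reaches_analytic_maximum(
        self, saturated_czech, czech
    ):
        env = m.EnvConfig(dev_steps=25, noise_sigma=0.0, actions_enabled=False)
        fb = m.fitness(m.rollout(saturated_czech, env, 0), czech, m.FitnessWeights())
        assert fb.score == 70.25  # 64 + 25 * 0.25, no stagnation penalty
        assert (fb.n_correct, fb.n_target_steps, fb.n_stagnant) == (64, 25, 0)

    def test_fully_wrong_stagnant_trajectory(self, grid8, czech):
        wrong = np.full((26, 8, 8), 0, dtype=int)
        wrong[:, czech.grid == 0] = 1  # differ from the target everywhere
        traj = traj_from_typemaps(wrong, grid8)
        fb = m.fitness(traj, czech, m.FitnessWeights())
        assert fb.n_correct == 0 and fb.n_stagnant == 25
        assert fb.score == -76.5  # (0 - 64) - 25 * 0.5

    def test_correctness_only_ignores_history(self, saturated_czech, czech):
        env = m.EnvConfig(dev_steps=25, noise_sigma=0.0, actions_enabled=False)
        fb = m.fitness(
            m.rollout(saturated_czech, env, 0),
            czech,
            m.FitnessWeights(correctness_only=True),
        )
        assert fb.score == 64.0

    def test_maintaining_the_target_is_never_penalized(self, grid8, czech):
        maps = np.broadcast_to(czech.grid, (6, 8, 8)).copy()
        fb = m.fitness(traj_from_typemaps(maps, grid8), czech, m.FitnessWeights())
        assert fb.n_stagnant == 0
        assert fb.n_target_steps == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_random_trajectories_match_brute_force_recount(self, seed):
        """Exhaustive oracle on a 2x2 grid over short random histories."""
        grid = m.GridSpec(nx=2, ny=2, n_types=3, n_hidden=1)
        rng = np.random.default_rng(seed)
        maps = rng.integers(0, 2, size=(4, 2, 2))  # few types: collisions likely
        target = rng.integers(0, 2, size=(2, 2))
        fb = m.fitness(
            traj_from_typemaps(maps, grid),
            m.TargetPattern(target, 3),
            m.FitnessWeights(),
        )
        n_g, n_t, n_s = brute_force_counts(maps, target)
        assert (fb.n_correct, fb.n_target_steps, fb.n_stagnant) == (n_g, n_t, n_s)
        assert fb.score == (2 * n_g - 4) + 0.25 * n_t - 0.5 * n_s

    def test_score_bounds_and_correct_cell_increment(self, grid8, czech):
        rng = np.random.default_rng(0)
        weights = m.FitnessWeights()
        for _ in range(20):
            maps = rng.integers(0, 3, size=(6, 8, 8))
            fb = m.fitness(traj_from_typemaps(maps, grid8), czech, weights)
            assert -64 - 0.5 * 5 <= fb.score <= 64 + 0.25 * 5
        # flipping one final cell to the target raises the score by exactly 2
        maps = rng.integers(0, 3, size=(3, 8, 8))
        wrong = np.argwhere(maps[-1] != czech.grid)[0]
        before = m.fitness(traj_from_typemaps(maps, grid8), czech, weights).score
        maps2 = maps.copy()
        maps2[-1, wrong[0], wrong[1]] = czech.grid[wrong[0], wrong[1]]
        after = m.fitness(traj_from_typemaps(maps2, grid8), czech, weights).score
        assert after - before == pytest.approx(2.0)

    def test_hidden_channels_do_not_affect_fitness(self, saturated_czech, czech):
        env = m.EnvConfig(dev_steps=5, noise_sigma=0.0, actions_enabled=False)
        base = m.fitness(m.rollout(saturated_czech, env, 0), czech).score
        jittered = m.Genome(
            structural=saturated_czech.structural
            + np.concatenate([np.zeros((8, 8, 3)), np.ones((8, 8, 1))], axis=-1),
            functional=saturated_czech.functional,
            arch=saturated_czech.arch,
            grid=saturated_czech.grid,
        )
        assert m.fitness(m.rollout(jittered, env, 0), czech).score == base

    def test_grid_mismatch_rejected(self, grid8, czech):
        small = m.GridSpec(nx=2, ny=2, n_types=3, n_hidden=1)
        traj = traj_from_typemaps(np.zeros((2, 2, 2), dtype=int), small)
        with pytest.raises(ValueError, match="grid"):
            m.fitness(traj, czech)


class TestL2Penalty:
    def test_worked_example(self):
        assert m.l2_penalty(np.array([1.0, -2.0]), 0.01) == pytest.approx(0.05)

    def test_zero_vector(self):
        assert m.l2_penalty(np.zeros(10), 0.01) == 0.0

    def test_sign_symmetric_competency_contribution(self):
        a = m.l2_penalty(np.array([0.0, 1.7]), 0.01)
        b = m.l2_penalty(np.array([0.0, -1.7]), 0.01)
        assert a == b

    def test_applied_to_full_genome_in_fitness(self, grid8, czech):
        traj_grid = m.GridSpec(nx=8, ny=8, n_types=3, n_hidden=1)
        maps = np.broadcast_to(czech.grid, (3, 8, 8)).copy()
        traj = traj_from_typemaps(maps, traj_grid)
        flat = np.ones(5)
        fb = m.fitness(traj, czech, m.FitnessWeights(l2_rate=0.01), genome_flat=flat)
        assert fb.l2 == pytest.approx(0.05)
        fb0 = m.fitness(traj, czech, m.FitnessWeights(l2_rate=0.01))
        assert fb.score == pytest.approx(fb0.score - 0.05)


class TestEvaluateGenome:
    def test_noiseless_replicates_are_identical(self, saturated_czech, czech):
        env = m.EnvConfig(dev_steps=25, noise_sigma=0.0, actions_enabled=False)
        f, breakdowns = m.evaluate_genome(
            saturated_czech, czech, env, n_reps=8, rng=0, return_breakdowns=True
        )
        assert f == 70.25
        assert len({b.score for b in breakdowns}) == 1

    def test_mean_of_replicates(self, saturated_czech, czech):
        env = m.EnvConfig(dev_steps=25, noise_sigma=0.6, actions_enabled=False)
        f, breakdowns = m.evaluate_genome(
            saturated_czech, czech, env, n_reps=4, rng=3, return_breakdowns=True
        )
        assert f == pytest.approx(np.mean([b.score for b in breakdowns]))

    def test_deterministic_under_master_seed(self, saturated_czech, czech):
        env = m.EnvConfig(dev_steps=10, noise_sigma=0.4, actions_enabled=False)
        a = m.evaluate_genome(saturated_czech, czech, env, n_reps=5, rng=7)
        b = m.evaluate_genome(saturated_czech, czech, env, n_reps=5, rng=7)
        assert a == b


class TestStructuralFitness:
    def test_equals_evaluation_when_actions_already_disabled(
        self, saturated_czech, czech
    ):
        env = m.EnvConfig(dev_steps=10, noise_sigma=0.3, actions_enabled=False)
        a = m.evaluate_genome(saturated_czech, czech, env, n_reps=4, rng=5)
        b = m.structural_fitness(saturated_czech, czech, env, n_reps=4, rng=5)
        assert a == b

    def test_functional_genes_cannot_act(self, czech, ff_spec, grid8):
        g = m.make_saturated_genome(czech, ff_spec, grid8)
        g.functional[:] = np.random.default_rng(0).standard_normal(g.functional.size)
        env = m.EnvConfig(dev_steps=25, noise_sigma=0.0, pd=1.0)
        assert m.structural_fitness(g, czech, env, n_reps=2, rng=0) == 70.25

    def test_identity_rollout_counts_matching_structural_types(
        self, ff_spec, grid8, czech
    ):
        rng = np.random.default_rng(9)
        g = m.init_genome(ff_spec, grid8, rng)
        env = m.EnvConfig(dev_steps=5, noise_sigma=0.0, pd=1.0)
        k = int((m.cell_types(g.structural, 3) == czech.grid).sum())
        f = m.structural_fitness(
            g, czech, env, m.FitnessWeights(correctness_only=True), n_reps=1, rng=0
        )
        assert f == 2 * k - 64
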