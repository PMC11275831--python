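"""Phenotype-based fitness of a developmental trajectory.

The composite score of a rollout against a target pattern is

    r = (2 n_G - N_j) + r_T n_T - r_S n_S - l2

with n_G the number of cells whose final type matches the target, n_T the
number of post-update steps at which the *entire* type map equals the
target (rewarding maintenance), and n_S the number of successive step
pairs whose type map is unchanged while still differing from the target
(penalizing stagnation of a suboptimal pattern; persisting the correct
pattern is never penalized).  An optional L2 penalty on the full flat
genome regularizes runs that evolve the competency gene.

Because development is noisy, a genome's evolutionary fitness F is the
mean score over NE statistically independent rollouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import EnvConfig, Trajectory, disable_actions, rollout
from .genome import Genome
from .patterns import TargetPattern


@dataclass(frozen=True)
class FitnessWeights:
    """Reward shaping of the composite score.

    Defaults: maintain_reward r_T = 0.25 per fully-correct step,
    stagnation_penalty r_S = 0.5 per stagnant suboptimal step pair,
    l2_rate 0 (0.01 is used when the competency gene is evolved).
    ``correctness_only`` forces r_T = r_S = 0, keeping just 2 n_G - N_j.
    """

    maintain_reward: float = 0.25
    stagnation_penalty: float = 0.5
    l2_rate: float = 0.0
    correctness_only: bool = False

    @property
    def r_t(self) -> float:
        return 0.0 if self.correctness_only else self.maintain_reward

    @property
    def r_s(self) -> float:
        return 0.0 if self.correctness_only else self.stagnation_penalty


@dataclass(frozen=True)
class FitnessBreakdown:
    """The counted components and resulting score of one rollout."""

    n_correct: int  # n_G: final cells matching the target
    n_target_steps: int  # n_T: post-update steps with a fully correct map
    n_stagnant: int  # n_S: stagnant step pairs away from the target
    l2: float
    score: float


def l2_penalty(flat: np.ndarray, l2_rate: float) -> float:
    """``l2_rate * sum(x^2)`` over the whole flat genome."""
    flat = np.asarray(flat, dtype=float).ravel()
    return float(l2_rate * np.dot(flat, flat))


def fitness(
    trajectory: Trajectory,
    target: TargetPattern,
    weights: FitnessWeights | None = None,
    genome_flat: np.ndarray | None = None,
) -> FitnessBreakdown:
    """Score one trajectory against a target pattern."""
    if weights is None:
        weights = FitnessWeights()
    typemaps = trajectory.typemaps
    if typemaps.shape[1:] != target.shape:
        raise ValueError(
            f"trajectory grid {typemaps.shape[1:]} != target {target.shape}"
        )
    n_cells = target.n_cells
    full_match = (typemaps == target.grid).all(axis=(1, 2))  # length T+1
    n_correct = int((typemaps[-1] == target.grid).sum())
    # maintenance counts post-update states only (k = 1..T)
    n_target_steps = int(full_match[1:].sum())
    stagnant = (typemaps[1:] == typemaps[:-1]).all(axis=(1, 2))
    n_stagnant = int((stagnant & ~full_match[:-1]).sum())
    l2 = 0.0
    if genome_flat is not None and weights.l2_rate:
        l2 = l2_penalty(genome_flat, weights.l2_rate)
    score = (
        (2 * n_correct - n_cells)
        + weights.r_t * n_target_steps
        - weights.r_s * n_stagnant
        - l2
    )
    return FitnessBreakdown(
        n_correct=n_correct,
        n_target_steps=n_target_steps,
        n_stagnant=n_stagnant,
        l2=l2,
        score=float(score),
    )


def evaluate_genome(
    genome: Genome,
    target: TargetPattern,
    env: EnvConfig,
    weights: FitnessWeights | None = None,
    n_reps: int = 8,
    rng=None,
    return_breakdowns: bool = False,
):
    """Averaged fitness F over ``n_reps`` independent noisy rollouts.

    The seed source is split into ``n_reps`` independent streams, so the
    result is deterministic under a fixed master seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .engine import _split_streams  # shared seed-splitting discipline

    if weights is None:
        weights = FitnessWeights()
    flat = genome.flatten() if weights.l2_rate else None
    streams = _split_streams(rng, n_reps)
    breakdowns = [
        fitness(rollout(genome, env, stream), target, weights, flat)
        for stream in streams
    ]
    f_mean = float(np.mean([b.score for b in breakdowns]))
    if return_breakdowns:
        return f_mean, breakdowns
    return f_mean


def structural_fitness(
    genome: Genome,
    target: TargetPattern,
    env: EnvConfig,
    weights: FitnessWeights | None = None,
    n_reps: int = 8,
    rng=None,
):
    """Fitness of the structural genes alone: same protocol, actions off.

    The same noise level and replicate averaging apply; the functional
    genes cannot act but still enter the L2 term when enabled.
    """
    return evaluate_genome(
        genome, target, disable_actions(env), weights, n_reps, rng
    )
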