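"""Neuroevolution driver: CMA-ES over the flat genome.

Three modes mirror the encoding comparison of the study design:

* ``direct`` — all cell actions are disabled during development, so only
  the structural genes can matter; the functional genes formally stay in
  the search vector to keep the search-space dimension balanced.
* ``multiscale`` — structural and functional genes are both expressed;
  the cells' controllers actively assemble and maintain the pattern.
* ``evolvable_competency`` — a scalar competency gene is appended to the
  genome and decoded into the decision-making probability at rollout
  time; L2 regularization (rate 0.01) is enabled on the full genome.

Every candidate is scored by the mean fitness of NE independent noisy
rollouts with fresh replicate seeds each generation.  All randomness
derives deterministically from the single EA seed, and the replicate seeds
of the best-ever candidate are logged so its fitness can be reproduced
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .cmaes import CMAES
from .engine import EnvConfig, disable_actions
from .fitness import FitnessWeights, evaluate_genome, structural_fitness
from .genome import (
    ControllerSpec,
    Genome,
    decode_competency,
    genome_from_dict,
    genome_to_dict,
    init_genome,
)
from .patterns import GridSpec, TargetPattern

MODES = ("direct", "multiscale", "evolvable_competency")


@dataclass(frozen=True)
class EAConfig:
    """Budget and search hyperparameters of one evolutionary run."""

    pop_size: int = 96
    max_generations: int = 2000
    n_eval_reps: int = 8
    sigma_init: float = 0.5
    solve_threshold: float | None = 64.0
    seed: int = 0
    warm_start: Genome | None = None
    warm_sigma: float = 0.1
    post_solve_patience: int = 0  # extra generations after the solve
    init_sigma_genome: float = 0.1  # spread of the random initial mean
    track_structural: bool = True


@dataclass
class GenRecord:
    """One generation's summary statistics (1-based generation index)."""

    generation: int
    best_ever_f: float
    gen_best_f: float
    pop_mean_f: float
    pop_std_f: float
    structural_f: float | None = None
    best_pd: float | None = None


@dataclass
class RunLog:
    """Complete record of one evolutionary run."""

    records: list[GenRecord]
    best_genome: Genome
    best_f: float
    solved_at: int | None
    config: dict
    best_eval_key: tuple[int, int, int]

    @property
    def best_ever_series(self) -> np.ndarray:
        return np.array([r.best_ever_f for r in self.records])

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"type": "config", **self.config}) + "\n")
            for rec in self.records:
                fh.write(json.dumps({"type": "generation", **asdict(rec)}) + "\n")
            fh.write(
                json.dumps(
                    {
                        "type": "final",
                        "best_f": self.best_f,
                        "solved_at": self.solved_at,
                        "best_eval_key": list(self.best_eval_key),
                        "best_genome": genome_to_dict(self.best_genome),
                    }
                )
                + "\n"
            )

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "RunLog":
        config: dict = {}
        records: list[GenRecord] = []
        final: dict = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                doc = json.loads(line)
                kind = doc.pop("type")
                if kind == "config":
                    config = doc
                elif kind == "generation":
                    records.append(GenRecord(**doc))
                elif kind == "final":
                    final = doc
        return cls(
            records=records,
            best_genome=genome_from_dict(final["best_genome"]),
            best_f=final["best_f"],
            solved_at=final["solved_at"],
            config=config,
            best_eval_key=tuple(final["best_eval_key"]),
        )


class ThresholdCrossing(NamedTuple):
    generations: int
    censored: bool


def candidate_seed(ea_seed: int, generation: int, index: int) -> np.random.SeedSequence:
    """The replicate seed source of candidate ``index`` in ``generation``.

    Generation 0 / index 0 is reserved for the pre-loop evaluation of the
    initial search mean (relevant for warm starts).
    """
    return np.random.SeedSequence(entropy=ea_seed, spawn_key=(1, generation, index))


def _structural_seed(ea_seed: int, generation: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=ea_seed, spawn_key=(2, generation))


def evolve(
    target: TargetPattern,
    arch: ControllerSpec,
    grid: GridSpec,
    env: EnvConfig,
    weights: FitnessWeights | None = None,
    ea: EAConfig | None = None,
    mode: str = "multiscale",
    log_path: str | Path | None = None,
) -> RunLog:
    """Run CMA-ES on the flat genome until solved (plus patience) or NM.

    Maximization is realized by negating the fitness for the minimizing
    optimizer.  ``log_path`` streams the run log incrementally as
    JSON-lines while the run progresses.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if weights is None:
        weights = FitnessWeights()
    if ea is None:
        ea = EAConfig()
    if ea.pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if not target.matches(grid):
        raise ValueError("target pattern incompatible with grid spec")

    include_competency = mode == "evolvable_competency"
    if mode == "direct":
        env = disable_actions(env)
    if include_competency:
        env = replace(env, pd=None, pd_source="genome")
        if weights.l2_rate == 0.0:
            weights = replace(weights, l2_rate=0.01)

    if ea.warm_start is not None:
        seed_genome = ea.warm_start
        if (seed_genome.arch, seed_genome.grid) != (arch, grid):
            raise ValueError("warm-start genome architecture/grid mismatch")
        if seed_genome.has_competency != include_competency:
            raise ValueError("warm-start genome competency layout mismatch")
        x0 = seed_genome.flatten()
        sigma0 = ea.warm_sigma
    else:
        init_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ea.seed, spawn_key=(3,))
        )
        x0 = init_genome(
            arch, grid, init_rng, include_competency, sigma=ea.init_sigma_genome
        ).flatten()
        sigma0 = ea.sigma_init

    def make_genome(flat: np.ndarray) -> Genome:
        return Genome.from_flat(flat, arch, grid, has_competency=include_competency)

    def score(flat: np.ndarray, key: tuple[int, int, int]) -> float:
        f = evaluate_genome(
            make_genome(flat),
            target,
            env,
            weights,
            n_reps=ea.n_eval_reps,
            rng=np.random.SeedSequence(entropy=ea.seed, spawn_key=key),
        )
        if not math.isfinite(f):
            raise ValueError(
                f"non-finite fitness {f} for candidate with key {key}; "
                f"|flat| stats: min={flat.min():.3g} max={flat.max():.3g}"
            )
        return f

    es = CMAES(
        x0,
        sigma0,
        popsize=ea.pop_size,
        rng=np.random.default_rng(np.random.SeedSequence(entropy=ea.seed, spawn_key=(0,))),
    )

    # Pre-loop evaluation of the initial mean: gives warm starts credit for
    # an already-solving seed genome within "generation 1".
    best_flat = x0.copy()
    best_f = score(x0, (1, 0, 0))
    best_key = (1, 0, 0)

    records: list[GenRecord] = []
    solved_at: int | None = None
    config = {
        "mode": mode,
        "seed": ea.seed,
        "pop_size": ea.pop_size,
        "max_generations": ea.max_generations,
        "n_eval_reps": ea.n_eval_reps,
        "sigma_init": sigma0,
        "solve_threshold": ea.solve_threshold,
        "dev_steps": env.dev_steps,
        "noise_sigma": env.noise_sigma,
        "pd": env.pd,
        "arch": arch.arch,
        "redundancy": arch.redundancy,
        "warm_start": ea.warm_start is not None,
    }

    log_fh = open(log_path, "w", encoding="utf-8") if log_path else None
    if log_fh:
        log_fh.write(json.dumps({"type": "config", **config}) + "\n")
    try:
        for g in range(1, ea.max_generations + 1):
            population = es.ask()
            fs = np.array(
                [score(flat, (1, g, j)) for j, flat in enumerate(population)]
            )
            es.tell(population, -fs)

            j_best = int(np.argmax(fs))
            if fs[j_best] > best_f:
                best_f = float(fs[j_best])
                best_flat = population[j_best].copy()
                best_key = (1, g, j_best)

            structural_f = None
            if ea.track_structural:
                structural_f = structural_fitness(
                    make_genome(population[j_best]),
                    target,
                    env,
                    weights,
                    n_reps=ea.n_eval_reps,
                    rng=_structural_seed(ea.seed, g),
                )
            best_pd = (
                decode_competency(population[j_best][-1])
                if include_competency
                else None
            )
            rec = GenRecord(
                generation=g,
                best_ever_f=best_f,
                gen_best_f=float(fs[j_best]),
                pop_mean_f=float(fs.mean()),
                pop_std_f=float(fs.std()),
                structural_f=structural_f,
                best_pd=best_pd,
            )
            records.append(rec)
            if log_fh:
                log_fh.write(json.dumps({"type": "generation", **asdict(rec)}) + "\n")

            if (
                solved_at is None
                and ea.solve_threshold is not None
                and best_f >= ea.solve_threshold
            ):
                solved_at = g
            if solved_at is not None and g >= solved_at + ea.post_solve_patience:
                break
    finally:
        if log_fh:
            log_fh.close()

    log = RunLog(
        records=records,
        best_genome=make_genome(best_flat),
        best_f=best_f,
        solved_at=solved_at,
        config=config,
        best_eval_key=best_key,
    )
    if log_path:
        log.to_jsonl(log_path)  # rewrite including the final record
    return log


def warm_start_evolve(
    seed_genome: Genome,
    new_target: TargetPattern,
    env: EnvConfig,
    weights: FitnessWeights | None = None,
    ea: EAConfig | None = None,
    mode: str | None = None,
    log_path: str | Path | None = None,
) -> RunLog:
    """Adapt a pre-evolved genome to a new target.

    The CMA-ES mean starts at the seed genome with the (small) transfer
    step size ``ea.warm_sigma``; both structural and functional genes stay
    mutable.  The mode is inferred from the genome layout unless given.
    """
    if ea is None:
        ea = EAConfig()
    if mode is None:
        mode = "evolvable_competency" if seed_genome.has_competency else "multiscale"
    ea = replace(ea, warm_start=seed_genome)
    return evolve(
        new_target,
        seed_genome.arch,
        seed_genome.grid,
        env,
        weights,
        ea,
        mode=mode,
        log_path=log_path,
    )


def generations_to_threshold(
    log: RunLog, threshold: float
) -> ThresholdCrossing:
    """First (1-based) generation whose best-ever F reaches ``threshold``.

    Runs that never cross are censored at the configured maximum
    generation count; aggregations must report the censoring fraction.
    """
    for rec in log.records:
        if rec.best_ever_f >= threshold:
            return ThresholdCrossing(rec.generation, False)
    max_gen = int(log.config.get("max_generations", len(log.records)))
    return ThresholdCrossing(max_gen, True)
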