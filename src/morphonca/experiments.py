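"""Experiment designs: competency/noise sweeps, generalization, transfer.

Every experiment is a pure function of its configuration and a master
seed: per-run seeds are derived deterministically, runs can be written to
and resumed from a content-addressed directory of JSON-lines logs, and all
summary tables are recomputable from the raw run records alone.

Two budget profiles are used throughout: the *full-scale* profile
(population 96, up to 2000 generations, 8 evaluation replicates on the
8x8 tasks) and a *desk-scale* profile (population 16, up to 300
generations, 4 replicates on small targets) that preserves the qualitative
design at a budget suitable for interactive work and test suites.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import EnvConfig
from .evolve import EAConfig, evolve, generations_to_threshold, warm_start_evolve
from .fitness import FitnessWeights
from .genome import ControllerSpec, Genome
from .patterns import GridSpec, TargetPattern

#: Desk-scale evolutionary budget (small targets, smoke experiments).
DESK_EA = EAConfig(pop_size=16, max_generations=300, n_eval_reps=4)
#: Full-scale evolutionary budget (8x8 flag tasks).
FULL_SCALE_EA = EAConfig(pop_size=96, max_generations=2000, n_eval_reps=8)


@dataclass(frozen=True)
class SweepPlan:
    """Axes of the competency/noise/redundancy sweep."""

    pd_values: tuple = (0.0, 0.125, 0.25, 0.5, 1.0)
    noise_values: tuple = (0.0, 0.125, 0.25, 0.375, 0.5)
    redundancy_values: tuple = (1, 2, 4, 8, 16)
    archs: tuple = ("ff", "rgrn")
    replicates: int = 15

    def cells(self):
        for pd in self.pd_values:
            for noise in self.noise_values:
                for r in self.redundancy_values:
                    for arch in self.archs:
                        yield pd, noise, r, arch

    @property
    def n_runs(self) -> int:
        return (
            len(self.pd_values)
            * len(self.noise_values)
            * len(self.redundancy_values)
            * len(self.archs)
            * self.replicates
        )


def _run_id(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def _derived_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    plan: SweepPlan,
    target: TargetPattern,
    grid: GridSpec,
    env: EnvConfig,
    weights: FitnessWeights | None = None,
    ea: EAConfig | None = None,
    controller_kwargs: dict | None = None,
    mode_for_pd=None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    solve_threshold: float | None = None,
):
    """Run the full (PD, noise, R, arch) x replicates sweep.

    A cell with PD = 0 is run in ``direct`` mode (actions disabled), all
    others in ``multiscale`` mode, unless ``mode_for_pd`` overrides the
    choice.  Completed runs found in ``out_dir`` are skipped; failures are
    recorded per run and never abort the sweep.  Returns ``(runs, summary,
    summary_by_arch)`` DataFrames.
    """
    if weights is None:
        weights = FitnessWeights()
    if ea is None:
        ea = DESK_EA
    controller_kwargs = dict(controller_kwargs or {})
    threshold = (
        solve_threshold if solve_threshold is not None else ea.solve_threshold
    )
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for cell_idx, (pd_value, noise, r, arch_name) in enumerate(plan.cells()):
        for rep in range(plan.replicates):
            seed = _derived_seed(master_seed, cell_idx, rep)
            params = {
                "pd": pd_value,
                "noise": noise,
                "redundancy": r,
                "arch": arch_name,
                "replicate": rep,
                "seed": seed,
                "target": target.name,
            }
            run_id = _run_id(params)
            row_path = out_dir / f"{run_id}.json" if out_dir else None
            if row_path and row_path.exists():
                rows.append(json.loads(row_path.read_text()))
                continue
            mode = "direct" if pd_value == 0 else "multiscale"
            if mode_for_pd is not None:
                mode = mode_for_pd(pd_value)
            arch = ControllerSpec(
                arch=arch_name,
                state_dim=grid.state_dim,
                redundancy=r,
                **controller_kwargs,
            )
            run_env = replace(env, noise_sigma=noise, pd=pd_value)
            run_ea = replace(ea, seed=seed, solve_threshold=threshold)
            row = dict(params, run_id=run_id)
            try:
                log = evolve(target, arch, grid, run_env, weights, run_ea, mode=mode)
                crossing = generations_to_threshold(log, threshold)
                row.update(
                    generations=crossing.generations,
                    censored=crossing.censored,
                    best_f=log.best_f,
                    solved=log.solved_at is not None,
                    error=None,
                )
                if out_dir:
                    log.to_jsonl(out_dir / f"{run_id}.log.jsonl")
            except Exception as exc:  # record, keep sweeping
                row.update(
                    generations=ea.max_generations,
                    censored=True,
                    best_f=float("nan"),
                    solved=False,
                    error=f"{type(exc).__name__}: {exc}",
                )
            rows.append(row)
            if row_path:
                row_path.write_text(json.dumps(row))

    runs = pd.DataFrame(rows)
    summary = summarize_sweep(runs, by_arch=False)
    summary_by_arch = summarize_sweep(runs, by_arch=True)
    return runs, summary, summary_by_arch


def summarize_sweep(runs: pd.DataFrame, by_arch: bool = False) -> pd.DataFrame:
    """Aggregate raw sweep rows into the heatmap table.

    Censored runs enter the mean at the maximum generation budget; the
    censoring fraction is reported alongside.  Pure function of the rows.
    """
    keys = ["pd", "noise"] + (["arch"] if by_arch else [])
    grouped = runs.groupby(keys, sort=True)
    summary = grouped.agg(
        mean_generations=("generations", "mean"),
        std_generations=("generations", "std"),
        censoring_fraction=("censored", "mean"),
        n_runs=("generations", "size"),
    ).reset_index()
    return summary


def generalization_eval(
    genome: Genome,
    target: TargetPattern,
    vary: str,
    values,
    lifetime: int = 100,
    reps: int = 100,
    env: EnvConfig | None = None,
    rng=0,
) -> pd.DataFrame:
    """Correctness-vs-time curves of a fixed genome under shifted conditions.

    For each value of the varied parameter ("noise" or "pd") the genome is
    rolled out ``reps`` times for ``lifetime`` steps without any further
    optimization, and the correctness-only score ``2 n_G(t) - N_j`` is
    recorded at every step.  Returns long-format rows
    (value, step, mean_score, std_score, reps).
    """
    from .engine import _split_streams, rollout

    if vary not in ("noise", "pd"):
        raise ValueError("vary must be 'noise' or 'pd'")
    if env is None:
        env = EnvConfig()
    if lifetime < 1:
        raise ValueError("lifetime must be >= 1")
    base = replace(env, dev_steps=lifetime)
    n_cells = target.n_cells
    rows = []
    for v_idx, value in enumerate(values):
        run_env = (
            replace(base, noise_sigma=float(value))
            if vary == "noise"
            else replace(base, pd=float(value), pd_source="auto")
        )
        master = int(rng) if isinstance(rng, (int, np.integer)) else 0
        streams = _split_streams(
            np.random.SeedSequence(entropy=master, spawn_key=(v_idx,)), reps
        )
        scores = np.empty((reps, lifetime + 1))
        for i, stream in enumerate(streams):
            traj = rollout(genome, run_env, stream)
            n_g = (traj.typemaps == target.grid).sum(axis=(1, 2))
            scores[i] = 2 * n_g - n_cells
        for step in range(lifetime + 1):
            rows.append(
                {
                    "value": float(value),
                    "step": step,
                    "mean_score": float(scores[:, step].mean()),
                    "std_score": float(scores[:, step].std()),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def transfer_matrix(
    seed_genomes: dict,
    targets,
    noise_values,
    env: EnvConfig,
    weights: FitnessWeights | None = None,
    ea: EAConfig | None = None,
    replicates: int = 3,
    master_seed: int = 0,
    correctness_threshold: float | None = None,
) -> pd.DataFrame:
    """Warm-started adaptation of pre-evolved genomes to new targets.

    ``seed_genomes`` maps a training decision-making probability to its
    pre-evolved genome.  For each (seed PD, target, noise) cell the genome
    is adapted with ``warm_start_evolve`` over ``replicates`` runs; solve
    detection uses the correctness-only fitness reaching the number of
    cells (all types correct).  Returns rows with mean/min generations and
    the censoring fraction.
    """
    if ea is None:
        ea = DESK_EA
    targets = list(targets)
    rows = []
    for p_idx, (seed_pd, genome) in enumerate(sorted(seed_genomes.items())):
        for t_idx, target in enumerate(targets):
            threshold = (
                correctness_threshold
                if correctness_threshold is not None
                else float(target.n_cells)
            )
            run_weights = (
                weights
                if weights is not None
                else FitnessWeights(correctness_only=True)
            )
            for n_idx, noise in enumerate(noise_values):
                gens, censored = [], []
                for rep in range(replicates):
                    seed = _derived_seed(master_seed, p_idx, t_idx, n_idx, rep)
                    run_env = replace(env, noise_sigma=float(noise), pd=float(seed_pd))
                    run_ea = replace(ea, seed=seed, solve_threshold=threshold)
                    log = warm_start_evolve(
                        genome, target, run_env, run_weights, run_ea
                    )
                    crossing = generations_to_threshold(log, threshold)
                    gens.append(crossing.generations)
                    censored.append(crossing.censored)
                rows.append(
                    {
                        "seed_pd": float(seed_pd),
                        "target": target.name,
                        "noise": float(noise),
                        "mean_generations": float(np.mean(gens)),
                        "min_generations": int(np.min(gens)),
                        "censoring_fraction": float(np.mean(censored)),
                        "n_runs": replicates,
                    }
                )
    return pd.DataFrame(rows)
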