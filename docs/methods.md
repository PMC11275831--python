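# Methods

## Model

The substrate is an `Nx × Ny` grid of cells, each holding a real state
vector of `N_C = N_G + N_H` channels clipped to `l_c = [-3, 3]`: `N_G`
type-indicator channels read out by argmax (ties break to the lowest type
index — a measure-zero event under noise, but determinism requires a
rule) and `N_H` hidden channels usable for signalling. The default task
geometry is 8×8 with `N_G = 3`, `N_H = 1`.

One developmental step is synchronous: every cell perceives the *current*
tissue, so permuting cell visitation order cannot change the result. A
cell perceives the 9 states of its Moore neighborhood, self included.
Boundary handling is "fixed": out-of-grid positions are virtual cells
with a constant zero state that participate in the 9-way mean, keeping
the aggregation count constant everywhere (a `boundary="truncated"`
toggle averages over real cells only, for sensitivity checks).

Perception is permutation-invariant by construction: each of the 9 states
passes through a shared bias-free linear map `N_C → s` followed by tanh,
and the 9 embeddings are averaged into the context vector. The controller
stage consists of `R` independently parameterized copies sharing that
context; their outputs are averaged *before* a single clip to
`l_a = [-1, 1]`, so exactly one bounded action enters the update rule.
Two controller families are provided:

* **FF** — bias-free linear readout `s → N_C` per copy. Defaults
  `s = 24`, giving `4·24 + R·24·4` parameters = 192 at `R = 1`.
* **RGRN** — per copy a private memory `m' = tanh(W_in s + W_rec m)` and
  readout `W_out m' + b` (output bias only). Defaults `s = 16`, `m = 4`,
  giving `4·16 + R·(16·4 + 4·4 + 4·4 + 4)` = 164 at `R = 1`.

These are the minimal layouts consistent with the reference parameter
counts; all dimensions are configurable. Memory is zero-initialized per
rollout, is invisible to neighbors, and updates every step by default
even when the cell's action is gated off (gating models the
environmental execution of an action, not the cell's internal
computation; a `gate_memory` toggle exists). The controller runs one
internal cycle per developmental step by default (`n_cycles` exposes
more).

The update applied to every cell is

    c' = clip(c + (gate · a + noise), l_c),

with `gate ~ Bernoulli(P_D)` i.i.d. per cell per step and noise i.i.d.
`N(0, ξ_c²)` per state element. Noise is applied regardless of gating —
at `P_D = 0` a noisy environment still erodes the tissue, which is what
makes active correction valuable. No noise is applied at `t_0`; the
initial tissue is the structural genome clipped to `l_c`. The written
parenthesization is the implemented floating-point evaluation order,
which the test suite's naive reference reproduces bit for bit.

## Fitness

For a trajectory of `t_D` steps scored against a target:

* `n_G` — cells whose final type matches the target;
* `n_T` — post-update steps `k ∈ {1..t_D}` at which the entire map is
  correct. Counting post-update states only is forced by the analytic
  maximum `64 + 0.25·25 = 70.25` (including `t_0` would give 70.5);
* `n_S` — step pairs `(k, k+1)`, `k ∈ {0..t_D−1}`, with an unchanged map
  that differs from the target. Restricting the stagnation penalty to
  *suboptimal* patterns resolves the otherwise contradictory incentives
  of rewarding maintenance while punishing stagnation; the `(t_0, t_1)`
  pair is included, which affects only suboptimal-stagnant scores.

Score: `(2 n_G − N_j) + r_T n_T − r_S n_S − r_L2 Σ x²` with defaults
`r_T = 0.25`, `r_S = 0.5`, `r_L2 = 0` (0.01 when the competency gene is
evolved; the L2 term is taken over the *full* flat genome). A
`correctness_only` flag forces `r_T = r_S = 0` for generalization
studies. The evolutionary fitness `F` of a genome is the mean score of
`N_E` independent rollouts (8 at full scale, 4 at desk scale).
Structural fitness uses the identical protocol (same noise level, same
replicate averaging) with all actions disabled.

## Evolution

The optimizer is a self-contained (μ/μ_w, λ)-CMA-ES with cumulative
step-size adaptation and rank-1 + rank-μ covariance updates, unit-tested
against analytic optima. The search space is unbounded; constraints are
enforced on the phenotype side (state clipping at compilation, competency
gene clipped to `[-3, 3]` before decoding) rather than as search bounds.
Defaults: σ₀ = 0.5 from a random N(0, 0.1²) initial mean, population 96,
at most 2000 generations; warm starts use σ₀ = 0.1 around the seed
genome. Three modes: `direct` (actions disabled; functional genes remain
in the search vector so the dimension is balanced), `multiscale`, and
`evolvable_competency` (appends the gene, decoded as
`P_D = (tanh x + 1)/2`, and enables L2 at 0.01).

Every candidate is scored with fresh replicate seeds each generation; all
seeds derive deterministically from the single EA seed, and the replicate
seed key of the best-ever candidate is logged so its fitness is exactly
reproducible. The initial search mean is itself evaluated before the
first generation, so a warm start from an already-solving genome is
recorded as solved at generation 1. Runs stop at the generation budget or
after a configurable post-solve patience (0 by default: stop at solve,
since sweeps measure generations-to-threshold). Solve detection uses the
best-ever averaged fitness reaching the threshold, 64 on the 8×8 task
(= the cell count; the correctness term equals `N_j` exactly when every
cell is correct).

Sweeps derive one seed per (cell, replicate) from a master seed, are
resumable through content-addressed per-run records, and aggregate with
censored runs entered at the generation budget alongside an explicit
censoring fraction (the aggregation is a pure function of the raw rows,
and the choice of mean-with-censoring is a package convention).

## Problem sizes and budgets

Two profiles are used. The *full-scale* profile (8×8 targets, population
96, ≤ 2000 generations, `N_E = 8`, `t_D = 25`) reproduces the study
conditions and is hours-scale per run. The *desk-scale* profile used by
the test suite and smoke experiments keeps `t_D = 25` and the update
rule identical but shrinks the task (2×2 solid or diagonal targets, a
feedforward controller with `s = 8`, population 16, ≤ 300–400
generations, `N_E = 4`, solve threshold = cell count 4). The desk profile
preserves the qualitative phenomena: under developmental noise 0.5,
evolution with competent cells (`P_D = 0.5`) crosses the solve threshold
in ~4 generations on average versus ~40 for the direct encoding, and at
zero noise the direct encoding solves in a handful of generations.

For transfer, a collective pre-evolved (to convergence, patience 50) on a
2×2 diagonal pattern at `P_D = 1`, `ξ_c = 0.25` adapts to a harsher
environment (`ξ_c = 0.5`) within 2–12 generations for the best of 8
warm-started runs. Cross-pattern transfer at this scale behaves
differently from the large task: the tiny controller over-commits to its
training pattern (it actively rebuilds it, fighting structural change),
so adapting e.g. diagonal→solid takes tens of generations; recovering the
fast cross-pattern transfer headline requires the full-scale budget.

## What the synthetic tasks do and do not show

All inputs are generated programmatically: built-in flag rasterizations
(fixed conventions of this package; the findings should be insensitive to
the exact raster) or plain-text grid files. The model abstracts development to a fixed
grid: no cell division, migration, or death, no anatomical geometry, no
explicit biochemistry. Passing tests therefore demonstrate properties of
this minimal model — synchronous, bounded, noisy local state regulation
with mean-field perception — not of any real developmental system.

## Numerical conventions

All matrix products in the rollout engine are evaluated as broadcast
multiply-sum reductions instead of BLAS calls: the grids are tiny, and
this makes every output element bit-identical to a per-cell reference
computation, which the oracle-equivalence tests exploit. The
permutation-invariant sensor mean in the single-cell API accumulates
embeddings in sorted order so the invariance is exact rather than
up-to-summation-order. One seed source per rollout is split into separate
noise and gate substreams, so changing `P_D` never reshuffles the noise
realization and vice versa. Degenerate configurations (`ξ_c = 0`,
`P_D ∈ {0, 1}`, 1×1 grids) are valid and covered by tests.

## Known limitations

Cross-pattern transfer and the full 8×8 sweep grid are only exercised at
reduced scale in the default test run (the machinery — warm starts, the
sweep matrix, redundancy stacking up to `R = 16` — is identical at both
scales). The CMA-ES implementation covers the standard update equations
but none of the restart or boundary-handling extensions of mature
optimization libraries.
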