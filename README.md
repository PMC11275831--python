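# morphonca

In silico morphogenesis with neural cellular automata (NCAs) and
neuroevolution, built for studying how *cellular competency* — the ability
of individual cells to sense their surroundings and correct their own state
— changes the course of an evolutionary process.

A small rectangular grid of cells must self-assemble a target pattern of
discrete cell types (the flagship task is an 8×8 Czech-flag raster over
blue/white/red, a richer cousin of the classic French-flag problem of
developmental biology). Every cell carries a real-valued state
`c_i ∈ R^{N_C}` whose first `N_G` channels are *type indicators* (the cell
expresses type `g_i = argmax` of those channels) and whose remaining
channels are hidden signalling dimensions. Development runs for `t_D`
synchronous steps of

```
c_i(t+1) = clip( c_i(t) + gate_i · a_i(t) + ξ_c ,  [-3, 3] )
```

where `a_i` is the action proposed by the cell's neural controller
(clipped to `[-1, 1]`), `gate_i ~ Bernoulli(P_D)` models the reliability
of action execution, and `ξ_c` is i.i.d. Gaussian developmental noise.
Perception is permutation-invariant: the 9 states of a cell's Moore
neighborhood (self included, fixed zero-state virtual cells at the
boundary) are embedded by a shared linear+tanh sensor and *averaged*, so a
cell cannot tell its neighbors apart. The controller is a stack of `R`
redundant copies (feedforward, or a recurrent variant with private
per-cell memory inspired by gene regulatory networks) whose outputs are
averaged into one action.

The evolvable genome is the concatenation of

* **structural genes** `x^(S)` — the initial cell states of every grid cell
  (256 numbers for the 8×8, `N_C = 4` task),
* **functional genes** `x^(F) = θ` — the controller weights (192 for the
  default feedforward controller, 164 for the recurrent one at `R = 1`),
* optionally a **competency gene** `x^(C)`, decoded to
  `P_D = (tanh x^(C) + 1)/2`.

A CMA-ES loop (population 96, up to 2000 generations at full scale)
maximizes the phenotype fitness

```
r = (2 n_G − N_j) + r_T n_T − r_S n_S − r_L2 Σ x²
```

with `n_G` the correctly typed cells at the end of development, `n_T` the
steps at which the whole pattern is correct (maintenance reward,
`r_T = 0.25`), and `n_S` the stagnant steps away from the target
(`r_S = 0.5`). Each candidate is scored by the mean of `N_E = 8`
independent noisy rollouts. Setting `P_D = 0` disables all actions and
recovers a *direct encoding* of the pattern by the structural genes;
`P_D = 1` is a fully reliable multi-scale competency architecture.

## Worked example

```python
import morphonca as m

grid = m.GridSpec(nx=8, ny=8, n_types=3, n_hidden=1)
czech = m.make_flag_pattern("czech", grid)
print(czech.type_counts())        # [20 22 22]  blue/white/red cells

# A saturated direct encoding: initial states spell out the target
genome = m.make_saturated_genome(czech, m.ControllerSpec(arch="ff"), grid)
env = m.EnvConfig(dev_steps=25, noise_sigma=0.0, actions_enabled=False)
f = m.evaluate_genome(genome, czech, env, m.FitnessWeights(), n_reps=8, rng=0)
print(f)                          # 70.25  = 64 + 25 * 0.25, the analytic maximum

# Evolve a competent collective for a small task
import numpy as np
target = m.TargetPattern(np.zeros((2, 2), int), 3, name="solid_blue")
small = m.GridSpec(nx=2, ny=2, n_types=3, n_hidden=1)
arch = m.ControllerSpec(arch="ff", state_dim=4, embed_dim=8)
ea = m.EAConfig(pop_size=16, max_generations=300, n_eval_reps=4,
                solve_threshold=4.0, seed=1)
log = m.evolve(target, arch, small, m.EnvConfig(dev_steps=25, noise_sigma=0.5,
               pd=0.5), m.FitnessWeights(), ea)
print(log.solved_at)              # 4: generations to reach the correctness threshold 4
```

The printed `70.25` is the maximum composite fitness of the 8×8 task (all
64 cells correct, plus the maintenance reward for all 25 steps); the solve
threshold of a task equals its cell count (`2 n_G − N_j = N_j` when every
cell is correct — 64 on the 8×8 grid).

The same functionality is exposed on the command line (`morphonca rollout
/ evolve / sweep / generalize / transfer`); see `morphonca --help`.

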