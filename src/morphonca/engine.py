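"""The developmental rollout: synchronous, noisy, gated cell-state updates.

Starting from the structural genome as the initial tissue state, each
developmental step lets every cell perceive its Moore neighborhood of the
*current* tissue, propose an action through its controller, and then apply

    c_i(t+1) = clip(c_i(t) + (gate_i * a_i(t) + noise_i), [-3, 3])

where ``gate_i ~ Bernoulli(PD)`` models the reliability of action execution
(the decision-making probability) and the noise is i.i.d. Gaussian with
standard deviation ``noise_sigma`` per state element.  Noise hits every
cell regardless of gating; with actions disabled and no noise the rollout
is the identity on states, i.e. a pure direct encoding.

Boundary handling: positions outside the grid are treated as virtual cells
with a constant all-zero state that participate in the 9-way sensor mean
(``boundary="virtual_zero"``, the default); ``boundary="truncated"``
instead averages over the real cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import ARCH_FF, Genome, split_theta
from .patterns import GridSpec

#: Perception order: self first, then the 8 Moore offsets row-major.
NEIGHBOR_OFFSETS = (
    (0, 0),
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, -1),
    (0, 1),
    (1, -1),
    (1, 0),
    (1, 1),
)


@dataclass(frozen=True)
class EnvConfig:
    """Developmental environment of a rollout.

    ``noise_sigma`` is counted in units of the action limit (max = 1).
    ``pd`` is the decision-making probability; ``None`` defers to the
    genome's competency gene.  ``pd_source`` may pin the authoritative
    source ("env" or "genome"); the default "auto" uses ``pd`` when set
    and the gene otherwise.
    """

    dev_steps: int = 25
    noise_sigma: float = 0.0
    pd: float | None = 1.0
    actions_enabled: bool = True
    state_limit: float = 3.0
    action_limit: float = 1.0
    pd_source: str = "auto"  # "auto" | "env" | "genome"
    gate_memory: bool = False  # if True, recurrent memory updates are gated too
    boundary: str = "virtual_zero"  # or "truncated"

    def __post_init__(self) -> None:
        if self.dev_steps < 1:
            raise ValueError("dev_steps must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.pd is not None and not 0.0 <= self.pd <= 1.0:
            raise ValueError("pd must lie in [0, 1]")
        if self.pd_source not in ("auto", "env", "genome"):
            raise ValueError(f"unknown pd_source {self.pd_source!r}")
        if self.boundary not in ("virtual_zero", "truncated"):
            raise ValueError(f"unknown boundary {self.boundary!r}")


@dataclass
class Trajectory:
    """States and derived type maps of a full developmental rollout.

    ``states`` has shape (T+1, ny, nx, NC) including the initial state,
    ``typemaps`` the per-step argmax readouts, and ``gate_mask`` the
    (T, ny, nx) record of which proposed actions were executed.
    """

    states: np.ndarray
    typemaps: np.ndarray
    gate_mask: np.ndarray
    pd: float
    grid: GridSpec

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    @property
    def final_typemap(self) -> np.ndarray:
        return self.typemaps[-1]


def cell_types(state: np.ndarray, n_types: int) -> np.ndarray:
    """Read out the type map: argmax over the first ``n_types`` channels.

    Ties break toward the lowest type index (numpy argmax convention).
    """
    return np.argmax(np.asarray(state)[..., :n_types], axis=-1)


def neighborhood(state: np.ndarray, row: int, col: int) -> list[np.ndarray]:
    """The 9 perceived states of cell (row, col), self first.

    Out-of-grid positions contribute the zero state of the fixed virtual
    boundary cells, so the list always has 9 entries.
    """
    state = np.asarray(state)
    ny, nx, nc = state.shape
    if not (0 <= row < ny and 0 <= col < nx):
        raise IndexError(f"cell ({row}, {col}) outside {ny}x{nx} grid")
    out = []
    for dr, dc in NEIGHBOR_OFFSETS:
        r, c = row + dr, col + dc
        if 0 <= r < ny and 0 <= c < nx:
            out.append(state[r, c])
        else:
            out.append(np.zeros(nc))
    return out


def resolve_pd(genome: Genome, env: EnvConfig) -> float:
    """Pick the effective decision-making probability for a rollout."""
    if not env.actions_enabled:
        return 0.0
    if env.pd_source == "genome":
        if env.pd is not None:
            raise ValueError(
                "conflicting PD sources: env.pd is set but pd_source='genome'"
            )
        if not genome.has_competency:
            raise ValueError("pd_source='genome' but genome has no competency gene")
        return genome.decoded_pd()
    if env.pd_source == "env":
        if env.pd is None:
            raise ValueError("pd_source='env' but env.pd is unset")
        return float(env.pd)
    # auto: env.pd wins when set, otherwise fall back to the gene
    if env.pd is not None:
        return float(env.pd)
    if genome.has_competency:
        return genome.decoded_pd()
    raise ValueError("no decision-making probability: env.pd unset and no gene")


class _CompiledController:
    """Stacked weight views of one genome, for vectorized rollouts."""

    def __init__(self, genome: Genome):
        spec = genome.arch
        self.spec = spec
        weights = split_theta(genome.functional, spec)
        self.sensor = weights["sensor"]  # (s, NC)
        copies = weights["copies"]
        if spec.arch == ARCH_FF:
            self.w_out = np.stack([c["w_out"] for c in copies])  # (R, NA, s)
        else:
            self.w_in = np.stack([c["w_in"] for c in copies])  # (R, m, s)
            self.w_rec = np.stack([c["w_rec"] for c in copies])  # (R, m, m)
            self.w_out = np.stack([c["w_out"] for c in copies])  # (R, NA, m)
            self.bias = np.stack([c["bias"] for c in copies])  # (R, NA)

    def init_memory(self, grid: GridSpec) -> np.ndarray | None:
        if self.spec.arch == ARCH_FF:
            return None
        return np.zeros(
            (grid.ny, grid.nx, self.spec.redundancy, self.spec.memory_dim)
        )

    def contexts(self, state: np.ndarray, boundary: str) -> np.ndarray:
        """Permutation-invariant context of every cell, shape (ny, nx, s).

        Matrix products are evaluated as broadcast multiply-sum reductions
        rather than BLAS calls: the grids are tiny, and this keeps every
        output element bit-identical to a per-cell reference computation.
        """
        ny, nx, _ = state.shape
        emb = np.tanh((state[..., None, :] * self.sensor).sum(-1))  # (ny, nx, s)
        padded = np.zeros((ny + 2, nx + 2, emb.shape[-1]))
        padded[1:-1, 1:-1] = emb
        ctx = np.zeros_like(emb)
        for dr, dc in NEIGHBOR_OFFSETS:
            ctx += padded[1 + dr : 1 + dr + ny, 1 + dc : 1 + dc + nx]
        if boundary == "virtual_zero":
            ctx /= 9.0
        else:  # truncated: average over real cells only
            ones = np.zeros((ny + 2, nx + 2))
            ones[1:-1, 1:-1] = 1.0
            counts = np.zeros((ny, nx))
            for dr, dc in NEIGHBOR_OFFSETS:
                counts += ones[1 + dr : 1 + dr + ny, 1 + dc : 1 + dc + nx]
            ctx /= counts[..., None]
        return ctx

    def actions(
        self, ctx: np.ndarray, memory: np.ndarray | None, action_limit: float
    ):
        """Averaged, clipped action of every cell; returns (actions, memory')."""
        if self.spec.arch == ARCH_FF:
            # (ny, nx, R, NA): per-copy linear readout of the context
            out = (ctx[..., None, None, :] * self.w_out).sum(-1)
            new_memory = None
        else:
            new_memory = np.array(memory, copy=True)
            drive = (ctx[..., None, None, :] * self.w_in).sum(-1)  # (ny, nx, R, m)
            for _ in range(self.spec.n_cycles):
                recur = (new_memory[..., None, :] * self.w_rec).sum(-1)
                new_memory = np.tanh(drive + recur)
            out = (new_memory[..., None, :] * self.w_out).sum(-1) + self.bias
        action = out.mean(axis=2)
        return np.clip(action, -action_limit, action_limit), new_memory


def _split_streams(rng, n: int) -> list[np.random.Generator]:
    """Deterministically split one seed source into n independent streams."""
    if rng is None:
        rng = np.random.SeedSequence()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.SeedSequence(int(rng))
    if isinstance(rng, np.random.SeedSequence):
        return [np.random.default_rng(child) for child in rng.spawn(n)]
    if isinstance(rng, np.random.Generator):
        return rng.spawn(n)
    raise TypeError(f"cannot derive random streams from {type(rng)!r}")


def _step(
    state: np.ndarray,
    controller: _CompiledController,
    env: EnvConfig,
    pd: float,
    memory: np.ndarray | None,
    noise_rng: np.random.Generator,
    gate_rng: np.random.Generator,
):
    ny, nx, nc = state.shape
    if env.actions_enabled:
        ctx = controller.contexts(state, env.boundary)
        gate = gate_rng.random((ny, nx)) < pd
        if env.gate_memory and memory is not None:
            action, new_memory = controller.actions(ctx, memory, env.action_limit)
            new_memory = np.where(gate[..., None, None], new_memory, memory)
        else:
            action, new_memory = controller.actions(ctx, memory, env.action_limit)
        update = gate[..., None] * action
    else:
        gate = np.zeros((ny, nx), dtype=bool)
        update = 0.0
        new_memory = memory
    if env.noise_sigma > 0:
        update = update + env.noise_sigma * noise_rng.standard_normal((ny, nx, nc))
    new_state = np.clip(state + update, -env.state_limit, env.state_limit)
    return new_state, new_memory, gate


def step(
    state: np.ndarray,
    genome: Genome,
    env: EnvConfig,
    memory: np.ndarray | None = None,
    rng=None,
):
    """One synchronous developmental step (convenience wrapper).

    All cells perceive the same input tissue; the result is independent of
    any cell visitation order.  Returns ``(state', memory', gate_mask)``.
    """
    controller = _CompiledController(genome)
    pd = resolve_pd(genome, env)
    noise_rng, gate_rng = _split_streams(rng, 2)
    if memory is None:
        memory = controller.init_memory(genome.grid)
    return _step(
        np.asarray(state, dtype=float), controller, env, pd, memory, noise_rng, gate_rng
    )


def rollout(genome: Genome, env: EnvConfig, rng=None) -> Trajectory:
    """Run a full developmental rollout of ``env.dev_steps`` steps.

    The initial tissue is the structural genome clipped to the state
    limits; no noise is applied at t0.  One seed source is split into
    separate noise and gate substreams so that changing PD never reshuffles
    the noise realization (and vice versa).
    """
    controller = _CompiledController(genome)
    pd = resolve_pd(genome, env)
    noise_rng, gate_rng = _split_streams(rng, 2)
    grid = genome.grid
    state = np.clip(genome.structural, -env.state_limit, env.state_limit)
    memory = controller.init_memory(grid)

    states = np.empty((env.dev_steps + 1, grid.ny, grid.nx, grid.state_dim))
    gates = np.empty((env.dev_steps, grid.ny, grid.nx), dtype=bool)
    states[0] = state
    for t in range(env.dev_steps):
        state, memory, gate = _step(
            state, controller, env, pd, memory, noise_rng, gate_rng
        )
        states[t + 1] = state
        gates[t] = gate
    typemaps = cell_types(states, grid.n_types)
    return Trajectory(states=states, typemaps=typemaps, gate_mask=gates, pd=pd, grid=grid)


def disable_actions(env: EnvConfig) -> EnvConfig:
    """The same environment with all cell actions switched off."""
    return replace(env, actions_enabled=False)
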