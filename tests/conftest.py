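"""Shared fixtures and the independent naive rollout reference."""

from __future__ import annotations

import numpy as np
import pytest

import morphonca as m
from morphonca.engine import NEIGHBOR_OFFSETS, _split_streams
from morphonca.genome import split_theta


@pytest.fixture
def grid8() -> m.GridSpec:
    return m.GridSpec(nx=8, ny=8, n_types=3, n_hidden=1)


@pytest.fixture
def ff_spec() -> m.ControllerSpec:
    return m.ControllerSpec(arch="ff", state_dim=4)


@pytest.fixture
def rgrn_spec() -> m.ControllerSpec:
    return m.ControllerSpec(arch="rgrn", state_dim=4)


@pytest.fixture
def czech(grid8) -> m.TargetPattern:
    return m.make_flag_pattern("czech", grid8)


@pytest.fixture
def saturated_czech(czech, ff_spec, grid8) -> m.Genome:
    return m.make_saturated_genome(czech, ff_spec, grid8)


@pytest.fixture
def grid2() -> m.GridSpec:
    return m.GridSpec(nx=2, ny=2, n_types=3, n_hidden=1)


@pytest.fixture
def solid_blue_2x2(grid2) -> m.TargetPattern:
    return m.TargetPattern(np.zeros((2, 2), dtype=int), grid2.n_types, name="solid_blue")


@pytest.fixture
def desk_arch() -> m.ControllerSpec:
    """Small feedforward controller for desk-scale evolution runs."""
    return m.ControllerSpec(arch="ff", state_dim=4, embed_dim=8)


def naive_rollout(genome: m.Genome, env: m.EnvConfig, rng) -> np.ndarray:
    """Per-cell, per-step reference rollout written from the update rule.

    Loops over every cell explicitly, gathers its 9 perceived states by
    hand (zero vectors outside the grid), evaluates the sensor/controller
    maps element by element, and applies gating, noise and clipping per
    the documented update

        c' = clip(c + (gate * a + noise), state limits)

    sharing only the engine's seed-splitting discipline so that the same
    noise and gate realizations are consumed.  Returns the (T+1, ny, nx,
    NC) state history.
    """
    w = split_theta(genome.functional, genome.arch)
    spec, grid = genome.arch, genome.grid
    noise_rng, gate_rng = _split_streams(rng, 2)
    pd = m.resolve_pd(genome, env)
    state = np.clip(genome.structural, -env.state_limit, env.state_limit)
    mem = np.zeros((grid.ny, grid.nx, spec.redundancy, spec.memory_dim))
    states = [state]
    for _ in range(env.dev_steps):
        new = np.empty_like(state)
        if env.actions_enabled:
            gate = gate_rng.random((grid.ny, grid.nx)) < pd
        else:
            gate = np.zeros((grid.ny, grid.nx), dtype=bool)
        if env.noise_sigma > 0:
            noise = env.noise_sigma * noise_rng.standard_normal(state.shape)
        else:
            noise = np.zeros_like(state)
        new_mem = mem.copy()
        for row in range(grid.ny):
            for col in range(grid.nx):
                if env.actions_enabled:
                    acc = np.zeros(spec.embed_dim)
                    for dr, dc in NEIGHBOR_OFFSETS:
                        r, c = row + dr, col + dc
                        if 0 <= r < grid.ny and 0 <= c < grid.nx:
                            s_vec = state[r, c]
                        else:
                            s_vec = np.zeros(grid.state_dim)
                        acc = acc + np.tanh((w["sensor"] * s_vec).sum(-1))
                    ctx = acc / 9.0
                    outs = []
                    for k, copy in enumerate(w["copies"]):
                        if spec.arch == "ff":
                            outs.append((copy["w_out"] * ctx).sum(-1))
                        else:
                            m_k = mem[row, col, k]
                            for _cycle in range(spec.n_cycles):
                                m_k = np.tanh(
                                    (copy["w_in"] * ctx).sum(-1)
                                    + (copy["w_rec"] * m_k).sum(-1)
                                )
                            new_mem[row, col, k] = m_k
                            outs.append((copy["w_out"] * m_k).sum(-1) + copy["bias"])
                    action = np.clip(
                        np.mean(outs, axis=0), -env.action_limit, env.action_limit
                    )
                    update = action if gate[row, col] else np.zeros_like(action)
                else:
                    update = np.zeros(grid.state_dim)
                new[row, col] = np.clip(
                    state[row, col] + (update + noise[row, col]),
                    -env.state_limit,
                    env.state_limit,
                )
        mem = new_mem
        state = new
        states.append(state)
    return np.array(states)
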