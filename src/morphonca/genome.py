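"""Genome layout and the permutation-invariant cell controllers.

Every cell on the grid runs the same tiny neural network.  Perception is
deliberately order-free: each of the 9 perceived states (self + 8 Moore
neighbors) is pushed through a shared linear+tanh *sensor* map and the 9
embeddings are averaged into a context vector, so a cell cannot tell its
neighbors apart (nor itself from them).  The context feeds a *controller*
stage made of R redundant, independently parameterized copies whose outputs
are averaged into a single action proposal, clipped to the action limits.

Two controller families are supported:

* ``ff``   — a bias-free linear readout from the context (stateless).
* ``rgrn`` — a recurrent core inspired by gene regulatory networks: each
  copy keeps a private m-dimensional memory, invisible to neighbors,
  updated as ``m' = tanh(W_in s + W_rec m)`` with action ``W_out m' + b``.

The evolved genome concatenates a *structural* part (the initial cell
states of every grid cell), a *functional* part (the flat controller
parameter vector theta), and optionally a scalar *competency gene* that is
decoded into the decision-making probability ``PD = (tanh(x) + 1) / 2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import GridSpec, TargetPattern

ARCH_FF = "ff"
ARCH_RGRN = "rgrn"

#: Numerical range of cell states and of the competency gene.
STATE_LIMIT = 3.0

GENOME_FORMAT = "morphonca-genome"
GENOME_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ControllerSpec:
    """Architecture of a cell's decision-making network.

    Defaults reproduce the reference parameter counts at redundancy 1:
    192 for the feedforward family (state_dim 4, embed_dim 24) and 164 for
    the recurrent family (embed_dim 16, memory_dim 4, output bias only).
    """

    arch: str = ARCH_FF
    state_dim: int = 4  # NC; also the action dimension NA
    embed_dim: int | None = None  # s; architecture-dependent default
    memory_dim: int = 4  # m, recurrent family only
    redundancy: int = 1  # R, number of averaged controller copies
    n_cycles: int = 1  # internal controller cycles per developmental step

    def __post_init__(self) -> None:
        arch = self.arch.lower()
        if arch not in (ARCH_FF, ARCH_RGRN):
            raise ValueError(f"unknown controller arch {self.arch!r}")
        object.__setattr__(self, "arch", arch)
        if self.embed_dim is None:
            object.__setattr__(
                self, "embed_dim", 24 if arch == ARCH_FF else 16
            )
        for name in ("state_dim", "embed_dim", "memory_dim", "redundancy", "n_cycles"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"ControllerSpec.{name} must be >= 1")

    @property
    def action_dim(self) -> int:
        return self.state_dim

    @property
    def is_recurrent(self) -> bool:
        return self.arch == ARCH_RGRN


def param_count(spec: ControllerSpec) -> int:
    """Total number of functional (controller) parameters.

    ``ff``:   NC*s sensor weights + R * (s*NA) readout weights.
    ``rgrn``: NC*s sensor weights + R * (s*m + m*m + m*NA + NA).
    """
    nc, s, na = spec.state_dim, spec.embed_dim, spec.action_dim
    sensor = nc * s
    if spec.arch == ARCH_FF:
        per_copy = s * na
    else:
        m = spec.memory_dim
        per_copy = s * m + m * m + m * na + na
    return sensor + spec.redundancy * per_copy


def split_theta(theta: np.ndarray, spec: ControllerSpec) -> dict:
    """Unpack a flat functional vector into named weight arrays.

    Returns ``{"sensor": (s, NC), "copies": [per-copy dict, ...]}`` where a
    feedforward copy holds ``w_out (NA, s)`` and a recurrent copy holds
    ``w_in (m, s)``, ``w_rec (m, m)``, ``w_out (NA, m)``, ``bias (NA,)``.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != param_count(spec):
        raise ValueError(
            f"theta has {theta.size} entries, expected {param_count(spec)}"
        )
    nc, s, na, m = spec.state_dim, spec.embed_dim, spec.action_dim, spec.memory_dim
    pos = s * nc
    out = {"sensor": theta[:pos].reshape(s, nc), "copies": []}
    for _ in range(spec.redundancy):
        if spec.arch == ARCH_FF:
            w = theta[pos : pos + na * s].reshape(na, s)
            pos += na * s
            out["copies"].append({"w_out": w})
        else:
            w_in = theta[pos : pos + m * s].reshape(m, s)
            pos += m * s
            w_rec = theta[pos : pos + m * m].reshape(m, m)
            pos += m * m
            w_out = theta[pos : pos + na * m].reshape(na, m)
            pos += na * m
            bias = theta[pos : pos + na]
            pos += na
            out["copies"].append(
                {"w_in": w_in, "w_rec": w_rec, "w_out": w_out, "bias": bias}
            )
    assert pos == theta.size
    return out


def decode_competency(x_c: float) -> float:
    """Map the competency gene to a decision-making probability.

    The gene is clipped to the state range [-3, 3] and decoded as
    ``PD = (tanh(x) + 1) / 2``, a monotone map with ``PD(-x) = 1 - PD(x)``.
    """
    x = float(np.clip(x_c, -STATE_LIMIT, STATE_LIMIT))
    return float(0.5 * (np.tanh(x) + 1.0))


def embed_and_aggregate(neighborhood, sensor_w: np.ndarray) -> np.ndarray:
    """Average the sensor embeddings of the 9 perceived cell states.

    ``neighborhood`` is the ordered list of 9 state vectors (self first,
    then the Moore neighbors); the output is invariant to any permutation
    of that order.  The embeddings are accumulated per component in sorted
    order, so the invariance holds exactly (bit for bit), not just up to
    floating-point summation order.
    """
    if len(neighborhood) != 9:
        raise ValueError(f"expected 9 neighborhood states, got {len(neighborhood)}")
    embeddings = np.stack(
        [
            np.tanh((sensor_w * np.asarray(state, dtype=float)).sum(-1))
            for state in neighborhood
        ]
    )
    return np.sort(embeddings, axis=0).sum(axis=0) / 9.0


def controller_forward(
    context: np.ndarray,
    memory: np.ndarray | None,
    theta: np.ndarray,
    spec: ControllerSpec,
    action_limit: float = 1.0,
):
    """Run the R redundant controller copies on one cell's context.

    Copy outputs are averaged first and the mean is clipped once to
    ``[-action_limit, action_limit]``.  For the recurrent family ``memory``
    has shape (R, m) and the updated memory is returned; feedforward
    controllers return ``None``.
    """
    context = np.asarray(context, dtype=float)
    weights = split_theta(theta, spec)
    outputs = []
    new_memory = None
    if spec.arch == ARCH_FF:
        for copy in weights["copies"]:
            outputs.append(copy["w_out"] @ context)
    else:
        if memory is None:
            memory = np.zeros((spec.redundancy, spec.memory_dim))
        new_memory = np.array(memory, dtype=float, copy=True)
        for r, copy in enumerate(weights["copies"]):
            m_r = new_memory[r]
            for _ in range(spec.n_cycles):
                m_r = np.tanh(copy["w_in"] @ context + copy["w_rec"] @ m_r)
            new_memory[r] = m_r
            outputs.append(copy["w_out"] @ m_r + copy["bias"])
    action = np.mean(outputs, axis=0)
    return np.clip(action, -action_limit, action_limit), new_memory


@dataclass
class Genome:
    """The full evolvable parameter set of one cellular collective.

    ``structural`` is the (ny, nx, NC) array of initial cell states,
    ``functional`` the flat controller vector theta, and ``competency`` the
    optional scalar gene for the decision-making probability.
    """

    structural: np.ndarray
    functional: np.ndarray
    arch: ControllerSpec
    grid: GridSpec
    competency: float | None = None

    def __post_init__(self) -> None:
        self.structural = np.asarray(self.structural, dtype=float)
        self.functional = np.asarray(self.functional, dtype=float).ravel()
        expected = (self.grid.ny, self.grid.nx, self.grid.state_dim)
        if self.structural.shape != expected:
            raise ValueError(
                f"structural shape {self.structural.shape} != {expected}"
            )
        if self.arch.state_dim != self.grid.state_dim:
            raise ValueError("controller state_dim must equal grid state_dim")
        if self.functional.size != param_count(self.arch):
            raise ValueError(
                f"functional length {self.functional.size} != "
                f"{param_count(self.arch)}"
            )

    @property
    def has_competency(self) -> bool:
        return self.competency is not None

    @property
    def flat_length(self) -> int:
        return (
            self.structural.size
            + self.functional.size
            + (1 if self.has_competency else 0)
        )

    def flatten(self) -> np.ndarray:
        """Concatenate structural | functional | [competency] row-major."""
        parts = [self.structural.ravel(), self.functional]
        if self.has_competency:
            parts.append(np.array([self.competency]))
        return np.concatenate(parts)

    @classmethod
    def from_flat(
        cls,
        flat: np.ndarray,
        arch: ControllerSpec,
        grid: GridSpec,
        has_competency: bool = False,
    ) -> "Genome":
        flat = np.asarray(flat, dtype=float).ravel()
        n_struct = grid.n_cells * grid.state_dim
        n_func = param_count(arch)
        expected = n_struct + n_func + (1 if has_competency else 0)
        if flat.size != expected:
            raise ValueError(f"flat length {flat.size} != {expected}")
        structural = flat[:n_struct].reshape(grid.ny, grid.nx, grid.state_dim)
        functional = flat[n_struct : n_struct + n_func]
        competency = float(flat[-1]) if has_competency else None
        return cls(
            structural=structural,
            functional=functional,
            arch=arch,
            grid=grid,
            competency=competency,
        )

    def decoded_pd(self) -> float:
        if not self.has_competency:
            raise ValueError("genome carries no competency gene")
        return decode_competency(self.competency)


def init_genome(
    arch: ControllerSpec,
    grid: GridSpec,
    rng: np.random.Generator | int,
    include_competency: bool = False,
    sigma: float = 0.1,
) -> Genome:
    """Draw a random genome with i.i.d. N(0, sigma^2) entries."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = grid.n_cells * grid.state_dim + param_count(arch) + (
        1 if include_competency else 0
    )
    flat = sigma * rng.standard_normal(n)
    return Genome.from_flat(flat, arch, grid, has_competency=include_competency)


def make_saturated_genome(
    pattern: TargetPattern,
    arch: ControllerSpec,
    grid: GridSpec,
) -> Genome:
    """Fixture genome whose initial states already spell out the target.

    For every cell the indicator channel of its target type is pinned to
    the upper state limit (+3), all other indicators to the lower limit
    (-3), hidden channels to 0; the functional part is all zeros and no
    competency gene is present.  With actions disabled and no noise the
    type map equals the pattern at every developmental step, realizing the
    direct-encoding limit with maximal margin against noise.
    """
    if not pattern.matches(grid):
        raise ValueError("pattern incompatible with grid spec")
    structural = np.zeros((grid.ny, grid.nx, grid.state_dim))
    structural[..., : grid.n_types] = -STATE_LIMIT
    rows, cols = np.indices(grid.shape)
    structural[rows, cols, pattern.grid] = STATE_LIMIT
    return Genome(
        structural=structural,
        functional=np.zeros(param_count(arch)),
        arch=arch,
        grid=grid,
        competency=None,
    )


def save_genome(genome: Genome, path: str | Path) -> None:
    """Serialize a genome to a self-describing JSON container."""
    Path(path).write_text(json.dumps(genome_to_dict(genome)), encoding="utf-8")


def genome_from_dict(doc: dict) -> Genome:
    if doc.get("format") != GENOME_FORMAT:
        raise ValueError("not a genome container")
    grid = GridSpec(**doc["grid"])
    arch = ControllerSpec(**doc["controller"])
    return Genome(
        structural=np.asarray(doc["structural"], dtype=float),
        functional=np.asarray(doc["functional"], dtype=float),
        arch=arch,
        grid=grid,
        competency=doc.get("competency"),
    )


def genome_to_dict(genome: Genome) -> dict:
    return {
        "format": GENOME_FORMAT,
        "version": GENOME_FORMAT_VERSION,
        "grid": {
            "nx": genome.grid.nx,
            "ny": genome.grid.ny,
            "n_types": genome.grid.n_types,
            "n_hidden": genome.grid.n_hidden,
        },
        "controller": {
            "arch": genome.arch.arch,
            "state_dim": genome.arch.state_dim,
            "embed_dim": genome.arch.embed_dim,
            "memory_dim": genome.arch.memory_dim,
            "redundancy": genome.arch.redundancy,
            "n_cycles": genome.arch.n_cycles,
        },
        "structural": genome.structural.tolist(),
        "functional": genome.functional.tolist(),
        "competency": genome.competency,
    }


def load_genome(path: str | Path) -> Genome:
    return genome_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
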