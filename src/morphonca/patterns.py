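"""Target cell-type patterns and the grid geometry they live on.

A morphogenesis task is specified by a small rectangular grid of integer
cell-type labels that the cellular collective has to self-assemble.  The
built-in targets are 8x8 flag rasterizations over three types
(0 = blue, 1 = white, 2 = red); arbitrary patterns can be loaded from a
plain-text grid file.

Coordinate convention: 0-based, row-major, row 0 is the top of the flag and
column 0 the hoist (left edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Number of surrounding cells each agent perceives (square Moore neighborhood).
MOORE_NEIGHBORS = 8

FLAG_NAMES = (
    "czech",
    "blue",
    "white",
    "red",
    "viennese",
    "blue_white_diag",
    "blue_red_diag",
)

_BLUE, _WHITE, _RED = 0, 1, 2


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the cellular grid and the per-cell state layout.

    Parameters
    ----------
    nx, ny
        Grid width and height in cells.
    n_types
        Number NG of discrete cell types, read out from the leading state
        channels by argmax.
    n_hidden
        Number NH of hidden state channels available for intercellular
        signalling; not visible in the type readout.
    """

    nx: int = 8
    ny: int = 8
    n_types: int = 3
    n_hidden: int = 1

    def __post_init__(self) -> None:
        for field in ("nx", "ny", "n_types", "n_hidden"):
            if int(getattr(self, field)) < 1:
                raise ValueError(f"GridSpec.{field} must be >= 1")

    @property
    def state_dim(self) -> int:
        """NC = NG + NH, the length of each cell's real-valued state."""
        return self.n_types + self.n_hidden

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def n_neighbors(self) -> int:
        return MOORE_NEIGHBORS

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx): numpy array shape of grids over this spec."""
        return (self.ny, self.nx)


@dataclass(frozen=True)
class TargetPattern:
    """An (ny, nx) grid of target cell-type indices in [0, n_types)."""

    grid: np.ndarray
    n_types: int
    name: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.int64)
        if grid.ndim != 2:
            raise ValueError("pattern grid must be 2-D")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if grid.size and (grid.min() < 0 or grid.max() >= self.n_types):
            raise ValueError(
                f"pattern entries must lie in [0, {self.n_types}); "
                f"got range [{grid.min()}, {grid.max()}]"
            )
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_cells(self) -> int:
        return self.grid.size

    def matches(self, spec: GridSpec) -> bool:
        return self.grid.shape == spec.shape and self.n_types == spec.n_types

    def type_counts(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=self.n_types)


def make_flag_pattern(name: str, spec: GridSpec | None = None) -> TargetPattern:
    """Build one of the canonical 8x8 flag targets.

    The rasterizations are fixed conventions of this package:

    * ``czech``: a cell is blue if ``col <= min(row, 7 - row)`` (the hoist
      triangle); otherwise white in the top half (``row <= 3``), red below.
    * ``blue`` / ``white`` / ``red``: solid single-type flags.
    * ``viennese``: rows 0-3 red, rows 4-7 white.
    * ``blue_white_diag``: blue if ``row > col`` else white.
    * ``blue_red_diag``: blue if ``row > col`` else red.
    """
    if spec is None:
        spec = GridSpec()
    if name not in FLAG_NAMES:
        raise ValueError(f"unknown flag {name!r}; choose from {FLAG_NAMES}")
    if (spec.nx, spec.ny, spec.n_types) != (8, 8, 3):
        raise ValueError("built-in flags require an 8x8 grid with 3 cell types")

    rows, cols = np.indices(spec.shape)
    if name == "czech":
        blue = cols <= np.minimum(rows, spec.ny - 1 - rows)
        grid = np.where(blue, _BLUE, np.where(rows <= 3, _WHITE, _RED))
    elif name == "blue":
        grid = np.full(spec.shape, _BLUE)
    elif name == "white":
        grid = np.full(spec.shape, _WHITE)
    elif name == "red":
        grid = np.full(spec.shape, _RED)
    elif name == "viennese":
        grid = np.where(rows <= 3, _RED, _WHITE)
    elif name == "blue_white_diag":
        grid = np.where(rows > cols, _BLUE, _WHITE)
    else:  # blue_red_diag
        grid = np.where(rows > cols, _BLUE, _RED)
    return TargetPattern(grid=grid, n_types=spec.n_types, name=name)


def save_pattern(pattern: TargetPattern, path: str | Path) -> None:
    """Write a pattern as UTF-8 text: one row per line, space-separated
    type indices, preceded by ``#``-prefixed header lines."""
    path = Path(path)
    lines = []
    if pattern.name:
        lines.append(f"# name: {pattern.name}")
    lines.append(f"# n_types: {pattern.n_types}")
    for row in pattern.grid:
        lines.append(" ".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_pattern(path: str | Path, n_types: int | None = None) -> TargetPattern:
    """Read a pattern grid file written by :func:`save_pattern`.

    ``n_types`` overrides the file header; if neither is present it is
    inferred as ``max entry + 1``.  Ragged rows and out-of-range tokens are
    rejected.
    """
    path = Path(path)
    name = ""
    header_types: int | None = None
    rows: list[list[int]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip().lower()
                if key == "name":
                    name = value.strip()
                elif key == "n_types":
                    header_types = int(value.strip())
            continue
        try:
            rows.append([int(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer token") from exc
    if not rows:
        raise ValueError(f"{path}: no grid rows found")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows (expected width {width})")
    if n_types is None:
        n_types = header_types
    grid = np.asarray(rows, dtype=np.int64)
    if n_types is None:
        n_types = int(grid.max()) + 1
    # TargetPattern validates the [0, n_types) range.
    return TargetPattern(grid=grid, n_types=n_types, name=name)
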