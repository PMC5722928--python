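"""Spatial stochastic model of subclonal tumor growth.

A tumor grows on a fixed 2D square lattice from a single wild-type (WT)
cell. Cells divide stochastically; at a chosen population size a single
cell is relabeled as a mutant (MUT) subclone that divides at
``fitness_ratio`` times the WT rate. Two division mechanics are
supported:

``PUSHING``
    A dividing cell places one daughter in a uniformly chosen empty
    Moore neighbor; if none is empty, a random direction among the 8
    Moore offsets is chosen and the chain of cells along that ray is
    pushed outward by one position to open space. No cell death.

``EMPTY_ONLY``
    Cells can only divide into an empty Moore neighbor (a blocked
    attempt is a no-op), and every cell dies at a fixed rate ``delta``
    per unit time.

Event scheduling is an exact Gillespie process: each WT cell attempts
division at rate 1, each MUT cell at rate ``fitness_ratio``, and (under
``EMPTY_ONLY``) each cell dies at rate ``death_rate``. Time is measured
in units of the WT division rate.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EMPTY",
    "WT",
    "MUT",
    "Mechanics",
    "SimParams",
    "LatticeState",
    "Trajectory",
    "BoundaryOverflowError",
    "SizingError",
    "initialize",
    "step",
    "push_chain",
    "introduce_mutant",
    "run",
    "default_quadrat_side",
    "save_snapshot",
]

EMPTY: int = 0
WT: int = 1
MUT: int = 2

# Moore neighborhood, row-major (dr, dc) offsets.
_DIRS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


class Mechanics(enum.Enum):
    """Division mechanics of the growth model."""

    PUSHING = "pushing"
    EMPTY_ONLY = "empty_only"


class BoundaryOverflowError(RuntimeError):
    """A push chain reached the lattice edge: the grid is undersized."""


class SizingError(ValueError):
    """Grid side too small for the requested final population."""


@dataclass
class SimParams:
    """Parameters of a single growth realization.

    Parameters
    ----------
    fitness_ratio
        Relative division rate of the mutant subclone vs wild type
        (dimensionless, >= 1; 1 is neutral evolution).
    arise_size
        Tumor population size at which the mutant is introduced as a
        single cell; the initial mutant frequency is ``1/arise_size``.
    final_size
        Population size at which the simulation stops.
    death_rate
        Per-cell death rate delta, in units of the WT division rate.
        Only used under ``EMPTY_ONLY`` mechanics; must be 0 for
        ``PUSHING``.
    mechanics
        Division mechanics variant.
    seed
        Master seed for the realization.
    side
        Lattice side length; defaults to ``ceil(3 * sqrt(final_size))``
        so the tumor never reaches the boundary.
    """

    fitness_ratio: float = 1.0
    arise_size: int = 100
    final_size: int = 10_000
    death_rate: float = 0.0
    mechanics: Mechanics = Mechanics.PUSHING
    seed: int = 0
    side: Optional[int] = None
    allow_small_grid: bool = False

    def resolved_side(self) -> int:
        if self.side is not None:
            return int(self.side)
        return int(np.ceil(3.0 * np.sqrt(self.final_size)))

    def validate(self) -> None:
        if self.fitness_ratio < 1.0:
            raise ValueError(f"fitness_ratio must be >= 1, got {self.fitness_ratio}")
        if not 2 <= self.arise_size < self.final_size:
            raise ValueError(
                f"need 2 <= arise_size < final_size, got "
                f"arise_size={self.arise_size}, final_size={self.final_size}"
            )
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if self.mechanics is Mechanics.PUSHING and self.death_rate != 0:
            raise ValueError("death_rate must be 0 under PUSHING mechanics")
        side = self.resolved_side()
        min_side = int(np.ceil(3.0 * np.sqrt(self.final_size)))
        if side < min_side and not self.allow_small_grid:
            raise SizingError(
                f"side={side} below 3*sqrt(final_size)={min_side}; pushing "
                "chains may hit the edge (set allow_small_grid=True to override)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mechanics"] = self.mechanics.value
        d["side"] = self.resolved_side()
        return d


class LatticeState:
    """Occupancy grid plus O(1) sampling structures.

    Attributes
    ----------
    grid : ndarray of int8, shape (side, side)
        Cell labels (0=EMPTY, 1=WT, 2=MUT).
    n_wt, n_mut : int
        Population counts; always equal to the number of non-empty
        grid positions of each label.
    t : float
        Elapsed time in units of the WT division rate.
    """

    __slots__ = (
        "grid",
        "side",
        "n_wt",
        "n_mut",
        "t",
        "extinct",
        "mutant_introduced",
        "_flat",
        "_pos_wt",
        "_pos_mut",
        "_slot",
        "_offs",
    )

    def __init__(self, side: int, capacity: int):
        self.side = int(side)
        self.grid = np.zeros((side, side), dtype=np.int8)
        self._flat = self.grid.reshape(-1)
        cap = int(capacity) + 16
        self._pos_wt = np.empty(cap, dtype=np.int64)
        self._pos_mut = np.empty(cap, dtype=np.int64)
        self._slot = np.zeros(side * side, dtype=np.int64)
        self._offs = _DIRS[:, 0] * side + _DIRS[:, 1]
        self.n_wt = 0
        self.n_mut = 0
        self.t = 0.0
        self.extinct = False
        self.mutant_introduced = False

    # -- bookkeeping -------------------------------------------------
    @property
    def population(self) -> int:
        return self.n_wt + self.n_mut

    def mutant_frequency(self) -> float:
        n = self.population
        return self.n_mut / n if n else float("nan")

    def _add(self, label: int, p: int) -> None:
        if label == WT:
            self._pos_wt[self.n_wt] = p
            self._slot[p] = self.n_wt
            self.n_wt += 1
        else:
            self._pos_mut[self.n_mut] = p
            self._slot[p] = self.n_mut
            self.n_mut += 1
        self._flat[p] = label

    def _remove(self, p: int) -> None:
        label = self._flat[p]
        i = self._slot[p]
        if label == WT:
            self.n_wt -= 1
            q = self._pos_wt[self.n_wt]
            self._pos_wt[i] = q
        else:
            self.n_mut -= 1
            q = self._pos_mut[self.n_mut]
            self._pos_mut[i] = q
        self._slot[q] = i
        self._flat[p] = EMPTY

    def _relabel(self, p: int, new_label: int) -> None:
        self._remove(p)
        self._add(new_label, p)

    def occupied_positions(self) -> np.ndarray:
        """Flat indices of all occupied sites (WT first, then MUT)."""
        return np.concatenate(
            (self._pos_wt[: self.n_wt], self._pos_mut[: self.n_mut])
        )

    def copy_grid(self) -> np.ndarray:
        return self.grid.copy()

    @classmethod
    def from_grid(cls, grid: np.ndarray) -> "LatticeState":
        """Build a state (with sampling structures) from a label grid."""
        grid = np.asarray(grid)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ValueError("grid must be square 2D")
        st = cls(grid.shape[0], int((grid > 0).sum()))
        for p in np.flatnonzero(grid.reshape(-1)):
            st._add(int(grid.reshape(-1)[p]), int(p))
        return st


def initialize(params: SimParams) -> LatticeState:
    """Seed the lattice with a single WT cell at the grid center."""
    params.validate()
    side = params.resolved_side()
    state = LatticeState(side, params.final_size)
    center = (side // 2) * side + side // 2
    state._add(WT, center)
    return state


def push_chain(state: LatticeState, origin: tuple, direction: tuple) -> LatticeState:
    """Push the chain of cells along ``direction`` from ``origin``.

    Every cell strictly between ``origin`` (exclusive) and the first
    empty site along the ray is translated one position outward, so the
    site adjacent to ``origin`` becomes empty. Clone labels travel with
    their cells; the total cell count is unchanged.

    Raises
    ------
    BoundaryOverflowError
        If no empty site exists before the lattice edge.
    """
    side = state.side
    r, c = origin
    p = r * side + c
    if state._flat[p] == EMPTY:
        raise ValueError(f"origin {origin!r} is empty")
    dr, dc = direction
    if (dr, dc) not in {tuple(d) for d in _DIRS}:
        raise ValueError(f"direction must be one of the 8 Moore offsets, got {direction!r}")
    k = int(np.nonzero((_DIRS[:, 0] == dr) & (_DIRS[:, 1] == dc))[0][0])
    _push(state, p, k)
    return state


def _ray_length(state: LatticeState, p: int, k: int) -> int:
    side = state.side
    r, c = divmod(p, side)
    dr, dc = _DIRS[k]
    lr = (r if dr < 0 else side - 1 - r) if dr != 0 else side
    lc = (c if dc < 0 else side - 1 - c) if dc != 0 else side
    return min(lr, lc)


def _push(state: LatticeState, p: int, k: int) -> None:
    """Shift the occupied chain from flat index ``p`` along direction k.

    Post: the site ``p + off_k`` is EMPTY and ready for a daughter.
    """
    L = _ray_length(state, p, k)
    off = int(state._offs[k])
    if L == 0:
        raise BoundaryOverflowError("origin is on the lattice edge")
    ray = p + off * np.arange(1, L + 1, dtype=np.int64)
    vals = state._flat[ray]
    zeros = vals == EMPTY
    j = int(np.argmax(zeros))
    if not zeros[j]:
        raise BoundaryOverflowError(
            "push chain reached the lattice edge; grid is undersized"
        )
    if j > 0:
        old = ray[:j]
        new = ray[1 : j + 1]
        labs = vals[:j]
        idx = state._slot[old]
        wt = labs == WT
        if wt.any():
            state._pos_wt[idx[wt]] = new[wt]
        if (~wt).any():
            state._pos_mut[idx[~wt]] = new[~wt]
        state._slot[new] = idx
        state._flat[new] = labs
        state._flat[ray[0]] = EMPTY


def introduce_mutant(state: LatticeState, rng: np.random.Generator) -> LatticeState:
    """Relabel one uniformly chosen occupied cell WT -> MUT.

    The initial mutant frequency is therefore 1/population.
    """
    if state.n_mut > 0 or state.mutant_introduced:
        raise RuntimeError("mutant already introduced")
    if state.n_wt == 0:
        raise RuntimeError("no cells to mutate")
    i = int(rng.integers(state.n_wt))
    p = int(state._pos_wt[i])
    state._relabel(p, MUT)
    state.mutant_introduced = True
    return state


def _daughter_site(state: LatticeState, parent: int, rng: np.random.Generator):
    """Uniformly chosen empty Moore neighbor of ``parent``, or None."""
    nbrs = parent + state._offs
    vals = state._flat[nbrs]
    empties = np.flatnonzero(vals == EMPTY)
    if empties.size == 0:
        return None
    return int(nbrs[empties[rng.integers(empties.size)]])


def _check_interior(state: LatticeState, p: int) -> None:
    side = state.side
    r, c = divmod(int(p), side)
    if r == 0 or c == 0 or r == side - 1 or c == side - 1:
        raise BoundaryOverflowError("cell placed on the lattice border ring")


def step(state: LatticeState, params: SimParams, rng: np.random.Generator) -> LatticeState:
    """Execute one Gillespie event in place and return the state.

    Event rates: each WT cell divides at rate 1, each MUT cell at rate
    ``fitness_ratio``; under EMPTY_ONLY every cell additionally dies at
    rate ``death_rate``. Exactly one event fires; the elapsed time
    advances by an exponential waiting time with the total rate.
    Blocked EMPTY_ONLY divisions consume the waiting time but leave the
    grid unchanged.
    """
    n_wt, n_mut = state.n_wt, state.n_mut
    if n_wt + n_mut == 0:
        raise RuntimeError("cannot step an empty lattice")
    rate_wt = float(n_wt)
    rate_mut = params.fitness_ratio * n_mut
    pushing = params.mechanics is Mechanics.PUSHING
    rate_death = 0.0 if pushing else params.death_rate * (n_wt + n_mut)
    total = rate_wt + rate_mut + rate_death
    state.t += rng.exponential() / total
    u = rng.random() * total

    if u < rate_wt + rate_mut:
        # division
        if u < rate_wt:
            label, parent = WT, int(state._pos_wt[rng.integers(n_wt)])
        else:
            label, parent = MUT, int(state._pos_mut[rng.integers(n_mut)])
        site = _daughter_site(state, parent, rng)
        if site is not None:
            _check_interior(state, site)
            state._add(label, site)
        elif pushing:
            k = int(rng.integers(8))
            _push(state, parent, k)
            site = parent + int(state._offs[k])
            _check_interior(state, site)
            state._add(label, site)
        # else: blocked EMPTY_ONLY attempt, no-op
    else:
        # death (EMPTY_ONLY only)
        v = u - rate_wt - rate_mut
        if v < params.death_rate * n_wt:
            victim = int(state._pos_wt[rng.integers(n_wt)])
        else:
            victim = int(state._pos_mut[rng.integers(n_mut)])
        state._remove(victim)
        if state.population == 0:
            state.extinct = True
    return state


@dataclass
class Trajectory:
    """Time course of (population size, mutant frequency, mixing score).

    Records are taken the first time the population reaches each
    checkpoint size. ``extinct`` flags realizations that died out
    before reaching the final size (EMPTY_ONLY only).
    """

    records: list = field(default_factory=list)
    quadrat_side: int = 0
    extinct: bool = False

    def append(self, size: int, t: float, frequency: float, mixing: float) -> None:
        self.records.append((size, t, frequency, mixing))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.records,
            columns=["checkpoint_size", "time", "mutant_frequency", "mixing_score"],
        )


def default_quadrat_side(final_size: int) -> int:
    """Quadrat side so the occupied bounding box holds ~100 quadrats.

    Matches the empirical quadrat counts used for annotated sections
    (about 96 per case on average).
    """
    return max(2, int(round(np.sqrt(final_size / 100.0))))


def _mixing_score(state: LatticeState, quadrat_side: int) -> float:
    from .metrics import CloneMap, QuadratSpec, shannon_entropy

    return shannon_entropy(
        CloneMap(state.grid), QuadratSpec(quadrat_side=quadrat_side)
    )


def run(
    params: SimParams,
    checkpoints: Optional[Sequence[int]] = None,
    quadrat_side: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LatticeState, Trajectory]:
    """Grow a tumor from one cell to ``final_size``, introducing the
    mutant the first time the population reaches ``arise_size``.

    Parameters
    ----------
    checkpoints
        Population sizes at which (size, time, mutant frequency,
        mixing score) are recorded. The final size is always recorded.
    quadrat_side
        Quadrat side for the mixing score; defaults to
        :func:`default_quadrat_side` of the final size, fixed for the
        whole run.
    rng
        Optional generator overriding ``params.seed`` (used by sweeps
        and ABC for independent per-draw streams).

    Returns
    -------
    (state, trajectory)
        Final lattice state and the recorded trajectory. Extinction
        before ``final_size`` (possible under EMPTY_ONLY) is flagged on
        both, not raised.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = initialize(params)
    qside = quadrat_side if quadrat_side is not None else default_quadrat_side(params.final_size)
    ckpts = sorted(set(int(c) for c in (checkpoints or [])) | {params.final_size})
    traj = Trajectory(quadrat_side=qside)
    next_i = 0
    # skip checkpoints below the starting population
    while next_i < len(ckpts) and ckpts[next_i] < state.population:
        next_i += 1
    while state.population < params.final_size:
        step(state, params, rng)
        n = state.population
        if n == 0:
            state.extinct = True
            traj.extinct = True
            break
        if not state.mutant_introduced and n >= params.arise_size:
            introduce_mutant(state, rng)
        while next_i < len(ckpts) and n >= ckpts[next_i]:
            traj.append(n, state.t, state.mutant_frequency(), _mixing_score(state, qside))
            next_i += 1
    return state, traj


def save_snapshot(state: LatticeState, params: SimParams, path) -> None:
    """Write the label grid as delimited integers plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, state.grid, fmt="%d", delimiter=" ")
    meta = {
        "params": params.to_dict(),
        "t": state.t,
        "n_wt": int(state.n_wt),
        "n_mut": int(state.n_mut),
        "extinct": bool(state.extinct),
        "labels": {"EMPTY": EMPTY, "WT": WT, "MUT": MUT},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
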