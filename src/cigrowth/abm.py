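"""On-lattice birth-death-migration simulator with contact inhibition.

Each cell occupies one site of a 2-d lattice (periodic or closed boundary).
Per time step, the cells existing at the start of the step are visited in
uniformly shuffled order; each cell

1. migrates with probability ``min(m*dt, 1)`` to a uniformly chosen empty
   site of its migration neighborhood (if any is empty),
2. divides with probability ``min(lam*dt, 1)``, placing the daughter on a
   uniformly chosen empty site of its birth neighborhood (if any is empty);
   a cell that migrated may still divide in the same step,
3. if no daughter was placed, dies with probability ``min(delta*dt, 1)``.

Cells born during a step do not act until the next step.  All randomness
comes from a single seeded generator consumed in a documented order
(shuffle, then per cell: migration draw, migration site, birth draw, birth
site, death draw), so identical seeds give bit-identical trajectories.

The per-step estimator of the blocked probability E[P(omega|n)] is the
fraction of cells whose entire birth neighborhood is occupied
(:func:`blocked_fraction`); the surface-cell count and the fractal-dimension
estimator D_hat = d*ln(n_s)/ln(n) quantify boundary geometry in the
low-migration regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "NEIGHBORHOOD_KINDS",
    "NeighborhoodSpec",
    "ABMParams",
    "LatticeState",
    "Trajectory",
    "neighborhood_offsets",
    "run_abm",
    "blocked_fraction",
    "surface_cell_count",
    "fractal_dimension_estimate",
    "ensemble_summary",
]

NEIGHBORHOOD_KINDS = (
    "von_neumann",
    "moore",
    "von_neumann2",
    "moore2",
    "full_domain",
    "custom",
)


def _kind_offsets(kind: str) -> list[tuple[int, int]]:
    if kind == "von_neumann":
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if kind == "moore":
        return [
            (dr, dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    if kind == "von_neumann2":
        return [
            (dr, dc)
            for dr in range(-2, 3)
            for dc in range(-2, 3)
            if (dr, dc) != (0, 0) and abs(dr) + abs(dc) <= 2
        ]
    if kind == "moore2":
        return [
            (dr, dc)
            for dr in range(-2, 3)
            for dc in range(-2, 3)
            if (dr, dc) != (0, 0)
        ]
    raise ValueError(f"unknown neighborhood kind {kind!r}")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A named or custom set of (row, col) offsets defining a neighborhood.

    Named kinds: ``von_neumann`` (omega=4), ``moore`` (8), ``von_neumann2``
    (12, Manhattan radius 2), ``moore2`` (24, Chebyshev radius 2),
    ``full_domain`` (every other site).  ``custom`` takes explicit offsets.
    """

    kind: str = "von_neumann"
    offsets: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in NEIGHBORHOOD_KINDS:
            raise ValueError(f"unknown neighborhood kind {self.kind!r}")
        if self.kind == "custom":
            offs = self.offsets
            if not offs:
                raise ValueError("custom neighborhood requires offsets")
            offs = tuple(tuple(int(v) for v in o) for o in offs)
            if (0, 0) in offs:
                raise ValueError("offsets must exclude (0, 0)")
            if len(set(offs)) != len(offs):
                raise ValueError("offsets must be distinct")
            object.__setattr__(self, "offsets", offs)
        elif self.kind == "full_domain":
            object.__setattr__(self, "offsets", None)
        else:
            object.__setattr__(
                self, "offsets", tuple(_kind_offsets(self.kind))
            )

    @property
    def is_full_domain(self) -> bool:
        return self.kind == "full_domain"

    @property
    def omega(self) -> int | None:
        """Neighborhood size; None for full_domain (omega = l - 1 there)."""
        return None if self.is_full_domain else len(self.offsets)

    def offset_array(self) -> np.ndarray:
        if self.is_full_domain:
            return np.zeros((0, 2), dtype=np.int64)
        return np.asarray(self.offsets, dtype=np.int64)

    @classmethod
    def from_name(cls, name: str) -> "NeighborhoodSpec":
        return cls(kind=name)


def neighborhood_offsets(spec: NeighborhoodSpec | str) -> tuple[tuple[int, int], ...]:
    """The offset set of a neighborhood spec (or named kind)."""
    if isinstance(spec, str):
        spec = NeighborhoodSpec(kind=spec)
    if spec.is_full_domain:
        raise ValueError("full_domain has no finite offset set")
    return spec.offsets


@dataclass(frozen=True)
class ABMParams:
    """Rates and neighborhoods of the step loop.

    ``lam``, ``delta`` and ``m`` are per-unit-time rates converted to
    per-step event probabilities ``min(rate*dt, 1)``; ``seed`` is mandatory.
    """

    lam: float
    delta: float = 0.0
    m: float = 0.0
    dt: float = 1.0
    birth_nbhd: NeighborhoodSpec = field(
        default_factory=lambda: NeighborhoodSpec("moore")
    )
    migration_nbhd: NeighborhoodSpec = field(
        default_factory=lambda: NeighborhoodSpec("moore")
    )
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("ABMParams requires an explicit seed")
        if min(self.lam, self.delta, self.m) < 0 or self.dt <= 0:
            raise ValueError("rates must be >= 0 and dt > 0")

    @property
    def p_birth(self) -> float:
        return min(self.lam * self.dt, 1.0)

    @property
    def p_death(self) -> float:
        return min(self.delta * self.dt, 1.0)

    @property
    def p_migrate(self) -> float:
        return min(self.m * self.dt, 1.0)


@dataclass
class LatticeState:
    """Occupancy grid A(q) in {0,1} with 0-based (row, col) coordinates."""

    occupancy: np.ndarray
    boundary: str = "periodic"
    time: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be a 2-d grid")
        if self.boundary not in ("periodic", "closed"):
            raise ValueError("boundary must be 'periodic' or 'closed'")
        if np.any(self.occupancy > 1):
            raise ValueError("occupancy values must be 0 or 1")

    @property
    def height(self) -> int:
        return self.occupancy.shape[0]

    @property
    def width(self) -> int:
        return self.occupancy.shape[1]

    @property
    def l(self) -> int:
        return self.occupancy.size

    @property
    def n(self) -> int:
        return int(self.occupancy.sum())

    @classmethod
    def single_center_cell(
        cls, width: int, height: int, boundary: str = "periodic"
    ) -> "LatticeState":
        occ = np.zeros((height, width), dtype=np.uint8)
        occ[height // 2, width // 2] = 1
        return cls(occ, boundary=boundary)

    @classmethod
    def random(
        cls,
        width: int,
        height: int,
        density: float,
        seed: int,
        boundary: str = "periodic",
    ) -> "LatticeState":
        """Exactly round(density*l) cells on uniformly random distinct sites."""
        l = width * height
        n = int(round(density * l))
        if not 0 <= n <= l:
            raise ValueError("density out of range")
        rng = np.random.default_rng(seed)
        occ = np.zeros(l, dtype=np.uint8)
        occ[rng.choice(l, size=n, replace=False)] = 1
        return cls(occ.reshape(height, width), boundary=boundary)

    @classmethod
    def full(cls, width: int, height: int, boundary: str = "periodic") -> "LatticeState":
        return cls(np.ones((height, width), dtype=np.uint8), boundary=boundary)


@dataclass
class Trajectory:
    """Per-step records of one simulation: population size, blocked-cell and
    surface-cell counts, plus optional occupancy snapshots."""

    times: np.ndarray
    n: np.ndarray
    blocked: np.ndarray
    surface: np.ndarray
    l: int
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def density(self) -> np.ndarray:
        return self.n / self.l


# --------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _occupy(r, c, grid, er, ec, eidx, n_empty):
    grid[r, c] = 1
    j = eidx[r, c]
    last = n_empty - 1
    lr = er[last]
    lc = ec[last]
    er[j] = lr
    ec[j] = lc
    eidx[lr, lc] = j
    eidx[r, c] = -1
    return n_empty - 1


@njit(cache=True)
def _vacate(r, c, grid, er, ec, eidx, n_empty):
    grid[r, c] = 0
    er[n_empty] = r
    ec[n_empty] = c
    eidx[r, c] = n_empty
    return n_empty + 1


@njit(cache=True)
def _pick_empty_neighbor(r, c, grid, off, periodic, h, w):
    cnt = 0
    for k in range(off.shape[0]):
        nr = r + off[k, 0]
        nc = c + off[k, 1]
        if periodic:
            nr %= h
            nc %= w
        elif nr < 0 or nr >= h or nc < 0 or nc >= w:
            continue
        if grid[nr, nc] == 0:
            cnt += 1
    if cnt == 0:
        return -1, -1
    t = np.random.randint(cnt)
    i = 0
    for k in range(off.shape[0]):
        nr = r + off[k, 0]
        nc = c + off[k, 1]
        if periodic:
            nr %= h
            nc %= w
        elif nr < 0 or nr >= h or nc < 0 or nc >= w:
            continue
        if grid[nr, nc] == 0:
            if i == t:
                return nr, nc
            i += 1
    return -1, -1


@njit(cache=True)
def _count_blocked(grid, rows, cols, n, off, full_dom, periodic, n_empty):
    if full_dom:
        return n if n_empty == 0 else 0
    h, w = grid.shape
    blocked = 0
    for i in range(n):
        r = rows[i]
        c = cols[i]
        full = True
        for k in range(off.shape[0]):
            nr = r + off[k, 0]
            nc = c + off[k, 1]
            if periodic:
                nr %= h
                nc %= w
            elif nr < 0 or nr >= h or nc < 0 or nc >= w:
                continue  # closed boundary: truncated neighborhood
            if grid[nr, nc] == 0:
                full = False
                break
        if full:
            blocked += 1
    return blocked


@njit(cache=True)
def _run_kernel(
    grid,
    periodic,
    p_b,
    p_d,
    p_m,
    b_off,
    b_full,
    m_off,
    m_full,
    steps,
    seed,
    snap_steps,
):
    np.random.seed(seed)
    h, w = grid.shape
    l = h * w
    cap = 2 * l + 4
    rows = np.empty(cap, np.int64)
    cols = np.empty(cap, np.int64)
    alive = np.zeros(cap, np.uint8)
    er = np.empty(l, np.int64)
    ec = np.empty(l, np.int64)
    eidx = np.full((h, w), -1, np.int64)
    n = 0
    n_empty = 0
    for r in range(h):
        for c in range(w):
            if grid[r, c]:
                rows[n] = r
                cols[n] = c
                alive[n] = 1
                n += 1
            else:
                er[n_empty] = r
                ec[n_empty] = c
                eidx[r, c] = n_empty
                n_empty += 1

    n_rec = np.empty(steps + 1, np.int64)
    blocked_rec = np.empty(steps + 1, np.int64)
    n_snap = snap_steps.shape[0]
    snaps = np.zeros((n_snap, h, w), np.uint8)

    n_rec[0] = n
    blocked_rec[0] = _count_blocked(grid, rows, cols, n, b_off, b_full, periodic, n_empty)
    si = 0
    while si < n_snap and snap_steps[si] == 0:
        snaps[si] = grid.copy()
        si += 1

    order = np.empty(cap, np.int64)
    for step in range(1, steps + 1):
        n_start = n
        for i in range(n_start):
            order[i] = i
        np.random.shuffle(order[:n_start])
        n_slots = n_start
        for k in range(n_start):
            i = order[k]
            r = rows[i]
            c = cols[i]
            # 1. migration
            if p_m > 0.0 and np.random.random() < p_m:
                if m_full:
                    if n_empty > 0:
                        j = np.random.randint(n_empty)
                        nr = er[j]
                        nc = ec[j]
                    else:
                        nr = -1
                        nc = -1
                else:
                    nr, nc = _pick_empty_neighbor(r, c, grid, m_off, periodic, h, w)
                if nr >= 0:
                    n_empty = _occupy(nr, nc, grid, er, ec, eidx, n_empty)
                    n_empty = _vacate(r, c, grid, er, ec, eidx, n_empty)
                    rows[i] = nr
                    cols[i] = nc
                    r = nr
                    c = nc
            # 2. birth
            born = False
            if p_b > 0.0 and np.random.random() < p_b:
                if b_full:
                    if n_empty > 0:
                        j = np.random.randint(n_empty)
                        br = er[j]
                        bc = ec[j]
                    else:
                        br = -1
                        bc = -1
                else:
                    br, bc = _pick_empty_neighbor(r, c, grid, b_off, periodic, h, w)
                if br >= 0:
                    n_empty = _occupy(br, bc, grid, er, ec, eidx, n_empty)
                    rows[n_slots] = br
                    cols[n_slots] = bc
                    alive[n_slots] = 1
                    n_slots += 1
                    n += 1
                    born = True
            # 3. death only when no daughter was placed this step
            if (not born) and p_d > 0.0 and np.random.random() < p_d:
                alive[i] = 0
                n_empty = _vacate(r, c, grid, er, ec, eidx, n_empty)
                n -= 1
        # compact live cells to the front
        m2 = 0
        for i in range(n_slots):
            if alive[i]:
                rows[m2] = rows[i]
                cols[m2] = cols[i]
                m2 += 1
        for i in range(m2, n_slots):
            alive[i] = 0
        for i in range(m2):
            alive[i] = 1
        n_rec[step] = n
        blocked_rec[step] = _count_blocked(
            grid, rows, cols, n, b_off, b_full, periodic, n_empty
        )
        while si < n_snap and snap_steps[si] == step:
            snaps[si] = grid.copy()
            si += 1
    return n_rec, blocked_rec, snaps


# --------------------------------------------------------------------------
# public API


def run_abm(
    width: int,
    height: int,
    params: ABMParams,
    init: LatticeState | str = "single_center_cell",
    horizon: int = 100,
    boundary: str = "periodic",
    snapshot_steps: Sequence[int] = (),
) -> Trajectory:
    """Run the birth-death-migration step loop for ``horizon`` steps.

    ``init`` may be a :class:`LatticeState` (its boundary wins) or the string
    ``"single_center_cell"``.  Records (time, n, blocked, surface) at every
    step including step 0; snapshots of the occupancy grid are stored for the
    requested step indices.
    """
    if horizon <= 0:
        raise ValueError("horizon must be a positive number of steps")
    if isinstance(init, str):
        if init != "single_center_cell":
            raise ValueError(f"unknown init {init!r}")
        state = LatticeState.single_center_cell(width, height, boundary=boundary)
    else:
        state = init
        if (state.height, state.width) != (height, width):
            raise ValueError("init grid shape does not match width/height")
    snap_steps = np.asarray(sorted(set(int(s) for s in snapshot_steps)), dtype=np.int64)
    if snap_steps.size and (snap_steps[0] < 0 or snap_steps[-1] > horizon):
        raise ValueError("snapshot steps must lie in [0, horizon]")
    grid = state.occupancy.copy()
    n_rec, blocked_rec, snaps = _run_kernel(
        grid,
        state.boundary == "periodic",
        params.p_birth,
        params.p_death,
        params.p_migrate,
        params.birth_nbhd.offset_array(),
        params.birth_nbhd.is_full_domain,
        params.migration_nbhd.offset_array(),
        params.migration_nbhd.is_full_domain,
        int(horizon),
        int(params.seed) % (2**32),
        snap_steps,
    )
    times = np.arange(horizon + 1, dtype=float) * params.dt
    return Trajectory(
        times=times,
        n=n_rec,
        blocked=blocked_rec,
        surface=n_rec - blocked_rec,
        l=width * height,
        snapshots={int(s): snaps[i] for i, s in enumerate(snap_steps)},
        meta={
            "width": width,
            "height": height,
            "boundary": state.boundary,
            "lam": params.lam,
            "delta": params.delta,
            "m": params.m,
            "dt": params.dt,
            "seed": int(params.seed),
            "birth_nbhd": params.birth_nbhd.kind,
            "migration_nbhd": params.migration_nbhd.kind,
        },
    )


def _blocked_mask(state: LatticeState, birth_nbhd: NeighborhoodSpec) -> np.ndarray:
    occ = state.occupancy.astype(bool)
    if birth_nbhd.is_full_domain:
        if state.n >= state.l:
            return occ.copy()
        return np.zeros_like(occ)
    full = occ.copy()
    if state.boundary == "periodic":
        for dr, dc in birth_nbhd.offsets:
            full &= np.roll(np.roll(occ, -dr, axis=0), -dc, axis=1)
    else:
        h, w = occ.shape
        for dr, dc in birth_nbhd.offsets:
            shifted = np.ones_like(occ)  # out-of-domain sites don't exist
            rs = slice(max(0, -dr), min(h, h - dr))
            cs = slice(max(0, -dc), min(w, w - dc))
            rs_src = slice(max(0, dr), min(h, h + dr))
            cs_src = slice(max(0, dc), min(w, w + dc))
            shifted[rs, cs] = occ[rs_src, cs_src]
            full &= shifted
    return full


def blocked_fraction(
    state: LatticeState,
    birth_nbhd: NeighborhoodSpec,
    normalization: str = "per_cell",
) -> float:
    """Fraction of cells whose entire birth neighborhood is occupied.

    ``per_cell`` divides the blocked-cell count by n (the estimator of the
    expected blocked probability E[P(omega|n)] that enters the mean-field
    law); ``per_lattice`` divides by the lattice size l instead.
    """
    blocked = int(_blocked_mask(state, birth_nbhd).sum())
    if normalization == "per_cell":
        if state.n == 0:
            raise ValueError("per_cell normalization undefined on an empty lattice")
        return blocked / state.n
    if normalization == "per_lattice":
        return blocked / state.l
    raise ValueError(f"unknown normalization {normalization!r}")


def surface_cell_count(state: LatticeState, birth_nbhd: NeighborhoodSpec) -> int:
    """Number of cells with at least one empty birth-neighborhood site;
    equals n minus the blocked-cell count."""
    return state.n - int(_blocked_mask(state, birth_nbhd).sum())


def fractal_dimension_estimate(n, n_s, d: int = 2):
    """Fractal-dimension estimator D_hat = d*ln(n_s)/ln(n) from the surface
    scaling n_s ~ n**(D/d).  Vectorized; requires n > 1 and n_s >= 1."""
    n = np.asarray(n, dtype=float)
    n_s = np.asarray(n_s, dtype=float)
    if np.any(n <= 1):
        raise ValueError("fractal dimension undefined for n <= 1")
    if np.any(n_s < 1):
        raise ValueError("need at least one surface cell")
    out = d * np.log(n_s) / np.log(n)
    return out if out.ndim else float(out)


def ensemble_summary(trajectories: Iterable[Trajectory]):
    """Pointwise mean and sample SD of n(t) across replicate trajectories on
    a common time grid.  Returns (times, mean, sd)."""
    trajs = list(trajectories)
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories")
    times = trajs[0].times
    for tr in trajs[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError("trajectories must share a common time grid")
    mat = np.vstack([tr.n for tr in trajs]).astype(float)
    return times, mat.mean(axis=0), mat.std(axis=0, ddof=1)
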