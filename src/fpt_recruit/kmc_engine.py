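"""Lattice kinetic Monte Carlo simulator of protein diffusion to the nucleus.

A single walker per replica performs an unbiased nearest-neighbour random
walk on a 3D lattice inside a reflecting rectangular box; each step moves
one lattice unit along one axis (all six moves with probability 1/6) and
advances the clock by the diffusive step time Δt = L²/(6D).  A step that
would leave the box, or carry the site center beyond the reflecting cell
membrane (the sphere of radius R about the box center), is rejected and
the walker stays in place for that step — the box is only the lattice
extent, the sphere is the physical membrane of the cell model.
The walk terminates when the walker's site center falls inside the
absorbing nucleus sphere (Euclidean distance to the box center ≤ ra), and
the first-passage time is the number of completed steps times Δt; runs
exceeding the horizon are censored at the horizon.

Replica seeds derive deterministically from ``SeedSequence([base_seed,
replica_index])`` so ensembles are bit-reproducible; the inner loop is a
numba kernel consuming direction streams pre-drawn from numpy Generators,
keeping reproducibility independent of the JIT runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cell_model import (CellGeometry, LatticeSpec, ProteinSpec,
                         TruncatedGaussian, start_distribution)

__all__ = [
    "WalkerState",
    "FPTEnsemble",
    "init_walker",
    "step",
    "run_replica",
    "run_ensemble",
]

_DIR_VECS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

#: directions drawn per kernel invocation
_CHUNK = 1 << 19


@dataclass
class WalkerState:
    """Position (integer lattice indices), step counter and absorption flag."""

    position: np.ndarray  # int64[3]
    elapsed_steps: int = 0
    absorbed: bool = False

    def copy(self) -> "WalkerState":
        return WalkerState(self.position.copy(), self.elapsed_steps,
                           self.absorbed)


@dataclass
class FPTEnsemble:
    """Replicate first-passage times with censoring flags and provenance."""

    times: np.ndarray  # seconds
    censored: np.ndarray  # bool
    n_replicas: int
    base_seed: int
    horizon: float
    protein: ProteinSpec | None = None
    lattice: LatticeSpec | None = None
    geometry: CellGeometry | None = None
    r0: float | None = None
    start_mode: str = "fixed"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if len(self.times) != self.n_replicas or len(self.censored) != self.n_replicas:
            raise ValueError("times/censored length must equal n_replicas")
        if np.any(self.times[~self.censored] > self.horizon + 1e-12):
            raise ValueError("uncensored times must not exceed the horizon")

    @property
    def uncensored_times(self) -> np.ndarray:
        return self.times[~self.censored]

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())


def _site_radius2(pos: np.ndarray, lattice: LatticeSpec) -> float:
    """Squared distance (μm²) of a site center from the nucleus center."""
    cx, cy, cz = lattice.nucleus_center
    dx = (pos[0] + 0.5) * lattice.unit_x - cx
    dy = (pos[1] + 0.5) * lattice.unit_y - cy
    dz = (pos[2] + 0.5) * lattice.unit_z - cz
    return dx * dx + dy * dy + dz * dz


def init_walker(r0: float, lattice: LatticeSpec, rng: np.random.Generator,
                geometry: CellGeometry | None = None) -> WalkerState:
    """Place a walker at the lattice site nearest a uniform point on the
    r0 sphere about the nucleus center.

    The realized radius deviates from r0 by at most one lattice diagonal.
    """
    geometry = geometry or CellGeometry()
    half = min(lattice.nucleus_center)
    if not geometry.nucleus_radius_ra < r0:
        raise ValueError(f"r0={r0} must exceed the nucleus radius")
    if r0 >= half:
        raise ValueError(f"r0={r0} sphere exits the box (half-extent {half})")
    # uniform point on the sphere
    v = rng.normal(size=3)
    v *= r0 / np.linalg.norm(v)
    cx, cy, cz = lattice.nucleus_center
    units = (lattice.unit_x, lattice.unit_y, lattice.unit_z)
    pos = np.array(
        [int(np.floor((c + dv) / u)) for c, dv, u in zip((cx, cy, cz), v, units)],
        dtype=np.int64,
    )
    pos[0] = min(max(pos[0], 0), lattice.n_x - 1)
    pos[1] = min(max(pos[1], 0), lattice.n_y - 1)
    pos[2] = min(max(pos[2], 0), lattice.n_z - 1)
    absorbed = _site_radius2(pos, lattice) <= geometry.nucleus_radius_ra**2
    return WalkerState(pos, elapsed_steps=0, absorbed=absorbed)


def step(state: WalkerState, lattice: LatticeSpec, rng: np.random.Generator,
         geometry: CellGeometry | None = None) -> WalkerState:
    """One kMC move: a single-axis unit step, reflected (reject-and-stay)
    at the box walls and, when ``geometry`` is given, at the membrane
    sphere of radius R.  Reference implementation of the kernel rule."""
    if state.absorbed:
        raise RuntimeError("cannot step an absorbed walker")
    d = int(rng.integers(0, 6))
    return _apply_move(state, lattice, d, geometry)


def _apply_move(state: WalkerState, lattice: LatticeSpec, d: int,
                geometry: CellGeometry | None = None) -> WalkerState:
    new = state.position + _DIR_VECS[d]
    bounds = (lattice.n_x, lattice.n_y, lattice.n_z)
    inside = all(0 <= new[i] < bounds[i] for i in range(3))
    if inside and geometry is not None:
        inside = _site_radius2(new, lattice) <= geometry.outer_radius_R**2
    pos = new if inside else state.position.copy()
    absorbed = state.absorbed
    if inside and geometry is not None:
        absorbed = _site_radius2(new, lattice) <= geometry.nucleus_radius_ra**2
    return WalkerState(pos, state.elapsed_steps + 1, absorbed)


@njit(cache=False)
def _walk_kernel(pos, dirs, ux, uy, uz, cx, cy, cz, ra2, R2,
                 nx, ny, nz, max_steps, steps_done):
    """Advance a walker through a pre-drawn direction stream.

    A proposed move is rejected (walker stays put, clock still advances)
    if it leaves the lattice box or carries the site center beyond the
    reflecting membrane sphere (squared radius R2 about (cx, cy, cz)).
    Returns (steps_used_from_stream, status): status 1 = absorbed,
    2 = horizon reached, 0 = stream exhausted (caller refills).
    """
    x, y, z = pos[0], pos[1], pos[2]
    n = dirs.shape[0]
    total = steps_done
    for i in range(n):
        if total >= max_steps:
            pos[0], pos[1], pos[2] = x, y, z
            return i, 2
        d = dirs[i]
        tx, ty, tz = x, y, z
        if d == 0:
            tx += 1
        elif d == 1:
            tx -= 1
        elif d == 2:
            ty += 1
        elif d == 3:
            ty -= 1
        elif d == 4:
            tz += 1
        else:
            tz -= 1
        if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
            dx = (tx + 0.5) * ux - cx
            dy = (ty + 0.5) * uy - cy
            dz = (tz + 0.5) * uz - cz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 <= R2:
                x, y, z = tx, ty, tz
                total += 1
                if r2 <= ra2:
                    pos[0], pos[1], pos[2] = x, y, z
                    return i + 1, 1
                continue
        total += 1
    pos[0], pos[1], pos[2] = x, y, z
    return n, 0


def _replica_rng(base_seed: int, replica_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), int(replica_index)]))


def run_replica(protein: ProteinSpec, lattice: LatticeSpec,
                geometry: CellGeometry, horizon: float, seed,
                r0: float | None = None) -> tuple[float, bool]:
    """Simulate one walker until absorption or the time horizon.

    ``seed`` is either an integer or an already-constructed Generator;
    ``r0`` defaults to the protein's mean starting radius.  Returns
    (first-passage time in seconds, censored flag); censored replicas
    carry the horizon as their time.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    r0 = protein.start_mean_r0 if r0 is None else r0
    state = init_walker(r0, lattice, rng, geometry)
    if state.absorbed:
        return 0.0, False
    dt = lattice.step_time_dt
    max_steps = int(np.ceil(horizon / dt))
    ra2 = geometry.nucleus_radius_ra**2
    R2 = geometry.outer_radius_R**2
    cx, cy, cz = lattice.nucleus_center
    pos = state.position
    steps_done = 0
    while True:
        dirs = rng.integers(0, 6, size=min(_CHUNK, max_steps - steps_done + 1),
                            dtype=np.int64)
        used, status = _walk_kernel(
            pos, dirs, lattice.unit_x, lattice.unit_y, lattice.unit_z,
            cx, cy, cz, ra2, R2, lattice.n_x, lattice.n_y, lattice.n_z,
            max_steps, steps_done)
        steps_done += used
        if status == 1:
            return steps_done * dt, False
        if status == 2 or steps_done >= max_steps:
            return horizon, True


def run_ensemble(protein: ProteinSpec, lattice: LatticeSpec,
                 geometry: CellGeometry, n_replicas: int, horizon: float,
                 base_seed: int, start_mode: str = "fixed",
                 r0: float | None = None,
                 start_dist: TruncatedGaussian | None = None) -> FPTEnsemble:
    """Independent replicas, one particle each (no concentration gradient).

    ``start_mode='fixed'`` places every walker on the same r0 sphere
    (default: the protein's mean starting radius); ``start_mode='sampled'``
    draws each replica's r0 from the truncated-Gaussian starting
    distribution.  Replica i uses the Generator seeded from
    SeedSequence([base_seed, i]).
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if start_mode not in ("fixed", "sampled"):
        raise ValueError(f"unknown start_mode {start_mode!r}")
    times = np.empty(n_replicas)
    censored = np.empty(n_replicas, dtype=bool)
    dist = start_dist or start_distribution(protein)
    fixed_r0 = protein.start_mean_r0 if r0 is None else r0
    for i in range(n_replicas):
        rng = _replica_rng(base_seed, i)
        ri = float(dist.rvs(1, rng)[0]) if start_mode == "sampled" else fixed_r0
        times[i], censored[i] = run_replica(protein, lattice, geometry,
                                            horizon, rng, r0=ri)
    return FPTEnsemble(times, censored, n_replicas, base_seed, horizon,
                       protein=protein, lattice=lattice, geometry=geometry,
                       r0=None if start_mode == "sampled" else fixed_r0,
                       start_mode=start_mode)


def msd_probe(lattice: LatticeSpec, n_steps: int, n_walkers: int,
              base_seed: int) -> float:
    """Mean squared displacement (μm²) after n_steps with absorption off.

    Validates the diffusive clock: MSD ≈ n_steps · L² away from the walls.
    """
    msd = 0.0
    center = np.array([lattice.n_x // 2, lattice.n_y // 2, lattice.n_z // 2],
                      dtype=np.int64)
    units2 = np.array([lattice.unit_x, lattice.unit_y, lattice.unit_z]) ** 2
    for i in range(n_walkers):
        rng = _replica_rng(base_seed, i)
        pos = center.copy()
        dirs = rng.integers(0, 6, size=n_steps, dtype=np.int64)
        _walk_kernel(pos, dirs, lattice.unit_x, lattice.unit_y,
                     lattice.unit_z, -1e9, -1e9, -1e9, -1.0, 1e30,
                     lattice.n_x, lattice.n_y, lattice.n_z,
                     n_steps + 1, 0)
        msd += float(((pos - center) ** 2 * units2).sum())
    return msd / n_walkers
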