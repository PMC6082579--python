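"""Geometry and physical parameters of the concentric-sphere cell model.

The cell is modelled as two concentric spheres: a reflecting outer membrane
of radius ``R`` and an absorbing nucleus of radius ``r_a`` (nuclear pore
complexes treated as a uniformly permeable surface).  Proteins are Brownian
particles released at a radius ``r0`` in between.  This module holds the
parameter containers and the elementary diffusion time-scale relation

    dt = <L^2> / (6 D)

used both for the kinetic Monte Carlo clock and for the upper validity time
of the short-time (fast-diffusion) asymptotics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "CellGeometry",
    "ProteinSpec",
    "LatticeSpec",
    "NBS1",
    "MRE11",
    "step_time",
    "fast_regime_bound",
    "make_lattice",
    "lattice_preset",
]

#: micrometres per nanometre
NM = 1e-3


@dataclass(frozen=True)
class CellGeometry:
    """Concentric-sphere cell: reflecting outer membrane, absorbing nucleus.

    Parameters
    ----------
    outer_radius_R : float
        Cell radius in μm (reflecting boundary).
    nucleus_radius_ra : float
        Nucleus radius in μm (absorbing boundary).
    """

    outer_radius_R: float = 25.0
    nucleus_radius_ra: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.nucleus_radius_ra < self.outer_radius_R:
            raise ValueError(
                f"need 0 < ra < R, got ra={self.nucleus_radius_ra}, "
                f"R={self.outer_radius_R}"
            )


@dataclass(frozen=True)
class ProteinSpec:
    """A diffusing species and its starting-radius distribution.

    The starting radius is modelled as a Gaussian with mean
    ``start_mean_r0`` truncated to [``start_lower``, ``start_upper``]
    (the stated range endpoints sit 3σ from the mean, σ = 1 μm).
    """

    name: str
    diffusion_D: float  # μm²/s
    start_mean_r0: float  # μm
    start_lower: float  # μm
    start_upper: float  # μm

    def __post_init__(self) -> None:
        if self.diffusion_D <= 0:
            raise ValueError(f"diffusion_D must be > 0, got {self.diffusion_D}")
        if not self.start_lower <= self.start_mean_r0 <= self.start_upper:
            raise ValueError(
                "need start_lower <= start_mean_r0 <= start_upper, got "
                f"{self.start_lower}, {self.start_mean_r0}, {self.start_upper}"
            )

    def validate_against(self, geometry: CellGeometry) -> None:
        """Check the start range lies strictly inside the diffusion shell."""
        if not geometry.nucleus_radius_ra < self.start_lower:
            raise ValueError("start range must lie outside the nucleus")
        if not self.start_upper < geometry.outer_radius_R:
            raise ValueError("start range must lie inside the cell membrane")

    @property
    def start_sigma(self) -> float:
        """σ of the truncated Gaussian; the range spans mean ± 3σ."""
        return (self.start_upper - self.start_lower) / 6.0


@dataclass(frozen=True)
class TruncatedGaussian:
    """Gaussian over the starting radius truncated to [lower, upper] (μm).

    ``sigma == 0`` degenerates to a point mass at ``mean``.
    """

    mean: float
    sigma: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.lower <= self.mean <= self.upper:
            raise ValueError("need lower <= mean <= upper")

    @property
    def is_point_mass(self) -> bool:
        return self.sigma == 0.0 or self.lower == self.upper

    def frozen(self):
        """The scipy frozen distribution (undefined for a point mass)."""
        from scipy import stats

        a = (self.lower - self.mean) / self.sigma
        b = (self.upper - self.mean) / self.sigma
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sigma)

    def grid_weights(self, r0_grid) -> "tuple":
        """Normalized quadrature weights of the pdf on a node grid."""
        import numpy as np

        r0_grid = np.asarray(r0_grid, dtype=float)
        if r0_grid.ndim != 1 or r0_grid.size == 0:
            raise ValueError("r0_grid must be a non-empty 1-d sequence")
        if self.is_point_mass:
            w = np.zeros_like(r0_grid)
            w[np.argmin(np.abs(r0_grid - self.mean))] = 1.0
            return r0_grid, w
        w = self.frozen().pdf(r0_grid)
        total = w.sum()
        if total <= 0:
            raise ValueError("distribution has no mass on the given grid")
        return r0_grid, w / total

    def rvs(self, n: int, rng) -> "object":
        import numpy as np

        if self.is_point_mass:
            return np.full(n, self.mean)
        return self.frozen().rvs(size=n, random_state=rng)


def start_distribution(protein: ProteinSpec) -> TruncatedGaussian:
    """The protein's truncated-Gaussian starting-radius distribution."""
    return TruncatedGaussian(protein.start_mean_r0, protein.start_sigma,
                             protein.start_lower, protein.start_upper)


#: Table-1 defaults for the two MRN subunits studied.
NBS1 = ProteinSpec("NBS1", diffusion_D=2.5, start_mean_r0=17.0,
                   start_lower=14.0, start_upper=20.0)
MRE11 = ProteinSpec("MRE11", diffusion_D=2.0, start_mean_r0=14.0,
                    start_lower=11.0, start_upper=17.0)


@dataclass(frozen=True)
class LatticeSpec:
    """Kinetic Monte Carlo discretization of the cell box.

    Lengths are stored in μm.  ``step_time_dt`` is derived from the
    effective step length through ``step_time``; ``effective_step`` selects
    whether the x/y lattice constant or the RMS of the three axis lengths
    is used (the two differ only for anisotropic grids).
    """

    unit_x: float
    unit_y: float
    unit_z: float
    n_x: int
    n_y: int
    n_z: int
    diffusion_D: float
    effective_step: str = "xy"  # "xy" | "rms"
    step_time_dt: float = field(init=False)
    nucleus_center: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        if min(self.unit_x, self.unit_y, self.unit_z) <= 0:
            raise ValueError("lattice constants must be positive")
        if self.effective_step not in ("xy", "rms"):
            raise ValueError(f"unknown effective_step {self.effective_step!r}")
        object.__setattr__(
            self, "step_time_dt",
            step_time(self.effective_step_length, self.diffusion_D),
        )
        object.__setattr__(
            self, "nucleus_center",
            (self.extent_x / 2.0, self.extent_y / 2.0, self.extent_z / 2.0),
        )

    @property
    def effective_step_length(self) -> float:
        if self.effective_step == "xy":
            return self.unit_x
        return math.sqrt((self.unit_x**2 + self.unit_y**2 + self.unit_z**2) / 3.0)

    @property
    def extent_x(self) -> float:
        return self.n_x * self.unit_x

    @property
    def extent_y(self) -> float:
        return self.n_y * self.unit_y

    @property
    def extent_z(self) -> float:
        return self.n_z * self.unit_z


def step_time(step_length_L: float, diffusion_D: float) -> float:
    """Time for one diffusive step of mean-square displacement L².

    Parameters
    ----------
    step_length_L : float
        Step length in μm (use ``cell_model.NM`` to convert from nm).
    diffusion_D : float
        Diffusion coefficient in μm²/s.

    Returns
    -------
    float
        L²/(6 D) in seconds.
    """
    if diffusion_D <= 0:
        raise ValueError(f"diffusion_D must be > 0, got {diffusion_D}")
    if step_length_L < 0:
        raise ValueError(f"step_length_L must be >= 0, got {step_length_L}")
    return step_length_L**2 / (6.0 * diffusion_D)


def fast_regime_bound(r0: float, diffusion_D: float) -> float:
    """Upper time bound for the short-time (Lévy) asymptotics.

    Identifies the mean-square displacement with r0², giving r0²/(6 D):
    beyond this time the walker has typically explored the whole distance
    to the nucleus and the free-space approximation breaks down.
    """
    return step_time(r0, diffusion_D)


def make_lattice(
    geometry: CellGeometry,
    unit_lengths_um: tuple[float, float, float],
    box_extent_um: tuple[float, float, float],
    diffusion_D: float,
    effective_step: str = "xy",
) -> LatticeSpec:
    """Discretize a rectangular box enclosing the cell into a lattice.

    Unit counts are round-half-up of extent/unit; the nucleus is centered
    in the box.  Raises if the nucleus sphere does not fit.
    """
    ra = geometry.nucleus_radius_ra
    for extent in box_extent_um:
        if extent < 2.0 * ra:
            raise ValueError(
                f"box extent {extent} μm cannot contain nucleus of radius {ra} μm"
            )
    counts = tuple(
        int(math.floor(extent / unit + 0.5))
        for extent, unit in zip(box_extent_um, unit_lengths_um)
    )
    return LatticeSpec(
        unit_x=unit_lengths_um[0],
        unit_y=unit_lengths_um[1],
        unit_z=unit_lengths_um[2],
        n_x=counts[0],
        n_y=counts[1],
        n_z=counts[2],
        diffusion_D=diffusion_D,
        effective_step=effective_step,
    )


def lattice_preset(name: str, diffusion_D: float,
                   effective_step: str = "xy") -> LatticeSpec:
    """Named lattice configurations.

    ``reference``  — 1300×1300×1200 units of 38.5×38.5×37.5 nm (box 50.05×50.05×45 μm)
    ``fine``   — cubic 20 nm units in a 50×50×45 μm box
    ``coarse`` — cubic 100 nm units in a 50×50×45 μm box (test/default scale;
                 first-passage statistics at cellular radii are insensitive
                 to lattice resolution at this scale)
    """
    if name == "reference":
        return LatticeSpec(38.5 * NM, 38.5 * NM, 37.5 * NM, 1300, 1300, 1200,
                           diffusion_D, effective_step)
    if name == "fine":
        return make_lattice(CellGeometry(), (20 * NM,) * 3, (50.0, 50.0, 45.0),
                            diffusion_D, effective_step)
    if name == "coarse":
        return make_lattice(CellGeometry(), (100 * NM,) * 3, (50.0, 50.0, 45.0),
                            diffusion_D, effective_step)
    raise ValueError(f"unknown lattice preset {name!r}")


def with_diffusion(lattice: LatticeSpec, diffusion_D: float) -> LatticeSpec:
    """Same grid, different species (recomputes the step time)."""
    return replace(lattice, diffusion_D=diffusion_D)
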