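"""Observables derived from first-passage-time ensembles.

Turns replicate first-passage times into the quantities compared with
fluorescence measurements: histograms of arrival times and accumulated
recruitment-fraction curves, optionally averaged over a distribution of
starting radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_model import TruncatedGaussian
from .kmc_engine import FPTEnsemble

__all__ = [
    "RecruitmentCurve",
    "fpt_histogram",
    "accumulate",
    "average_over_start",
]

_PROVENANCES = ("analytic", "simulated", "synthetic", "observed")


def default_bins(regime: str) -> np.ndarray:
    """Histogram bin edges resolving each regime at ~10³ replicas:
    2 s bins on [0, 100] for the short-time burst, 25 s bins on [0, 1800]
    for the exponential tail."""
    if regime == "fast":
        return np.arange(0.0, 100.0 + 1.0, 2.0)
    if regime == "slow":
        return np.arange(0.0, 1800.0 + 12.5, 25.0)
    raise ValueError(f"unknown regime {regime!r}")


@dataclass
class RecruitmentCurve:
    """Fraction of proteins recruited to the nucleus versus time.

    ``provenance`` records how the curve was produced (analytic theory,
    kMC simulation, synthetic surrogate data, or an observed measurement);
    ``meta`` carries the species/start-distribution context.  Monotonicity
    is enforced for all provenances except noisy observed/synthetic data.
    """

    times: np.ndarray
    fraction: np.ndarray
    provenance: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.times.ndim != 1 or self.times.shape != self.fraction.shape:
            raise ValueError("times and fraction must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if self.provenance in ("analytic", "simulated"):
            if np.any(np.diff(self.fraction) < -1e-12):
                raise ValueError("recruitment fraction must be nondecreasing")
            if np.any(self.fraction < -1e-12) or np.any(self.fraction > 1 + 1e-12):
                raise ValueError("recruitment fraction must lie in [0, 1]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecruitmentCurve):
            return NotImplemented
        return (self.provenance == other.provenance
                and np.array_equal(self.times, other.times)
                and np.array_equal(self.fraction, other.fraction))


def fpt_histogram(ensemble: FPTEnsemble, bin_edges) -> dict:
    """Empirical first-passage-time density over time bins.

    The density is normalized so its integral equals the uncensored
    fraction of the ensemble; censored replicas never enter a bin and are
    reported separately, so histogram mass + censored fraction = 1 when
    the bins cover [0, horizon].
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a 1-d increasing sequence")
    t = ensemble.uncensored_times
    if t.size == 0:
        raise ValueError("all replicas censored: histogram is empty")
    counts, _ = np.histogram(t, bins=edges)
    widths = np.diff(edges)
    density = counts / (ensemble.n_replicas * widths)
    return {
        "edges": edges,
        "density": density,
        "counts": counts,
        "censored_fraction": ensemble.censored_fraction,
        "out_of_range_fraction": (t.size - counts.sum()) / ensemble.n_replicas,
    }


def accumulate(ensemble: FPTEnsemble, time_grid) -> RecruitmentCurve:
    """Empirical recruitment curve: fraction of replicas absorbed by t.

    Right-continuous step interpolation of the empirical CDF of the
    uncensored first-passage times onto the grid, normalized by the total
    replica count (so the plateau is 1 − censored fraction).
    """
    grid = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    t = np.sort(ensemble.uncensored_times)
    frac = np.searchsorted(t, grid, side="right") / ensemble.n_replicas
    meta = {"r0": ensemble.r0, "start_mode": ensemble.start_mode,
            "horizon": ensemble.horizon, "n_replicas": ensemble.n_replicas}
    if ensemble.protein is not None:
        meta["protein"] = ensemble.protein.name
        meta["D"] = ensemble.protein.diffusion_D
    return RecruitmentCurve(grid, frac, "simulated", meta)


def average_over_start(curves: dict[float, RecruitmentCurve],
                       distribution: TruncatedGaussian) -> RecruitmentCurve:
    """Pointwise mixture of fixed-start curves under a start distribution.

    ``curves`` maps starting radius r0 (μm) to the curve simulated or
    computed at that radius; all members must share the same time grid.
    Weights are the truncated-Gaussian pdf at the member radii, normalized
    to sum to one.
    """
    if not curves:
        raise ValueError("empty curve family")
    r0s = np.array(sorted(curves))
    ref = curves[r0s[0]]
    for r0 in r0s[1:]:
        if not np.array_equal(curves[r0].times, ref.times):
            raise ValueError(f"curve at r0={r0} is on a different time grid")
    if not distribution.is_point_mass and not (
            r0s.min() <= distribution.lower and r0s.max() >= distribution.upper - 1e-9):
        raise ValueError("curve family does not cover the distribution support")
    _, weights = distribution.grid_weights(r0s)
    frac = np.zeros_like(ref.fraction)
    for r0, w in zip(r0s, weights):
        frac += w * curves[r0].fraction
    prov = ref.provenance if ref.provenance != "observed" else "simulated"
    meta = {"mixture": {"mean": distribution.mean, "sigma": distribution.sigma,
                        "lower": distribution.lower, "upper": distribution.upper},
            "members": r0s.tolist(), "weights": weights.tolist()}
    return RecruitmentCurve(ref.times.copy(), frac, prov, meta)
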