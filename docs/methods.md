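# Methods

## Model and assumptions

A eukaryotic cell is idealized as two concentric spheres: a nucleus of
radius `ra = 5 μm` whose surface absorbs (nuclear pore complexes are
assumed dense and uniformly permeable, so any contact counts as entry)
and a cell membrane at `R = 25 μm` that reflects. MRE11 and NBS1 are
independent Brownian point particles with constant diffusion
coefficients `D_MRE11 = 2.0 μm²/s` and `D_NBS1 = 2.5 μm²/s`; crowding,
subdiffusion, active transport, and interactions between particles are
all outside the model. A protein is synthesized at radius `r0` and its
recruitment time is the first-passage time (FPT) to the nuclear surface.
Because ribosomes are distributed, ensemble observables average `r0`
over a Gaussian truncated to a stated range: NBS1 mean 17 μm on
[14, 20] μm, MRE11 mean 14 μm on [11, 17] μm. The range endpoints are
interpreted as 3σ points, giving σ = 1 μm for both species; the
truncated density is renormalized on its support.

## Analytic layer (`analytic_fpt`)

The Laplace transform of the FPT density (`laplace_flux`) is the
hyperbolic closed form quoted in the README. Numerical care:

* hyperbolics are rescaled by their dominant exponential so only
  decaying factors appear — no overflow at large λ, and the λ → 0 and
  `r0 = ra` limits are returned analytically (both raw forms are 0/0);
* complex λ is accepted (principal branch of √(λ/D), Re s ≥ 0), which
  the Talbot inversion contour requires;
* `laplace_flux_bessel` evaluates the same quantity through the
  D₋₁/₂-type combinations of modified Bessel functions I, K of orders
  −1/2 and −3/2 using exponentially scaled `scipy.special.ive/kve`.
  The two routes agree to better than 1e-10 relative over
  λ ∈ [1e-4, 1e2] and all tested `r0`; the Bessel route refuses λ = 0.

Three real-time reductions:

* `slow_rate` / `slow_pdf` / `nsd_curve`: the small-λ pole expansion
  yields an exponential tail with rate
  `k = 6 D r0 ra / |denominator polynomial|`. The polynomial is reduced
  at the default geometry by exact `Fraction` arithmetic
  (`slow_rate_polynomial`), giving coefficients 3/2, −122375/30
  (≈ −4079.17) and 46875 exactly; floats are formed only at evaluation.
  The implementation stores the positive rate; the printed form of the
  expansion carries the sign through a negative polynomial.
* `fast_pdf` / `nfd_curve`: the short-time Lévy law, with total mass
  `ra/r0` (the transient hitting probability without an outer wall) and
  mode `(r0 − ra)²/6D` — 15 s at `r0 = 20`, `D = 2.5`. The scale
  constant `(r0 − ra)²/4D` is 22.5 s at the same parameters; a published
  histogram-peak reading of 22 s coincides with the scale constant, not
  the analytic mode, and is left uninterpreted here.
* `invert_flux_numeric` / `numeric_cdf`: fixed-Talbot inversion
  (Abate–Valkó contour, M = 32 nodes, vectorized complex numpy) of the
  flux or of flux/λ (the accumulated fraction). Double-precision fixed
  Talbot is accurate to roughly 1e-8 for these smooth transforms; every
  reported density value is cross-checked against Gaver–Stehfest
  (N = 14) within an absolute-plus-relative 1e-4 guard, and an
  `mpmath`-based arbitrary-precision route is available via
  `precision=`. Inversion requires t > 0; t = 0 maps to 0 by the
  analytic limit.

Two distinct long-time scales coexist by construction: the exact mean
FPT `τ(r0) = (1/3D)[R³(1/ra − 1/r0) − (r0² − ra²)/2]` (276.5 s at
`r0 = 17`, `D = 2.5`) and the reciprocal pole-expansion rate `1/k`
(355.3 s). The expansion behind `k` Taylor-expands the two terms of the
reciprocal flux separately and does not preserve the first moment; both
quantities are exposed (`mean_fpt`, `slow_rate`) and the tail *shape*
follows `k` while the mean follows τ. Related: the Lévy density is
accurate to 1e-3 only well inside the regime bound. At `r0 = 20` the
membrane is 5 μm away and its reflection lifts the exact density ~3.6%
above the free-space asymptote already at t = 10 s (and the accumulated
mass at the 27 s bound by ~22%); mid-time work should always use the
numerical inversion, which is what the simulator is tested against.

Validity of the time-scale formula Δt = ⟨L²⟩/6D is taken as the source
of truth for every step time; the per-step values printed for the
published grids (9.88e-5 s for 38.5 nm at D = 2.5; 1.235e-4 s for
38.5 nm at D = 2.0; 3.33e-5 s for 20 nm at D = 2.0) follow from it
directly. The fast/slow labels attached to two of the published step
times do not follow from the formula with either stated grid (one value,
2.66e-4 s, matches no grid/D pairing at all); this package derives Δt
from the lattice and never from a label.

## Lattice kinetic Monte Carlo (`kmc_engine`)

Space is discretized on a rectangular lattice filling a
50 × 50 × 45 μm³ box (presets: `reference` 38.5 × 38.5 × 37.5 nm with the
conventional 1300 × 1300 × 1200 counts; `fine` cubic 20 nm; `coarse`
cubic 100 nm). Each step moves the walker one lattice unit along one
axis, all six moves with probability 1/6, and advances the clock by
Δt = L²/6D with L the x/y lattice constant by default (`rms` option for
anisotropic grids). A site is absorbing iff its *center* lies within
`ra` of the nucleus center (box center); the FPT is (completed
steps)·Δt with no sub-step interpolation.

Boundary handling is reject-and-stay: a move whose target site leaves
the box **or whose site center lies beyond the membrane sphere R** is
rejected and the walker stays put for that step (stochastically
equivalent to mirror reflection for lattice walks at this resolution,
and simpler to reason about). Reflecting at the sphere rather than at
the box walls is a deliberate design choice: the theory and every
closed-form oracle assume the spherical membrane, and a reflecting box
of 1.7× the sphere's volume would lengthen the mean FPT by ~60%,
breaking the simulation/theory correspondence the package exists to
test. The box truncates the sphere's polar caps (45 < 2R = 50 μm),
removing ~1.4% of the cell volume; the residual bias is well inside the
testing allowance.

Reproducibility: replica `i` of an ensemble uses
`numpy.random.Generator(SeedSequence([base_seed, i]))`. The jit kernel
(numba) consumes direction streams pre-drawn from that generator, so
results are bit-reproducible and independent of the JIT runtime's own
RNG; a pure-Python `step` implements the identical rule and the test
suite asserts kernel/reference equivalence on a shared direction
stream. Walkers start at the lattice site nearest a uniform point on
the `r0` sphere (realized radius within one lattice diagonal);
ensembles support fixed-`r0` and per-replica sampled starts.

Default problem sizes: validation uses the `coarse` (100 nm) lattice
with 300–500 replicas per starting radius at an 1800 s horizon. FPT
statistics at cellular radii are insensitive to lattice resolution well
below `ra`, and these sizes put the closed-form mean within ~3 standard
errors; the production-scale protocol (thousands of replicas on the
38.5/20 nm grids) is available through the same API and the `reference` /
`fine` presets.

## Observables (`recruitment_stats`)

`fpt_histogram` normalizes bin mass so the histogram integrates to the
uncensored fraction — censored replicas are never binned and are
reported separately, keeping mass + censored = 1. Default bins resolve
the two regimes at ~10³ replicas: 2 s on [0, 100] s, 25 s on
[0, 1800] s. `accumulate` is the right-continuous empirical CDF
normalized by the *total* replica count, so its plateau is
1 − censored fraction. `average_over_start` forms the convex mixture of
fixed-start curves with truncated-Gaussian weights and requires the
curve family to cover the distribution's support.

## Inference (`start_inference`)

The fitted quantity is the mean of the truncated Gaussian of starting
radii; the half-range (±3 μm) and σ (1 μm) stay fixed — with
recruitment-curve data at realistic density the width is poorly
identified and fixing it keeps the problem one-dimensional. The
criterion is ordinary least squares on the recruitment fraction over
the observed grid; the agreement standard it formalizes was originally
visual, and OLS is the minimal explicit version of it. The objective is
scanned on a grid (default 0.25 μm) rather than descended: the
simulated-mixture variant is stochastic, the domain is a short
interval, and the grid makes the convexity diagnostic trivial. Model
curves come from the Talbot-inverted accumulated flux averaged over the
candidate distribution (`analytic-mixture`, default) or from fixed-seed
kMC ensembles (`simulated-mixture`); single-start curves are cached
across candidates. Uncertainty is a residual bootstrap (B = 200)
re-minimized over the cached candidate-curve matrix.
`compare_proteins` reports the difference of fitted means and flags the
qualitative signature of interest: the faster-diffusing species fitting
a *larger* starting radius, which pure diffusion from a common
compartment cannot produce.

## Synthetic data (`synthetic_data`)

`generate_curve` emulates normalized fluorescence accumulation
measurements: the noiseless analytic-mixture curve under a known truth
distribution on a uniform grid (default 0–600 s at 5 s, comparable to
imaging time series), optional plateau normalization, additive i.i.d.
Gaussian noise per time point (default σ = 0.02 on the fraction scale),
clipped to [0, 1.05]. A ground-truth record always accompanies the
curve. What this does **not** emulate: photobleaching, background
drift, detector shot noise (which would be heteroscedastic), temporal
autocorrelation of the noise, or the distinction between arrival at the
nucleus and arrival at the damage focus itself — so recovery tests
validate the inference machinery under the model's own assumptions, not
the full measurement physics. `generate_fpt_samples` draws FPTs by
inverse-transform sampling from the Talbot-inverted CDF tabulated on a
log-time grid (400 nodes, starting radii quantized to 0.1 μm), as a
fast surrogate for the kMC engine; a two-sample KS test against the
lattice simulation is part of the suite.

## Configuration and pipeline (`cli_io`)

Curves travel as plain CSV (`time_s, value, kind, r0_um, D_um2_s`,
12 significant digits, unknown columns preserved); fits and manifests
as JSON. Every stochastic stage requires an explicit seed — a missing
seed is an error, not a silent default. `run_pipeline` checks stage
dependencies before any computation and writes a manifest with the
config echo, seeds and SHA-256 hashes of all outputs; identical config
and seeds reproduce identical hashes.

## Known limitations

* The exponential-tail rate and the exact mean disagree by design (see
  above); users comparing tails against means should pick the quantity
  deliberately.
* Degenerate inputs: the rate polynomial has a root inside (ra, R) for
  some geometries; `slow_rate` raises rather than returning a signed
  rate. The Bessel flux route is singular at λ = 0.
* The kMC absorption test uses site centers, so the effective absorber
  radius is accurate only to half a lattice constant; at the `coarse`
  resolution this is a ≤1% effect on the mean FPT.
* Observation noise in the synthetic generator is homoscedastic and
  uncorrelated; real fluorescence noise is neither.
* Only the starting-radius mean is fitted; D and the width are assumed
  known. Joint fits are out of scope.
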