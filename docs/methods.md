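# Methods

## Susceptibility and the Cole–Cole fit

Spectra live on a (q, ν) grid with q in Å⁻¹ and ν in THz. An
energy-transfer axis in μeV (the natural unit of backscattering
spectrometers) is accepted on input and converted by ν = E/h with
h = 4.135668 μeV/THz; the Bose factor uses k_B = 86.17333 μeV/K. The
structure-factor → susceptibility conversion is the plain cell-wise
division χ″ = S/n_B(ν) — any instrument-dependent proportionality
constant is absorbed into χ₀, which is fitted freely per q. Resolution
deconvolution is out of scope: input spectra are treated as
resolution-corrected, and the synthetic spectra need none.

The Cole–Cole model is fitted per q-slice by weighted least squares with
`scipy.optimize.least_squares`, parameterised in (ln τ, α, χ₀) so the
τ bounds [10⁻³, 10⁶] ps act on a log scale. Weights are 1/σ² when an
error matrix is present, otherwise a trapezoid measure in ln ν, which
makes linearly and logarithmically spaced grids behave alike. The
initial guess is τ₀ = 1/(2πν_argmax), χ₀ = 2 × peak height, and three α
starts {0.05, 0.2, 0.5} are tried, keeping the lowest cost. α is bounded
at [0, 0.99]; a solution at the τ bounds or the α *upper* bound is
flagged unconverged, but α = 0 is the physical Debye limit and is
accepted. The convergence flag also requires the relative weighted
residual norm to stay below 0.25 (far above noiseless residuals ~10⁻⁶,
comfortably above the ~0.05 of 5%-noise data, but failing when the model
cannot describe the slice). No additive background term is included, and
χ₀ is free per q rather than shared — both choices are revisitable via
the fit interface but are the defaults throughout.

The fit window defaults to the full frequency grid; a window can be
passed explicitly.

## q-scaling and MSD exponents

τ(q) power laws are ordinary least squares of ln τ on ln q, unweighted —
with typically 3–7 q-points and percent-level τ uncertainties nothing
more elaborate is warranted; the slope standard error and R² are
reported. β = 2/n exactly. The band-average ᾱ is the unweighted mean of
α over converged fits with q ∈ [0.7, 1.5] Å⁻¹.

`compute_msd` averages |r(t₀+Δ) − r(t₀)|² over particles and sliding
origins (stride configurable, capped at 10⁴ origins per lag, evenly
subsampled beyond). For ageing processes — heavy-tailed CTRW — sliding
origins systematically push the apparent exponent towards 1, so
`origin_stride = 0` selects the pure ensemble MSD from the initial
frame; that mode also accepts non-uniform (log-spaced) time grids. MSD
exponents are log-log OLS slopes over a window, default 5–1000 ps.

## Residence times

First passage is sequential with reset: the reference starts at the
first frame; the first frame whose Euclidean displacement from the
reference reaches 3.5 Å closes an interval, and the reference moves
there. Durations are frame-quantised (no interpolation), so a uniform
frame spacing well below the typical residence time should be used
(0.25 ps in the bundled studies). The final unfinished interval per
particle is counted as censored and excluded from P(τ_res); including it
would bias the tail downward, and the censored fraction is reported so
heavy censoring is visible. Distributions are log-binned (10 bins per
decade) over the sample range; the degenerate all-equal case widens the
range by ±5% to keep edges strictly increasing.

Layers above the plane z = 0 are 3.5 Å slabs indexed from 1; a residence
interval belongs to the layer of its starting frame. With reflecting
boundaries, jumps that bounce off a wall have net displacement below the
jump length, so boundary layers show slightly longer residence times
even for homogeneous dynamics — a geometric effect worth remembering
when reading per-layer tables.

## The random-jump simulator

Event-driven: per particle the event times are the cumulative sum of
waits (no fixed time step — a fixed step is either biased or wasteful
under heavy tails), the position between jumps is constant, and the jump
occurs at the end of each wait. Jumps are ±l₀ with equal probability
(axis directions, uniform over 2d choices, in d dimensions — keeping the
analytic MSD oracle exact for the constant-step walk). Waiting models:

* exponential(mean) — normal diffusion, MSD = (l₀²/⟨τ⟩)t;
* Pareto ψ(t) = βt_min^β t^−(1+β), β ∈ (0, 1], t ≥ t_min, sampled by
  inverse CDF — sub-diffusion, MSD ∼ t^β;
* empirical — a log-binned histogram (typically an extracted P(τ_res)):
  bin by mass, then log-uniform within the bin, matching the log-spaced
  binning and avoiding pile-up at edges.

The asymptotic regime MSD ∼ t^β sets in only for t ≫ t_min (the leading
correction decays like (t/t_min)^(β−1)), so the bundled heavy-tail
studies use t_min = 0.01 ps, two to three decades below the 5–1000 ps
fit window; with t_min = 1 ps the window is pre-asymptotic and the
fitted exponent runs ~0.1 high. The simulator's MSD is the ensemble
average from t = 0 (see above) and its β comes from the same window as
the trajectory route, for comparability.

Implementation notes: waits are drawn in blocks and extended until every
particle's event sequence passes the horizon; positions at observation
times are recovered with a single offset `searchsorted` over the sorted
per-particle event times. Everything is reproducible bit-for-bit from
the seed. The default observation grid is 64 log-spaced times from 1 ps
to t_max plus a 0.25 ps uniform grid over the first 10 ps (MSD fits span
decades; the fine head resolves the first jumps).

## Synthetic data: what it emulates, and what it does not

The spectra generator evaluates the Cole–Cole model exactly per (q, ν)
cell, optionally multiplies by n_B(ν) to mimic a raw structure factor,
and applies multiplicative Gaussian noise (1 + noise·ε) truncated at
zero — mimicking the intensity scaling of counting statistics without a
full Poisson model. It does not emulate instrument resolution, detector
geometry, multiple scattering, or elastic/background contributions.

The trajectory generators produce constant-step random jumps —
homogeneous (1-D or 3-D) or in a water slab above a reflecting plane
with layer-dependent exponential waiting means (slowest at the surface).
The slab ceiling (`z_max`) is optional; the default geometry is the open
half-space, but a hydrated powder or film holds only a few layers of
water, so the bundled layered studies confine a slab. These walks have
the paper-thin surface physics of the coarse-grained model itself: no
molecular structure, no hydrogen-bond network, no correlated jump
directions. Passing tests therefore demonstrate that the *analysis
chain* is correct and self-consistent — not that real hydration water is
a constant-step CTRW.

The matched heterogeneity series ties a Pareto tail exponent β* to
spectra with α = 1 − β* and τ(q) = τ₀q^(−2/β*). The α ↔ β* map encodes
the qualitative broader-distribution ↔ stronger-sub-diffusion link at
the level where it can be asserted by construction; the exact functional
form is a modelling convenience, not a derived relation.

## Study scales

Bundled studies and checks run at desk scale, chosen to keep sampling
error comfortably inside the tolerances they are tested against:
10⁴ walkers for parametric RJ exponents (β within ±0.02 of 1.0 for
exponential waits, ±0.05 for a β = 0.5 tail), 800 slab particles ×
2000 ps at 0.25 ps frames for the layered systems, 8000 walkers for the
residence-driven RJ. The layered equivalence study uses the lateral
(x, y) MSD: the slab-normal coordinate saturates at the slab width and
would bend the exponent down for reasons unrelated to waiting-time
statistics.

## Known limitations

* The residence-driven RJ reduction treats waits as i.i.d. draws from
  the pooled P(τ_res). In layered systems a slow particle draws several
  consecutive slow waits, and beyond roughly 16× surface-to-bulk
  contrast this serial correlation makes the trajectory ensemble
  measurably more sub-diffusive than the i.i.d. model (discrepancies of
  ~0.05–0.10 in β at 24–32×). The default study series stays inside the
  validity regime; pushing it further would need a correlated-wait
  extension.
* Censoring truncates P(τ_res) at the trajectory length; driving the RJ
  with a heavily censored distribution underestimates the tail and
  biases its β upward. Keep trajectories several times longer than the
  slowest mean wait.
* Aging/ergodicity-breaking corrections for heavy-tailed CTRW
  (time-average vs ensemble-average MSD) are deliberately not modelled;
  the package always compares ensemble quantities.
* No 2-D/3-D variant of the RJ simulator, and no correlated jump
  directions; exponent comparisons between 1-D RJ and 3-D trajectories
  are exponent-only, never amplitude.
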