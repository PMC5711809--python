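# Methods

## Binding model

The package models a titration of a fluorescently labelled partner at fixed
concentration `c_fl` (nM) with a ligand at concentration `c` (nM).  The
fraction of labelled molecules in complex is the physical root of the
mass-action quadratic,

    fb(c) = (c_fl + c + K_D − sqrt((c_fl + c + K_D)² − 4 c_fl c)) / (2 c_fl),

and the measured response interpolates the plateaus: `f(c) = U + (B − U)·fb(c)`.
This form is exact when ligand depletion matters (`c` comparable to `c_fl`),
and reduces to the hyperbolic isotherm `c/(c + K_D)` as `c_fl → 0` (verified
to 1e-6 relative at `c_fl = 1e-6·K_D`).  Numerically the root is evaluated in
the conjugate form `fb = 2c/(s + sqrt(s² − 4 c_fl c))`, `s = c_fl + c + K_D`,
because the subtractive textbook form cancels catastrophically at trace
ligand concentrations (the low plateau of a log-spaced series); the result is
clamped to [0, 1] against floating-point excursions.  Free energies use the
van't Hoff relation `ΔG = RT ln K_D` with K_D converted to molar against the
1 M reference state, `R = 8.3144626 J/(mol·K)`, default `T = 297.15 K`.

**Internal units.** Concentrations are nM throughout.  The K_D prior bounds
(1 to 1e6) are only mutually consistent with sub-µM affinities when read in
nM, so that is the package-wide convention; responses are on the per-mil
Fnorm scale (0–1000).

## Serial-dilution error model

A two-fold dilution step pipettes one volume of the previous solution and
one of buffer; both are modelled `Normal(V_target, cov·V_target)` with a
shared spec (equal means, equal variance).  The realized concentration is

    c_k = c_{k−1} · N_{a,k} / (N_{a,k} + N_{b,k}),

a biased multiplicative random walk: log-concentration variance grows with
step index, and the ratio's skew biases the series low.  Draws are
truncated positive by rejection resampling — a physical volume cannot be
negative; for any realistic CoV the branch is essentially never taken
(P < 1e-6 at CoV 0.2).  At `cov = 0` the series equals the targeted
geometric series `c_start·(1/2)^k` to machine precision.  The default
series length is 15 steps (16 concentrations), matching common MST
capillary practice.

## Synthetic-data generator

One simulated experiment consists of `repeats` independent dilution series.
Responses are the mass-action curve evaluated at the *realized* (noisy)
concentrations plus `Normal(0, noise_sd)` measurement noise applied once
per observation at response level (the noise does not scale with dilution
step).  Then exactly `floor(outlier_fraction·N)` points — 20% by default —
chosen uniformly without replacement over the pooled experiment, are
replaced by `Uniform(min(U,B) − m, max(U,B) + m)` draws.  The analyst-facing
x-coordinate is always the *targeted* concentration: dilution error is a
hidden corruption, exactly as in the laboratory.  Everything is
deterministic given the seed (numpy `default_rng`; per-repeat draws consumed
in a fixed order).

Parameter choices where the study conditions leave a value open, fixed once:

* outlier margin `m = 0.25·|B − U|` (the uniform must "include" the U–B
  range; a quarter-range margin makes the extremes unambiguous junk);
* `c_fl,true = 50 nM` — a typical labelled-protein working concentration;
* stock concentration `c_start = 100·K_D,true`, so a 16-point two-fold
  series spans ~3 nM to 100× K_D and brackets the inflection;
* the benchmark table's pipette error column (0.1–2 µl, quoted as an
  absolute volume spread) is applied on a 10 µl targeted transfer volume,
  giving relative CoVs of 0.01–0.2.

The ten benchmark configurations (`TABLE_CASES`) vary true K_D
(0.05–5 µM), amplitude (B−U of −20 or −5), noise sd (0.5–2), pipette CoV
(0.01/0.02) and repeats (1/3/10).

**What the generator does not emulate:** ligand-induced fluorescence
quenching, aggregation or adsorption kinetics, capillary-scan artifacts,
temperature drift, or correlated (systematic) pipette offsets.  Passing
tests therefore demonstrate recovery under compounded random dilution error
plus gross uniform contamination — not under every pathology of real MST
data.

## Robust Bayesian inference

Priors: `K_D ~ U(1, 1e6) nM` (flat on the natural scale; a log-uniform
variant would concentrate less mass at large K_D but the flat prior is the
package default), `U, B ~ U(0, 1000)`, `c_fl ~ N(c_fl,nom, τ = 10·c_fl,nom)`
truncated to (0, 1e5) nM, `ν ~ DiscreteUniform{1..30}`, `λ ~ U(0, 100)`.
The `τ = 10·c_fl` default makes the c_fl prior very tight (sd ≈ 0.045 nM at
50 nM); it encodes that the labelled concentration is fixed by a single
dilution and nominally known, and it is overridable (`cfl_tau`).  The
likelihood is Student-t with location on the binding curve, discrete dof ν
and precision-like scale λ (`λ = 1/σ²` recovers the conventional scale
form); the heavy tails absorb outliers without any rejection rule.

Sampling: the five continuous parameters are mapped to unbounded space by a
logit transform of each bounded support and sampled with a No-U-Turn
sampler (slice-variable doubling-tree variant, diagonal mass matrix,
analytic gradients of the log posterior including the transform Jacobian);
ν is updated between NUTS transitions by exact categorical Gibbs — the
conditional likelihood is evaluated for all 30 dof values and sampled
directly.  Warm-up (default 1000 iterations, discarded) adapts the step
size by dual averaging toward a 0.8 acceptance statistic and the mass
matrix from warm-up draws at 40% and 75% of warm-up; the initial mass comes
from a finite-difference curvature estimate at a data-driven start point
(plateau means, geometric-mean K_D, moment-matched λ).  Defaults: 5000 kept
iterations, a single chain, max tree depth 8, divergence threshold 1000.
Gradients are verified against finite differences in the test suite, and
the t-density normalization against quadrature.

Point estimate: posterior median.  Interval: 95% highest-density interval,
computed as the narrowest contiguous window containing `ceil(0.95·n)`
sorted draws, ties broken to the lowest window.  Multi-chain runs report
split-chain R-hat and effective sample size via arviz; R-hat > 1.05 issues
a warning, never a failure (diagnostics are advisory).  Responses must lie
inside the (0, 1000) prior window; out-of-window data are affinely
rescaled into it (the CLI does this automatically and inverts the map on
output) rather than silently truncated.

A/B comparison: posterior draws of two systems are independently shuffled,
paired (equal thinning to the shorter set) and compared; reported are
`P(K_D_A < K_D_B)` and the posterior of `log10(K_D_A/K_D_B)`.  Shuffling
before pairing makes the comparison of a posterior with itself come out at
0.5, as it must.

## Least-squares comparator

`fit_nllsq` minimizes the residual sum of squares over (K_D, U, B) with
`c_fl` fixed at its nominal value (P = 3 parameters) using MINPACK
Levenberg–Marquardt (`scipy.optimize.least_squares(method="lm")`), started
by default from scale-free heuristics (U/B from the three lowest/highest-
concentration responses, K_D from the geometric mean of the concentration
range).  Confidence intervals profile one parameter at a time: the
interval is the set where the RSS re-minimized over the other two stays
below `RSS·(1 + F₁,N−P(α)/(N−P))`.  This threshold is deliberately the
plain-F form; the conventional profile-likelihood threshold multiplies F
by P and is available behind `conventional_threshold=True`.  Endpoints are
located by an outward geometric/linear scan from the estimate followed by
Brent root-finding on a deterministic profile (each profile evaluation is
warm-started from the global optimum so repeated evaluation is
reproducible); endpoints satisfy |RSS(p_end) − threshold| < 1e-6·RSS.  The
K_D search window is [1e-3, 1e6] nM and U/B windows are ±10 data ranges;
sides where the threshold is never crossed are reported at the window edge
with an open-ended flag.  Truth-coverage flags in the benchmark table use
a 1e-9 relative epsilon so a zero-width interval on noise-free data counts
as covering the value it sits on.

## Trace reduction

Raw MST traces (time, fluorescence per capillary; time zero = IR laser on)
are reduced to the per-mil normalized response
`Fnorm = 1000·mean(F_hot)/mean(F_cold)` with default cold window (−3, −1) s
and hot window (27, 29) s.  The single ratio deliberately combines the
T-jump and thermophoresis contributions.  An optional cold-anchored linear
detrend fits a line to the cold-window samples and references the hot mean
to its extrapolation, removing photobleaching drift exactly in the linear
case.  The per-mil scaling matches the magnitude of the plateaus the other
modules expect; `scale=1.0` gives the unit ratio.

## Problem sizes and determinism

The default sampler setting (5000 kept draws after 1000 warm-up, one
chain) fits a 48-point experiment in about two seconds and a 160-point one
in about the same, with K_D effective sample sizes above 2000.  The test
suite exercises the stochastic end-to-end properties (multi-seed recovery,
ten-case coverage, 50-trial robustness comparison) at a reduced size of
1200–1500 kept draws with 400–500 warm-up — posterior medians are stable
well below this size, and the choice keeps the whole suite fast while the
acceptance script uses the full 5000-iteration setting.  All random paths
(generator and sampler) flow from explicit integer seeds through numpy
`SeedSequence` spawning, so every reported number is exactly reproducible
from its seed.

## Known limitations

* The flat K_D prior on (1, 1e6) nM concentrates prior mass at large K_D;
  with weak data the posterior inherits this tilt (visible in the
  no-signal B = U case, where the posterior drifts toward the flat-curve
  region of parameter space).
* Single-site binding only; no cooperativity, kinetics or
  enthalpy/entropy decomposition.
* The NLLSQ profile assumes a unimodal RSS profile along each parameter;
  pathological multimodal profiles could place an endpoint on the wrong
  branch (the grid-profile oracle in the tests guards the supported
  regime).
* ν is sampled over {1..30}; data favouring effectively normal tails sit
  at the boundary ν = 30 rather than ν → ∞.
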