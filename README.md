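# mstbayes

Robust Bayesian estimation of binding affinity from MicroScale
Thermophoresis (MST) and other titration data.

## The problem

An MST titration measures a scalar response (normalized fluorescence,
T-jump + thermophoresis) of a fluorescently labelled protein at fixed
concentration `c_fl`, against a two-fold serial dilution of an unlabelled
ligand.  Real titrations are plagued by two error sources that classical
fitting handles badly:

* **serial-dilution errors** — every dilution step multiplies the
  concentration by `N_a/(N_a + N_b)`, a ratio of two noisy pipetted
  volumes, so concentration errors compound as a biased multiplicative
  random walk along the series;
* **anomalous observations** — a sizeable fraction of points (adsorption,
  aggregation, handling errors) simply do not sit on the binding curve.

Standard non-linear least squares (NLLSQ) requires a human to spot and
delete the outliers.  `mstbayes` instead fits the binding curve with a
Student-t observation model inside a fully Bayesian model, so heavy tails
absorb the outliers and the posterior quantifies the K_D uncertainty
without any manual rejection.

## The model

The response at ligand concentration `c` follows the law of mass action
(quadratic isotherm, exact at comparable `c` and `c_fl`):

    f(c) = U + (B − U) · (c_fl + c + K_D − sqrt((c_fl + c + K_D)² − 4 c_fl c)) / (2 c_fl)

with unbound/bound plateaus `U`, `B`.  Observations are Student-t
distributed around the curve, `D(c) ~ StudentT(μ = f(c), ν, λ)` with
discrete degrees of freedom `ν ∈ {1..30}` and precision-like scale `λ`.
Priors: `K_D ~ U(1, 10⁶) nM`, `U, B ~ U(0, 1000)`,
`c_fl ~ N(c_fl,nominal, τ = 10·c_fl,nominal)` truncated to (0, 10⁵) nM,
`ν ~ DU{1..30}`, `λ ~ U(0, 100)`.  Sampling combines a No-U-Turn (NUTS)
transition over the five continuous parameters — implemented in-package
with analytic gradients on logit-transformed supports — with an exact
categorical Gibbs update of `ν`.  The headline estimate is the posterior
median; intervals are 95% highest-density intervals (HDI).  Affinities are
converted to free energies by the van't Hoff relation `ΔG = RT ln K_D`
(1 M reference state, T = 297.15 K by default).

The classical comparator (`mstbayes.nllsq`) is a Levenberg–Marquardt fit of
(K_D, U, B) with per-parameter confidence intervals from the F-statistic
profile criterion `RSS(p) < RSS·(1 + F₁,N−P(α)/(N−P))`.

The synthetic-data generator (`mstbayes.synthgen`) reproduces the
benchmark study conditions: two-fold serial dilutions with pipetting CoV,
normal response noise, and 20% of points replaced by uniform draws spanning
the U–B range; the analyst-facing concentrations are the *targeted* ones,
so dilution errors act as hidden corruption.

## Worked example

```sh
python examples/01_simulate_and_fit.py
```

```
simulated 48 points, 9 of them outliers; true K_D = 5.0 µM
robust Bayes : K_D = 4.83 µM, 95% HDI (4.00, 5.65), ΔG = -30.2 kJ/mol
NLLSQ        : K_D = 3.92 µM, 95% CI (2.27, 6.67)
```

Three simulated dilution series (48 points, 9 of them junk) are fitted by
both methods.  The robust posterior median lands within 4% of the true
5 µM with a tight credible interval; the least-squares estimate is pulled
a further 20% off by the outliers and its F-test confidence interval is
almost three times wider.  The other scripts in `examples/` demonstrate
dilution-error propagation, Fnorm extraction from raw time traces, and
Bayesian A/B testing of two affinities.

## Command line

Every step is also available as a subcommand of the `mstbayes` console
script: `simulate`, `fit-bayes`, `fit-nllsq`, `compare`, `fnorm`,
`benchmark`.  For instance, the full ten-case simulation benchmark
(generate → fit both ways → tabulate coverage):

```sh
mstbayes benchmark --seed 0 --iterations 5000 --tune 1000 --out results/
```

All commands log to stderr, write results only under `--out`, and echo
their effective configuration (including the seed) to `run_config.yaml`.

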