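"""Robust Bayesian estimation of binding affinity from titration data.

The observation model is a Student-t distribution centred on the mass-action
binding curve:

    D(c) ~ StudentT(mu = U + (B - U) * fb(c; K_D, c_fl), dof = nu, precision = lam)

with priors

    K_D  ~ Uniform(1, 1e6) nM
    U, B ~ Uniform(0, 1000)
    c_fl ~ Normal(mu = c_fl_nominal, tau = 10 * c_fl_nominal), truncated to (0, 1e5) nM
    nu   ~ DiscreteUniform{1, ..., 30}
    lam  ~ Uniform(0, 100)

The heavy Student-t tails absorb anomalous observations, so no outlier
rejection is needed.  Sampling combines a No-U-Turn (NUTS) transition over
the five continuous parameters (on logit-transformed, bounded supports, with
analytic gradients) with an exact categorical Gibbs update of the discrete
degrees of freedom ``nu`` — the Metropolis/NUTS compound scheme.

The headline point estimate is the posterior median; intervals are highest
density intervals (HDI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, log_expit

from . import _nuts
from .binding import BindingParams, DEFAULT_TEMPERATURE_K, delta_g, mass_action_response
from .synthgen import DEFAULT_C_FL_NM, TitrationDataset

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "PosteriorSamples",
    "AffinityComparison",
    "student_t_logpdf",
    "log_likelihood",
    "fit_bayes",
    "hdi",
    "posterior_curve_swarm",
    "compare_affinities",
]

_PARAM_NAMES = ("kd", "u", "b", "c_fl", "lam")
_NU_VALUES = np.arange(1, 31)


@dataclass(frozen=True)
class PriorConfig:
    """Prior bounds and hyperparameters of the robust model.

    ``cfl_mu`` is the nominal labelled-partner concentration (nM); its prior
    precision defaults to ``10 * cfl_mu`` — an intentionally tight prior,
    reflecting that the labelled concentration is pipetted once and known.
    """

    kd_bounds: tuple[float, float] = (1.0, 1e6)
    u_bounds: tuple[float, float] = (0.0, 1000.0)
    b_bounds: tuple[float, float] = (0.0, 1000.0)
    cfl_mu: float = DEFAULT_C_FL_NM
    cfl_tau: float | None = None
    cfl_bounds: tuple[float, float] = (0.0, 1e5)
    nu_bounds: tuple[int, int] = (1, 30)
    lambda_bounds: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("kd_bounds", "u_bounds", "b_bounds", "cfl_bounds", "lambda_bounds", "nu_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper bound")
        if not self.cfl_mu > 0:
            raise ValueError("cfl_mu must be positive")
        if self.cfl_tau is not None and not self.cfl_tau > 0:
            raise ValueError("cfl_tau must be positive")

    @property
    def cfl_precision(self) -> float:
        return self.cfl_tau if self.cfl_tau is not None else 10.0 * self.cfl_mu

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "kd": self.kd_bounds,
            "u": self.u_bounds,
            "b": self.b_bounds,
            "c_fl": self.cfl_bounds,
            "lam": self.lambda_bounds,
        }


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: kept draws, warm-up, chains, seed."""

    n_iterations: int = 5000
    n_tune: int = 1000
    n_chains: int = 1
    rng_seed: int = 0
    target_accept: float = 0.8
    max_tree_depth: int = 8

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_chains < 1 or self.n_tune < 0:
            raise ValueError("n_iterations >= 1, n_chains >= 1, n_tune >= 0 required")


def student_t_logpdf(x, mu, nu, lam):
    """Log density of the Student-t with location, dof and precision-like scale.

    Parameterized so the density is
    ``G((nu+1)/2)/G(nu/2) * sqrt(lam/(pi*nu)) * [1 + lam*(x-mu)^2/nu]^(-(nu+1)/2)``,
    i.e. ``lam = 1/sigma^2`` recovers the conventional scale-``sigma`` form.
    """
    x, mu, nu, lam = np.broadcast_arrays(x, mu, nu, lam)
    r2 = (np.asarray(x, float) - mu) ** 2
    return (
        gammaln((nu + 1) / 2.0)
        - gammaln(nu / 2.0)
        + 0.5 * (np.log(lam) - np.log(np.pi * nu))
        - (nu + 1) / 2.0 * np.log1p(lam * r2 / nu)
    )


def log_likelihood(
    dataset: TitrationDataset,
    kd: float,
    u: float,
    b: float,
    c_fl: float,
    nu: int,
    lam: float,
    priors: PriorConfig | None = None,
) -> float:
    """Summed Student-t log likelihood of the dataset at one parameter draw.

    Returns ``-inf`` when the draw lies outside the prior support.
    """
    priors = priors or PriorConfig()
    theta = {"kd": kd, "u": u, "b": b, "c_fl": c_fl, "lam": lam}
    for name, (lo, hi) in priors.bounds.items():
        if not lo < theta[name] < hi:
            return -np.inf
    nu_lo, nu_hi = priors.nu_bounds
    if not (nu_lo <= nu <= nu_hi and float(nu).is_integer()):
        return -np.inf
    mu = mass_action_response(dataset.concentrations, BindingParams(kd=kd, u=u, b=b, c_fl=c_fl))
    return float(np.sum(student_t_logpdf(dataset.responses, mu, nu, lam)))


# ---------------------------------------------------------------------------
# transformed-space posterior and gradients
# ---------------------------------------------------------------------------


class _Model:
    """Log posterior and gradient on the logit-transformed continuous parameters."""

    def __init__(self, x: np.ndarray, y: np.ndarray, priors: PriorConfig):
        self.x = x
        self.y = y
        self.priors = priors
        self.lo = np.array([priors.bounds[n][0] for n in _PARAM_NAMES])
        self.hi = np.array([priors.bounds[n][1] for n in _PARAM_NAMES])
        self.width = self.hi - self.lo
        # nu-dependent normalization constants of the Gibbs update
        n = x.size
        self._nu_const = n * (
            gammaln((_NU_VALUES + 1) / 2.0) - gammaln(_NU_VALUES / 2.0) - 0.5 * np.log(_NU_VALUES)
        )

    def to_theta(self, z: np.ndarray) -> np.ndarray:
        return self.lo + self.width * expit(z)

    def to_z(self, theta: np.ndarray) -> np.ndarray:
        p = np.clip((theta - self.lo) / self.width, 1e-12, 1 - 1e-12)
        return np.log(p) - np.log1p(-p)

    def logp_grad(self, z: np.ndarray, nu: int) -> tuple[float, np.ndarray]:
        sig = expit(z)
        theta = self.lo + self.width * sig
        kd, u, b, c_fl, lam = theta
        x, y = self.x, self.y

        s = c_fl + x + kd
        root = np.sqrt(s * s - 4.0 * c_fl * x)
        fb = 2.0 * x / (s + root)
        mu = u + (b - u) * fb
        resid = y - mu
        r2 = resid * resid

        denom = nu + lam * r2
        n = x.size
        loglik = (
            n * (gammaln((nu + 1) / 2.0) - gammaln(nu / 2.0) + 0.5 * (np.log(lam) - np.log(np.pi * nu)))
            - (nu + 1) / 2.0 * np.sum(np.log1p(lam * r2 / nu))
        )
        # d loglik / d mu_i
        gmu = (nu + 1.0) * lam * resid / denom

        dfb_dkd = -2.0 * x / (root * (s + root))
        dfb_dcfl = (1.0 - (s - 2.0 * x) / root) / (2.0 * c_fl) - fb / c_fl
        dl_kd = (b - u) * np.dot(gmu, dfb_dkd)
        dl_u = np.dot(gmu, 1.0 - fb)
        dl_b = np.dot(gmu, fb)
        dl_cfl = (b - u) * np.dot(gmu, dfb_dcfl)
        dl_lam = 0.5 * n / lam - (nu + 1) / 2.0 * np.sum(r2 / denom)

        # truncated-normal prior on c_fl (bounds constant => no extra term)
        tau = self.priors.cfl_precision
        logprior = -0.5 * tau * (c_fl - self.priors.cfl_mu) ** 2
        dl_cfl += -tau * (c_fl - self.priors.cfl_mu)

        dtheta = np.array([dl_kd, dl_u, dl_b, dl_cfl, dl_lam])
        jac = self.width * sig * (1.0 - sig)
        logjac = float(np.sum(np.log(self.width) + log_expit(z) + log_expit(-z)))
        grad = dtheta * jac + (1.0 - 2.0 * sig)
        return float(loglik + logprior + logjac), grad

    def gibbs_nu(self, z: np.ndarray, rng: np.random.Generator) -> int:
        """Exact categorical Gibbs draw of the Student-t dof given the rest."""
        theta = self.to_theta(z)
        kd, u, b, c_fl, lam = theta
        mu = u + (b - u) * (2.0 * self.x / (
            (c_fl + self.x + kd) + np.sqrt((c_fl + self.x + kd) ** 2 - 4.0 * c_fl * self.x)
        ))
        a = lam * (self.y - mu) ** 2
        ll = self._nu_const - (_NU_VALUES + 1.0) / 2.0 * np.sum(
            np.log1p(a[None, :] / _NU_VALUES[:, None]), axis=1
        )
        p = np.exp(ll - ll.max())
        p /= p.sum()
        return int(rng.choice(_NU_VALUES, p=p))


def _initial_theta(dataset: TitrationDataset, priors: PriorConfig) -> np.ndarray:
    """Data-driven starting point: plateau means, geometric-mean K_D,
    nominal c_fl, moment-matched precision."""
    x, y = dataset.concentrations, dataset.responses
    order = np.argsort(x)
    k = max(1, min(3, x.size // 4))
    u0 = float(np.mean(y[order[:k]]))
    b0 = float(np.mean(y[order[-k:]]))
    kd0 = float(np.exp(np.mean(np.log(x))))
    resid_scale = float(np.var(y - np.median(y)))
    lam0 = 1.0 / max(resid_scale, 1e-3)
    theta = np.array([kd0, u0, b0, priors.cfl_mu, lam0])
    lo = np.array([priors.bounds[n][0] for n in _PARAM_NAMES])
    hi = np.array([priors.bounds[n][1] for n in _PARAM_NAMES])
    pad = 1e-4 * (hi - lo)
    return np.clip(theta, lo + pad, hi - pad)


def _hessian_inv_mass(model: _Model, z: np.ndarray, nu: int) -> np.ndarray:
    """Diagonal inverse mass from finite-difference curvature at the start point.

    Flat or non-concave directions fall back to unit mass (the natural scale
    of a prior-dominated logit-transformed coordinate).
    """
    inv_mass = np.ones_like(z)
    for j in range(z.size):
        h = 1e-4 * max(1.0, abs(z[j]))
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        _, gp = model.logp_grad(zp, nu)
        _, gm = model.logp_grad(zm, nu)
        curv = -(gp[j] - gm[j]) / (2.0 * h)
        if np.isfinite(curv) and curv > 1e-8:
            inv_mass[j] = min(max(1.0 / curv, 1e-8), 1e8)
    return inv_mass


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """MCMC draws of (K_D, U, B, c_fl, nu, lam), shaped (n_chains, n_draws)."""

    draws: dict[str, np.ndarray]
    priors: PriorConfig
    mcmc: McmcConfig
    n_divergences: int = 0

    @property
    def n_chains(self) -> int:
        return self.draws["kd"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["kd"].shape[1]

    def array(self, name: str, combined: bool = True) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1) if combined else a

    def median(self, name: str = "kd") -> float:
        return float(np.median(self.array(name)))

    def hdi(self, name: str = "kd", mass: float = 0.95) -> tuple[float, float]:
        return hdi(self.array(name), mass)

    def summary(self, temperature_k: float = DEFAULT_TEMPERATURE_K, mass: float = 0.95) -> dict:
        """Medians, HDIs and the van't Hoff free energy of the K_D estimate."""
        out: dict = {}
        for name in ("kd", "u", "b", "c_fl", "nu", "lam"):
            lo, hi_ = self.hdi(name, mass)
            out[name] = {"median": self.median(name), "hdi_lower": lo, "hdi_upper": hi_}
        kd = out["kd"]
        out["delta_g_kJ_per_mol"] = {
            "median": delta_g(kd["median"], temperature_k),
            "hdi_lower": delta_g(kd["hdi_lower"], temperature_k),
            "hdi_upper": delta_g(kd["hdi_upper"], temperature_k),
        }
        out["hdi_mass"] = mass
        out["temperature_K"] = temperature_k
        return out

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_draws
        frames = []
        for chain in range(self.n_chains):
            frames.append(
                pd.DataFrame(
                    {
                        "kd_nM": self.draws["kd"][chain],
                        "u": self.draws["u"][chain],
                        "b": self.draws["b"][chain],
                        "c_fl_nM": self.draws["c_fl"][chain],
                        "nu": self.draws["nu"][chain].astype(int),
                        "lambda": self.draws["lam"][chain],
                        "chain": chain,
                        "iteration": np.arange(n),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def save_draws(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def diagnostics(self) -> dict:
        """Effective sample size and split-chain R-hat per parameter (arviz)."""
        import arviz as az

        out = {}
        for name in ("kd", "u", "b", "c_fl", "nu", "lam"):
            a = self.draws[name][None] if self.draws[name].ndim == 1 else self.draws[name]
            data = az.convert_to_dataset({name: a})
            out[name] = {
                "ess": float(az.ess(data)[name].values),
                "rhat": float(az.rhat(data)[name].values) if self.n_chains >= 2 else np.nan,
            }
        return out


# ---------------------------------------------------------------------------
# sampling driver
# ---------------------------------------------------------------------------


def fit_bayes(
    dataset: TitrationDataset,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior of (K_D, U, B, c_fl, nu, lam).

    Each iteration applies one NUTS transition to the continuous block and an
    exact Gibbs draw of the discrete dof.  Warm-up adapts the step size by
    dual averaging and the diagonal mass matrix from the warm-up draws
    (seeded from a finite-difference curvature estimate at the start point).
    Reproducible given ``mcmc.rng_seed``.
    """
    if dataset.n_points < 1:
        raise ValueError("dataset must contain at least one point")
    if priors is None:
        cfl = dataset.ground_truth.c_fl_true if dataset.ground_truth is not None else DEFAULT_C_FL_NM
        priors = PriorConfig(cfl_mu=cfl)
    mcmc = mcmc or McmcConfig()

    y = dataset.responses
    u_lo, u_hi = priors.u_bounds
    if y.min() < u_lo or y.max() > u_hi:
        raise ValueError(
            "responses fall outside the (U, B) prior window "
            f"({u_lo}, {u_hi}); rescale them first (the CLI does this automatically)"
        )

    model = _Model(dataset.concentrations, y, priors)
    seeds = np.random.SeedSequence(mcmc.rng_seed).spawn(mcmc.n_chains)
    names = ("kd", "u", "b", "c_fl", "lam", "nu")
    all_draws = {n: np.empty((mcmc.n_chains, mcmc.n_iterations)) for n in names}
    n_div = 0

    for chain, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        z = model.to_z(_initial_theta(dataset, priors))
        nu = 5
        inv_mass = _hessian_inv_mass(model, z, nu)
        lp, grad = model.logp_grad(z, nu)

        logp_grad = lambda zz: model.logp_grad(zz, nu)  # noqa: E731 - rebound per nu below
        eps = _nuts.find_reasonable_epsilon(z, lp, grad, logp_grad, inv_mass, rng)
        da = _nuts.DualAveraging.start(eps, target=mcmc.target_accept)

        z_hist = np.empty((mcmc.n_tune, z.size))
        mass_updates = (
            {int(0.4 * mcmc.n_tune), int(0.75 * mcmc.n_tune)} if mcmc.n_tune >= 200 else set()
        )
        for t in range(mcmc.n_tune):
            z, lp, grad, astat, div = _nuts.nuts_transition(
                z, lp, grad, logp_grad, eps, inv_mass, rng, mcmc.max_tree_depth
            )
            eps = da.update(astat)
            nu_new = model.gibbs_nu(z, rng)
            if nu_new != nu:
                nu = nu_new
                lp, grad = model.logp_grad(z, nu)
            z_hist[t] = z
            if t + 1 in mass_updates:
                window = z_hist[(t + 1) // 2 : t + 1]
                var = window.var(axis=0)
                inv_mass = np.where(var > 1e-12, var, inv_mass)
                eps = _nuts.find_reasonable_epsilon(z, lp, grad, logp_grad, inv_mass, rng)
                da = _nuts.DualAveraging.start(eps, target=mcmc.target_accept)
        if mcmc.n_tune:
            eps = da.adapted_eps

        for t in range(mcmc.n_iterations):
            z, lp, grad, astat, div = _nuts.nuts_transition(
                z, lp, grad, logp_grad, eps, inv_mass, rng, mcmc.max_tree_depth
            )
            n_div += div
            nu_new = model.gibbs_nu(z, rng)
            if nu_new != nu:
                nu = nu_new
                lp, grad = model.logp_grad(z, nu)
            theta = model.to_theta(z)
            for name, val in zip(_PARAM_NAMES, theta):
                all_draws[name][chain, t] = val
            all_draws["nu"][chain, t] = nu

    posterior = PosteriorSamples(draws=all_draws, priors=priors, mcmc=mcmc, n_divergences=n_div)
    if mcmc.n_chains >= 2:
        diag = posterior.diagnostics()
        worst = max(d["rhat"] for d in diag.values())
        if worst > 1.05:
            warnings.warn(
                f"split-chain R-hat {worst:.3f} exceeds 1.05; chains may not have converged",
                RuntimeWarning,
                stacklevel=2,
            )
    return posterior


# ---------------------------------------------------------------------------
# posterior summaries and comparisons
# ---------------------------------------------------------------------------


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally narrow windows are broken toward the lowest window.
    """
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size
    if n < 2:
        raise ValueError("hdi requires at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def posterior_curve_swarm(
    posterior: PosteriorSamples,
    n_curves: int,
    c_grid,
    rng_seed: int = 0,
) -> np.ndarray:
    """Binding curves at jointly drawn posterior parameter sets.

    Returns an array of shape ``(n_curves, len(c_grid))``; each row evaluates
    the mass-action curve at one randomly selected joint draw (marginals are
    never mixed across draws).
    """
    c_grid = np.asarray(c_grid, dtype=float)
    total = posterior.n_chains * posterior.n_draws
    if n_curves > total:
        raise ValueError(f"n_curves = {n_curves} exceeds the {total} available draws")
    if n_curves == 0:
        return np.empty((0, c_grid.size))
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(total, size=n_curves, replace=False)
    kd = posterior.array("kd")[idx]
    u = posterior.array("u")[idx]
    b = posterior.array("b")[idx]
    c_fl = posterior.array("c_fl")[idx]
    curves = np.empty((n_curves, c_grid.size))
    for i in range(n_curves):
        curves[i] = mass_action_response(c_grid, BindingParams(kd=kd[i], u=u[i], b=b[i], c_fl=c_fl[i]))
    return curves


@dataclass
class AffinityComparison:
    """Posterior A/B comparison of two affinities."""

    prob_a_less: float
    log10_ratio: np.ndarray  # draws of log10(K_D_A / K_D_B)

    def summary(self, mass: float = 0.95) -> dict:
        lo, hi = hdi(self.log10_ratio, mass)
        return {
            "prob_kd_a_less_than_b": self.prob_a_less,
            "log10_ratio_median": float(np.median(self.log10_ratio)),
            "log10_ratio_hdi": (lo, hi),
        }


def compare_affinities(
    posterior_a: PosteriorSamples | np.ndarray,
    posterior_b: PosteriorSamples | np.ndarray,
    rng_seed: int = 0,
) -> AffinityComparison:
    """Probability that system A binds tighter (lower K_D) than system B.

    Draws are independently shuffled and paired (equal thinning to the
    shorter set), so comparing a posterior with itself yields ~0.5.  Raw K_D
    sample arrays are accepted in place of :class:`PosteriorSamples`.
    """
    ka = posterior_a.array("kd") if isinstance(posterior_a, PosteriorSamples) else np.asarray(posterior_a, float).ravel()
    kb = posterior_b.array("kd") if isinstance(posterior_b, PosteriorSamples) else np.asarray(posterior_b, float).ravel()
    if ka.size == 0 or kb.size == 0:
        raise ValueError("both posteriors must contain draws")
    rng = np.random.default_rng(rng_seed)
    n = min(ka.size, kb.size)
    ka = rng.permutation(ka)[:n]
    kb = rng.permutation(kb)[:n]
    return AffinityComparison(
        prob_a_less=float(np.mean(ka < kb)),
        log10_ratio=np.log10(ka / kb),
    )


def rescale_responses(dataset: TitrationDataset, priors: PriorConfig | None = None):
    """Affine map of responses into the middle of the (U, B) prior window.

    Returns ``(rescaled_dataset, (scale, offset))`` with
    ``rescaled = scale * response + offset``; medians/HDIs of U, B and lam
    from a fit on the rescaled data are inverted with
    :func:`invert_rescaled_summary`.
    """
    priors = priors or PriorConfig()
    lo, hi = priors.u_bounds
    y = dataset.responses
    span = y.max() - y.min()
    span = span if span > 0 else 1.0
    target_lo = lo + 0.2 * (hi - lo)
    target_hi = hi - 0.2 * (hi - lo)
    scale = (target_hi - target_lo) / span
    offset = target_lo - scale * y.min()
    return dataset.with_responses(scale * y + offset), (scale, offset)


def invert_rescaled_summary(summary: dict, transform: tuple[float, float]) -> dict:
    """Map a :meth:`PosteriorSamples.summary` from rescaled response units back
    to the original ones (U and B affinely, lam as a precision)."""
    scale, offset = transform
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in summary.items()}
    for name in ("u", "b"):
        for key in ("median", "hdi_lower", "hdi_upper"):
            out[name][key] = (out[name][key] - offset) / scale
    for key in ("median", "hdi_lower", "hdi_upper"):
        out["lam"][key] = out["lam"][key] * scale**2
    return out
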