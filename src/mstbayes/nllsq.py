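"""Classical non-linear least-squares fit with F-statistic confidence intervals.

The comparator to the robust Bayesian fit: minimize the residual sum of
squares of the mass-action curve over (K_D, U, B) with the labelled-partner
concentration fixed at its nominal value (P = 3 free parameters), using the
MINPACK Levenberg-Marquardt implementation.  Per-parameter confidence
intervals come from profiling: the interval for parameter ``p`` is the range
over which the RSS re-minimized over the other parameters stays below

    RSS * (1 + F_{1, N-P}(alpha) / (N - P))

the F-statistic criterion at confidence level ``1 - alpha``.  (The
conventional profile threshold multiplies F by P; a switch selects it.)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .binding import BindingParams, mass_action_response
from .synthgen import DEFAULT_C_FL_NM, TitrationDataset

__all__ = ["NllsqFit", "ProfileCI", "default_init", "fit_nllsq", "confidence_interval", "confidence_intervals"]

N_PARAMS = 3
_KD_WINDOW = (1e-3, 1e6)  # nM search window for the K_D profile
_KD_FLOOR = 1e-12  # guard inside the model evaluation; LM is unbounded


@dataclass(frozen=True)
class ProfileCI:
    """One profiled confidence interval; open-ended sides hit the search window."""

    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class NllsqFit:
    """Point estimates, RSS and (optionally) profiled confidence intervals."""

    kd: float
    u: float
    b: float
    c_fl: float
    rss: float
    n_points: int
    converged: bool
    n_params: int = N_PARAMS
    ci: dict[str, ProfileCI] | None = None

    @property
    def estimates(self) -> dict[str, float]:
        return {"kd": self.kd, "u": self.u, "b": self.b}


def _model(x: np.ndarray, kd: float, u: float, b: float, c_fl: float) -> np.ndarray:
    # LM explores an unbounded space; keep the quadratic root real
    return mass_action_response(x, BindingParams(kd=max(kd, _KD_FLOOR), u=u, b=b, c_fl=c_fl))


def default_init(dataset: TitrationDataset) -> tuple[float, float, float]:
    """Scale-free starting point: K_D at the geometric mean of the
    concentration range, U/B at the means of the 3 lowest/highest-c responses."""
    x, y = dataset.concentrations, dataset.responses
    order = np.argsort(x)
    k = max(1, min(3, x.size // 4))
    kd0 = float(np.exp(np.mean(np.log(x))))
    u0 = float(np.mean(y[order[:k]]))
    b0 = float(np.mean(y[order[-k:]]))
    return kd0, u0, b0


def fit_nllsq(
    dataset: TitrationDataset,
    init: tuple[float, float, float] | None = None,
    c_fl: float | None = None,
) -> NllsqFit:
    """Levenberg-Marquardt fit of (K_D, U, B) with c_fl fixed at nominal.

    Deterministic given ``init``; requires more points than parameters.
    """
    if dataset.n_points <= N_PARAMS:
        raise ValueError(f"need more than {N_PARAMS} points, got {dataset.n_points}")
    if c_fl is None:
        c_fl = dataset.ground_truth.c_fl_true if dataset.ground_truth is not None else DEFAULT_C_FL_NM
    if init is None:
        init = default_init(dataset)
    if not np.all(np.isfinite(init)):
        raise ValueError("initial parameters must be finite")
    x, y = dataset.concentrations, dataset.responses

    def residuals(p):
        return y - _model(x, p[0], p[1], p[2], c_fl)

    sol = optimize.least_squares(residuals, np.asarray(init, float), method="lm", xtol=1e-12, ftol=1e-12)
    kd, u, b = sol.x
    return NllsqFit(
        kd=float(max(kd, _KD_FLOOR)),
        u=float(u),
        b=float(b),
        c_fl=float(c_fl),
        rss=float(2.0 * sol.cost),
        n_points=dataset.n_points,
        converged=bool(sol.status > 0),
    )


def _profile_rss(x, y, c_fl, parameter, fixed_value, free_init):
    """RSS minimized over the two parameters other than ``parameter``."""
    order = ["kd", "u", "b"]
    free = [n for n in order if n != parameter]

    def residuals(p):
        vals = dict(zip(free, p))
        vals[parameter] = fixed_value
        return y - _model(x, vals["kd"], vals["u"], vals["b"], c_fl)

    sol = optimize.least_squares(residuals, np.asarray(free_init, float), method="lm", xtol=1e-12, ftol=1e-12)
    return float(2.0 * sol.cost), sol.x


def rss_threshold(rss: float, n_points: int, alpha: float = 0.05, conventional: bool = False, n_params: int = N_PARAMS) -> float:
    """F-criterion RSS threshold ``RSS * (1 + F/(N-P))`` (or ``* P`` conventionally)."""
    dof = n_points - n_params
    f = stats.f.ppf(1.0 - alpha, 1, dof)
    mult = n_params * f if conventional else f
    return rss * (1.0 + mult / dof)


def _crossing(profile, p_hat, threshold, edge, multiplicative):
    """Outward bracket + Brent root of ``profile(p) - threshold`` on one side.

    Returns ``(endpoint, open_flag)``; the flag is set when the threshold is
    never crossed inside the search window.
    """
    n_grid = 60
    if multiplicative:
        grid = np.geomspace(p_hat, edge, n_grid)
    else:
        grid = np.linspace(p_hat, edge, n_grid)
    prev_p = grid[0]
    for p in grid[1:]:
        g = profile(p) - threshold
        if g > 0:
            if profile(prev_p) - threshold >= 0:
                # minimum sits so close to the cell edge that the whole cell
                # is above threshold; fall back to the estimate itself
                prev_p = p_hat
            root = optimize.brentq(lambda q: profile(q) - threshold, prev_p, p, xtol=1e-12, rtol=1e-14)
            return float(root), False
        prev_p = p
    return float(edge), True


def confidence_interval(
    fit: NllsqFit,
    dataset: TitrationDataset,
    parameter: str,
    alpha: float = 0.05,
    conventional_threshold: bool = False,
    search_window: tuple[float, float] | None = None,
) -> ProfileCI:
    """Profiled F-criterion confidence interval for one parameter.

    The profile RSS (re-minimized over the other two parameters, warm-started
    from the fit) is scanned outward from the estimate on both sides; each
    endpoint is the Brent root of ``RSS(p) - threshold``.  Sides on which the
    threshold is never crossed within the search window are reported at the
    window edge with the open flag set.
    """
    if not fit.converged:
        raise ValueError("confidence_interval requires a converged fit")
    if parameter not in ("kd", "u", "b"):
        raise ValueError(f"unknown parameter {parameter!r}")
    x, y = dataset.concentrations, dataset.responses
    threshold = rss_threshold(fit.rss, fit.n_points, alpha, conventional_threshold)
    p_hat = fit.estimates[parameter]
    free_init = [v for n, v in fit.estimates.items() if n != parameter]

    def profile(p):
        # deterministic warm start from the global optimum, so repeated
        # evaluation at the same p always returns the same RSS
        rss, _ = _profile_rss(x, y, fit.c_fl, parameter, p, free_init)
        return rss

    multiplicative = parameter == "kd"
    if search_window is None:
        if multiplicative:
            search_window = _KD_WINDOW
        else:
            span = y.max() - y.min()
            span = span if span > 0 else 1.0
            search_window = (p_hat - 10.0 * span, p_hat + 10.0 * span)
    lo_edge, hi_edge = search_window

    upper, upper_open = _crossing(profile, p_hat, threshold, hi_edge, multiplicative)
    lower, lower_open = _crossing(profile, p_hat, threshold, lo_edge, multiplicative)
    return ProfileCI(lower=lower, upper=upper, lower_open=lower_open, upper_open=upper_open)


def confidence_intervals(
    fit: NllsqFit,
    dataset: TitrationDataset,
    alpha: float = 0.05,
    conventional_threshold: bool = False,
) -> NllsqFit:
    """Fit with the ``ci`` field populated for all three parameters."""
    ci = {
        name: confidence_interval(fit, dataset, name, alpha, conventional_threshold)
        for name in ("kd", "u", "b")
    }
    return replace(fit, ci=ci)
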