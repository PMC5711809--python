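"""A self-contained No-U-Turn sampler with dual-averaging step-size adaptation.

Implements the slice-variable NUTS recursion (doubling tree with the no-U-turn
termination criterion) over a user-supplied log-density and gradient, with a
diagonal mass matrix.  The kernel is a single transition function so callers
can interleave it with other updates (here: a Gibbs step on the discrete
Student-t degrees of freedom between NUTS transitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DualAveraging", "find_reasonable_epsilon", "nuts_transition"]

# log-joint drop beyond which a trajectory is declared divergent
_DELTA_MAX = 1000.0


@dataclass
class DualAveraging:
    """Nesterov dual averaging of log step size toward a target accept rate."""

    mu: float
    target: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0
    log_eps: float = 0.0

    @classmethod
    def start(cls, eps0: float, target: float = 0.8) -> "DualAveraging":
        da = cls(mu=np.log(10.0 * eps0), target=target)
        da.log_eps = np.log(eps0)
        return da

    def update(self, accept_stat: float) -> float:
        """Feed one acceptance statistic; returns the step size for the next step."""
        self._t += 1
        frac = 1.0 / (self._t + self.t0)
        self._h_bar = (1 - frac) * self._h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self._t) / self.gamma * self._h_bar
        w = self._t ** (-self.kappa)
        self._log_eps_bar = w * self.log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted_eps(self) -> float:
        """Averaged step size to freeze after warm-up."""
        return float(np.exp(self._log_eps_bar)) if self._t else float(np.exp(self.log_eps))


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * inv_mass, p))


def find_reasonable_epsilon(z, logp, grad, logp_grad, inv_mass, rng) -> float:
    """Heuristic initial step size: double/halve until the one-step
    acceptance probability crosses 1/2."""
    eps = 1.0
    p = rng.normal(size=z.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)

    def one_step(eps):
        p1 = p + 0.5 * eps * grad
        z1 = z + eps * inv_mass * p1
        lp1, g1 = logp_grad(z1)
        p1 = p1 + 0.5 * eps * g1
        return lp1 - _kinetic(p1, inv_mass)

    h1 = one_step(eps)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0 ** direction
        h1 = one_step(eps)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def _leapfrog(z, p, grad, eps, inv_mass, logp_grad):
    p = p + 0.5 * eps * grad
    z = z + eps * inv_mass * p
    logp, grad = logp_grad(z)
    p = p + 0.5 * eps * grad
    return z, p, logp, grad


def _no_uturn(z_minus, z_plus, p_minus, p_plus, inv_mass) -> bool:
    dz = z_plus - z_minus
    return (np.dot(dz, inv_mass * p_minus) >= 0) and (np.dot(dz, inv_mass * p_plus) >= 0)


def nuts_transition(z, logp, grad, logp_grad, eps, inv_mass, rng, max_depth=8):
    """One NUTS transition.

    Returns ``(z', logp', grad', accept_stat, diverged)`` where
    ``accept_stat`` is the mean Metropolis acceptance probability over the
    trajectory (the dual-averaging statistic).
    """
    p0 = rng.normal(size=z.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    log_u = h0 - rng.exponential()

    z_minus = z_plus = z
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    z_new, logp_new, grad_new = z, logp, grad
    n_valid = 1
    sum_alpha = 0.0
    n_alpha = 0
    diverged = False

    def build_tree(z, p, grad, direction, depth):
        nonlocal sum_alpha, n_alpha, diverged
        if depth == 0:
            z1, p1, lp1, g1 = _leapfrog(z, p, grad, direction * eps, inv_mass, logp_grad)
            h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
            n1 = int(log_u <= h1)
            stop = (h1 - log_u) < -_DELTA_MAX
            if stop:
                diverged = True
            sum_alpha += min(1.0, np.exp(min(0.0, h1 - h0)))
            n_alpha += 1
            return z1, p1, g1, z1, p1, g1, z1, lp1, g1, n1, not stop
        # build left/inner subtree then outer
        zm, pm, gm, zp, pp, gp, zc, lpc, gc, n1, ok = build_tree(z, p, grad, direction, depth - 1)
        if ok:
            if direction == -1:
                zm, pm, gm, _, _, _, zc2, lpc2, gc2, n2, ok2 = build_tree(zm, pm, gm, direction, depth - 1)
            else:
                _, _, _, zp, pp, gp, zc2, lpc2, gc2, n2, ok2 = build_tree(zp, pp, gp, direction, depth - 1)
            if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
                zc, lpc, gc = zc2, lpc2, gc2
            n1 += n2
            ok = ok2 and _no_uturn(zm, zp, pm, pp, inv_mass)
        return zm, pm, gm, zp, pp, gp, zc, lpc, gc, n1, ok

    for depth in range(max_depth):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            (z_minus, p_minus, grad_minus, _, _, _,
             z_cand, logp_cand, grad_cand, n_new, ok) = build_tree(z_minus, p_minus, grad_minus, -1, depth)
        else:
            (_, _, _, z_plus, p_plus, grad_plus,
             z_cand, logp_cand, grad_cand, n_new, ok) = build_tree(z_plus, p_plus, grad_plus, 1, depth)
        if ok and n_new > 0 and rng.random() < min(1.0, n_new / n_valid):
            z_new, logp_new, grad_new = z_cand, logp_cand, grad_cand
        n_valid += n_new
        if not ok or not _no_uturn(z_minus, z_plus, p_minus, p_plus, inv_mass):
            break

    accept_stat = sum_alpha / max(n_alpha, 1)
    return z_new, logp_new, grad_new, accept_stat, diverged
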