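"""Serial two-fold dilution with stochastic pipetting errors.

A titration series is produced by repeatedly mixing one pipetted volume of
the previous solution with one pipetted volume of fresh buffer.  Each
pipetting event is modelled as a normally distributed volume with mean equal
to the targeted volume and standard deviation ``cov * target_volume``.  The
realized concentration after step ``k`` is therefore

    c_k = c_{k-1} * N_a,k / (N_a,k + N_b,k)

a product of ratios of normal variables: a biased multiplicative random walk
whose variance and skew compound with the number of steps.  At ``cov = 0``
the series reduces exactly to the targeted geometric series
``c_starting * (1/2)**k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PipetteSpec", "DilutionSeries", "targeted_concentrations", "simulate_dilution_series"]

#: Number of dilution steps supported by common MST practice (16 capillaries).
DEFAULT_N_STEPS = 15


@dataclass(frozen=True)
class PipetteSpec:
    """Pipetting-event model: targeted volume (µl) and coefficient of variation.

    Both pipetting events of one dilution step (solution and buffer) share a
    single spec, i.e. equal mean and equal variance.
    """

    target_volume: float = 10.0
    cov: float = 0.0

    def __post_init__(self) -> None:
        if not self.target_volume > 0:
            raise ValueError(f"target_volume must be positive, got {self.target_volume}")
        if self.cov < 0:
            raise ValueError(f"cov must be non-negative, got {self.cov}")

    @property
    def volume_sd(self) -> float:
        """Standard deviation of a pipetted volume in µl."""
        return self.cov * self.target_volume

    @classmethod
    def from_volume_sd(cls, target_volume: float, volume_sd: float) -> "PipetteSpec":
        """Build a spec from an absolute volume standard deviation in µl."""
        if not target_volume > 0:
            raise ValueError(f"target_volume must be positive, got {target_volume}")
        return cls(target_volume=target_volume, cov=volume_sd / target_volume)


@dataclass(frozen=True)
class DilutionSeries:
    """Realized and targeted concentrations of one serial dilution (nM).

    Index 0 is the undiluted stock; the arrays have length ``n_steps + 1``.
    """

    c_starting: float
    n_steps: int
    concentrations: np.ndarray
    targeted: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        targ = np.asarray(self.targeted, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "targeted", targ)
        if conc.shape != (self.n_steps + 1,) or targ.shape != (self.n_steps + 1,):
            raise ValueError("concentration arrays must have length n_steps + 1")
        if not np.all(conc > 0):
            raise ValueError("all realized concentrations must be positive")


def targeted_concentrations(c_starting: float, n_steps: int) -> np.ndarray:
    """Targeted geometric series ``c_starting * (1/2)**k`` for k = 0..n_steps (nM)."""
    if not c_starting > 0:
        raise ValueError(f"c_starting must be positive, got {c_starting}")
    if n_steps < 0:
        raise ValueError(f"n_steps must be non-negative, got {n_steps}")
    return c_starting * 0.5 ** np.arange(n_steps + 1)


def _draw_positive_volumes(rng: np.random.Generator, pipette: PipetteSpec, shape: tuple) -> np.ndarray:
    """Draw pipetted volumes, rejection-resampling any non-positive draw.

    A physical volume cannot be negative; for any realistic CoV (< 0.25) the
    resampling branch is essentially never taken.
    """
    vols = rng.normal(pipette.target_volume, pipette.volume_sd, size=shape)
    bad = vols <= 0
    while np.any(bad):
        vols[bad] = rng.normal(pipette.target_volume, pipette.volume_sd, size=int(bad.sum()))
        bad = vols <= 0
    return vols


def simulate_dilution_series(
    c_starting: float,
    n_steps: int,
    pipette: PipetteSpec,
    rng_seed: int | np.random.Generator = 0,
) -> DilutionSeries:
    """Simulate one serial two-fold dilution with pipetting noise.

    Parameters
    ----------
    c_starting
        Stock concentration in nM.
    n_steps
        Number of dilution steps; the series has ``n_steps + 1`` concentrations.
    pipette
        Volume/CoV model shared by both pipetting events of every step.
    rng_seed
        Integer seed or a ``numpy.random.Generator`` (consumed in place).

    At ``cov = 0`` the realized series equals the targeted series to machine
    precision.
    """
    targeted = targeted_concentrations(c_starting, n_steps)
    rng = np.random.default_rng(rng_seed)
    if pipette.cov == 0 or n_steps == 0:
        realized = targeted.copy()
    else:
        # one (solution, buffer) volume pair per step, drawn in step order
        vols = _draw_positive_volumes(rng, pipette, (n_steps, 2))
        ratios = vols[:, 0] / (vols[:, 0] + vols[:, 1])
        realized = c_starting * np.concatenate([[1.0], np.cumprod(ratios)])
    return DilutionSeries(c_starting=c_starting, n_steps=n_steps, concentrations=realized, targeted=targeted)
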