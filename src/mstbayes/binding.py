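"""Law-of-mass-action binding response and free-energy conversion.

For a labelled partner at fixed concentration ``c_fl`` titrated with ligand
at concentration ``c``, the equilibrium fraction of labelled molecules in
complex is the physical root of the mass-action quadratic

    fb(c) = (c_fl + c + K_D - sqrt((c_fl + c + K_D)^2 - 4 c_fl c)) / (2 c_fl)

and the measured response interpolates between the unbound level ``U`` and
the fully bound level ``B``:

    response(c) = U + (B - U) * fb(c)

All concentrations are in nM throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BindingParams", "bound_fraction", "mass_action_response", "delta_g", "GAS_CONSTANT_KJ"]

#: Universal gas constant in kJ / (mol K).
GAS_CONSTANT_KJ = 8.31446261815324e-3

#: Standard temperature used for the van't Hoff conversion (K).
DEFAULT_TEMPERATURE_K = 297.15


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the binding response: K_D and c_fl in nM, U/B in response units."""

    kd: float
    u: float
    b: float
    c_fl: float

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if not self.c_fl > 0:
            raise ValueError(f"c_fl must be positive, got {self.c_fl}")
        if not (np.isfinite(self.u) and np.isfinite(self.b)):
            raise ValueError("u and b must be finite")


def bound_fraction(c, kd: float, c_fl: float):
    """Fraction of labelled partner bound at ligand concentration ``c`` (nM).

    Evaluated in the conjugate form ``2 c / (s + sqrt(s^2 - 4 c_fl c))`` with
    ``s = c_fl + c + K_D``, which avoids the catastrophic cancellation the
    textbook form suffers at trace ligand concentrations.  Clamped to [0, 1]
    against floating-point excursions.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("ligand concentration must be non-negative")
    s = c_fl + c + kd
    root = np.sqrt(np.maximum(s * s - 4.0 * c_fl * c, 0.0))
    return np.clip(2.0 * c / (s + root), 0.0, 1.0)


def mass_action_response(c, params: BindingParams):
    """Noise-free binding response ``U + (B - U) * fb(c)``.

    ``c`` may be a scalar or array of ligand concentrations in nM.
    """
    fb = bound_fraction(c, params.kd, params.c_fl)
    return params.u + (params.b - params.u) * fb


def delta_g(kd_nm: float, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Van't Hoff binding free energy ``R T ln K_D`` in kJ/mol.

    ``kd_nm`` is converted to molar against the 1 M reference state before
    taking the logarithm, so sub-molar affinities give negative energies.
    """
    kd_nm = np.asarray(kd_nm, dtype=float)
    if np.any(kd_nm <= 0):
        raise ValueError("K_D must be positive")
    if not temperature_k > 0:
        raise ValueError("temperature must be positive")
    out = GAS_CONSTANT_KJ * temperature_k * np.log(kd_nm * 1e-9)
    return float(out) if out.ndim == 0 else out
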