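"""Blood constitutive models.

Two rheologies are supported:

* a Newtonian fluid with constant dynamic viscosity, and
* the generalized power law (GPL) of Ballyk-type, a shear-thinning model
  that interpolates between a low-shear power-law regime and a high-shear
  Newtonian asymptote,

      mu(gamma) = lambda(gamma) * |gamma|^(n(gamma) - 1)
      lambda(gamma) = mu_inf + d_mu * exp[-(1 + |gamma|/a) * exp(-b/|gamma|)]
      n(gamma)      = n_inf  - d_n  * exp[-(1 + |gamma|/c) * exp(-d/|gamma|)]

The GPL constants are conventionally quoted in CGS units: ``lambda`` is a
consistency in poise so that the high-shear asymptote ``mu_inf = 0.035``
poise equals the usual Newtonian blood viscosity of 0.0035 Pa·s.
:func:`apparent_viscosity` performs the poise → Pa·s conversion so that both
models share SI units at the solver interface.

The model is a fit to steady rheometry over shear rates 0.1–1000 1/s; the
shear rate is clamped to that window before evaluation (the power-law factor
diverges as the shear rate goes to zero for n < 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NewtonianModel",
    "GeneralizedPowerLawModel",
    "shear_rate_magnitude",
    "gpl_lambda",
    "gpl_n",
    "apparent_viscosity",
]

#: density of whole blood, kg/m^3
BLOOD_DENSITY = 1060.0
#: Newtonian dynamic viscosity of whole blood, Pa·s
BLOOD_VISCOSITY = 0.0035

POISE_TO_PA_S = 0.1


@dataclass(frozen=True)
class NewtonianModel:
    """Constant-viscosity blood model (SI units)."""

    mu: float = BLOOD_VISCOSITY  # Pa·s
    rho: float = BLOOD_DENSITY  # kg/m^3

    name = "newtonian"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")

    def apparent_viscosity(self, gamma_dot):
        """Viscosity in Pa·s; independent of the shear rate."""
        return np.broadcast_to(self.mu, np.shape(gamma_dot)).copy() \
            if np.ndim(gamma_dot) else self.mu


@dataclass(frozen=True)
class GeneralizedPowerLawModel:
    """Shear-thinning generalized power law for whole blood.

    ``mu_inf`` and ``delta_mu`` are consistencies in poise; ``a``..``d`` are
    shape constants in 1/s; ``gamma_min``/``gamma_max`` bound the validity
    range of the underlying rheometric fit (1/s).
    """

    mu_inf: float = 0.035  # poise
    n_inf: float = 1.0
    delta_mu: float = 0.25  # poise
    delta_n: float = 0.45
    a: float = 50.0
    b: float = 3.0
    c: float = 50.0
    d: float = 4.0
    gamma_min: float = 0.1
    gamma_max: float = 1000.0
    rho: float = field(default=BLOOD_DENSITY)

    name = "generalized_power_law"

    def __post_init__(self) -> None:
        if self.mu_inf <= 0:
            raise ValueError("mu_inf must be positive")
        if not (0.0 < self.n_inf <= 1.0):
            raise ValueError("n_inf must lie in (0, 1]")
        if self.delta_mu < 0:
            raise ValueError("delta_mu must be non-negative")
        if not (0.0 <= self.delta_n < self.n_inf):
            raise ValueError("delta_n must lie in [0, n_inf)")
        if not (0.0 < self.gamma_min < self.gamma_max):
            raise ValueError("require 0 < gamma_min < gamma_max")

    def apparent_viscosity(self, gamma_dot):
        """Apparent viscosity in Pa·s at shear rate ``gamma_dot`` (1/s)."""
        g = np.clip(np.abs(np.asarray(gamma_dot, dtype=float)),
                    self.gamma_min, self.gamma_max)
        lam = gpl_lambda(g, self)
        n = gpl_n(g, self)
        mu_poise = lam * g ** (n - 1.0)
        out = mu_poise * POISE_TO_PA_S
        return float(out) if np.ndim(gamma_dot) == 0 else out


def _double_exponential(g, scale, decay):
    # exp[-(1 + g/scale) * exp(-decay/g)]; g is already clamped away from 0.
    return np.exp(-(1.0 + g / scale) * np.exp(-decay / g))


def gpl_lambda(gamma_dot, model: GeneralizedPowerLawModel):
    """Consistency factor lambda(gamma) in poise.

    Decreases monotonically from ``mu_inf + delta_mu`` at low shear to
    ``mu_inf`` at high shear.
    """
    g = np.abs(np.asarray(gamma_dot, dtype=float))
    lam = model.mu_inf + model.delta_mu * _double_exponential(g, model.a, model.b)
    return float(lam) if np.ndim(gamma_dot) == 0 else lam


def gpl_n(gamma_dot, model: GeneralizedPowerLawModel):
    """Power-law index n(gamma), rising from ``n_inf - delta_n`` to ``n_inf``."""
    g = np.abs(np.asarray(gamma_dot, dtype=float))
    n = model.n_inf - model.delta_n * _double_exponential(g, model.c, model.d)
    return float(n) if np.ndim(gamma_dot) == 0 else n


def shear_rate_magnitude(grad_u):
    """Shear-rate magnitude sqrt(2 D:D) from velocity gradient tensor(s).

    Parameters
    ----------
    grad_u : array, shape (..., 2, 2)
        Velocity gradient with component [i, j] = du_i/dx_j, in 1/s.

    Returns
    -------
    Scalar or array of shear-rate magnitudes, 1/s (non-negative).
    """
    G = np.asarray(grad_u, dtype=float)
    if G.shape[-2:] != (2, 2):
        raise ValueError("velocity gradient must have trailing shape (2, 2)")
    D = 0.5 * (G + np.swapaxes(G, -1, -2))
    gd = np.sqrt(2.0 * np.einsum("...ij,...ij->...", D, D))
    return float(gd) if G.ndim == 2 else gd


def apparent_viscosity(gamma_dot, model):
    """Apparent viscosity in Pa·s of either rheology at ``gamma_dot`` (1/s)."""
    return model.apparent_viscosity(gamma_dot)
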