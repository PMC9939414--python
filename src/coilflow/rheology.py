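"""Casson blood rheology with hematocrit-dependent yield stress.

Blood is modelled as a regularised Casson fluid.  The apparent dynamic
viscosity follows the correlation

    mu = 0.1 * ( sqrt(eta) + sqrt( tau_y * (1 - exp(-m*|gdot|)) / |gdot| ) )**2
    tau_y = (0.625 * H)**3

where ``H`` is the hematocrit fraction, ``eta`` the Casson plastic viscosity
in poise, ``tau_y`` the yield stress in dyn/cm**2, ``m`` (s) the exponential
regularisation constant that keeps the viscosity finite at vanishing shear,
and the leading 0.1 converts poise to Pa*s so that ``mu`` is returned in SI
units.  The hematocrit enters only through the yield stress: a higher red-cell
fraction raises ``tau_y`` and hence the low-shear viscosity, while the
infinite-shear viscosity ``0.1*eta`` is hematocrit-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyParams",
    "yield_stress",
    "casson_viscosity",
    "shear_rate_magnitude",
]


@dataclass(frozen=True)
class RheologyParams:
    """Blood rheology parameters.

    Attributes
    ----------
    H : float
        Hematocrit fraction in [0, 1); 0.35 and 0.45 are the two study values.
    eta : float
        Casson plastic viscosity, poise.  Default 0.035 poise gives an
        infinite-shear viscosity of 3.5 mPa*s, the standard high-shear value
        for whole blood.
    m : float
        Regularisation constant, s.  Larger values track the ideal Casson
        limit more closely at low shear but raise the zero-shear viscosity.
    rho : float
        Density, kg/m**3.
    newtonian : bool
        If True, the yield-stress term is switched off and the fluid is
        Newtonian with viscosity ``0.1*eta`` (used for benchmark runs).
    """

    H: float = 0.45
    eta: float = 0.035
    m: float = 100.0
    rho: float = 1060.0
    newtonian: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.H < 1.0:
            raise ValueError("hematocrit H must lie in [0, 1)")
        if self.eta <= 0 or self.m <= 0 or self.rho <= 0:
            raise ValueError("eta, m and rho must be positive")

    @property
    def tau_y(self) -> float:
        return 0.0 if self.newtonian else yield_stress(self.H)

    @property
    def mu_inf(self) -> float:
        """Infinite-shear dynamic viscosity, Pa*s."""
        return 0.1 * self.eta

    @property
    def mu_zero(self) -> float:
        """Zero-shear dynamic viscosity, Pa*s (regularised limit)."""
        return 0.1 * (np.sqrt(self.eta) + np.sqrt(self.tau_y * self.m)) ** 2


def yield_stress(H: float) -> float:
    """Casson yield stress tau_y = (0.625*H)**3 in dyn/cm**2.

    Strictly increasing in the hematocrit fraction ``H``; zero for plasma.
    """
    if not 0.0 <= H < 1.0:
        raise ValueError("hematocrit H must lie in [0, 1)")
    return (0.625 * H) ** 3


def casson_viscosity(gamma_dot, params: RheologyParams):
    """Apparent dynamic viscosity mu(gamma_dot) in Pa*s.

    Continuous at zero shear through the limit
    ``(1 - exp(-m*g))/g -> m``; strictly decreasing in ``gamma_dot`` whenever
    the yield stress is positive, and constant (``0.1*eta``) when it is zero.

    Parameters
    ----------
    gamma_dot : array_like
        Shear-rate magnitude, 1/s; must be non-negative.
    params : RheologyParams
    """
    params.validate()
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate magnitude must be non-negative")
    tau_y = params.tau_y
    if tau_y == 0.0:
        mu = np.full_like(g, 0.1 * params.eta)
        return mu if mu.ndim else float(mu)
    mg = params.m * g
    # (1 - exp(-m g))/g, series below 1e-8 to avoid 0/0
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(mg < 1e-8, params.m * (1.0 - 0.5 * mg), -np.expm1(-mg) / np.where(g > 0, g, 1.0))
    mu = 0.1 * (np.sqrt(params.eta) + np.sqrt(tau_y * factor)) ** 2
    return mu if mu.ndim else float(mu)


def shear_rate_magnitude(dudx, dudy, dvdx, dvdy):
    """Shear-rate magnitude sqrt(2 D:D) of a 2D velocity-gradient field.

    ``D`` is the symmetric rate-of-strain tensor; the result is frame
    invariant (zero for rigid rotation, ``|k|`` for simple shear with
    du/dy = k, ``2|a|`` for pure extension with du/dx = a = -dv/dy).
    """
    dudx = np.asarray(dudx, dtype=float)
    return np.sqrt(
        2.0 * (dudx**2 + np.asarray(dvdy, dtype=float) ** 2)
        + (np.asarray(dudy, dtype=float) + np.asarray(dvdx, dtype=float)) ** 2
    )
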