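"""Blatz-Ko hyperelasticity for lung parenchyma under radial symmetry.

The tissue is modelled as a compressible Blatz-Ko-type hyperelastic solid
with strain energy density (per unit reference volume, kPa)

    W(C) = c (I1 - 3) + (c / beta) (I3^(-beta) - 1)
         + c1 (I1 I3^(-1/3) - 3)^d1 + c3 (I3^(1/3) - 1)^d3,

where ``I1 = tr C`` and ``I3 = det C`` are invariants of the right
Cauchy-Green tensor ``C = F^T F``.  The shear-like modulus ``c`` and the
volumetric exponent ``beta`` map to the small-strain Young's modulus and
Poisson ratio through ``E = 4 c (1 + nu)`` and ``nu = beta / (1 + 2 beta)``.

Under spherically symmetric kinematics the deformation gradient is
``F = diag(lambda_r, lambda_t, lambda_t)`` with radial stretch
``lambda_r = d(phi)/dR`` and circumferential stretch
``lambda_t = phi / R``, so

    I1 = lambda_r^2 + 2 lambda_t^2,    I3 = (lambda_r lambda_t^2)^2,
    J  = lambda_r lambda_t^2.

First Piola-Kirchhoff effective stresses follow by differentiating W with
respect to the stretches: ``P_r = dW/dlambda_r`` and, because the two hoop
directions carry the same stretch, ``P_t = (1/2) dW/dlambda_t``.  The
pore-pressure (Terzaghi) contribution to the total stress is added in the
solver, not here.

All stresses and energies are in kPa; stretches are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParameters",
    "KinematicState",
    "elastic_constants",
    "strain_energy",
    "strain_energy_derivatives",
    "effective_stress_radial",
]


@dataclass(frozen=True)
class MaterialParameters:
    """Constitutive constants of the Blatz-Ko energy.

    Parameters
    ----------
    c : float
        Shear-like modulus (kPa), > 0.
    beta : float
        Volumetric exponent (dimensionless), > 0.
    c1 : float
        Deviatoric modulus (kPa), > 0.
    c3 : float
        Volumetric modulus (kPa), > 0.
    d1, d3 : int
        Integer exponents, fixed to 3 and 6; the tissue response is
        insensitive to them so they are not part of the sampled
        parameter space.
    """

    c: float
    beta: float
    c1: float
    c3: float
    d1: int = 3
    d3: int = 6

    def __post_init__(self) -> None:
        for name in ("c", "beta", "c1", "c3"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"MaterialParameters.{name} must be > 0")
        if self.d1 != 3 or self.d3 != 6:
            raise ValueError("exponents are fixed: d1 = 3, d3 = 6")


@dataclass(frozen=True)
class KinematicState:
    """Radially symmetric kinematic state given by the two stretches."""

    lambda_r: float
    lambda_t: float

    def __post_init__(self) -> None:
        if not (np.all(np.asarray(self.lambda_r) > 0.0) and np.all(np.asarray(self.lambda_t) > 0.0)):
            raise ValueError("stretches must be positive")

    @property
    def I1(self):
        return self.lambda_r**2 + 2.0 * self.lambda_t**2

    @property
    def J(self):
        return self.lambda_r * self.lambda_t**2

    @property
    def I3(self):
        return self.J**2


def elastic_constants(c: float, beta: float) -> tuple[float, float]:
    """Small-strain Young's modulus and Poisson ratio of the model.

    ``nu = beta / (1 + 2 beta)`` and ``E = 4 c (1 + nu)``.

    Returns
    -------
    (E, nu) : tuple of float
        Young's modulus in kPa and the (dimensionless) Poisson ratio,
        with 0 < nu < 0.5 for any beta > 0.
    """
    if not (c > 0.0 and beta > 0.0):
        raise ValueError("elastic_constants requires c > 0 and beta > 0")
    nu = beta / (1.0 + 2.0 * beta)
    E = 4.0 * c * (1.0 + nu)
    return E, nu


def _signed_power(x, d: int):
    # Literal reading of the energy: d1 is odd, so the deviatoric term may
    # be negative.  Integer powers already preserve sign for odd d; route
    # through sign*|x|^d so non-integer experimentation stays well-defined.
    return np.sign(x) * np.abs(x) ** d


def strain_energy(I1, I3, p: MaterialParameters):
    """Blatz-Ko strain energy density W(I1, I3) in kPa.

    Accepts scalars or numpy arrays; raises on any ``I3 <= 0`` (a
    non-physical, inverted configuration).
    """
    I1 = np.asarray(I1, dtype=float)
    I3 = np.asarray(I3, dtype=float)
    if np.any(I3 <= 0.0):
        raise ValueError("strain_energy requires I3 > 0")
    dev = I1 * I3 ** (-1.0 / 3.0) - 3.0
    vol = I3 ** (1.0 / 3.0) - 1.0
    W = (
        p.c * (I1 - 3.0)
        + (p.c / p.beta) * (I3 ** (-p.beta) - 1.0)
        + p.c1 * _signed_power(dev, p.d1)
        + p.c3 * vol**p.d3
    )
    return W if W.ndim else float(W)


def strain_energy_derivatives(I1, I3, p: MaterialParameters):
    """Partial derivatives (dW/dI1, dW/dI3) of the strain energy.

    Vectorized; used by the radial stress response and by the shell solver
    at quadrature points.
    """
    I1 = np.asarray(I1, dtype=float)
    I3 = np.asarray(I3, dtype=float)
    if np.any(I3 <= 0.0):
        raise ValueError("strain_energy_derivatives requires I3 > 0")
    dev = I1 * I3 ** (-1.0 / 3.0) - 3.0
    dev_pow = p.d1 * np.sign(dev) * np.abs(dev) ** (p.d1 - 1)
    vol = I3 ** (1.0 / 3.0) - 1.0
    W1 = p.c + p.c1 * dev_pow * I3 ** (-1.0 / 3.0)
    W3 = (
        -p.c * I3 ** (-p.beta - 1.0)
        + p.c1 * dev_pow * (-I1 / 3.0) * I3 ** (-4.0 / 3.0)
        + p.c3 * p.d3 * vol ** (p.d3 - 1) * (1.0 / 3.0) * I3 ** (-2.0 / 3.0)
    )
    return W1, W3


def effective_stress_radial(k: KinematicState, p: MaterialParameters):
    """First Piola-Kirchhoff effective stresses (P_r, P_t) in kPa.

    ``P_r = dW/dlambda_r`` and ``P_t = (1/2) dW/dlambda_t`` under the
    radial-symmetry parametrization (the factor 1/2 undoes the double
    counting of the two identical hoop directions).  Both vanish in the
    stress-free reference configuration.
    """
    lr = np.asarray(k.lambda_r, dtype=float)
    lt = np.asarray(k.lambda_t, dtype=float)
    return _stress_from_stretches(lr, lt, p)


def _stress_from_stretches(lr, lt, p: MaterialParameters):
    """Vectorized core of :func:`effective_stress_radial`."""
    I1 = lr**2 + 2.0 * lt**2
    I3 = (lr * lt**2) ** 2
    W1, W3 = strain_energy_derivatives(I1, I3, p)
    P_r = 2.0 * lr * (W1 + W3 * lt**4)
    P_t = 2.0 * lt * (W1 + W3 * lr**2 * lt**2)
    if P_r.ndim:
        return P_r, P_t
    return float(P_r), float(P_t)
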