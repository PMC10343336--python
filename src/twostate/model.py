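"""Mean-field free energy of a lattice fluid of two-state, size-switching particles.

The system is a binary mixture of solvent molecules and particles on a lattice
of equal sites.  Each particle resides in one of two internal states: a small
(S) state occupying one site (volume nu0, the unit of volume) or a large (L)
state occupying ``xi >= 1`` sites.  With volume fractions ``phiL`` and ``phiS``
the scaled particle number ``phi0 = phiL/xi + phiS`` is conserved.

Three dimensionless contributions (all in units of kB*T per lattice site) make
up the free energy:

* a lattice-sublattice mixing entropy, obtained by placing the L-particles on
  a sublattice of M/xi blocks and the S-particles and solvent on the remaining
  sites,
* a state-switching energy ``lam * phiS`` (``lam`` is the cost of switching a
  single particle from L to S),
* a particle-solvent contact term ``chi * (1 - phiL - phiS) * (phiL + phiS)``
  acting like a surface tension, blind to the internal state.

The entropy coefficient ``(1/xi - 1)`` vanishes at ``xi = 1``, so the equal-size
case needs no special treatment: the expression reduces exactly to standard
Bragg-Williams mixing of two distinguishable equal-size states.

Everything here is closed-form; solvers live in :mod:`twostate.equilibrium`
and :mod:`twostate.coexistence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = [
    "ModelParams",
    "StateComposition",
    "PhiSInterval",
    "Partials",
    "entropy_per_site",
    "interaction_per_site",
    "free_energy_per_site",
    "free_energy_partials",
    "feasible_interval",
]

# slack for validating compositions against closed-interval bounds
_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters (xi, lam, chi) defining one thermodynamic system.

    Parameters
    ----------
    xi : float
        Size ratio of the L-state to the S-state volume, ``xi >= 1``.
    lam : float
        Energy cost (units of kB*T) for one particle to switch from the
        L-state to the S-state.  Positive values penalize the S-state.
    chi : float
        Particle-solvent interaction strength (units of kB*T); ``1/chi``
        plays the role of temperature in phase diagrams.
    """

    xi: float
    lam: float
    chi: float

    def __post_init__(self):
        if not (np.isfinite(self.xi) and self.xi >= 1.0):
            raise DomainError(f"xi must be a finite real >= 1, got {self.xi}")
        if not np.isfinite(self.lam):
            raise DomainError(f"lam must be finite, got {self.lam}")
        if not np.isfinite(self.chi):
            raise DomainError(f"chi must be finite, got {self.chi}")


@dataclass(frozen=True)
class StateComposition:
    """A lattice composition (phiL, phiS).

    ``phiL`` and ``phiS`` are the volume fractions of sites occupied by L- and
    S-particles; the solvent fraction is ``1 - phiL - phiS``.  The scaled
    particle number ``phi0 = phiL/xi + phiS`` depends on the size ratio and is
    obtained from :meth:`phi0`.
    """

    phiL: float
    phiS: float

    def __post_init__(self):
        if not (-_TOL <= self.phiL <= 1.0 + _TOL):
            raise DomainError(f"0 <= phiL <= 1 violated: phiL={self.phiL}")
        if not (-_TOL <= self.phiS <= 1.0 + _TOL):
            raise DomainError(f"0 <= phiS <= 1 violated: phiS={self.phiS}")
        if self.phiL + self.phiS > 1.0 + _TOL:
            raise DomainError(
                f"phiL + phiS <= 1 violated: phiL+phiS={self.phiL + self.phiS}"
            )

    def phi0(self, p: ModelParams) -> float:
        """Scaled particle number ``phiL/xi + phiS`` for size ratio ``p.xi``."""
        return self.phiL / p.xi + self.phiS

    @classmethod
    def from_phi0(cls, phi0: float, phiS: float, p: ModelParams) -> "StateComposition":
        """Composition with ``phiL = xi*(phi0 - phiS)`` fixed by conservation."""
        return cls(phiL=p.xi * (phi0 - phiS), phiS=phiS)


@dataclass(frozen=True)
class PhiSInterval:
    """Closed interval of phiS values compatible with a given (phi0, xi)."""

    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo


def feasible_interval(phi0: float, p: ModelParams) -> PhiSInterval:
    """Interval of ``phiS`` compatible with ``phiL = xi*(phi0 - phiS) in [0, 1-phiS]``.

    For ``phi0 <= 1/xi`` the lower bound is 0; beyond that the lattice cannot
    hold all particles in the L-state and ``lo = (xi*phi0 - 1)/(xi - 1)``.
    """
    if not (0.0 <= phi0 <= 1.0):
        raise DomainError(f"phi0 must lie in [0, 1], got {phi0}")
    if p.xi > 1.0 and p.xi * phi0 > 1.0:
        lo = (p.xi * phi0 - 1.0) / (p.xi - 1.0)
    else:
        lo = 0.0
    return PhiSInterval(lo=lo, hi=min(phi0, 1.0))


def _xlogx(x):
    """x*log(x) with the continuous-limit convention 0 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape)
    pos = x > 0.0
    out[pos] = x[pos] * np.log(x[pos])
    if out.ndim == 0:
        return float(out)
    return out


def _entropy(phiL, phiS, xi):
    phiL = np.asarray(phiL, dtype=float)
    phiS = np.asarray(phiS, dtype=float)
    return (
        _xlogx(phiL) / xi
        + (1.0 / xi - 1.0) * _xlogx(1.0 - phiL)
        + _xlogx(1.0 - phiL - phiS)
        + _xlogx(phiS)
    )


def _interaction(phiL, phiS, chi):
    t = np.asarray(phiL, dtype=float) + np.asarray(phiS, dtype=float)
    return chi * (1.0 - t) * t


def _free_energy(phiL, phiS, p: ModelParams):
    return p.lam * np.asarray(phiS, dtype=float) + _entropy(phiL, phiS, p.xi) + _interaction(
        phiL, phiS, p.chi
    )


def entropy_per_site(c: StateComposition, p: ModelParams) -> float:
    """Dimensionless entropy density ``-S/(M kB)`` of the lattice-sublattice count.

    Finite and continuous on the closed feasible domain; every ``x log x``
    term is 0 at ``x = 0``.
    """
    return float(_entropy(c.phiL, c.phiS, p.xi))


def interaction_per_site(c: StateComposition, p: ModelParams) -> float:
    """Particle-solvent contact energy ``chi*(1 - phiL - phiS)*(phiL + phiS)``."""
    return float(_interaction(c.phiL, c.phiS, p.chi))


def free_energy_per_site(c: StateComposition, p: ModelParams) -> float:
    """Free energy per site ``f = lam*phiS + entropy + interaction`` (kB*T units)."""
    return float(_free_energy(c.phiL, c.phiS, p))


# ---------------------------------------------------------------------------
# Reduced (phi0, phiS) coordinates.
#
# Solvers substitute phiL = xi*(phi0 - phiS) and work with the quantities
#   u   = phiL                      (L-occupied fraction)
#   omu = 1 - u
#   omt = 1 - u - phiS              (solvent fraction)
# Passing these explicitly lets boundary-hugging callers compute them without
# cancellation (e.g. u = xi*d from the distance d to the all-S boundary).
# ---------------------------------------------------------------------------


def _quants(phi0, phiS, xi):
    u = xi * (phi0 - phiS)
    return u, 1.0 - u, 1.0 - u - phiS


def _f_reduced(phiS, u, omu, omt, p: ModelParams):
    """Free energy from precomputed occupancies (array-friendly)."""
    return (
        p.lam * np.asarray(phiS, dtype=float)
        + _xlogx(u) / p.xi
        + (1.0 / p.xi - 1.0) * _xlogx(omu)
        + _xlogx(omt)
        + _xlogx(phiS)
        + p.chi * np.asarray(omt, dtype=float) * (1.0 - np.asarray(omt, dtype=float))
    )


def _fS_reduced(phiS, u, omu, omt, p: ModelParams):
    """d f / d phiS at fixed phi0 (array-friendly; requires interior point)."""
    phiS = np.asarray(phiS, dtype=float)
    u = np.asarray(u, dtype=float)
    omu = np.asarray(omu, dtype=float)
    omt = np.asarray(omt, dtype=float)
    return (
        p.lam
        + np.log(phiS)
        - np.log(u)
        + (p.xi - 1.0) * (np.log(omt) - np.log(omu) - p.chi * (2.0 * omt - 1.0))
    )


def _f0_reduced(phiS, u, omu, omt, p: ModelParams):
    """d f / d phi0 at fixed phiS (array-friendly; requires u, omu, omt > 0)."""
    u = np.asarray(u, dtype=float)
    omu = np.asarray(omu, dtype=float)
    omt = np.asarray(omt, dtype=float)
    return (
        np.log(u)
        + (p.xi - 1.0) * np.log(omu)
        - p.xi * np.log(omt)
        + p.chi * p.xi * (2.0 * omt - 1.0)
    )


def _fS_scalar(phi0, phiS, p: ModelParams) -> float:
    u, omu, omt = _quants(phi0, phiS, p.xi)
    return (
        p.lam
        + math.log(phiS)
        - math.log(u)
        + (p.xi - 1.0) * (math.log(omt) - math.log(omu) - p.chi * (2.0 * omt - 1.0))
    )


def _second_partials(phiS, u, omu, omt, p: ModelParams):
    """(f_SS, f_S0, f_00) from the occupancies (array-friendly)."""
    xi, chi = p.xi, p.chi
    A = 1.0 / np.asarray(u, dtype=float)
    B = 1.0 / np.asarray(omu, dtype=float)
    C = 1.0 / np.asarray(omt, dtype=float)
    D = 1.0 / np.asarray(phiS, dtype=float)
    f_SS = D + xi * A + (xi - 1.0) ** 2 * C - xi * (xi - 1.0) * B - 2.0 * chi * (xi - 1.0) ** 2
    f_S0 = -xi * A + xi * (xi - 1.0) * B - xi * (xi - 1.0) * C + 2.0 * chi * xi * (xi - 1.0)
    f_00 = xi * A - xi * (xi - 1.0) * B + xi**2 * C - 2.0 * chi * xi**2
    return f_SS, f_S0, f_00


def _curvature_reduced(phiS, u, omu, omt, p: ModelParams):
    """Second total derivative d2f/dphi0^2 of the envelope at a stationary phiS.

    Implements ``f_00 - f_S0**2/f_SS`` in a regrouped form,

        D2 = [xi*A*(D + C - 2 chi) + D*H + H*E - G^2] / (D + xi*A + E),

    with A=1/u, B=1/(1-u), C=1/omt, D=1/phiS, which stays accurate when the
    optimum hugs a boundary (u or phiS many orders of magnitude below 1), where
    the naive difference of near-equal large terms loses all digits.
    """
    xi, chi = p.xi, p.chi
    A = 1.0 / np.asarray(u, dtype=float)
    B = 1.0 / np.asarray(omu, dtype=float)
    C = 1.0 / np.asarray(omt, dtype=float)
    D = 1.0 / np.asarray(phiS, dtype=float)
    E = (xi - 1.0) ** 2 * C - xi * (xi - 1.0) * B - 2.0 * chi * (xi - 1.0) ** 2
    G = xi * (xi - 1.0) * (B - C) + 2.0 * chi * xi * (xi - 1.0)
    H = xi**2 * C - xi * (xi - 1.0) * B - 2.0 * chi * xi**2
    num = xi * A * (D + C - 2.0 * chi) + D * H + H * E - G * G
    den = D + xi * A + E
    return num / den


@dataclass(frozen=True)
class Partials:
    """Closed-form partial derivatives of f in reduced (phi0, phiS) coordinates.

    ``f_S`` and ``f_0`` are the first partials at fixed phi0 and fixed phiS,
    respectively, of ``f(xi*(phi0 - phiS), phiS)``; ``f_SS``, ``f_S0`` and
    ``f_00`` are the second partials.  ``curvature`` is the second *total*
    phi0-derivative ``f_00 - f_S0**2/f_SS`` along the constrained optimum
    (meaningful where ``f_S = 0``).
    """

    f_S: float
    f_0: float
    f_SS: float
    f_S0: float
    f_00: float
    curvature: float


def free_energy_partials(c: StateComposition, p: ModelParams) -> Partials:
    """Analytic partial derivatives of the substituted free energy.

    The composition must be strictly inside the feasible domain (all logarithm
    arguments positive); at the boundary the derivatives diverge and a
    :class:`~twostate.exceptions.DomainError` is raised.
    """
    phiS = c.phiS
    phi0 = c.phi0(p)
    u, omu, omt = _quants(phi0, phiS, p.xi)
    for name, val in (("phiS", phiS), ("phiL", u), ("1-phiL", omu), ("1-phiL-phiS", omt)):
        if val <= 0.0:
            raise DomainError(f"derivatives diverge at the boundary: {name} = {val} <= 0")
    f_SS, f_S0, f_00 = _second_partials(phiS, u, omu, omt, p)
    return Partials(
        f_S=float(_fS_reduced(phiS, u, omu, omt, p)),
        f_0=float(_f0_reduced(phiS, u, omu, omt, p)),
        f_SS=float(f_SS),
        f_S0=float(f_S0),
        f_00=float(f_00),
        curvature=float(_curvature_reduced(phiS, u, omu, omt, p)),
    )
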