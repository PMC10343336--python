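"""Pressure-volume isotherms from the equilibrium free energy.

The scaled pressure follows from the envelope free energy by the lattice-gas
Legendre relation ``nu0*P = phi0 * df/dphi0 - f(phi0)``; isotherms are plotted
against the reduced volume per particle ``nu/nu0 = 1/phi0``.  Inside a
coexistence interval the common tangent replaces the tangent slope, which is
equivalent to the Maxwell equal-area rule and yields a constant plateau
pressure equal to minus the tangent intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coexistence import common_tangent
from .equilibrium import envelope_curve, envelope_f0, optimize_state_fraction
from .exceptions import CuspAmbiguityError, DomainError
from .model import ModelParams

__all__ = ["Isotherm", "pressure", "isotherm"]


@dataclass(frozen=True)
class Isotherm:
    """Scaled pressure nu0*P on a reduced-volume grid with coexistence plateaus."""

    params: ModelParams
    nu_over_nu0: np.ndarray
    v0P: np.ndarray
    on_plateau: np.ndarray
    plateaus: tuple  # ((nu_lo, nu_hi, pressure), ...) in increasing nu


def pressure(phi0: float, p: ModelParams, side: str | None = None,
             grid_n: int = 512) -> float:
    """Scaled pressure ``nu0*P = phi0*f'(phi0) - f(phi0)`` at one composition.

    At a state-jump cusp the derivative is one-sided; there the two deepest
    minima are degenerate and a branch must be chosen explicitly with
    ``side='low'`` (smaller phiS) or ``side='high'``; otherwise a
    :class:`CuspAmbiguityError` is raised.
    """
    if not 0.0 < phi0 < 1.0:
        raise DomainError(f"phi0 must lie in (0, 1), got {phi0}")
    eq = optimize_state_fraction(phi0, p, grid_n=grid_n)
    if eq.is_degenerate:
        if side is None:
            raise CuspAmbiguityError(
                f"phi0={phi0} sits at a state-jump cusp; pass side='low' or side='high'"
            )
        from .equilibrium import _local_minima

        minima = _local_minima(phi0, p, grid_n)
        best2 = sorted(minima, key=lambda c: c.f)[:2]
        best2.sort(key=lambda c: c.phiS)
        c = best2[0] if side == "low" else best2[-1]
        from .model import _f0_reduced

        fp = float(_f0_reduced(c.phiS, c.u, c.omu, c.omt, p))
        return phi0 * fp - c.f
    f, fp = envelope_f0(phi0, p, grid_n=grid_n)
    return phi0 * fp - f


def isotherm(p: ModelParams, nu_grid, phi0_grid=None, grid_n: int = 512) -> Isotherm:
    """Equilibrium isotherm nu0*P versus nu/nu0 with Maxwell plateaus.

    Coexistence intervals are taken from the common-tangent construction on a
    dense envelope; wherever ``phi0 = nu0/nu`` falls inside one, the constant
    coexistence pressure (minus the tangent intercept) is substituted.
    """
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(nu <= 1.0):
        raise DomainError("nu/nu0 grid must be > 1 (phi0 = nu0/nu must be < 1)")
    if phi0_grid is None:
        phi0_grid = np.linspace(1e-3, 1.0 - 1e-3, 2001)
    curve = envelope_curve(p, phi0_grid, grid_n=grid_n, refine_jumps=False)
    coex = common_tangent(curve, p)
    phi0s = 1.0 / nu
    v0P = np.empty_like(phi0s)
    on_plateau = np.zeros(phi0s.shape, dtype=bool)
    for k, q in enumerate(phi0s):
        inside = next(
            (cx for cx in coex if cx.phi0_dilute < q < cx.phi0_dense), None
        )
        if inside is not None:
            v0P[k] = inside.pressure
            on_plateau[k] = True
        else:
            v0P[k] = pressure(q, p, side="low", grid_n=grid_n)
    plateaus = tuple(
        sorted((1.0 / cx.phi0_dense, 1.0 / cx.phi0_dilute, cx.pressure) for cx in coex)
    )
    return Isotherm(params=p, nu_over_nu0=nu, v0P=v0P, on_plateau=on_plateau,
                    plateaus=plateaus)
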