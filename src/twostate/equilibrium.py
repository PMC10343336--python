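"""Global minimization of the free energy over the internal state partition.

For fixed scaled particle number ``phi0`` the equilibrium split between S- and
L-particles is the global minimizer ``phiS_opt`` of ``f(xi*(phi0-phiS), phiS)``
over the feasible phiS interval.  The stationarity condition is transcendental
and can have several roots (two competing minima drive the discontinuous state
switching seen at large chi), so the solver scans the interval densely, signs
the analytic derivative, polishes every bracketed root, and keeps the deepest
minimum.  Scanning uses a uniform grid augmented with geometrically spaced
points near both interval ends, because at strongly negative (positive) lam
the minimizer approaches the all-S (all-L) boundary exponentially closely.

The minimized free energy defines the envelope curve f(phi0), whose kinks
(discontinuities of phiS_opt) are located by :func:`detect_state_jump` from
the equal-depth condition of the two competing minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, JumpNotFoundError
from .model import (
    ModelParams,
    _curvature_reduced,
    _f0_reduced,
    _f_reduced,
    _fS_reduced,
    _quants,
    _second_partials,
    feasible_interval,
)

__all__ = [
    "EquilibriumPoint",
    "FreeEnergyCurve",
    "SlopeResult",
    "StateJump",
    "optimize_state_fraction",
    "envelope_curve",
    "detect_state_jump",
    "initial_slope",
]

_XTOL = 1e-14  # absolute phiS tolerance for root polishing


@dataclass(frozen=True)
class EquilibriumPoint:
    """Equilibrium state split at one phi0: the global minimizer and its value."""

    phi0: float
    phiS_opt: float
    phiL_opt: float
    f_opt: float
    n_local_minima: int
    is_degenerate: bool


@dataclass(frozen=True)
class StateJump:
    """A discontinuity of phiS_opt(phi0): two equally deep minima coexist."""

    phi0_jump: float
    phiS_low: float
    phiS_high: float
    f_low: float
    f_high: float


@dataclass
class FreeEnergyCurve:
    """Envelope free energy f(phi0) sampled on a grid, with jump locations."""

    params: ModelParams
    phi0: np.ndarray
    phiS_opt: np.ndarray
    phiL_opt: np.ndarray
    f: np.ndarray
    n_local_minima: np.ndarray
    is_degenerate: np.ndarray
    jumps: list = field(default_factory=list)


@dataclass(frozen=True)
class SlopeResult:
    """Initial slope s = d phiS_opt/d phi0 at phi0 = 0."""

    s: float


class _Candidate:
    """An interior stationary minimum in boundary-accurate coordinates."""

    __slots__ = ("phiS", "u", "omu", "omt", "f")

    def __init__(self, phiS, u, omu, omt, p):
        self.phiS = phiS
        self.u = u
        self.omu = omu
        self.omt = omt
        self.f = float(_f_reduced(phiS, u, omu, omt, p))


def _fS_near_hi(d, phi0, p):
    """f_S at phiS = phi0 - d (distance d from the all-S boundary)."""
    xi, chi = p.xi, p.chi
    phiS = phi0 - d
    u = xi * d
    omu = 1.0 - u
    omt = (1.0 - phi0) - (xi - 1.0) * d
    return (
        p.lam
        + math.log(phiS)
        - math.log(u)
        + (xi - 1.0) * (math.log(omt) - math.log(omu) - chi * (2.0 * omt - 1.0))
    )


def _fS_near_lo(d, phi0, lo, p):
    """f_S at phiS = lo + d when lo > 0 (solvent fraction omt = (xi-1)*d)."""
    xi, chi = p.xi, p.chi
    phiS = lo + d
    u = xi * (phi0 - lo) - xi * d
    omu = lo + xi * d
    omt = (xi - 1.0) * d
    return (
        p.lam
        + math.log(phiS)
        - math.log(u)
        + (xi - 1.0) * (math.log(omt) - math.log(omu) - chi * (2.0 * omt - 1.0))
    )


def _fS_interior(x, phi0, p):
    xi, chi = p.xi, p.chi
    u = xi * (phi0 - x)
    omu = 1.0 - u
    omt = omu - x
    return (
        p.lam
        + math.log(x)
        - math.log(u)
        + (xi - 1.0) * (math.log(omt) - math.log(omu) - chi * (2.0 * omt - 1.0))
    )


def _candidate_from_phiS(phiS, phi0, p):
    u, omu, omt = _quants(phi0, phiS, p.xi)
    return _Candidate(phiS, u, omu, omt, p)


def _local_minima(phi0, p, grid_n=512):
    """All interior local minima of phiS -> f at fixed phi0, sorted by phiS.

    f_S runs from -inf at the lower interval end to +inf at the upper end, so
    every minimum is interior.  Roots are bracketed on a uniform grid extended
    by geometric offsets from both ends and polished with Brent's method; the
    off-grid brackets adjacent to the ends are solved in log-distance to the
    boundary so that exponentially boundary-hugging minima keep full relative
    accuracy in the small occupancy.
    """
    iv = feasible_interval(phi0, p)
    lo, hi, w = iv.lo, iv.hi, iv.width
    if w <= 1e-15:
        return [_candidate_from_phiS(hi, phi0, p)]
    offs = w * 10.0 ** (-np.arange(2.0, 14.0))
    xs = np.unique(
        np.concatenate([lo + w * np.arange(1, grid_n + 1) / (grid_n + 1), lo + offs, hi - offs])
    )
    xs = xs[(xs > lo) & (xs < hi)]
    u, omu, omt = _quants(phi0, xs, p.xi)
    ok = (u > 0) & (omu > 0) & (omt > 0) & (xs > 0)
    xs, u, omu, omt = xs[ok], u[ok], omu[ok], omt[ok]
    vals = np.asarray(_fS_reduced(xs, u, omu, omt, p))

    roots = []
    # boundary-hugging root below xs[0]
    if vals[0] > 0.0:
        if lo == 0.0:
            g = lambda v: _fS_interior(math.exp(v), phi0, p)
        else:
            g = lambda v: _fS_near_lo(math.exp(v), phi0, lo, p)
        v_hi = math.log(xs[0] - lo)
        v_lo = max(v_hi - 600.0, -700.0)
        if g(v_lo) < 0.0:
            v = brentq(g, v_lo, v_hi, xtol=1e-13)
            d = math.exp(v)
            if lo == 0.0:
                roots.append(_candidate_from_phiS(d, phi0, p))
            else:
                xi = p.xi
                roots.append(
                    _Candidate(lo + d, xi * (phi0 - lo) - xi * d, lo + xi * d, (xi - 1.0) * d, p)
                )
    # interior brackets
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(_fS_interior, xs[i], xs[i + 1], args=(phi0, p), xtol=_XTOL)
        roots.append(_candidate_from_phiS(r, phi0, p))
    # boundary-hugging root above xs[-1] (phiS -> phi0, all-S)
    if vals[-1] < 0.0:
        g = lambda v: _fS_near_hi(math.exp(v), phi0, p)
        v_hi = math.log(hi - xs[-1])
        v_lo = max(v_hi - 600.0, -700.0)
        if g(v_lo) > 0.0:
            v = brentq(g, v_lo, v_hi, xtol=1e-13)
            d = math.exp(v)
            xi = p.xi
            roots.append(
                _Candidate(phi0 - d, xi * d, 1.0 - xi * d, (1.0 - phi0) - (xi - 1.0) * d, p)
            )
        else:
            # minimum below double resolution of the boundary: clamp to it
            roots.append(_Candidate(hi, 0.0, 1.0, 1.0 - phi0, p))
    # keep minima only (f_SS >= 0); guard the clamped boundary case
    minima = []
    for c in roots:
        if c.u <= 0.0 or c.phiS <= 0.0:
            minima.append(c)
            continue
        f_SS, _, _ = _second_partials(c.phiS, c.u, c.omu, c.omt, p)
        if f_SS >= 0.0:
            minima.append(c)
    minima.sort(key=lambda c: c.phiS)
    return minima


def optimize_state_fraction(
    phi0: float,
    p: ModelParams,
    grid_n: int = 512,
    tol_degenerate: float = 1e-9,
) -> EquilibriumPoint:
    """Global minimizer of the constrained free energy at fixed phi0.

    Scans the feasible phiS interval on ``grid_n`` points (plus geometric
    boundary refinement), polishes every sign change of the analytic
    derivative, and returns the deepest minimum.  ``is_degenerate`` is set
    when the two best distinct minima agree in f within ``tol_degenerate``;
    ties report the smaller-phiS minimizer for deterministic output.
    """
    if not (0.0 < phi0 <= 1.0):
        raise DomainError(f"phi0 must lie in (0, 1], got {phi0}")
    if grid_n < 64:
        raise DomainError(f"grid_n must be >= 64, got {grid_n}")
    minima = _local_minima(phi0, p, grid_n)
    best = min(minima, key=lambda c: (c.f, c.phiS))
    is_degenerate = False
    sep = max(1e-6 * (feasible_interval(phi0, p).width or 1.0), 10 * _XTOL)
    others = [c for c in minima if abs(c.phiS - best.phiS) > sep]
    if others:
        second = min(others, key=lambda c: c.f)
        is_degenerate = (second.f - best.f) < tol_degenerate
        if is_degenerate and second.phiS < best.phiS:
            best = second
    return EquilibriumPoint(
        phi0=phi0,
        phiS_opt=best.phiS,
        phiL_opt=p.xi * (phi0 - best.phiS),
        f_opt=best.f,
        n_local_minima=len(minima),
        is_degenerate=is_degenerate,
    )


def envelope_curve(
    p: ModelParams,
    phi0_grid,
    grid_n: int = 512,
    jump_factor: float = 10.0,
    refine_jumps: bool = True,
) -> FreeEnergyCurve:
    """Envelope free energy f(phi0) = min over phiS, sampled on ``phi0_grid``.

    Neighbor pairs whose change in phiS_opt exceeds ``jump_factor`` times the
    median neighbor step are flagged as discontinuities and (optionally)
    refined by :func:`detect_state_jump`.
    """
    phi0_grid = np.asarray(phi0_grid, dtype=float)
    if phi0_grid.ndim != 1 or len(phi0_grid) < 2 or np.any(np.diff(phi0_grid) <= 0):
        raise DomainError("phi0_grid must be a strictly increasing 1-D grid")
    if phi0_grid[0] <= 0.0 or phi0_grid[-1] > 1.0:
        raise DomainError("phi0_grid must lie within (0, 1]")
    pts = [optimize_state_fraction(q, p, grid_n=grid_n) for q in phi0_grid]
    phiS = np.array([e.phiS_opt for e in pts])
    curve = FreeEnergyCurve(
        params=p,
        phi0=phi0_grid,
        phiS_opt=phiS,
        phiL_opt=np.array([e.phiL_opt for e in pts]),
        f=np.array([e.f_opt for e in pts]),
        n_local_minima=np.array([e.n_local_minima for e in pts]),
        is_degenerate=np.array([e.is_degenerate for e in pts]),
    )
    steps = np.abs(np.diff(phiS))
    med = np.median(steps)
    thresh = jump_factor * max(med, 1e-12)
    for i in np.nonzero(steps > thresh)[0]:
        bracket = (phi0_grid[i], phi0_grid[i + 1])
        if refine_jumps:
            try:
                curve.jumps.append(detect_state_jump(p, bracket, grid_n=grid_n))
            except JumpNotFoundError:
                pass
        else:
            mid = 0.5 * (bracket[0] + bracket[1])
            curve.jumps.append(
                StateJump(mid, min(phiS[i], phiS[i + 1]), max(phiS[i], phiS[i + 1]), np.nan, np.nan)
            )
    return curve


def detect_state_jump(p: ModelParams, bracket, grid_n: int = 512, tol: float = 1e-10) -> StateJump:
    """Locate a discontinuity of phiS_opt(phi0) inside ``bracket``.

    First narrows the bracket by bisection on which competing branch holds the
    global minimum, then solves the equal-depth condition
    ``f(minimum on low-phiS branch) = f(minimum on high-phiS branch)`` by
    Brent's method, tracking both branch minima by local polishing.
    Raises :class:`JumpNotFoundError` when phiS_opt is continuous in the
    bracket.
    """
    a, b = float(bracket[0]), float(bracket[1])
    if not 0.0 < a < b <= 1.0:
        raise DomainError(f"invalid bracket {bracket}")
    ea = optimize_state_fraction(a, p, grid_n=grid_n)
    eb = optimize_state_fraction(b, p, grid_n=grid_n)
    sep = abs(ea.phiS_opt - eb.phiS_opt)
    if sep < 1e-4:
        raise JumpNotFoundError(
            f"phiS_opt changes by only {sep:.2e} over {bracket}; no discontinuity"
        )
    sA, sB = ea.phiS_opt, eb.phiS_opt
    # bisect on branch membership of the global minimizer
    while b - a > 1e-6:
        mid = 0.5 * (a + b)
        em = optimize_state_fraction(mid, p, grid_n=grid_n)
        if abs(em.phiS_opt - sA) <= abs(em.phiS_opt - sB):
            a, sA = mid, em.phiS_opt
        else:
            b, sB = mid, em.phiS_opt
    seeds = {"A": sA, "B": sB}

    def depth_diff(q):
        minima = _local_minima(q, p, grid_n)
        if len(minima) < 2:
            raise JumpNotFoundError(f"only one free-energy minimum at phi0={q}")
        cA = min(minima, key=lambda c: abs(c.phiS - seeds["A"]))
        cB = min(minima, key=lambda c: abs(c.phiS - seeds["B"]))
        if cA is cB:
            raise JumpNotFoundError(f"competing branches merged at phi0={q}")
        seeds["A"], seeds["B"] = cA.phiS, cB.phiS
        return cA.f - cB.f

    da, db = depth_diff(a), depth_diff(b)
    if da == 0.0:
        q_jump = a
    elif db == 0.0:
        q_jump = b
    elif da * db > 0.0:
        # branches re-polished consistently; the kink sits between a and b
        q_jump = 0.5 * (a + b)
    else:
        q_jump = brentq(depth_diff, a, b, xtol=tol)
    depth_diff(q_jump)
    minima = _local_minima(q_jump, p, grid_n)
    cA = min(minima, key=lambda c: abs(c.phiS - seeds["A"]))
    cB = min(minima, key=lambda c: abs(c.phiS - seeds["B"]))
    lo_c, hi_c = (cA, cB) if cA.phiS < cB.phiS else (cB, cA)
    return StateJump(
        phi0_jump=q_jump,
        phiS_low=lo_c.phiS,
        phiS_high=hi_c.phiS,
        f_low=lo_c.f,
        f_high=hi_c.f,
    )


def initial_slope(p: ModelParams) -> SlopeResult:
    """Closed-form dilute-limit slope of the state distribution.

    ``s = 1 / (1 + (1/xi) * exp(lam - chi*(xi - 1)))`` is the S-state share of
    particles added to an almost empty lattice: lam suppresses the S-state,
    solvent tension chi (times the size difference) promotes it, and the 1/xi
    factor is the entropic weight of the sparser L sublattice.
    """
    arg = p.lam - p.chi * (p.xi - 1.0)
    if arg > 700.0:
        return SlopeResult(s=0.0)
    return SlopeResult(s=1.0 / (1.0 + math.exp(arg) / p.xi))


def _best_candidate(phi0, p, grid_n=512):
    """Global-minimum _Candidate with boundary-accurate occupancies."""
    minima = _local_minima(phi0, p, grid_n)
    return min(minima, key=lambda c: (c.f, c.phiS))


def envelope_f0(phi0: float, p: ModelParams, grid_n: int = 512):
    """Envelope value and total derivative (f, df/dphi0) at one phi0.

    By the envelope theorem df/dphi0 equals the partial derivative at fixed
    phiS evaluated at the optimum.  When the optimizer clamps to the all-S
    boundary (u below double resolution) the all-S branch derivative is used.
    """
    c = _best_candidate(phi0, p, grid_n)
    if c.u <= 0.0:
        fp = p.lam + math.log(phi0) - math.log(1.0 - phi0) + p.chi * (1.0 - 2.0 * phi0)
    else:
        fp = float(_f0_reduced(c.phiS, c.u, c.omu, c.omt, p))
    return c.f, fp


def envelope_curvature(phi0: float, p: ModelParams, grid_n: int = 512) -> float:
    """Second total derivative of the envelope free energy at one phi0."""
    c = _best_candidate(phi0, p, grid_n)
    if c.u <= 0.0:  # all-S limit
        return 1.0 / phi0 + 1.0 / (1.0 - phi0) - 2.0 * p.chi
    return float(_curvature_reduced(c.phiS, c.u, c.omu, c.omt, p))
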