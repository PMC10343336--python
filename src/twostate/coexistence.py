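"""Phase coexistence: common tangents, spinodals, critical points, phase diagrams.

Coexistence on the envelope free energy f(phi0) follows the common-tangent
construction: two compositions coexist when they share the slope (chemical
potential) and the tangent line (exchange grand potential).  Candidate
intervals come from the lower convex hull of the sampled curve; each hull gap
is refined by matching tangent intercepts, using envelope-theorem derivatives
so that no numerical differentiation of f is needed.

The spinodal is the locus where the second *total* derivative of the envelope
(along the re-optimized state split) vanishes; the critical point at fixed
(lam, xi) solves stationarity in phiS together with vanishing second and third
total phi0-derivatives, found by bisection on chi of the minimal curvature and
polished with a damped Newton (scipy's hybr) iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .equilibrium import (
    FreeEnergyCurve,
    envelope_curvature,
    envelope_curve,
    envelope_f0,
    optimize_state_fraction,
)
from .exceptions import ConvergenceError, DomainError, ResolutionError
from .model import ModelParams

__all__ = [
    "CoexistenceResult",
    "SpinodalPoints",
    "CriticalPoint",
    "PhaseDiagram",
    "common_tangent",
    "spinodal_points",
    "critical_point",
    "phase_diagram",
]


@dataclass(frozen=True)
class CoexistenceResult:
    """A pair of coexisting compositions with their common tangent."""

    phi0_dilute: float
    phi0_dense: float
    slope: float
    intercept: float
    phiS_dilute: float
    phiS_dense: float
    pressure: float
    residual: float


@dataclass(frozen=True)
class SpinodalPoints:
    """Roots of the envelope curvature at fixed (chi, lam, xi)."""

    params: ModelParams
    roots: tuple


@dataclass(frozen=True)
class CriticalPoint:
    """Solution (chi*, phi0_c, phiS_c) of the three critical-point conditions."""

    chi_star: float
    phi0_c: float
    phiS_c: float
    residual: float


@dataclass
class PhaseDiagram:
    """Binodal, spinodal and critical data over a chi grid, plus a state heat map."""

    lam: float
    xi: float
    chi_grid: np.ndarray
    critical: CriticalPoint
    binodals: list = field(default_factory=list)  # (chi, [CoexistenceResult, ...])
    spinodals: list = field(default_factory=list)  # (chi, SpinodalPoints)
    phi0_grid: np.ndarray | None = None
    heatmap: np.ndarray | None = None  # phiS_opt/phi0, shape (len(chi), len(phi0))


def _lower_hull_indices(x, y):
    """Indices of the lower convex hull of the sorted curve (x, y)."""
    hull = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = (x[i1] - x[i0]) * (y[i] - y[i0]) - (x[i] - x[i0]) * (y[i1] - y[i0])
            if cross <= 0.0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def common_tangent(curve: FreeEnergyCurve, p: ModelParams, refine: bool = True,
                   tol: float = 1e-8) -> list[CoexistenceResult]:
    """Coexisting composition pairs from the sampled envelope free energy.

    Builds the lower convex hull of (phi0, f); every maximal hull gap marks a
    non-convex stretch and yields one coexistence interval.  With ``refine``
    the two tangency conditions are solved exactly: for a trial slope m the
    touching points on either side are roots of f'(phi0) = m near the hull
    contacts, and m is adjusted by Brent's method until both tangent
    intercepts agree.  Raises :class:`ResolutionError` for a hull gap ending
    at the grid boundary (the grid window is too narrow).
    """
    x, y = curve.phi0, curve.f
    hull = _lower_hull_indices(x, y)
    results = []
    grid_n = 512
    for k in range(len(hull) - 1):
        i, j = hull[k], hull[k + 1]
        if j <= i + 1:
            continue
        # ignore float-noise gaps (curve rises above the hull chord in a true gap)
        chord = y[i] + (y[j] - y[i]) * (x[i + 1 : j] - x[i]) / (x[j] - x[i])
        if np.max(y[i + 1 : j] - chord) < 1e-11:
            continue
        if i == 0 or j == len(x) - 1:
            raise ResolutionError(
                f"coexistence interval touches the grid boundary at phi0={x[i]:.4g}"
                f"..{x[j]:.4g}; widen or refine the phi0 grid"
            )
        x1, x2 = x[i], x[j]
        m = (y[j] - y[i]) / (x2 - x1)
        if not refine:
            c = y[i] - m * x1
            results.append(_assemble_result(x1, x2, m, c, p, np.nan, grid_n))
            continue
        dl = max(i - 5, 0)
        dr = min(j + 5, len(x) - 1)
        wins = ((x[dl], min(x[i + 5], x[j - 1])), (max(x[j - 5], x[i + 1]), x[dr]))

        fps = {}

        def fp(q):
            if q not in fps:
                fps[q] = envelope_f0(q, p, grid_n)
            return fps[q]

        def touch(m_try, win):
            g = lambda q: fp(q)[1] - m_try
            ga, gb = g(win[0]), g(win[1])
            if ga * gb > 0.0:
                return None
            return brentq(g, win[0], win[1], xtol=1e-13)

        def intercept_gap(m_try):
            q1 = touch(m_try, wins[0])
            q2 = touch(m_try, wins[1])
            if q1 is None or q2 is None:
                return None
            c1 = fp(q1)[0] - m_try * q1
            c2 = fp(q2)[0] - m_try * q2
            return c1 - c2, q1, q2

        # bracket the slope using f' at the window ends
        m_lo = max(fp(wins[0][0])[1], fp(wins[1][0])[1])
        m_hi = min(fp(wins[0][1])[1], fp(wins[1][1])[1])
        refined = None
        if m_lo < m_hi:
            glo = intercept_gap(m_lo)
            ghi = intercept_gap(m_hi)
            if glo and ghi and glo[0] * ghi[0] <= 0.0:
                m_star = brentq(lambda mm: intercept_gap(mm)[0], m_lo, m_hi, xtol=1e-14)
                refined = intercept_gap(m_star)
                m = m_star
        if refined is None:
            # fall back to the hull contacts (within 2 grid steps of the truth)
            c = y[i] - m * x1
            results.append(_assemble_result(x1, x2, m, c, p, np.nan, grid_n))
            continue
        gap, q1, q2 = refined
        f1, fp1 = fp(q1)
        f2, fp2 = fp(q2)
        c = f1 - m * q1
        chord_slope = (f2 - f1) / (q2 - q1)
        residual = max(abs(fp1 - chord_slope), abs(fp2 - chord_slope), abs(gap))
        results.append(_assemble_result(q1, q2, m, c, p, residual, grid_n))
    return results


def _assemble_result(q1, q2, m, c, p, residual, grid_n=512):
    """Assemble a CoexistenceResult, attaching per-phase state fractions."""
    e1 = optimize_state_fraction(q1, p, grid_n=grid_n)
    e2 = optimize_state_fraction(q2, p, grid_n=grid_n)
    return CoexistenceResult(
        phi0_dilute=q1,
        phi0_dense=q2,
        slope=m,
        intercept=c,
        phiS_dilute=e1.phiS_opt,
        phiS_dense=e2.phiS_opt,
        pressure=-c,
        residual=residual,
    )


def spinodal_points(p: ModelParams, phi0_window=(1e-4, 1.0 - 1e-4), n: int = 801,
                    grid_n: int = 512) -> SpinodalPoints:
    """Zeros of the envelope curvature d2f/dphi0^2 inside ``phi0_window``.

    Sign changes on an ``n``-point scan are polished by Brent bisection to
    better than 1e-8 in phi0.  Returns an empty tuple when the curvature is
    positive throughout (chi below the critical value).
    """
    a, b = phi0_window
    if not (0.0 < a < b < 1.0):
        raise DomainError(f"phi0_window must lie inside (0, 1), got {phi0_window}")
    grid = np.linspace(a, b, n)
    vals = np.array([envelope_curvature(q, p, grid_n) for q in grid])
    roots = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(lambda q: envelope_curvature(q, p, grid_n), grid[i], grid[i + 1],
                   xtol=1e-10)
        roots.append(r)
    return SpinodalPoints(params=p, roots=tuple(roots))


def _min_curvature(chi, lam, xi, phi0_grid, grid_n):
    p = ModelParams(xi=xi, lam=lam, chi=chi)
    vals = np.array([envelope_curvature(q, p, grid_n) for q in phi0_grid])
    i = int(np.argmin(vals))
    return vals[i], phi0_grid[i]


def _d3(phi0, p, grid_n, h=1e-4):
    """Third total derivative of the envelope: Richardson-extrapolated
    central difference of the analytic second total derivative."""
    d2 = lambda q: envelope_curvature(q, p, grid_n)
    return (8.0 * (d2(phi0 + h) - d2(phi0 - h)) - (d2(phi0 + 2 * h) - d2(phi0 - 2 * h))) / (
        12.0 * h
    )


def critical_point(lam: float, xi: float, init=None, grid_n: int = 512,
                   scan_n: int = 161, tol: float = 1e-8) -> CriticalPoint:
    """Critical point (chi*, phi0_c, phiS_c) at fixed (lam, xi).

    The conditions are stationarity of f in phiS (enforced by the inner global
    optimization) plus vanishing second and third total phi0-derivatives of
    the envelope.  Seeding: bisection on chi of the minimal envelope curvature
    (the smallest chi at which the curvature first touches zero), with the
    minimizing phi0 as composition seed; ``init=(chi0, phi00)`` overrides.
    The seed is polished by a damped Newton iteration on (chi, phi0).
    Raises :class:`ConvergenceError` with the best residual on failure.
    """
    xi = float(xi)
    lam = float(lam)
    ModelParams(xi=xi, lam=lam, chi=0.0)  # validate
    phi0s = np.linspace(0.005, 0.995, scan_n)
    if init is not None:
        chi0, p0 = float(init[0]), float(init[1])
    else:
        chis = np.geomspace(0.05, 16.0, 30)
        m_prev, _ = _min_curvature(chis[0], lam, xi, phi0s, grid_n)
        if m_prev < 0.0:
            lo_chi, hi_chi = chis[0] / 4.0, chis[0]
        else:
            lo_chi = hi_chi = None
            for c in chis[1:]:
                m, _ = _min_curvature(c, lam, xi, phi0s, grid_n)
                if m < 0.0:
                    hi_chi = c
                    break
                lo_chi = c
            if hi_chi is None:
                raise ConvergenceError(
                    f"no negative envelope curvature found up to chi={chis[-1]}",
                    seed=(lam, xi),
                )
        for _ in range(18):
            mid = 0.5 * (lo_chi + hi_chi)
            m, _ = _min_curvature(mid, lam, xi, phi0s, grid_n)
            if m < 0.0:
                hi_chi = mid
            else:
                lo_chi = mid
        chi0 = hi_chi
        _, p0 = _min_curvature(chi0, lam, xi, phi0s, grid_n)

    def system(z):
        chi, q = z
        q = min(max(q, 1e-6), 1.0 - 1e-6)
        p = ModelParams(xi=xi, lam=lam, chi=chi)
        return [envelope_curvature(q, p, grid_n), _d3(q, p, grid_n)]

    sol = root(system, [chi0, p0], method="hybr", tol=1e-13)
    res = float(np.max(np.abs(system(sol.x))))
    if res > tol:
        raise ConvergenceError(
            f"critical-point iteration stalled at residual {res:.2e}",
            residual=res,
            seed=(chi0, p0),
        )
    chi_star, phi0_c = float(sol.x[0]), float(sol.x[1])
    p = ModelParams(xi=xi, lam=lam, chi=chi_star)
    phiS_c = optimize_state_fraction(phi0_c, p, grid_n=grid_n).phiS_opt
    return CriticalPoint(chi_star=chi_star, phi0_c=phi0_c, phiS_c=phiS_c, residual=res)


def phase_diagram(lam: float, xi: float, chi_grid=None, phi0_grid=None,
                  grid_n: int = 512, heatmap: bool = True) -> PhaseDiagram:
    """Assemble binodal, spinodal, critical point and a phiS_opt/phi0 heat map.

    For every chi in ``chi_grid`` above the critical chi* the common tangent
    and the spinodal roots are computed on ``phi0_grid``; the heat map stores
    the S-state particle fraction at each (chi, phi0).  A fixed phi0 (for
    example 0.5 at lam=0, xi=4) can therefore cross the two-phase region
    twice along a 1/chi scan, exposing re-entrant behavior.
    """
    cp = critical_point(lam, xi, grid_n=grid_n)
    if chi_grid is None:
        chi_grid = np.linspace(cp.chi_star * 1.02, cp.chi_star * 2.5, 16)
    chi_grid = np.asarray(chi_grid, dtype=float)
    if phi0_grid is None:
        phi0_grid = np.linspace(1e-3, 1.0 - 1e-3, 1001)
    phi0_grid = np.asarray(phi0_grid, dtype=float)
    diagram = PhaseDiagram(lam=lam, xi=xi, chi_grid=chi_grid, critical=cp,
                           phi0_grid=phi0_grid)
    heat = np.full((len(chi_grid), len(phi0_grid)), np.nan) if heatmap else None
    for r, chi in enumerate(chi_grid):
        p = ModelParams(xi=xi, lam=lam, chi=chi)
        curve = envelope_curve(p, phi0_grid, grid_n=grid_n, refine_jumps=False)
        if heat is not None:
            heat[r] = curve.phiS_opt / phi0_grid
        if chi <= cp.chi_star:
            diagram.binodals.append((chi, []))
            diagram.spinodals.append((chi, SpinodalPoints(params=p, roots=())))
            continue
        coex = common_tangent(curve, p)
        diagram.binodals.append((chi, coex))
        window = (phi0_grid[0], phi0_grid[-1])
        diagram.spinodals.append((chi, spinodal_points(p, window, n=401, grid_n=grid_n)))
    diagram.heatmap = heat
    return diagram
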