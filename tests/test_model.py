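"""Free energy, entropy and analytic derivatives of the two-state lattice model."""

import math

import numpy as np
import pytest

from twostate import (
    DomainError,
    ModelParams,
    StateComposition,
    entropy_per_site,
    feasible_interval,
    free_energy_partials,
    free_energy_per_site,
    interaction_per_site,
)
from twostate.model import _curvature_reduced, _quants, _second_partials


def comp(phiL, phiS):
    return StateComposition(phiL=phiL, phiS=phiS)


@pytest.mark.parametrize(
    "phiL, phiS, xi, expected",
    [
        (0.0, 0.0, 4.0, 0.0),  # empty lattice: every x ln x term vanishes
        (0.0, 0.5, 4.0, 2 * 0.5 * math.log(0.5)),  # binary mixing entropy
        (0.0, 0.5, 1.7, 2 * 0.5 * math.log(0.5)),  # ... for any xi
        (0.5, 0.0, 4.0, -0.17328679513998632),  # (1/xi)[x ln x + (1-x)ln(1-x)]
    ],
)
def test_entropy_known_values(phiL, phiS, xi, expected):
    p = ModelParams(xi=xi, lam=0.0, chi=0.0)
    assert entropy_per_site(comp(phiL, phiS), p) == pytest.approx(expected, abs=1e-12)


def test_entropy_reductions(rng):
    """phiL=0 recovers binary Bragg-Williams mixing; phiS=0 recovers the
    single-species large-particle entropy scaled by 1/xi."""
    for _ in range(200):
        x = rng.uniform(0.01, 0.99)
        xi = rng.uniform(1.0, 8.0)
        p = ModelParams(xi=xi, lam=0.0, chi=0.0)
        bw = x * math.log(x) + (1 - x) * math.log(1 - x)
        assert entropy_per_site(comp(0.0, x), p) == pytest.approx(bw, abs=1e-12)
        assert entropy_per_site(comp(x, 0.0), p) == pytest.approx(bw / xi, abs=1e-12)


def test_interaction_values_and_symmetry(rng):
    p = ModelParams(xi=4.0, lam=0.0, chi=1.2)
    assert interaction_per_site(comp(0.0, 0.0), p) == 0.0
    assert interaction_per_site(comp(0.6, 0.4), p) == 0.0  # full lattice
    assert interaction_per_site(comp(0.3, 0.2), p) == pytest.approx(0.3)
    # invariant under total particle fraction t -> 1 - t
    for _ in range(50):
        t = rng.uniform(0.0, 1.0)
        split = rng.uniform(0.0, 1.0)
        a = interaction_per_site(comp(t * split, t * (1 - split)), p)
        b = interaction_per_site(comp((1 - t) * split, (1 - t) * (1 - split)), p)
        assert a == pytest.approx(b, abs=1e-12)


def test_free_energy_no_L_closed_form():
    """With no L-particles and chi=0, f is the ideal two-component lattice form
    lam*phi0 + phi0 ln phi0 + (1-phi0) ln(1-phi0)."""
    lam = 0.7
    p = ModelParams(xi=3.0, lam=lam, chi=0.0)
    for phi0 in (0.1, 0.35, 0.8):
        expected = lam * phi0 + phi0 * math.log(phi0) + (1 - phi0) * math.log(1 - phi0)
        assert free_energy_per_site(comp(0.0, phi0), p) == pytest.approx(expected, abs=1e-14)
    assert free_energy_per_site(comp(0.0, 0.0), p) == 0.0


def test_free_energy_local_minimum_in_phiS(reference_params):
    """Near phi0=0.23 the S-rich split phiS ~ 0.2 is a local minimum of
    phiS -> f(xi(phi0-phiS), phiS)."""
    p = reference_params
    phi0 = 0.23

    def f(phiS):
        return free_energy_per_site(StateComposition.from_phi0(phi0, phiS, p), p)

    phiS0 = 0.2
    assert f(phiS0) < f(phiS0 - 0.02)
    assert f(phiS0) < f(phiS0 + 0.02)


def test_partials_match_finite_differences(rng):
    """Analytic f_S and f_0 agree with centered differences of f at 1000
    random interior compositions to relative tolerance 1e-6."""
    h = 1e-6
    checked = 0
    while checked < 1000:
        xi = rng.uniform(1.0, 6.0)
        p = ModelParams(xi=xi, lam=rng.uniform(-3, 3), chi=rng.uniform(-1, 3))
        phi0 = rng.uniform(0.05, 0.95)
        iv = feasible_interval(phi0, p)
        phiS = iv.lo + rng.uniform(0.1, 0.9) * iv.width
        c = StateComposition.from_phi0(phi0, phiS, p)
        if min(c.phiL, c.phiS, 1 - c.phiL - c.phiS) < 1e-3:
            continue
        pr = free_energy_partials(c, p)

        def f(q0, qS):
            return free_energy_per_site(StateComposition.from_phi0(q0, qS, p), p)

        fd_S = (f(phi0, phiS + h) - f(phi0, phiS - h)) / (2 * h)
        fd_0 = (f(phi0 + h, phiS) - f(phi0 - h, phiS)) / (2 * h)
        assert pr.f_S == pytest.approx(fd_S, rel=1e-6, abs=1e-6)
        assert pr.f_0 == pytest.approx(fd_0, rel=1e-6, abs=1e-6)
        checked += 1


def test_second_partials_against_symbolic_oracle(rng):
    """All closed-form second partials and the regrouped envelope curvature
    agree with sympy-differentiated expressions at random interior points."""
    import sympy as sp

    xi_s, lam_s, chi_s, q0, qS = sp.symbols("xi lam chi q0 qS", positive=True)
    u_s = xi_s * (q0 - qS)
    t_s = u_s + qS
    f_s = (
        lam_s * qS
        + u_s / xi_s * sp.log(u_s)
        + (1 / xi_s - 1) * (1 - u_s) * sp.log(1 - u_s)
        + (1 - t_s) * sp.log(1 - t_s)
        + qS * sp.log(qS)
        + chi_s * (1 - t_s) * t_s
    )
    syms = (xi_s, lam_s, chi_s, q0, qS)
    d = {
        "f_SS": sp.lambdify(syms, sp.diff(f_s, qS, 2)),
        "f_S0": sp.lambdify(syms, sp.diff(f_s, qS, q0)),
        "f_00": sp.lambdify(syms, sp.diff(f_s, q0, 2)),
    }
    for _ in range(25):
        xi = rng.uniform(1.05, 6.0)
        lam, chi = rng.uniform(-2, 2), rng.uniform(0, 2.5)
        p = ModelParams(xi=xi, lam=lam, chi=chi)
        phi0 = rng.uniform(0.1, 0.9)
        iv = feasible_interval(phi0, p)
        phiS = iv.lo + rng.uniform(0.2, 0.8) * iv.width
        u, omu, omt = _quants(phi0, phiS, xi)
        if min(u, omu, omt, phiS) < 1e-3:
            continue
        f_SS, f_S0, f_00 = _second_partials(phiS, u, omu, omt, p)
        args = (xi, lam, chi, phi0, phiS)
        assert f_SS == pytest.approx(d["f_SS"](*args), rel=1e-10)
        assert f_S0 == pytest.approx(d["f_S0"](*args), rel=1e-10)
        assert f_00 == pytest.approx(d["f_00"](*args), rel=1e-10)
        curv = _curvature_reduced(phiS, u, omu, omt, p)
        naive = d["f_00"](*args) - d["f_S0"](*args) ** 2 / d["f_SS"](*args)
        assert curv == pytest.approx(naive, rel=1e-9, abs=1e-9)


def test_equal_size_limit_is_continuous():
    """At xi=1 the sublattice term drops out exactly; the free energy and its
    derivatives continue smoothly from xi = 1 + epsilon."""
    c = StateComposition(phiL=0.3, phiS=0.25)
    f1 = free_energy_per_site(c, ModelParams(xi=1.0, lam=0.8, chi=1.1))
    f1eps = free_energy_per_site(c, ModelParams(xi=1.0 + 1e-6, lam=0.8, chi=1.1))
    assert f1 == pytest.approx(f1eps, abs=1e-5)
    # and it equals plain Bragg-Williams mixing of two equal-size states
    phi0 = 0.3 + 0.25
    expected = (
        0.8 * 0.25
        + 0.3 * math.log(0.3)
        + 0.25 * math.log(0.25)
        + (1 - phi0) * math.log(1 - phi0)
        + 1.1 * phi0 * (1 - phi0)
    )
    assert f1 == pytest.approx(expected, abs=1e-14)


def test_entropy_continuous_to_boundary():
    p = ModelParams(xi=4.0, lam=0.0, chi=0.0)
    eps = 1e-9
    near = entropy_per_site(comp(0.0, 1.0 - eps), p)
    assert abs(near - entropy_per_site(comp(0.0, 1.0), p)) < 1e-7
    assert np.isfinite(entropy_per_site(comp(1.0, 0.0), p))


@pytest.mark.parametrize(
    "phi0, xi, lo, hi",
    [
        (0.2, 4.0, 0.0, 0.2),
        (0.5, 4.0, 1.0 / 3.0, 0.5),
        (1.0, 4.0, 1.0, 1.0),
        (1.0, 1.0, 0.0, 1.0),
        (0.7, 1.0, 0.0, 0.7),
    ],
)
def test_feasible_interval(phi0, xi, lo, hi):
    p = ModelParams(xi=xi, lam=0.0, chi=0.0)
    iv = feasible_interval(phi0, p)
    assert iv.lo == pytest.approx(lo, abs=1e-14)
    assert iv.hi == pytest.approx(hi, abs=1e-14)
    if iv.lo > 0:
        # phiL + phiS = 1 exactly at the lower end
        assert xi * (phi0 - iv.lo) + iv.lo == pytest.approx(1.0, abs=1e-12)


def test_domain_errors_name_the_constraint():
    with pytest.raises(DomainError, match="xi"):
        ModelParams(xi=0.5, lam=0.0, chi=0.0)
    with pytest.raises(DomainError, match="phiL"):
        StateComposition(phiL=-0.1, phiS=0.2)
    with pytest.raises(DomainError, match="phiL \\+ phiS"):
        StateComposition(phiL=0.7, phiS=0.5)
    with pytest.raises(DomainError, match="phi0"):
        feasible_interval(1.2, ModelParams(xi=2.0, lam=0.0, chi=0.0))
    with pytest.raises(DomainError, match="boundary"):
        free_energy_partials(comp(0.0, 0.3), ModelParams(xi=2.0, lam=0.0, chi=0.0))
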