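# Methods

## Model and assumptions

The package treats a binary mixture of solvent and N₀ particles on a lattice
of M equal sites. A particle occupies one site in its small (S) state and ξ
contiguous sites in its large (L) state; ξ ≥ 1 may be any real number, since
the mean-field expressions below are well defined for non-integer ξ (integer
ξ only matters for drawing lattices). The solvent molecule has the S-particle
volume; generalizing that, allowing more than two states, or state-dependent
interaction strengths, are out of scope.

Three approximations define the model:

1. **Lattice–sublattice entropy.** The mixing entropy is estimated by first
   distributing the N_L large particles over a sublattice of M/ξ blocks and
   then mixing small particles and solvent over the remaining M − ξN_L sites.
   Carrying out both ideal-mixing counts and adding them gives, per site,

       −S/(M k_B) = (φ_L/ξ) ln φ_L + (1/ξ − 1)(1 − φ_L) ln(1 − φ_L)
                  + (1 − φ_L − φ_S) ln(1 − φ_L − φ_S) + φ_S ln φ_S.

   The coefficient of the second term is (1/ξ − 1): it vanishes at ξ = 1, and
   the expression then reduces *exactly* to Bragg–Williams mixing of two
   distinguishable equal-size species, φ_L ln φ_L + φ_S ln φ_S +
   (1 − φ₀) ln(1 − φ₀). The equal-size case therefore needs no special-casing
   anywhere in the code, and it reproduces the classical critical point
   (χ* = 2, φ₀ᶜ = 1/2) with an internal state split given by the Boltzmann
   factor φ_S = φ₀/(1 + e^λ). Setting φ_S = 0 reduces the entropy to
   (1/ξ)[φ_L ln φ_L + (1 − φ_L) ln(1 − φ_L)], the single-species result on a
   lattice of ξ-fold larger sites; both reductions are asserted to 1e−12 in
   the tests.

2. **Mean-field contact interaction.** Particle–solvent contacts contribute
   χ(1 − φ_L − φ_S)(φ_L + φ_S) per site, independent of the internal state —
   an effective surface (or, in 2-D, line) tension. χ > 0 favors particle
   aggregation and, for isolated particles, the S-state (less perimeter).

3. **Two-state internal energy.** Switching one particle L→S costs λ, giving
   λφ_S per site. Both λ and χ are in units of k_BT; no temperature variable
   exists at runtime — phase diagrams use 1/χ as the temperature axis.

Boundary convention: every x ln x term is evaluated as 0 at x = 0 explicitly,
so f is continuous on the closed feasible domain.

## Parameters

| parameter | meaning | default used in examples |
|---|---|---|
| ξ ≥ 1 | L/S volume ratio (dimensionless) | 4 |
| λ | L→S switching energy (k_BT); positive penalizes S | 1.5 |
| χ | particle–solvent tension (k_BT); 1/χ ∝ temperature | 1.2 |
| grid_n | φ_S scan resolution of the global minimizer | 512 |
| tol_degenerate | free-energy window for flagging degenerate minima | 1e−9 |

## Solvers and numerical choices

**Global state-split minimizer.** At fixed φ₀ the feasible interval is
φ_S ∈ [max(0, (ξφ₀ − 1)/(ξ − 1)), φ₀]. The derivative ∂f/∂φ_S runs from −∞
at the lower end to +∞ at the upper end, so all minima are interior; they are
bracketed by signing the analytic derivative on a 512-point uniform grid
augmented with geometric offsets (10⁻² … 10⁻¹³ of the interval width) from
both ends, and polished by Brent's method (xtol 1e−14). The geometric points
matter because for |λ| of order 10 or more the minimizer approaches a
boundary exponentially closely; those brackets are solved in the logarithm of
the distance to the boundary, and the occupancies u = φ_L, 1 − u, and the
solvent fraction are carried explicitly so that no precision is lost to
cancellation (at λ = −30 the L-occupancy at the optimum is ~10⁻¹⁴ and is
still resolved to full relative accuracy). The deepest minimum wins; exact
ties (within tol_degenerate, used to flag cusp compositions) report the
smaller-φ_S minimizer for deterministic output. A 20001-point brute-force
scan serves as the test oracle over randomized parameters. All solvers are
deterministic given their grids; the package contains no randomness.

**State jumps.** A discontinuity of φ_S^opt is located by first bisecting on
which branch holds the global minimum and then solving the equal-depth
condition f(branch A minimum) = f(branch B minimum) with Brent's method,
re-polishing both branch minima at every iterate. For ξ = 4, λ = 1.5,
χ = 1.2 this yields φ₀ = 0.2333391, confirmed by an independent 40-digit
multiprecision bisection of the same condition.

**Envelope derivatives.** Along continuous branches ∂f/∂φ_S = 0 at the
optimum, so df/dφ₀ equals the fixed-φ_S partial there (envelope theorem); no
numerical differentiation of the envelope is used. The second total
derivative d²f/dφ₀² = f₀₀ − f₀ₛ²/f_SS is implemented in an algebraically
regrouped closed form whose singular 1/u and 1/φ_S pieces factor out of
numerator and denominator; the naive difference loses all significant digits
when the optimum hugs a boundary, the regrouped form does not (verified
symbolically with sympy and numerically near the λ = ±30 limits).

**Common tangent.** The sampled envelope's lower convex hull (monotone-chain)
marks non-convex stretches; each hull gap is refined by a one-parameter
search over the tangent slope m: the touching compositions on either side are
roots of f′(φ₀) = m near the hull contacts, and m is adjusted by Brent's
method until the two tangent intercepts coincide (residuals ~1e−13,
comfortably below the 1e−8 target). Refinement operates on the two smooth
branches flanking the cusp, which the hull contacts never straddle. Multiple
hull gaps would each produce a coexistence pair; none are discarded. A gap
touching the grid boundary raises a resolution error instead of returning a
truncated interval. Default hull grids: 4001 points for production use
(examples in the tests use 1001–2001 to keep the suite fast; results agree
to the stated tolerances).

**Spinodal and critical point.** Spinodal roots are sign changes of the
total curvature along the re-optimized envelope, polished by bisection to
1e−10 in φ₀. The critical-point conditions are stationarity in φ_S (enforced
by the inner minimization) plus vanishing second and third total
φ₀-derivatives. The third derivative is a Richardson-extrapolated central
difference (h = 1e−4) of the analytic curvature — accurate to ~1e−9, which
is why the curvature itself had to be cancellation-free. Seeding is a
bisection on χ of the minimal curvature over a φ₀ scan (161 points), i.e.
the smallest χ whose envelope first develops a flat inflection; a hybrid
Newton (scipy `root`, method hybr) then drives the 2-vector
(d²f/dφ₀², d³f/dφ₀³) below 1e−8. Whether the mixed derivatives in the
critical conditions are total or partial is a genuine modeling choice; total
derivatives along φ_S^opt(φ₀) are used because the first condition already
imposes stationarity, and this choice reproduces all closed-form limits:
(χ*, φ₀ᶜ) → (2, 1/2) as λ → −∞ for any ξ, and (2/ξ, 1/(2ξ)) as λ → +∞
(checked at λ = ∓30, where the limits hold to ~1e−9).

**Isotherms.** ν₀P = φ₀ f′(φ₀) − f(φ₀) pointwise; inside a coexistence
interval the constant plateau pressure −(tangent intercept) is substituted.
The plateau is taken from the common tangent rather than equal-area
quadrature (they are equivalent; the tangent data already exists and carries
no quadrature error) — the equal-area identity
∫P dv = f₂/φ₂ − f₁/φ₁ is kept as a test oracle. Exactly at a state-jump
cusp the pressure is one-sided; evaluation there requires an explicit branch
choice and otherwise raises an ambiguity error.

## Degenerate and edge inputs

φ₀ = 1 forces the all-S composition (feasible interval collapses to {1}).
φ₀ ≤ 0 or > 1, compositions outside the simplex, and derivative evaluation on
the domain boundary raise domain errors naming the violated constraint.
Negative χ (solvent-philic particles) is allowed and simply suppresses
aggregation.

## Known limitations

* Strictly bulk mean-field: no correlations, interfacial/gradient terms,
  nucleation, or dynamics; spinodals and binodals carry the usual mean-field
  critical exponents (e.g. the coexistence width grows like
  √(χ/χ* − 1), so it is ~0.05 even at χ only 0.1% above χ*).
* One state-blind interaction parameter; no L–S, L–solvent, S–solvent
  distinction.
* The common-tangent detector needs the non-convex region resolved by its
  grid; coexistence intervals narrower than about two grid steps (χ extremely
  close to χ*) fall below the hull noise filter and are reported as single
  phase. Tighten the grid near the critical point if that regime matters.
* Very large |λ| (beyond ~700) saturates the closed-form dilute slope to its
  limit value before floating-point overflow.
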