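# Methods

## Model

A population of `m` discrete cell phenotypes (attractor states of the
underlying regulatory network) is described by its vector of cell counts
`N(t)`.  Two processes change it: net growth of each phenotype — birth minus
death, a single rate `g_i` (1/day), because only the net rate is measurable
in bulk culture — and first-order interconversion with directed rates
`k_ij` (1/day) from phenotype `i` to `j`.  The dynamics are linear:

    dN/dt = T N,      T = G + K,

with `G = diag(g)` and `K` the conversion part, `K[j,i] = k_ij` for `j ≠ i`
and `K[i,i] = −Σ_j k_ij`.  Columns of `K` sum to zero because conversion
moves cells between phenotypes without creating or destroying them; with
`g = 0` the system is exactly a continuous-time Markov chain on phenotypes.

Assumptions: rates are constant (no drug pulses, no density dependence, no
cell–cell interactions), counts are continuous (no demographic noise), and
transitions are cell-autonomous and first-order.

## Spectral analysis

`T` is a Metzler matrix (nonnegative off-diagonal), so Perron–Frobenius
applies to `T + cI` for large enough `c`: when the transition graph is
strongly connected (irreducible), the leading eigenvalue `λ_max` is real
and simple and its right eigenvector strictly positive.  Normalised to the
simplex, that eigenvector is the **stationary composition** — the fractions
every positive initial condition converges to — and `λ_max` is the
asymptotic exponential growth rate of the total population.  Adding a
constant to all growth rates shifts every eigenvalue by that constant and
leaves eigenvectors (hence the composition) unchanged; this shift
invariance is used both numerically (to keep long-horizon integrations in
floating-point range) and statistically (it is why composition data cannot
identify absolute growth rates).

Regimes follow the eigenvalue sign pattern: all real parts positive —
coexistent growth; all negative — joint extinction; mixed — at least one
phenotype persists only through backflow from the others ("derived").  For
`m = 2` the same-sign condition is exactly `det T > 0`.  A phenotype is
*independent* when `g_i` strictly exceeds its total outflow `Σ_j k_ij`
(zero outflow counts as independent: nothing to be derived from).  When
every phenotype's outflow exceeds `dominance_factor × |g_i|` (default
factor 10), conversions dominate so strongly that the phenotypes behave as
one population with a mean growth rate; this "blurred" label takes
precedence over the sign-based one.  The magnitude `|g_i|` is used rather
than `g_i` so that slowly dying pairs with tiny transitions are still
classified by their eigenvalue signs.  Eigenvalue sign decisions use a
tolerance of `1e-12` relative to the 1-norm of `T`; an eigenvalue at zero
within tolerance yields a "marginal" report with no hard regime.

Degenerate cases (non-real or non-simple leading mode, reducible graphs)
fall back to long-time integration over `t = 200 / gap` (fixed horizon 200
days when the gap is ~0) with a flag; reducible models raise when the
fallback is disabled.

## Two-phenotype closed forms

For the ratio `r = N_X / N_Y` the linear system induces the Riccati
equation

    dr/dt = k_YX + Δ r − k_XY r²,     Δ = (g_X − g_Y) − (k_XY − k_YX),

which factorises through its roots `r± = (Δ ± S) / (2 k_XY)`,
`S = sqrt(Δ² + 4 k_XY k_YX)`.  The package always reports the nonnegative
root `r* = r₊` (count ratios are nonnegative; the other root is
diagnostic only).  Partial fractions give the explicit time course

    t(r0 → r) = (1/S) ln[ (r − r₋)(r0 − r₊) / ((r − r₊)(r0 − r₋)) ],

implemented piecewise on `(0, r*)` and `(r*, ∞)`; requests that straddle
the fixed point raise (trajectories are monotone and cannot cross it), and
a target behind the start returns the negative algebraic time.  The
inverse (`ratio_at_time`) solves the same relation for `r`.  The double
root `S = 0` (forces `Δ = 0`, `k_YX = 0`) is handled by the algebraic
`r(t) = r0 / (1 + k_XY r0 t)`.  With `k_XY = 0` the equation is affine and
the ratio generically diverges; these degenerate answers are returned only
behind an explicit `allow_degenerate` flag rather than silently as
infinities.

The drift peaks at `r_peak = Δ / (2 k_XY)` with rate
`k_YX + Δ² / (4 k_XY)`.  For `Δ > 0` the peak is interior, so
re-equilibration from a pure-Y start accelerates before decelerating — a
sigmoidal time course; for `Δ ≤ 0` the rate is maximal at `r = 0` (value
`k_YX`) and decreases monotonically — exponential saturation.  `1/S` sets
the relaxation timescale; empirically the (1−1/e)-fold approach time lies
within one decade of `1/S` across random parameter draws (the tighter
"within a factor of two" does not hold in general).

The total population grows asymptotically at
`(g_X r* + g_Y) / (r* + 1)`, the growth of the stationary mixture, which
coincides with `λ_max`; the equality is used as a cross-check in the tests
rather than as the implementation of either quantity.

## Fraction dynamics (m phenotypes)

Fractions `x = N / Σ N` obey the replicator-like system
`dx/dt = T x − (g·x) x` (the conversion part conserves total mass, so
`1'T x = g·x`).  Its interior fixed point is the stationary composition;
setting the right-hand side to zero yields coupled quadratics with no
general closed form.  The numerical root-finder is a damped Newton
iteration on the simplex: the dependent m-th equation is replaced by the
normalisation constraint, steps are halved (up to 40 times) until the
residual decreases, iterations are capped at 500, and the residual
tolerance is `1e-12` (scaled by the 1-norm of `T`).  If the iteration
stalls from the default uniform start, it restarts once from a warm start
obtained by evolving the shift-normalised fractions for 40 relaxation
times; remaining failures raise with the achieved residual attached.  The
root, the Perron eigenvector and the long-time integrated fractions agree
pairwise to 1e-6 on random irreducible models (tested).

A ratio-to-reference view (`N_i / N_ref`) is provided as a pure coordinate
change on the simplex for users who parameterise compositions that way.

## Simulation

Because the count system is linear it is propagated exactly: through the
eigenbasis when the eigenvector matrix has condition number below 1e10,
otherwise by matrix exponentials between grid points.  Roundoff-level
negative counts are clipped to zero (the exact flow preserves
nonnegativity).  A sorting panel starts one trajectory per phenotype from
a composition with `purity` on its own type (default 1.0; the residual
impurity of a real FACS sort is configurable) and the remainder split
evenly.

**Time to equilibrium** is operationalised as the smallest time on a
0.1-day grid after which the L∞ distance between the fraction vector and
the stationary composition stays below 0.01 for the remainder of a horizon
of five times that time.  The tolerance 0.01 sits below the order of the
smallest published composition component in the bundled case study (0.62%)
while remaining robust to solver noise; the horizon grows geometrically
(cap 4000 days) and integration uses the growth-shifted model so counts
stay bounded.

## Case study and the table-reading convention

The bundled SUM159/SUM149 models carry three phenotypes (stem, basal,
luminal) with published equilibrium proportions ≈ 1.9 : 97.3 : 0.62 and
≈ 3.9 : 3.3 : 92.8 respectively.  The published rate table prints nine
numbers per line, but its column headers are not machine-readable in the
available sources, so the assignment of columns to the three growth rates
and six directed transitions is fixed by enumeration: all 3!·6! = 4320
candidate readings are scored by the joint L1 distance between the
resulting stationary compositions and the published proportions of both
lines.  The minimiser — growth columns read as (luminal, stem, basal) and
transition columns as (L→S, L→B, B→L, B→S, S→L, S→B) — wins by a factor of
two over the runner-up (L1 0.037 vs 0.072) and is recorded in the
versioned config `data/sum_rate_mapping.json`; a test re-runs the
enumeration against the shipped choice.  Under this convention the sorted
SUM159 cultures re-equilibrate (sustained L∞ ≤ 0.01) within 9.6 days and
the SUM149 cultures take 26.6–93.9 days, matching the qualitative
fast/slow contrast the two lines are known for.

## Fitting

The inverse problem is solved as an exhaustive Cartesian grid scan.  The
objective is the summed squared difference between simulated and observed
fraction vectors over all sorted-start conditions and positive timepoints
(an L1 option exists); day-0 compositions are treated as the initial
condition of each condition, not as fitted points.  The published analysis
this emulates states no objective; summed squared fraction error is the
simplest convex choice consistent with fitting compositions.  Feasibility
filtering keeps only candidates whose eigenvalue real parts all share the
configured sign (coexistence), optionally also requiring every phenotype
to be independently survivable.  Ties are broken toward the
lexicographically smallest parameter tuple, and chunked evaluation reduces
with an order-independent key, so results are identical for any worker
count or chunk size.  Grid axes are rounded to 12 decimals so on-grid
truths are recovered bit-exactly.

Identifiability: composition-only objectives are invariant under uniform
growth shifts (verified numerically), so scans either fix the growth rates
or report the absolute scale as unidentifiable; total-count fold-change
observations restore it.  The shipped example scan fixes growths and scans
the six transition rates at step 0.1 over [0, 1] (a step of 0.05 over six
dimensions would be an 86-million-point grid — use the coarse pass plus a
coordinate-wise refinement instead).

## Synthetic data

The generator emulates the sorting experiment: pure (or configurable
purity) starts, exact linear dynamics for the truth, and observed
compositions drawn from a Dirichlet distribution centred on the truth
(`alpha = concentration × x_true`; concentration ∞ returns the truth
exactly, structural zeros stay zero).  Flow-cytometry fractions are
compositional, which motivates the Dirichlet; optional total-count
readings get multiplicative lognormal noise.  One integer seed drives all
randomness.  What the generator does *not* emulate: gating/classification
error correlated across phenotypes, demographic stochasticity at small
cell numbers, day-0 measurement error (the sorted composition is taken as
known), and rate drift over the culture period — so passing recovery tests
demonstrate correctness of the estimator under the stated noise model, not
robustness to these real-data effects.

## Numerical choices, problem sizes, limitations

- Eigenvalue sign tolerance `1e-12 ×` matrix 1-norm; simplex validation
  `1e-9` (inputs) and `1e-6` (observation files).
- Mode decomposition refuses eigenvector bases with condition number above
  1e12 and directs callers to the integrator.
- Test-suite problem sizes: 1000 random models for the spectral and
  two-state dual-route checks, 200 for the multi-phenotype consistency
  sweep, 100 for the closed-form-vs-integrator and kinetic-dichotomy
  sweeps (draws with `|Δ| < 0.02` are redrawn there: the interior rate
  maximum is `O(Δ²)` above the boundary value and numerically
  unresolvable), 10 seeds for noisy recovery.
- The linear model cannot saturate: it describes the exponential-growth
  phase, and total counts are meaningful only relative to the start.
  Absolute growth rates require count data by construction.  Fits inherit
  the grid resolution; no confidence intervals are attempted.
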