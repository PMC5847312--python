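# Methods notes

## Model and assumptions

The package treats metabolism as a stoichiometric network with modular
rate-law kinetics.  Internal metabolites are balanced at steady state and
constrained to concentration bounds; external metabolites are fixed
parameters of a condition, never decision variables.  All concentrations
are in mM, and equilibrium constants follow the mM convention — the choice
of convention matters because K_eq values rescale with the concentration
unit whenever a reaction changes mole numbers; bundles must be supplied in
this convention.

The enzyme demand of an active reaction is
`E_r = v_r / (kcat⁺_r · η_rev · η_sat)` with

* `θ_r = ln K_eq,r − Σ_i n_ir · ln c_i` (RT units), oriented along the flux;
  for a reversible reaction running backward the stoichiometry is negated
  and K_eq inverted, while kcat⁺ is reused (the factorized parameterization
  never uses a backward kcat, so Haldane consistency is moot — bundles
  should not supply a conflicting kcat⁻);
* `η_rev = 1 − e^(−θ_r)`;
* `η_sat = Π_S (c/K)^m / [Π_S (1+c/K)^m + Π_P (1+c/K)^m − 1]`, the common
  modular form with molecularities m as exponents.  Only reactants with a
  Michaelis constant participate: internal reactants must carry one
  (validated at load time); external reactants may, which is how transporter
  saturation creates Monod-type dependence on the external substrate.
  A substrate-only variant (`EcmOptions.simple_saturation`) is available
  for sensitivity checks.

The cost weight of an enzyme is its molecular mass `w_r` (Da = mg/mmol), so
`E_met = Σ w_r E_r` is a mass concentration in mg/l.  Alternative weightings
can be plugged in via `EcmOptions.weight_fn`.

The biomass reaction is given a very large default kcat⁺ (10⁶ s⁻¹) so it
never limits the cost; the value is configurable per bundle.

## EFM enumeration

Nullspace/double-description with exact `fractions.Fraction` arithmetic:
reversible reactions are split, the cone `{u ≥ 0 : S u = 0}` is constructed
one metabolite balance at a time, and candidate rays are pruned by
support-minimality (in these combinatorial cones the extreme rays are
exactly the support-minimal ones).  Futile forward/backward two-cycles are
dropped and split halves merged back to net fluxes; a mode whose support is
fully reversible is reported in the orientation with positive biomass flux
(or positive first nonzero flux).  Floats appear only at the very end;
entries below 1e-12 after normalization are zeroed before support
computation.  A configurable cap on intermediate rays (default 200 000)
raises an explicit overflow error rather than truncating.  Correctness was
prioritized over speed: exact arithmetic is cheap at the ~10³-EFM scale this
package targets, and the enumerator is cross-checked against an exhaustive
support-subset oracle on networks up to 12 reactions.

Biomass-producing EFMs are normalized so the biomass reaction carries the
model's flux convention (1 mM/s by default) and carry their yield
`Y = v_bm_mass / (carbon · v_uptake · 3600)` in g per C-mol; modes without
biomass flux are enumerated and kept for diagnostics but excluded from
rate/yield analyses.  Condition filtering classifies modes by the oxygen
rules (a mode using both an oxygen-sensitive and an oxygen-dependent
reaction is discarded everywhere; aerobic feasibility excludes
oxygen-sensitive usage, anaerobic excludes oxygen-dependent usage), and both
countings — before and after dropping non-biomass modes — are accessible,
since either may be wanted when comparing against published totals.

## The convex solve

Variables are `x = ln(c/1 mM)` for internal metabolites touched by the
mode.  Constraints: box bounds from the metabolite table (defaults
1e-3–10 mM when a bundle omits them) and `θ_r ≥ ε` with ε = 1e-6 RT — a
strict-positivity floor the rate law needs; its exact value is immaterial
at optima, which keep driving forces well above it.  A linear max–min
driving-force pre-solve (HiGHS LP) certifies that the polytope is nonempty
— reporting the tightest reaction when it is not — and supplies the
starting point.  The cost is then minimized with SLSQP using analytic
gradients; convexity of `E_met(x)` makes the single-start solve globally
optimal, and determinism follows from the fixed starting point.  The
objective is scaled by its value at the start to keep tolerances
(`ftol = 1e-12` scaled) meaningful across bundles whose costs span orders
of magnitude.  A failed solve retries once from a midpoint; the solution
object always carries converged/diagnostic fields, never a silent partial
answer.

The solver is cross-checked against a 400×400 grid search on
two-metabolite toys (agreement within 1e-4 relative) and against 1000
random feasible points per model.

## Growth conversion

`μ = a·f_prot·v_BM / (E_met + b·f_prot·v_BM)`, with defaults a = 0.27,
b = 0.2 h, f_prot = 0.5, v_BM = 7.45e7 mg l⁻¹ h⁻¹ — a semi-empirical
proteome-allocation law for E. coli-like cells in which the metabolic
enzyme fraction of protein declines linearly with growth rate.  The biomass
density never appears: it cancels algebraically, so it is not an input.
None of the constants are hard-coded; they live in each bundle's
`config.json` because the law is organism-specific.  The equivalent
doubling-time form `T = τ_met/(a·f_prot) + ln2·b/a` is implemented
separately and tested to agree with `ln2/μ` identically.  Unit conversions
(mM s⁻¹ ↔ mmol l⁻¹ h⁻¹) are centralized in one constant.

## Sensitivities, knockouts, epistasis

At an ECM optimum, the first-order effect of a kinetic parameter on the
minimal cost equals its effect at fixed metabolite levels (envelope
theorem), so `dE_met/d ln p` comes from the rate law's partial derivatives:
−E_r·w_r for kcat⁺, the `e^(−θ)/η_rev`-weighted term for K_eq, and the
negated saturation gradient for each K_M; external-concentration
sensitivities combine the θ- and saturation channels.  Growth sensitivities
multiply by `dμ/dE_met = −a·f_prot·v_BM/(E_met + b·f_prot·v_BM)²`.
Verified against central finite differences of fully re-optimized growth
rates (1e-3 relative).

Knockouts discard EFMs whose support intersects the knocked-out set and
re-use the precomputed spectrum; the wild-type advantage is
`μ_wt/μ_ko − 1`, with an infinity sentinel when no mode survives.
Epistasis between two knockouts uses the multiplicative score
`ε = (μ_AB·μ_wt)/(μ_A·μ_B)`; since other definitions exist, all four
growth rates are returned and the definition is recorded in the output.

Monod scans treat every grid cell as an independent condition (log-spaced
grids by default, since realistic scans span decades), apply the anaerobic
feasibility rule at zero oxygen, and break growth-rate ties (within 1e-10)
deterministically by higher yield, then lower EFM id.  ECM solutions are
cached by content hash of (model, EFM, condition).

## Synthetic bundles

The generators produce fully specified bundles at toy scale: chains (one
EFM), diamonds (two), a branch model with a certified rate/yield trade-off,
and seeded random networks (backbone chain plus shortcuts, some reversible,
some with 2:1 stoichiometry) for oracle comparisons.  Kinetic constants are
sampled log-uniformly from central-metabolism-like ranges (kcat 1–100 s⁻¹,
K_M 0.01–1 mM, masses 10⁴–10⁵ Da); equilibrium constants are assigned so
every forward-oriented mode has a 1-RT driving-force margin at a reference
profile (1 mM internal concentrations) — feasibility by construction rather
than post-hoc rejection, which keeps fixtures stable across solver
versions.  Each toy's `v_bm_mass` is set so yields land in the realistic
single-digit-to-tens g/C-mol range (e.g. 10 g/C-mol for the chain's unit
uptake, 20/10 g/C-mol for the branch model's two routes).

These toys exercise every code path but are not miniature E. coli: they
lack cofactor coupling, branched biomass composition, and realistic
parameter correlations.  Passing tests demonstrate algorithmic correctness
(enumeration, convex optimality, envelope identities, monotonicities), not
predictive accuracy on real networks — the latter depends entirely on the
quality of the kinetic constants in a user's bundle.

## Known limitations

* No flux bounds: optimal modes are always EFMs; elementary flux vectors
  under bounds are out of scope.
* No allosteric regulation terms in the rate law (the saturation-variant
  flag is the extension hook).
* Enumeration is exact but exponential; intended for core-scale networks,
  not genome scale.
* The growth-conversion law is a fitted approximation; its constants must
  be re-estimated for other organisms or media.
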