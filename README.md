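# efcm — Enzyme-Flux Cost Minimization

`efcm` predicts which metabolic strategy a fast-growing microbe should use,
and how fast it can grow, from a kinetic model of its metabolism.  It is
aimed at systems biologists studying rate/yield trade-offs (overflow
metabolism, respiration versus fermentation, ED versus EMP glycolysis) who
have a stoichiometric network plus kinetic constants and want quantitative,
condition-dependent growth predictions without imposing ad-hoc flux bounds.

## The method

A steady-state flux mode, scaled to unit biomass production, costs the cell
enzyme.  Under the common modular rate law the enzyme demand of reaction
*r* factorizes as

    E_r = v_r / (kcat_r · η_rev · η_sat)

with the thermodynamic efficiency `η_rev = 1 − e^(−θ_r)` (driving force
`θ_r = ln K_eq,r − Σ_i n_ir ln c_i`, in RT units) and the saturation
efficiency `η_sat` built from `c/K_M` terms.  The total enzyme mass
concentration `E_met = Σ_r w_r E_r` (mg/l, `w_r` = enzyme molecular mass)
is **convex** in the log metabolite concentrations, so its minimum over the
metabolite polytope (concentration bounds plus positive driving forces) is
found reliably by a single convex solve — this is Enzyme Cost Minimization
(ECM).

Because the optimized cost is concave on the flux polytope, the flux mode
that maximizes biomass production per enzyme is always an **elementary flux
mode** (EFM).  `efcm` therefore (1) enumerates all EFMs with an exact
rational double-description algorithm, (2) runs ECM on each, and
(3) converts each minimal cost into a growth rate via the proteome
allocation law

    μ = a·f_prot·v_BM / (E_met + b·f_prot·v_BM),

equivalently a doubling time `T = τ_met/(a·f_prot) + ln2·b/a` with
`τ_met = ln2·E_met/v_BM`.  Screening all EFMs yields the full spectrum of
achievable growth rates and biomass yields (g biomass per C-mol substrate),
its Pareto front, Monod surfaces over substrate concentrations, envelope
sensitivities `dμ/d ln p` for every kinetic parameter, and knockout and
epistasis predictions — the last two by simply discarding EFMs, with no new
optimization.

## Worked example

A built-in toy bundle with two routes from glucose to biomass — a
high-yield route with a slow, heavy enzyme, and a wasteful route (two
glucose per biomass) with a fast, cheap enzyme:

```sh
$ efcm synth --topology branch --out toy
$ efcm spectrum --model toy --out results --pareto
$ cat results/spectrum.tsv
efm_id  yield_g_per_cmol  mu_per_h        e_met_mg_per_l  pareto
0       10                1.26535747383   2889.74238999   1
1       20                0.564810182103  60055.9288907   1
```

EFM 0 (the wasteful route) halves the yield (10 vs 20 g/C-mol) but needs
~20× less enzyme (2 890 vs 60 056 mg/l), so it more than doubles the growth
rate (1.27 vs 0.56 h⁻¹).  Both modes are Pareto-optimal: this toy has a
genuine rate/yield trade-off.  Forcing the cell onto the efficient route:

```sh
$ efcm knockout --model toy --knockout low_yield --out ko
$ cat ko/knockout.tsv
knockouts   mu_wt          mu_ko           advantage
low_yield   1.26535747383  0.564810182103  1.24032341116
```

i.e. the wild type grows 124% faster than the knockout strain.

Other subcommands: `enumerate` (EFMs with yields and oxygen-rule
feasibility classes), `cost` (per-EFM metabolite profiles, enzyme demands
and efficiency factors), `monod` (glucose × oxygen scans with winner maps),
`sensitivity`, `pareto`, and `synth` for chain/diamond/branch/random toy
bundles.  The same functionality is available as a library
(`efcm.enumerate_efms`, `efcm.minimize_enzyme_cost`,
`efcm.rate_yield_spectrum`, ...).

## Model bundles

A model is a directory: `compounds.tsv` (internal metabolites with
concentration bounds in mM, externals with fixed concentrations),
`reactions.tsv` (formula, kcat⁺ in 1/s, K_eq in the mM convention, enzyme
mass in Da, tags such as `oxygen_sensitive`/`oxygen_dependent`), `km.tsv`
(per-reactant Michaelis constants, mM) and `config.json` (biomass and
uptake reaction ids, growth-conversion constants).  SBML can seed the
stoichiometry (`efcm.io.stoichiometry_from_sbml`); kinetics always come
from the tables.

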