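# Methods

## The problem

Multiscale biochemical networks are routinely reduced by the
quasi-steady-state approximation (QSSA): fast species are assumed
equilibrated given the slow state, their QSS values are substituted into
the slow equations, and non-elementary rate functions (Hill,
Michaelis–Menten, total-QSS roots) appear in place of the eliminated
elementary steps. The *stochastic* QSSA takes the same non-elementary
functions and uses them as propensities in a Gillespie simulation. That
step is heuristic: a reduction can be deterministically excellent and
stochastically wrong, because fluctuations push the system into regions of
state space the deterministic trajectory never visits.

`qssakit` operationalises a deterministic test of the stochastic QSSA:

1. simulate the *reduced* stochastic model to stationarity (or around its
   limit cycle);
2. form an initial-condition region: each slow species' mean ± 3 SD
   (or 1st–99th percentiles over one period in the oscillatory case),
   crossed with the **entire physical range** of each fast species, whose
   distribution is unknown without the full model;
3. over that region, measure the worst-case deterministic discrepancy

       E = max_{IC ∈ N}  ∫₀ᵀ |X_full(t) − X_QSSA(t)| dt
                         ───────────────────────────────
                             ∫₀ᵀ |X_QSSA(t)| dt

   between matched full/reduced ODE solutions of an observable X, the
   reduced model starting from the slow coordinates only.

If `E` stays below a threshold the stochastic reduction is declared valid.
The full model is integrated deterministically but **never simulated
stochastically** — that is the method's selling point.

The companion stochastic error measure (used to corroborate the criterion,
not by the verdict itself) is the relative difference of the observable's
stationary coefficient of variation between full and reduced SSA, with a
moving-block bootstrap standard error.

## Analytic companions

For the genetic negative-feedback system the package also exposes the
closed-form estimates that explain *why* the criterion works:

- **Initial-transient (IT) estimate.** While the promoter occupancy D_A
  relaxes (timescale `t_DA = 1/(k_f·R0 + k_b)`), the repressor moves by
  roughly `|ΔR|/R0 ≈ (β_R/k_f + D_A^max)/(R0 + K_D)`. `D_A^max` defaults
  to the fast species' upper physical bound (1 in the DNA-scaled model),
  the most conservative choice. The measured counterpart
  (`measure_it_phase_change`) integrates the full ODE over `5·t_DA` from
  the fast variable's extreme initial values and reports the worst
  relative change of R.
- **Stochastic validity terms.** The reduction is trustworthy when
  `k_f ≫ β_R` (binding genuinely fast) and
  `Var(D_A/D_T)·D_T/(R+K_D) ≪ 1` (the deterministic QSS tracks the
  conditional average of the fast species). Both are returned by
  `stochastic_validity_terms`.

## Model catalog

| entry | full model | reduction(s) | observable | time unit | default T |
|---|---|---|---|---|---|
| `genetic_nfl` | repressor/promoter NFL, D_A+D_R=1 | Hill transcription `α_M K_D/(K_D+R)`, K_D=k_b/k_f | R | h | 20 |
| `coop_enzyme` | two-step cooperative enzyme, E+E_S+E_S2=1 | `k_p S²/(K_m²+S²)`, K_m²=K_m1·K_m2 | S | s | 4000 |
| `oscillator` | NFL oscillator with promoter binding, D_A+D_R=D_T | tQSSA (in T=R+D_R) and pQSSA (in R, prefactor p(R)) | M | h | 40 |
| `composite_nfl` | NFL with enzymatic degradation, two conservation laws | ER / DR / EDR partial reductions | R | s | 2000 |
| `linear_cascade` | constitutive mRNA→protein | birth–death for P at rate `α_M α_P/k_M` | P | – | 100 |

Reference parameter values are the catalog defaults (`qssa catalog` prints
them with units). Choices that were genuinely open:

- **K_d of the total/prefactor QSS root.** Solving the fast balance
  `k_f(T−D_R)D_A −(k_b+β_R)D_R = 0` with `D_R = D_T−D_A` gives the
  quadratic root with **K_d = (k_b+β_R)/k_f**. A dimensionally
  inconsistent variant of this constant ((k_f+β_R)/k_b) circulates; we
  implement the algebraically derived form and enforce it with a residual
  test (`< 1e-8` across `T ∈ [0, 2·D_T]`).
- **Stochastic pQSSA.** The prefactor p(R) multiplies dR/dt and has no
  unambiguous stochastic counterpart. The ODE engine divides the
  assembled derivative by the prefactor; the stochastic pQSSA
  (`reduced.without_prefactor()`) uses the reduced reaction rates as
  propensities on the untransformed variable. SSA engines refuse
  prefactored networks outright so the choice is always explicit.
- **Total enzyme E_T of the composite model** is not part of the
  reference set. We scale concentrations by total enzyme (E_T = 1), as in
  the cooperative model; this puts the reduced steady state near R ≈ 94,
  the scale at which the Hill-reduced transcription visibly disagrees
  with the elementary chemistry. It is a plain parameter
  (`make_composite_nfl(E_T=...)`).
- **Composite translation constant** appears both as a generic
  translation rate and as k_R in the reduced equations; one parameter
  named `k_R` is used.
- **Composite initial condition** starts the promoter unrepressed
  (D(0)=D_T) with M(0)=R(0)=E_R(0)=0 — a switch-on experiment.
- **Oscillator initial conditions** default to a point on the
  deterministic limit cycle of the full model, found by integrating 200 h
  past transients (cached per parameter set).
- **α_R of the genetic NFL** is not fixed by the reference set; default
  1/h.

## Numerical choices

- **ODE integration**: `scipy.integrate.solve_ivp` with LSODA,
  rtol = 1e-8, atol = 1e-10. The full models are stiff when binding
  constants are large, and the IT phase (timescale `1/(k_f·R+k_b)`) must
  be resolved; a convergence test checks that halving the tolerances
  moves reported errors by < 1%.
- **Error quadrature**: trapezoidal rule on the shared uniform output
  grid, default 2000 intervals. The integrand is piecewise smooth and the
  metric is a ratio, so modest grids suffice (verified against adaptive
  quadrature to 1e-6 on analytic pairs).
- **IC grid**: full cartesian product, 5 points per dimension including
  endpoints; grid points violating joint constraints (e.g. promoter
  states summing past D_T) are skipped; the argmax IC is reported so
  users can refine locally.
- **Verdict threshold**: there is no universal pass line for a relative
  L1 error — the underlying claim is comparative. The default, 0.02, is a
  convention calibrated on the catalog: every known-good reduction
  measures ≤ 0.006 under the default settings and every known-bad one
  ≥ 0.033, so 0.02 sits ≥ 3× from both sides. It is reported alongside
  the raw error and is always overridable.
- **Default horizons** T (table above) cover the slow transient at each
  entry's parameters: ~20 slow lifetimes for the genetic loop, ~11
  periods for the oscillator, ~5 repressor lifetimes (and the ~900 s DNA
  re-equilibration) for the composite model. Longer horizons dilute the
  transient discrepancy that the metric is meant to catch; much shorter
  ones miss slow re-equilibration entirely.
- **SSA**: exact direct method. Propensities are `a_j = Ω·f_j(n/Ω)` for
  both elementary and non-elementary macroscopic rates f_j; Ω = 1 unless
  a model requires otherwise (the composite model uses Ω = 100 so the
  DNA total D_T = 0.01 maps to one promoter copy). An optional
  `microscopic_exact` flag switches identical-reactant mass action to the
  combinatorial n(n−1)/2Ω form; no catalog model needs it.
- **Ensembles**: stationary statistics take one sample per replicate at
  t_end (no within-trajectory pooling, hence no autocorrelation).
  Defaults are desk-scale — 10⁴ replicates for moment checks, 10³ for
  sweeps, 300–500 for validation regions — with block-bootstrap standard
  errors (block length 100, the samples resampled in contiguous blocks
  and the statistic recomputed per resample) quantifying what those sizes
  resolve. Burn-in defaults to 10× the slowest first-order decay
  timescale of the simulated network; entries whose slowest relaxation is
  not a declared decay (cooperative enzyme ≈ 900 s, composite ≈ 400 s)
  carry explicit defaults (6000 s, 1500 s).
- **Seeding**: one root seed; replicate r uses the counter
  `seed_base + r` passed through a SplitMix64 hash before seeding the
  stream (consecutive-integer Mersenne seeding leaves early-sequence
  cross-correlation between streams that measurably biases ensemble
  moments). Ensembles are bit-reproducible and order-independent. The
  single-trajectory reference implementation (`gillespie_run`, pure
  Python over PCG64) is an independent cross-check of the compiled
  kernel.
- **Unbounded fast species** (the cascade's mRNA) have no "entire
  physical range". The validator demands an explicit cap, or — if the
  user permits a short auxiliary full-model SSA — caps at the fast
  species' stationary mean + 5 SD. Both paths are recorded in the report
  provenance.

## What the simulations do and do not show

All experiments are self-generated: the SSA ensembles play the role of
data. They emulate well-mixed intrinsic noise exactly (direct-method
sampling of the chemical master equation); they do not emulate extrinsic
noise, cell growth/division, or spatial effects, so a passing verdict
speaks to the master-equation model only. Ensemble sizes are desk-scale
rather than the 10⁶-replicate scale a cluster study would use; all
reported stochastic quantities therefore carry bootstrap standard errors,
and tests assert agreement within 3 SE rather than to fixed digits.

Two failure modes of the criterion itself are inherited from its design
and demonstrable with the catalog:

- **False negatives** when the fast species' real fluctuation range is
  much smaller than its physical range (e.g. the unscaled promoter model
  at large copy number D_T: requiring accuracy over *all* D_A values is
  stricter than the fluctuations warrant). Normalising the fast species
  so that copy number enters only through rate constants removes the
  artefact.
- **False positives** when fluctuations of an unbounded fast species
  matter but the tested region cannot cover them: the linear cascade at
  small k_P passes the deterministic test while its stochastic CV error
  remains at the ~25% level, because the discrepancy lives in the
  variance, not in any single deterministic trajectory. The closed-form
  variances (`closed_form_variances`) quantify exactly this gap and its
  √k_P decay.

## Known limitations

- The verdict threshold is a calibrated convention, not a theorem; treat
  borderline errors (within ~2× of the threshold) as "inspect by hand",
  starting from the reported argmax initial condition.
- No linear-noise or moment-closure refinement of the fast-species
  distribution is implemented; the fast ranges are physical ranges.
- No tau-leaping or hybrid acceleration: SSA is exact and the costly
  regime (very fast binding cycles) is exactly where the validator lets
  you avoid full-model SSA altogether.
- Closed-form rate expressions are restricted to a whitelisted grammar
  (+, −, ×, ÷, powers, sqrt); arbitrary functions would defeat both the
  safety argument and the compiled SSA kernel.
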