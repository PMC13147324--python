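# Methods

## Scope and model

`saftsol` predicts the equilibrium solubility of a crystalline drug (API)
in pure and mixed organic solvents.  Two ingredients define the model:

1. **Solid–liquid equilibrium (SLE).**  Equating the chemical potential of
   the pure crystal and of the drug in the saturated liquid, with the
   hypothetical subcooled liquid as reference state and a temperature-
   independent Δc_p, gives

       x_API · γ_API(x, T) = exp[ −Δh_SL/(R·T) · (T_SL − T)/T_SL
                                  − Δc_p_SL/R · (ln(T_SL/T) + (T − T_SL)/T) ]

   The right-hand side depends only on the melting properties of the
   polymorph (T_SL, Δh_SL, Δc_p_SL).  Polymorphs of the same drug share all
   liquid-phase parameters and differ only in these three numbers, so
   polymorph solubilities follow from one parameter set plus per-polymorph
   melting data.  When Δc_p_SL has not been measured it is approximated by
   the melting entropy Δh_SL/T_SL (`approximate_dcp`); approximated entries
   in the bundled table carry a flag.

2. **PC-SAFT activity coefficients.**  γ_API is computed from the
   perturbed-chain SAFT equation of state as
   γ_i = exp(ln φ_i(T, P, x) − ln φ_i_pure(T, P)), both fugacity
   coefficients on the liquid branch at the same (T, P).  The reduced
   residual Helmholtz energy is hard chain + second-order dispersion +
   Wertheim association restricted to the 2B scheme (one donor-like A site
   and one acceptor-like B site per associating molecule; only A–B bonds
   form).  Each substance carries five parameters — segment number m_seg,
   segment diameter σ (Å), dispersion energy u/k_B (K), association energy
   ε^AB/k_B (K), association volume κ^AB — plus the molar mass.

### Mixing and combining rules

* σ_ij = (σ_i + σ_j)/2;  u_ij = √(u_i·u_j)·(1 − k_ij).  The binary
  parameter k_ij enters only the cross dispersion energy; k_ij = 0
  recovers the plain Berthelot–Lorentz combining rules, and absent pairs
  default to 0 with a logged notice.
* Cross association uses the Wolbach–Sandler rules:
  ε^AiBj = (ε^AiBi + ε^AjBj)/2 and
  κ^AiBj = √(κ^AiBi·κ^AjBj)·(√(σ_i σ_j)/(½(σ_i+σ_j)))³.
* Association strength Δ^AiBj = σ_ij³·g_ij^hs(d_ij)·κ^AiBj·(exp(ε^AiBj/T) − 1),
  the convention of the widely used open PC-SAFT implementations.
* A 2B record with κ > 0 but ε = 0 (two of the bundled drugs) has zero
  self-association strength but acquires a nonzero cross-ε with an
  associating solvent through the arithmetic-mean rule: it behaves as an
  induced cross-associator, which is the natural reading of such parameter
  sets and is what these combining rules produce without special cases.

### Numerics

* **Derivatives.**  All first derivatives of the residual Helmholtz
  function (density for Z and pressure; mole numbers for fugacity
  coefficients) are evaluated by complex-step differentiation with step
  1e-100.  This is exact to machine precision — no truncation or
  subtractive cancellation — and keeps the whole property stack driven by
  one scalar function.  The test suite cross-checks these derivatives
  against centered finite differences (rel. 1e-6) and the hard-chain and
  dispersion terms against an independent transcription of the published
  expressions kept inside the test suite.
* **Site fractions.**  The 2B mass balance is solved by damped successive
  substitution (damping 0.5) from X = 1 to a 1e-12 max-norm residual, 500
  iterations maximum; for a pure 2B fluid the quadratic closed form is
  available as a check (ρΔ = 2 ⇒ X = ½).  The iteration is vectorised
  across density grids and propagates complex perturbations, so derivative
  information flows through the association term consistently.
* **Density roots.**  P(η) is scanned on a vectorised packing-fraction
  grid over (1e-12, 0.74); sign-change brackets are refined by Brent's
  method plus a secant polish to a 1e-10 relative pressure residual.  The
  liquid branch takes the largest mechanically stable root (dP/dη > 0),
  the vapor branch the smallest, which avoids the unstable middle root.
  Iterative callers (the SLE fixed point, k_ij regression) warm-start the
  root from the previous solve and skip the scan.
* **Reference state.**  All activity coefficients and solubilities are
  evaluated at 101325 Pa.  Below the melting point the pure-drug reference
  is the subcooled liquid: the density solve is forced onto the liquid
  branch, consistent with the SLE reference state.  Pure-component ln φ
  values are cached per (substance, T, P).
* **SLE solver.**  The equilibrium residual g(ln x) = ln x + ln γ(x) − ln(RHS)
  is driven to zero by a safeguarded secant iteration (the plain fixed
  point is a unit-slope Newton step and crawls when ln γ varies strongly
  with ln x; the secant estimates the true slope 1 + ∂ln γ/∂ln x and
  converges in ~10 evaluations).  Damped (0.5) fixed-point steps are the
  safeguard whenever the secant slope is unusable, and bisection on g is
  the final fallback.  Convergence: |Δ ln x| < 1e-10.  A root driven to
  x → 1 is reported as fully miscible, not an error.  A `damping=`
  argument restores the plain damped iteration.
* **g/L conversion.**  S = ρ_solvent[g/L] · x/(1−x) · M_API/M_solvent.
  The molar-mass ratio orientation is fixed by dimensional analysis and
  two checks the conversion must satisfy: the symmetric case (x = ½, equal
  molar masses) returns the solvent density, and the Henry limit is linear
  in x with slope ρ·M_API/M_solvent.  For blends, M_solvent is the
  API-free mole-weighted mean and ρ_solvent defaults to the PC-SAFT
  API-free blend density at (T, 101325 Pa); a user-supplied experimental
  density overrides it.

## Parameter data

* The bundled drug table covers 21 APIs with ML-derived five-parameter
  sets (2B or non-associating) and a melting-property table with the
  approximation flags.  Tables at rest keep the conventional printed units
  (σ in Å, energies in K, Δh in kJ/mol); loaders convert to J/mol once at
  the boundary.
* The bundled solvent table carries 13 common solvents with literature
  PC-SAFT sets (Gross & Sadowski 2001 non-associating; Gross & Sadowski
  2002 2B associating), each row with a citation string.  Users can swap
  in their own tables via the YAML config.
* k_ij is temperature independent, stored symmetrically with provenance
  (`ml_given`, `fitted_single_point`, `literature`); k_ii = 0.

## Fitting and evaluation

* `fit_kij_single_point` solves ln x_calc(k) = ln x_exp by Brent's method
  in k, bracketed in [−0.2, 0.2] and expanded stepwise to [−0.5, 0.5]; no
  sign change in the maximal bracket returns a non-converged report with
  the best k found.  The least-squares variant minimises Σ(Δ ln x)² over
  the same bracket and reduces exactly to the single-point fit for one
  point.
* `evaluate_dataset` scores predictions with R² on ln x, MAE on ln x and
  AARD (%).  MAE and R² operate on ln x because solubilities span orders
  of magnitude; AARD defaults to the ln-x scale as well and can be
  switched to linear x (the choice is logged in every report).  In the
  single-point-fit scenario each single-solvent system's k_ij is refit to
  its anchor point (default: the point at the system's median temperature)
  and anchors remain in the evaluated set; a flag excludes them.

## Synthetic data

The generators exist so every fitting and evaluation path can be tested
with known ground truth.  Toy components are drawn inside the parameter
spans of the bundled drug table (m_seg ∈ [3.5, 12.1], σ ∈ [2.8, 3.9] Å,
u/k_B ∈ [247, 353] K, ε ∈ [0, 4339] K, κ ∈ [0, 0.046]); toy solvents are
lighter (m_seg ∈ [1.8, 3.6], M_w ∈ [30, 120] g/mol), matching common
organic solvents.  Pseudo-experimental datasets put Gaussian noise on
ln x — multiplicative solubility error is the empirical norm — with
default σ = 0.1, six points per system over 278–323 K, and true k_ij
drawn uniformly from ±0.05, the magnitude range typical of fitted PC-SAFT
binary parameters.  All randomness flows from a single seed through
numpy's PCG64.

The benchmark emulates the two data-availability scenarios: "given" k_ij
values are the true ones perturbed by ±0.02 (imperfectly estimated
parameters), against which the single-anchor refit is compared.  What the
synthetic data does *not* emulate: systematic experimental bias,
polymorph misassignment, solvate formation, electrolyte effects, or any
structure–parameter relationship — passing these tests shows the solver,
fitting and scoring machinery is correct, not that the physical model
reproduces any particular laboratory dataset.

## Problem sizes

Default study sizes: the scenario benchmark uses 20 systems × 5 points
(noise σ = 0.1, perturbation ±0.02); the noisy recovery study uses 100
replicates at σ = 0.05 in the test suite and 50 in the acceptance script;
the self-consistency scan uses 10 random pairs against a 45-point log
grid.  These sizes give stable medians and aggregate metrics while
keeping a full run in the minutes range on one core.

## Known limitations

* Only the 2B association topology is implemented (the bundled drug sets
  use nothing else); 3B/4C schemes, polar/quadrupolar terms and
  electrolyte (ePC-SAFT) contributions are out of scope, so buffered or
  salt-containing aqueous systems are outside the model's domain.
* No vapor–liquid flash or phase-envelope tracing; the density/fugacity
  primitives are present but equilibrium between fluid phases is not
  solved.
* Solid solutions, solvates/hydrates and amorphous solubility are not
  modeled; the crystal is assumed pure and stoichiometric.
* The solvent–solvent k_ij of a blend must come from external data
  (VLE-fitted or estimated elsewhere); the sweep warns loudly when it is
  left at 0.
* Liquid densities inherit the bias of the literature parameter sets
  (e.g. the 2B water set underestimates the ambient liquid density by
  ~8%), which propagates into g/L conversions computed from PC-SAFT
  densities; supplying experimental solvent densities avoids this.
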