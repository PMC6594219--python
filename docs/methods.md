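# Methods

## Scope and units

ionsolv implements the analysis arm of an alchemical solvation study of
hydronium and chloride ions in water/organic mixtures: free-energy
estimation from reduced-potential samples, analytical corrections,
water→solvent transfer cycles, solvent-structure descriptors, and a
correlative model for reaction kinetics. It does not run molecular
dynamics: no thermostats, barostats, Ewald electrostatics, force-field
parameterization, or bond constraints. Production MD output can be
converted to the package's TSV reduced-energy dialect (one row per stored
configuration, one column per λ window, entries u = βU) and analyzed
identically.

Units are fixed package-wide: kJ/mol for energies, nm for lengths, K for
temperature, elementary charges for charge. Reduced potentials are
dimensionless; conversion to kJ/mol happens only at result boundaries,
using k_B = 0.0083144621 kJ/(mol·K).

## Alchemical model

The coupled potential scales solute–solvent Lennard-Jones interactions by
λ_LJ and electrostatics by λ_elec, leaving solvent–solvent and
intramolecular terms untouched. The package's toy solutes are monatomic,
so the intramolecular terms are configuration-independent constants that
cancel in every free-energy difference; they are documented here rather
than simulated.

The LJ term uses the Beutler soft-core form

    U_sc(r; λ) = λ · 4ε [ (σ⁶ / (α σ⁶ (1−λ)^p + r⁶))² − σ⁶ / (α σ⁶ (1−λ)^p + r⁶) ],

with the conventional defaults α = 0.5 and p = 1 and a linear λ
prefactor. These constants are a documented assumption: the soft-core
family has several common parameterizations, and any member that is
finite at r → 0 for λ < 1 and reduces to plain 12-6 LJ at λ = 1 (which
this one does identically) serves the estimators equally. Electrostatics
are a truncated-and-shifted Coulomb interaction scaled linearly by
λ_elec; the package deliberately avoids lattice sums.

The default schedule has 17 windows ordered decoupled → coupled: λ_LJ ∈
{0, 0.00922, 0.04794, 0.11505, 0.260634, 0.31608, 0.43738, 0.56262,
0.68392, 0.79366, 0.88495, 0.95206, 0.99078, 1} at λ_elec = 0 (a 12-point
Gaussian interior sequence plus endpoints), then λ_elec ∈ {0.25, 0.75, 1}
at λ_LJ = 1. Growing repulsion before charge avoids the divergence of a
bare charge inside an overlapping solvent. Solvation ΔG is defined as
coupled minus decoupled.

## Estimators

`mbar_solve` solves the multistate self-consistency equations with the
gauge f_0 = 0, using log-sum-exp throughout. The solver iterates the
self-consistent update (robust far from the solution) and switches to
damped Newton–Raphson on the gradient of the convex MBAR objective once
the residual drops below 1 reduced unit; convergence means the maximum
per-state change is below `tol` (default 1e-8 reduced units, max 10,000
iterations — both exposed because no universal choice exists).
Zero-sample states participate only as evaluation states. `bar_pair`
solves the Bennett self-consistency equation by bracketed root finding
(brentq inside an expanding bracket around the mean forward/reverse
work); it agrees with two-state MBAR to solver tolerance and is used for
adjacent-window consistency checks. `exp_averaging` is one-sided Zwanzig
averaging with a log-sum-exp guard; it is a diagnostic, not the
production estimator, since its bias decays slowly with poor overlap.

Samples are treated as uncorrelated. The well-separated subsampling
interval of the intended inputs justifies this; for heavily correlated
input the user should thin before building the matrix (a statistical-
inefficiency pre-step is deliberately not applied by default, so that the
estimator output is a pure function of the supplied samples).

**Uncertainty** follows the two-trial protocol: each window's time-ordered
samples are split (first ⌈N/2⌉ / rest), the endpoint ΔG is estimated
independently on each half, and the report is the trial mean ± the trial
sample standard deviation (divisor n−1, i.e. |ΔG₁−ΔG₂|/√2). With one
degree of freedom this error bar is itself noisy; consistency tests
therefore compare estimators at 3 combined standard deviations.
Covariance-matrix MBAR errors are intentionally out of scope — the
two-trial protocol is the reporting convention this package mirrors.

## Analytical corrections

Three additive terms, each reported separately and summed exactly:

* **finite-size** — leading-order periodic self-interaction of a charged
  solute on a cubic lattice, ξ_EW q²/(8π ε₀ ε_r L) per mole with
  ξ_EW = −2.837297. Higher-order (quadrupole/solvent-response) terms are
  omitted; for the 6 nm boxes and high dielectrics this package targets,
  the leading term is itself only a few tenths of kJ/mol.
* **compression** — RT ln(c₂/c₁) with c₁ = P/(RT), the standard-state
  change from a 1 atm ideal gas to a 1 mol/L ideal solution. Evaluated at
  298.15 K by default (7.9 kJ/mol; 300 K gives 8.0) because the value is
  a thermochemical reference-state convention rather than a property of
  the simulated ensemble; the temperature is overridable.
* **interface** — qFχ per mole for carrying charge q across the
  vacuum→liquid surface potential χ. χ is a per-solvent-model
  configuration input; no value is shipped as authoritative because χ is
  model-dependent and sign conventions vary across the literature.

Corrections never mutate raw estimates; both raw and corrected values are
retained in the solvation record.

## Transfer cycles

Transfer free energies are exact differences of solvation records for the
same ion; uncertainties combine in quadrature (the underlying trials are
independent; no propagation rule is canonical here, quadrature is the
package's choice). The electroneutral sum is the exact sum of the
hydronium and chloride transfers. Classification by the hydronium
transfer sign calls zero "destabilizing": zero transfer means no driving
force, and the water baseline itself must not be labelled stabilizing.

## Structure descriptors

RDFs use mass-weighted centers of mass, cubic minimum-image distances,
0.02 nm bins by default, and per-frame normalization density (so NPT box
fluctuations are handled frame by frame). The local/bulk cutoff is
defined as the first radius past the global maximum where the smoothed
RDF (centered moving average, 5 bins) enters the band 1 ± tol
(tol = 0.05) and stays inside for at least 5 consecutive bins. "Reaches
unity" is genuinely ambiguous for noisy RDFs; the sustained-entry rule
makes the detector robust to single-bin crossings, and both tol and the
window are exposed. Typical solute–water RDFs in the intended systems
settle near 1.6 nm; that number is context, not a constant in the code.

Γ is averaged per frame; frames with an empty bulk water domain are
skipped and counted rather than failing the run (the ratio n_C^B/n_W^B is
undefined there, and discarding such frames biases nothing when the bulk
is well populated, which the box-size precondition enforces). The
uncertainty is a 10-block standard error over the per-frame values. Γ′
multiplies Γ by the sign of the hydronium water→pure-organic transfer;
a transfer of exactly zero has no sign and raises.

## Correlative kinetics

σ = ln(k_org/k_water). The defining ratio form cannot be negative, yet
negative solvent effects are physically meaningful and discussed
throughout the intended application, so the natural logarithm of the
ratio is adopted — the antecedent kinetics literature defines the solvent
parameter on a log rate-ratio scale. This choice is flagged prominently
because it is an interpretation, not a transcription.

The one-descriptor model σ_pred = A·Γ′ is fit without intercept (its
defining form has none). The two-descriptor model standardizes Γ′ and
the hydronium solvation ratio with sample statistics (divisor n−1), fits
ordinary least squares with intercept, and freezes the training
means/SDs into the model so prediction on new data is well defined.
Standardized descriptors with |r| > 0.999 raise a collinearity error.
Parity slope is the least-squares slope, with intercept, of observed σ
on predicted σ (the parity line the model-quality figures report is a
best-fit line, not a forced y = x). RMSE is over σ_pred − σ_exp
directly, not over parity-line residuals — the alternative is noted as
unresolved in the source material and this is the package's choice.
Pearson r is reported overall and per solvent subset.

## Synthetic generators

* **Harmonic ensembles** sample 1-D Gaussians exactly; state i has
  reduced potential βk_i(x−x0_i)²/2 and analytic reduced free energy
  ½ ln(k_i/k_0). This is the primary estimator oracle: recovery is a
  property of the estimator alone, with no sampling-systematics
  confound.
* **The LJ fluid** is Metropolis Monte Carlo: a point solute fixed at the
  center of a cubic box, single-particle displacement moves accepted with
  the full coupled potential at the window's λ, step size tuned toward
  ~40% acceptance during the burn-in (first 20% of steps, discarded),
  and a warning if the final acceptance rate leaves [0.05, 0.95].
  Retained configurations are re-evaluated at every window to build the
  cross-evaluated matrix. Desk-scale guard: at most 100 particles.
  Cross-estimator consistency checks run at 40 particles, box 1.6 nm,
  ε = 0.65 kJ/mol, σ = 0.32 nm, cutoff 0.75 nm, 15,000 steps/window
  sampled every 15 — a moderately dense fluid (ρσ³ ≈ 0.33) chosen so the
  endpoint free energy is non-trivial while adjacent windows keep
  generous overlap.
* **Mixture trajectories** realize a piecewise-constant water mole
  fraction x_W(r) around a fixed central solute. Per frame, region
  totals (profile shells plus the remaining box volume at bulk
  composition) are drawn by randomized systematic rounding against the
  uniform number density — totals are conserved exactly in every frame
  and per-region expectations equal the continuous targets exactly —
  then positions are placed uniformly within each region and species
  shuffled within regions. Frames are i.i.d.; there is no dynamics. The
  expected Γ for any cutoff follows from region/sphere overlap volumes,
  with the frame-average ratio approximated by the ratio of expectations
  (accurate to ≪ 0.1 at the generator's default counts). Supplied
  molecule totals must be consistent with the profile to within one
  molecule per shell, or the generator raises; `consistent_counts`
  produces matching totals.
* **Kinetic datasets** draw σ from the standardized two-descriptor model
  plus Gaussian noise, using the same standardization convention as the
  fitting routine, so the zero-noise round trip is exact to machine
  precision. Default design: 8 composition points, descriptor ranges
  Γ′ ∈ [−2, 2] and ΔG ratio ∈ [1.0, 1.3] (ratios above unity, as for
  cosolvent systems whose hydronium solvation is stronger than water's),
  noise SD 0.1 — comparable to experimental scatter in σ.

What the generators do **not** emulate: real solvation shells with
correlated structure, autocorrelated trajectories, NPT volume
fluctuations, multi-site molecules with rotational degrees of freedom,
and force-field physics. Passing tests therefore demonstrate the
correctness of the estimators, descriptors, cycles, and fits as
mathematical procedures on their defined inputs — not the accuracy of any
force field or sampling protocol on real systems.

## Numerical choices and degenerate inputs

* Log-sum-exp guards every exponential average; BAR's Fermi sums use the
  logistic function directly (bounded, no overflow).
* BAR raises a non-overlap error when forward and reverse work
  distributions are both one-sided beyond 50 reduced units.
* The TSV reader reports the offending line number for ragged rows,
  non-finite entries, and unknown state labels; rows grouped out of
  order are re-sorted stably by origin state.
* GRO output uses the standard fixed 3-decimal format; coordinates
  round-trip at that precision (the XYZ dialect carries 6 decimals).
  Multi-atom GRO molecules are reduced to equal-mass centers; synthetic
  trajectories are single-site so this is exact for them.
* Identical config and seed give byte-identical numeric outputs; all
  randomness flows from one integer seed per generator call
  (numpy PCG64).

## Test and acceptance problem sizes

The suite runs harmonic oracles at 2,000–50,000 samples per state,
replicate studies at 100 seeds, the LJ pipeline at 40 particles ×
15,000 steps × 17 windows, and Γ recovery at 50 seeds × 300 frames of
700 molecules — sizes chosen to keep statistical power high (coverage
tests have ≥ 5-point margins) while the whole suite and the acceptance
script each complete in about a minute on a single CPU.

## Known limitations

* The two-trial error bar has one degree of freedom and fluctuates
  widely; it mirrors a reporting convention rather than best practice.
* Chained EXP retains O(1/N) bias under imperfect overlap; it is included
  as a diagnostic only.
* The finite-size correction is leading-order only and the interface
  term is linear in a user-supplied χ; neither replaces a rigorous
  charge-correction scheme for quantitative single-ion work.
* `expected_gamma` uses the ratio-of-expectations approximation; for
  very small bulk water counts it degrades, and the generator's
  feasibility checks keep usage away from that regime.
* The kinetic model is correlative: coefficients carry no mechanistic
  meaning beyond the descriptors' definitions.
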