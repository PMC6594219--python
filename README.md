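# ionsolv

Desk-scale tooling for quantifying the stability of hydronium (H3O+) and
chloride ions in water/organic mixed solvents, and for linking that
stability to the rates of Brønsted acid-catalyzed reactions such as the
dehydration of 1,2-propanediol in aqueous dioxane, THF, GVL, NMP, acetone,
or DMSO.

It is written for molecular-simulation practitioners who want the full
analysis arm of an alchemical solvation study — estimators, corrections,
thermodynamic cycles, structural descriptors, and the correlative kinetic
model — as tested, seedable Python, exercisable end to end on synthetic
data with analytically known ground truth.

## What it computes

**Solvation free energies.** Samples from a ladder of alchemical windows
(λ_LJ, λ_elec), in which solute–solvent Lennard-Jones and electrostatic
interactions are progressively coupled, are combined with the multistate
Bennett acceptance ratio. MBAR solves

    f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_k N_k exp(f_k − u_k(x_n)),  f_0 = 0,

for the reduced free energy f_i of every window from the reduced-potential
matrix u_k(x_n) = βU_k(x_n). Exponential averaging (EXP) and the two-state
Bennett acceptance ratio (BAR) are provided as cross-checks. Uncertainty
follows a two-trial protocol: each window's time series is split in half,
the endpoint ΔG is estimated on each half, and the mean ± sample standard
deviation of the two trials is reported. The default schedule has 17
windows: 14 growing the soft-core Lennard-Jones interaction at zero
charge, then 3 charging at full LJ.

**Analytical corrections.** Three standard terms bridge simulation and
experiment: the periodic finite-size self-interaction
(ξ_EW q²/(8π ε₀ ε_r L), cubic lattice), the standard-state compression
term RT ln(c₂/c₁) for moving a 1 atm ideal gas into a 1 mol/L ideal
solution (7.9 kJ/mol at 298.15 K), and the surface-crossing term qFχ.

**Transfer cycles.** ΔG_transfer(H2O→k) = ΔG_solv(k) − ΔG_solv(H2O) per
ion; the electroneutral sum ∑ΔG over the H3O+/Cl− pair proxies the
solvent's effect on acid dissociation; solvents are classified as
stabilizing (negative hydronium transfer) or destabilizing.

**Structure descriptors.** Solute-centered radial distribution functions
with minimum-image convention, the local/bulk domain cutoff where g(r)
settles back to unity after its main peak, and the preferential exclusion
coefficient

    Γ = −⟨ n_C^L − n_W^L (n_C^B / n_W^B) ⟩,

positive when the local domain is depleted of cosolvent. Its sign-corrected
form Γ′ = Γ·sign(ΔG_transfer^{H3O+, H2O→pure organic}) tracks enrichment of
whichever solvent stabilizes the catalyst.

**Correlative kinetics.** The kinetic solvent parameter
σ = ln(k_org/k_water) is fit against standardized descriptors,
σ_pred = A·ẑ(Γ′) + B·ẑ(ΔG ratio) + C, and judged by parity slope, RMSE,
and Pearson r.

**Synthetic generators.** Every input above can be produced with known
ground truth: exact 1-D harmonic alchemical ensembles (analytic
Δf = ½ ln(k_j/k_i)), a Metropolis Monte Carlo Lennard-Jones fluid over
the 17-window schedule, mixture trajectories with a prescribed radial
water-enrichment profile (expected Γ computable by shell integration),
and kinetic datasets drawn from the correlative model itself.

## Worked example

```bash
ionsolv all --seed 7 --out demo
```

chains the full pipeline on synthetic data and logs:

```
pipeline complete: {"compression_kJ_per_mol": 7.925869722586361,
 "gamma": 18.84148340151821,
 "harmonic_delta_f_analytic": 0.6931471805599453,
 "harmonic_delta_f_estimate": 0.7090768290944975,
 "model_parity_slope": 1.0000000000000002,
 "model_rmse": 0.052269772334794795}
```

Reading these numbers: the standard-state compression correction
reproduces the 7.9 kJ/mol reference value; MBAR with the two-trial
protocol recovers the analytic harmonic free-energy difference
½ ln 4 ≈ 0.693 within its statistical error; a mixture trajectory whose
inner nanometre is built 90% water over a 50% bulk yields a strongly
positive preferential exclusion coefficient (Γ ≈ 18.8, cosolvent pushed
out of the local domain); and the two-descriptor model refit on data
generated at noise 0.05 gives a parity slope of 1 and an RMSE at the
injected noise level. Per-stage outputs (free_energy.json,
transfer_table.csv, gamma.json, model.json, config.yaml, and the run log)
land in `demo/`.

The same stages are available individually (`simulate`, `estimate`,
`correct`, `cycle`, `rdf`, `gamma`, `correlate`) and as library functions
(`ionsolv.mbar_solve`, `ionsolv.gamma`, `ionsolv.fit_multilinear`, ...).

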