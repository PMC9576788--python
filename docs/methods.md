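# Methods

## The model

A cell migrating inside a stiff confining microchannel is represented as a
one-dimensional two-phase medium on `x in [0, L]`, written in the frame
moving with the cell: the back of the cell is at `x = 0`, the front at
`x = L`, and positive steady velocity `v0` means migration toward the
front.

**Mechanics.**  The cytosol (pressure `p`, velocity `v_c`) and the F-actin
network (concentration `theta_n`, velocity `v_n`) exchange momentum through
interfacial friction `eta theta_n (v_c - v_n)`; incompressibility makes
`v_c` spatially constant.  The network carries a swelling stress
`sigma_n = k_sigma theta_n` and transmits focal-adhesion traction
`-eta_st theta_n v_n` to the substrate.  G-actin (`theta_c`) diffuses and
advects; polymerization occurs only at the front membrane at the saturating
rate `J_actin = J_f theta_c / (theta_cc + theta_c)`, depolymerization at a
constant rate `gamma` throughout.  Total actin is conserved:
`int (theta_n + theta_c) dx = L theta_*`.

**Water.**  Each end exchanges water osmotically,
`J_water = -alpha [(p - p_*) - RT (c - c0)]` with `c` the total osmolyte
concentration at that end, and the effective outside pressure `p_*`
accounts for channel hydraulic resistance: `p_*^f = p0 + d_g (v0 - J_f)`
and `p_*^b = p0 - d_g (v0 + J_b)`.  The water fluxes close the cytosol
problem through `v_c - v0 = -J_water^f` at the front and
`v_c - v0 = +J_water^b` at the back; at steady state this forces
`J_water^f = -J_water^b` (stationary volume).

**Electrodynamics.**  Eight solutes are carried: Na+, K+, Cl-, H+, HCO3-,
an impermeant average protein A^(z_A), and a protonatable buffer pair
Buf-/HBuf.  Bulk transport is Nernst-Planck,
`J_n = -D_n c_n' + u c_n - D_n (z_n F / RT) c_n phi'`, closed by
electroneutrality `sum z_n c_n = 0` (which determines the potential `phi`)
instead of a Poisson equation.  pH is the primary acid-base unknown;
`c_H = 10^3 10^-pH`, `c_HCO3 = (P_CO2/k_H) 10^(pH - pK_c)` and
`c_HBuf = c_Buf 10^(pK_B - pH)` are substituted algebraically wherever they
appear, so derived fields can never drift out of sync.  H+, HCO3- and the
buffer are transported as one combined family (flux
`J_HCO3 + J_Buf - J_H`); the buffer total and A- obey zero-flux and global
content constraints.

**Membrane pathways** (per end, positive inward): passive
electrodiffusive leaks for Na+, K+ and Cl-
(`J = alpha_n G_m [RT ln Gamma_n - z_n F V_m]`, `Gamma_n = c_n^0/c_n`),
with the Cl- leak representing the volume-regulated anion channel SWELL1;
the Na+/K+ pump (3 Na+ out : 2 K+ in, voltage-gated and
substrate-saturating); the electroneutral exchangers NHE (Na+ in / H+ out,
quiescent at alkaline pH) and AE2 (Cl- in / HCO3- out, quiescent at acidic
pH).  All four gates are logistic (Boltzmann) functions; the single
mechanosensitive gate `G_m(tau_m)` multiplies all three passive leaks at
its end, with tension `tau_m = b/2 (sigma_n + p - p_*)` from the membrane
normal force balance.  Channel polarization (SWELL1 at the rear, NHE at
the front) is encoded purely as front/back asymmetry of the `alpha`
coefficients.

**Whole-cell force balance** closes `v0`:
`-(p0^f - p0^b) - (d_g^f + d_g^b)(v0 - J_water^f) - eta_st int theta_n v_n dx - xi v0 = 0`,
with `xi` the channel-wall friction.  The hydraulic term is implemented as
written above (front water flux only); a `force_balance: symmetrized`
switch applies each end's resistance to its own flux instead — at a
converged steady state the two agree because `J_water^b = -J_water^f`.

### Frame-relative advection

Steadiness holds in the frame moving with the cell, and every boundary
condition of the transport problem is a relative-flux condition (e.g. the
front actin condition `theta_n (v0 - v_n) = J_actin`).  Consistency then
requires the bulk advective fluxes to use relative velocities (`v - v0`);
with lab velocities the actin subsystem's four flux conditions plus the
conservation integral are mutually inconsistent whenever `v0 != 0`.  The
package therefore uses `v - v0` in all bulk fluxes by default and provides
`advection: lab` to reproduce the lab-velocity form (for the ion species
the two differ only at order `v0 L / D ~ 1e-5`).  Similarly, the G-actin
front condition includes the diffusive flux,
`(v_c - v0) theta_c - D theta_c' = J_actin`, which the second-order
monomer balance requires.

## Units

One conversion layer: lengths um, time s, pressure Pa, potential mV,
concentration mM — which equals attomol/um^3, so `RT = R*T` multiplies mM
to give Pa directly and `F/1000` multiplies mM*mV to give Pa.  Ion
permeabilities are stored pre-scaled so every membrane ion flux is in
mM um/s (concentration x velocity), matching the advective bulk flux.

## Discretization and solver

Vertex-centred finite volumes on a uniform grid of `N` nodes: fluxes at
interval midpoints (central averages; the advective term switches to
donor-cell upwinding if the cell Peclet number `|u| h / D` exceeds 2, which
never triggers at these parameters), conservation rows at nodes, boundary
half-cells carrying the membrane fluxes directly.  The scheme telescopes
exactly, so imposing all rows of a species forces the steady front/back
membrane flux balance at the solution, and all bulk blocks are second
order (verified by a manufactured-solution truncation study, observed
order 2.0).

The square system has `11 N + 2` unknowns (eleven nodal fields plus `v_c`
and `v0`).  Families with zero total membrane flux (A-, buffer, and — in
diagnostic scenarios — any species whose every pathway is shut off) are
amplitude-deficient; their back-boundary row is replaced by the
corresponding content integral (trapezoidal), pinning the amplitude: A-
and the buffer to the prescribed totals `N_A` and `N_Buf + N_HBuf`,
auto-detected shut-off species to their initial-guess content.  The
G-actin back row is likewise replaced by the total-actin integral; the
displaced zero-flux condition is implied by discrete conservation and
reported as a diagnostic.

Unknowns and residuals are scaled by typical magnitudes (concentrations by
the bath osmolarity, pressure by `RT x 1 mM`, velocities by `1e-3 um/s`,
potential by `RT/F`; flux-difference rows additionally by `N/64`, since
their round-off floor grows with resolution) before a damped Newton
iteration: dense forward-difference Jacobian, LU factorization reused
while the step contracts strongly, Armijo backtracking on the residual
2-norm with a physical-domain guard (positive Na+/K+/Cl-, non-negative
buffer, pH in [2, 12]), convergence at scaled residual inf-norm 1e-10, and
up to three seeded perturbed restarts.  Initialization is a Donnan-
adjusted uniform rest state (exact electroneutrality and content
integrals), refined by a well-mixed 0D solve of the per-species membrane
flux balance — without the refinement Newton can fall into the
non-physiological pump-off (Donnan) basin.  Parameter continuation ramps
overrides geometrically (linearly through zero) with automatic step
halving and warm starts; where multiple steady states might exist, the
branch continuously connected to the rest state is the one reported.

Default problem sizes: `N = 64` for single solves, sweeps and scenario
tables; `N = 128/256` for the grid-convergence study (`v0` changes by
~2e-7 relative); `N = 32` for the fitting studies, whose cost is dominated
by repeated solves.

## Default parameters

The defaults in `src/osmoengine/data/defaults.yaml` are physiologically
motivated placeholder choices made once (each flagged in the file): a
50 um x 30 um^2 confined cell at 310 K in a standard saline bath (140 Na+,
5 K+, 110 Cl- mM, pH 7.4, ~24 mM HCO3-), impermeant protein and buffer
totals chosen so that a feasible electroneutral, iso-osmotic interior
exists (~67 mM A-, ~41 mM buffer), and cytoplasmic diffusivities at about
half their dilute-water values.  Transport magnitudes were calibrated, as
part of the study conditions, so the model reproduces the qualitative
behaviours the experiments established: the steady velocity rises
monotonically with rear SWELL1 enrichment and reverses sign within a
rear/front ratio range of [0.1, 10]; migration persists without actin
polymerization but stalls when SWELL1 is knocked down on top of it; dual
NHE1+SWELL1 knockdown is at least as slow as either single knockdown.
Mechanistically this places the Cl- (SWELL1) conductance as the
rate-limiting leg of the osmotic circulation (NHE and AE2 run near
equilibrium at higher capacity), which is what makes a 10x SWELL1
knockdown bite on the water engine.  The baseline polarization is SWELL1
rear/front = 4 and NHE front/back = 1.1; baseline `v0 ~ 1e-4 um/s`
(~0.3 um/h) with front water influx ~1e-4 um/s, membrane potential
~-64 mV, interior pH ~7.3.

Because the calibrated conditions leave small residual velocities at the
"stalled" scenarios (the NHE asymmetry and actin drive do not vanish),
"motility ceases" is asserted quantitatively as: symmetric-SWELL1 velocity
below 0.3x baseline, and LatA+SWELL1-KD velocity below 0.2x of both
baseline and the LatA velocity.

Knockdowns are modeled as 0.1x multiplicative scaling of the corresponding
permeability at both ends (protein depletion is spatially uniform;
polarization is a separate axis).  Polarization sweeps hold the geometric
mean of the two ends fixed so total conductance is ratio-independent; a
`hold_front` normalization is also provided since the swept axis's
normalization is a modeling choice.

## Synthetic data

`gen_velocity_observations` draws per-cell velocities as the model `v0`
plus Gaussian noise (default sd 30% of baseline speed, emulating the
scatter of single-cell measurements; ~11 cells per condition).  It does
not emulate cell-to-cell parameter heterogeneity, temporal velocity
fluctuation, or measurement-window effects — so recovery tests demonstrate
estimator correctness under the assumed noise model, not robustness to
model misspecification.  `gen_polarized_cell_image` builds rectangular
membrane-label phantoms: bright pole bands of prescribed mean at both ends
of axis 0 (front = high indices), an unlabeled (zero or dim) interior, and
truncated-at-zero additive Gaussian noise; there is no PSF/optics
simulation, and the phantom is not a rendering of the PDE solution.
`gen_trajectory` produces drift-diffusion tracks
(`x_{k+1} = x_k + v dt e_0 + N(0, sqrt(2 D dt))` per axis) at uniform
sampling.  Every generator records parameters + seed, and regeneration
from that record is bit-identical.

## Fitting

`fit_parameters` minimizes the sum of squared velocity residuals over
bounded free axes (polarization ratios are searched in log space) with
seeded multi-start trust-region least squares and a per-fit cache of
solves.  Confidence intervals come from the Gauss-Newton curvature at the
optimum (`cov = s^2 (J^T J)^{-1}`, t-quantile with `n - p` degrees of
freedom, delta method back to the natural scale).  With 11 observations at
10% noise the 95% interval covers the generating ratio in ~95% of seeded
replicates (checked over 50 replicates in the acceptance script with a
>= 90% pass line, leaving binomial slack below the nominal level).

## Quantification

The polarity ratio uses explicit rectangular pole windows (depth is a
required input — the measurement is defined by where the windows are
placed, so it is never inferred): within each window, pixels at or below
`zero_threshold` (default 0, the strict non-zero rule; configurable for
noisy backgrounds) are excluded, the rest are summed and divided by their
count, and the ratio is front mean / rear mean.  A window with no included
pixels raises an explicit undefined-ratio error.  Instantaneous velocity
is the windowed forward difference of the migration-axis coordinate
(positive = toward the front, matching the solver's orientation); MSD is
time-averaged over all start times up to a lag fraction of the track.
Shape metrics use exact polygon geometry (shoelace area, vertex-chain
perimeter, circularity `4 pi A / P^2`, expansion `A_t / A_0`), rejecting
self-intersecting outlines.

## Diagnostics and conservation

`check_solution` recomputes, from the profiles alone: per-species spatial
flux constancy (normalized by the species' gross membrane traffic — the
fair scale when the net flux nearly cancels, as for K+ whose leak and pump
fluxes are large but opposite); back-influx = front-efflux balance;
electroneutrality relative to ionic strength; actin and impermeant content
errors; the force-balance residual; water closure; and the emergent
zero-total-actin-flux condition at the back.  At converged solutions these
sit at the solver-tolerance level (constancy < 1e-7, electroneutrality
< 1e-12 relative, contents < 1e-10 relative).

## Degenerate inputs and edge cases

The network momentum balance carries a `1e-8 mM` additive regularization
in its friction coefficients so `v_n` stays determined when F-actin
vanishes (latrunculin-A drives `theta_n -> 0` exactly).  Negative G-actin
at the front (transient Newton iterates) yields zero polymerization flux
rather than an error.  `d_g = 0` reduces `p_*` to `p0`; `xi > 0` or
`d_g > 0` is required so the `v0` equation stays well posed.  A
`gating.clamp_gm` diagnostic override pins the mechanosensitive gate
(used by the single-permeant-ion Nernst check, where the solved `V_m`
matches `(RT/zF) ln Gamma_K` to machine precision).

## Known limitations

Steady state only (no transients, no bifurcation tracking); 1D geometry
with lumped end membranes; no NKCC co-transporter and no explicit
aquaporin pathway beyond the lumped water permeability; no myosin
contraction (network stress is passive swelling only); fluorescence
phantoms are not linked to the model's channel densities; the default
parameter set is a calibrated placeholder, not a transcription of any
measured table, so quantitative outputs (velocity magnitudes, crossing
ratios) characterize this parameterization rather than a specific cell
line.
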