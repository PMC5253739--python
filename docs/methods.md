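# Methods

## The model

`cersim` implements a mass-action kinetic model of C16:0 ceramide
metabolism in stimulated macrophages.  Ten sphingolipids are dynamic
state variables — dhSph, dhCer, dhSM, dhGluCer, Cer, SM, GluCer, C1P,
Sph, S1P — connected by the de novo synthesis route (SPT → dhSph →
dhCer → Cer), the salvage route (Cer → Sph → Cer, re-acylation by
CERS), the sphingomyelinase branch (SM ↔ Cer), and the
glucosylceramide, ceramide-1-phosphate and sphingosine-1-phosphate side
branches.  Three metabolites that the inflammatory stimulus perturbs
directly — palmitoyl-CoA, DAG and PC — are *drivers*: time-dependent
inputs represented as piecewise-linear interpolants of measured
concentrations.  They multiply the fluxes of the reactions they
modulate and are never produced or consumed; outside their knot range
they are clamped to the endpoint values, which avoids negative
extrapolated concentrations when a simulation runs past the last
measurement.

The reference network has exactly 29 reactions with free rate
constants: 19 conversions (each mediated by one of SPT, CERS, DEGS,
SMS, SMA, UGCG, GBA, CERK, CAPP, ASAH, SPHK, SGPP1, SGPL1) and one
first-order clearance per dynamic species.  Sphinganine (dhSph) is a
dynamic species with an explicit synthesis reaction, not a driver.
CERS5 and CERS6 are merged into a single CERS label mediating exactly
two reactions — the de novo acylation dhSph → dhCer and the salvage
acylation Sph → Cer — because the CERS5 contribution to C16:0 flux in
macrophages is negligible next to CERS6.  SMS is assigned to both
directions of the Cer/SM and dhCer/dhSM interconversions (the enzyme
is reversible and does not discriminate backbone saturation); the
PC-mediated direction synthesizes (dh)SM, the DAG-mediated direction
regenerates (dh)Cer.  Serine is folded into the SPT reaction's rate;
a dihydro-S1P branch is omitted to keep the free-rate count at 29.

Enzyme concentrations are folded into the rate constants, kf = [E]·kf′.
An enzyme therefore exists in the model purely as a label grouping the
reactions it mediates, and scaling an enzyme by a factor means scaling
those rate constants — which is exactly how every perturbation
experiment is implemented.

All kinetics are mass action; there is no Michaelis–Menten saturation,
no allosteric regulation, and no compartmental structure.  Units are
pmol/µg DNA for concentrations, hours for time.

## Deterministic and stochastic simulation

The concentration ODEs dX/dt = Sᵀ v(X, t), with v the mass-action flux
vector, are integrated with an adaptive explicit Dormand–Prince 5(4)
Runge–Kutta pair (default rtol 1e-8, atol 1e-10).  The stepper is
implemented as a compiled (numba) kernel because the multistart fit
needs on the order of 10⁵ trajectory solves; a test cross-validates it
against `scipy.integrate.solve_ivp` on the reference network, and the
package falls back to scipy transparently when numba is unavailable.
Negative undershoots at the tolerance level are clipped to zero;
anything larger aborts with the failing time.  Solutions at tolerance
1e-8 agree with tolerance 1e-10 within 1e-5 relative on the reference
network (tolerance-robustness test).

The stochastic view is an exact Gillespie (direct-method) simulation in
molecule counts.  Concentrations convert to counts via
N_A · 10⁻¹² · 10⁻⁶ / s, where s is a dimensionless scaling factor that
shrinks the effective system size: s = 1000 (the default) gives
~600 molecules per pmol/µg DNA and visible fluctuations, s → 1
approaches the deterministic limit.  Initial counts round half-up
(counts below 1 may round to 0).  Stochastic rate constants follow from
the deterministic ones by the mass-action order conversion
c = kf / F^(order−1) with F the count-per-concentration factor; the
kinetic order counts reactant stoichiometry plus driver modifiers, so
first-order constants are unchanged.  Drivers enter each propensity in
count units, interpolated at the *current* simulation time — a
quasi-static approximation justified because the driver curves vary
over hours while inter-event times at these counts are fractions of a
second.  Grid sampling records the state immediately before each grid
time.  One independent generator per replicate is seeded by
(base seed, replicate index), so ensembles are reproducible and
order-independent.

The ensemble mean over 100 replicates converges to the ODE solution as
the scaling factor decreases through 1000 → 100 → 10, with strictly
decreasing relative RMS — the package's system-size consistency check.
It is run over the first 6 h of the response (which spans the driver
pulse onset) with 100 replicates per scaling factor; event counts grow
as 1/s, and this window keeps the s = 10 ensemble at roughly 3×10⁸
events.

## Parameter estimation

The objective is the relative-error least squares

  J(k) = Σ_i Σ_{t ∈ T} ((X_i(t) − Exp_i(t)) / Exp_i(t))²,

summed over the ten dynamic sphingolipids and the fitting times
T = {0.5, 1, 2, 4, 8, 12, 24} h (t = 0 sets the initial conditions and
is excluded; drivers are inputs and are never fitted).  Relative
weighting matters because abundances span four orders of magnitude
(SM ~300, C1P ~0.005 pmol/µg DNA); with absolute errors SM would
dominate every fit.  The objective is invariant under joint rescaling
of one species' data and trajectory, and under permutation of the
summation order — both are property-tested.

`fit_multistart` draws n_starts (default 200; the trajectory-recovery
check uses 50) points log-uniformly within per-rate bounds, default
[1e-6, 1e3], and runs a bound-constrained trust-region-reflective
least-squares solve (`scipy.optimize.least_squares`, residual vector =
the per-(species, time) relative errors) from each.  Local solves are
parameterized in log10-rate space: rates span nine decades, and the
log transform is the natural scaling for the trust region.  Termination
is at step/function tolerances of 1e-10 or 400 function evaluations.
Each residual evaluation carries an integration-step budget (default
6000 steps); rate vectors whose fastest timescale stalls the explicit
solver count as failed evaluations with a large flat residual, so local
solves cannot stall in infeasibly stiff corners of the bounds box and
the multistart simply records those starts as failures.  The best local
optimum is returned with the full per-start table.

With 29 rates and 70 residuals the problem is structurally
non-identifiable: individual rate recovery is *not* claimed anywhere.
The recovery property asserted (and recomputed by the acceptance
script) is trajectory-space: on noiseless synthetic data the best of 50
starts reaches J < 1e-4 and matches the data within 1% at every fit
point.

For primary-macrophage-style validation data the same machinery is
reused with swapped data tables (the BMDM time layout
{0, 0.25, 0.5, 1, 2, 4, 8, 20} h is built in), driver curves retained
from the cell-line experiment, and an optional user-supplied rescaling
of the dhSph-synthesis rate, since dhSph levels differ strongly between
the two systems.

## Perturbation experiments

All perturbations are scored by log₂(AUC-perturbed / AUC-control) per
species, with AUC the trapezoidal integral over the simulated span on
a 0.1 h output grid (dense enough that the quadrature error is
negligible relative to the reported ratios).  Positive values mean the
perturbation increased the species' cumulative exposure.  The control
row is identically zero by construction.

* **Availability scans** scale one enzyme's reactions by factors
  0.1 … 1.0.
* **Expression fold-change experiments** apply 2^x (up-regulated) or
  2^−x (down-regulated) factors to whole enzyme groups simultaneously,
  over an FC grid of 0.25–4 (single enzyme) or 1–4 (groups), emulating
  differential-expression contrasts supplied as (enzyme, direction)
  tables.
* **Dynamic perturbations** redraw FC ~ Normal(0, sd) per enzyme at
  each scheduled time and scale by 2^FC, *replacing* the previous
  draw's factor.  Replacement (rather than compounding) is the chosen
  semantics because compounded draws form a random walk whose variance
  grows without bound, which contradicts the intended use as a
  robustness check around a stable control.
* **Initial-condition scans** scale the starting concentrations of
  transport-sensitive metabolites (default {Cer, GluCer, SM},
  user-overridable) by factors 1 … 0.2 to probe sensitivity to
  inter-compartment transport impairment.

## Sensitivity networks

Each of the 29 rates is scaled across {0.01, 0.04, 0.25, 1, 4, 16, 100}
(four orders of magnitude; enzymes across {0.01, 0.1, 1, 4, 10}) and
scored as above.  The interaction network is built from the tables at a
single representative fold change of 4, inside the monotone response
range.  An edge factor → metabolite is kept iff |AUC ratio − 1| exceeds
0.01 for rates or 0.001 for enzymes — the filter operates on the *raw*
ratio while the edge weight is |log₂ ratio|; the asymmetry (a ratio of
1.01 passes where 0.99 does not, at the boundary) is deliberate and
documented because the filter and the weight serve different purposes.
Doubling and halving a species give equal weight 1.  Node degree is
stored as an attribute; layout is left to external viewers, and the
network is exported as GraphML or an edge-list CSV with exact
round-trips.

## Synthetic data

The generator makes every pipeline stage testable without downloads.
Driver curves come in pulse (rise-then-decay with a unique interior
maximum, stimulation-like), ramp and constant shapes, with knots at the
dataset time points.  Datasets simulate the ODE under recorded truth
rates at the RAW264.7 layout {0, 0.5, 1, 2, 4, 8, 12, 24} h (or the
BMDM layout) and apply independent multiplicative lognormal noise per
cell and replicate: each value is multiplied by exp(σz − σ²/2) with
σ = sqrt(log(1 + cv²)), which is mean-preserving (E[noisy] = clean)
with coefficient of variation exactly `noise_cv`.  Lognormal
multiplicative noise is the standard error model for lipidomics
intensities and guarantees positivity.  Defaults: noise_cv = 0.1
(a typical LC-MS lipidomics precision), 3 replicates.

The packaged default rates and initial values are hand-tuned for
approximate flux balance at baseline driver levels, produce
stimulation-like transients (dhCer rises from 3 to ~4.6 pmol/µg DNA
over the driver pulse), and span >4 decades of abundance across
species.  They are illustrative, not fitted values from any published
dataset.  Two qualitative patterns are regression-tested on this
parameterization: reducing CERS lowers Cer exposure while raising S1P
(the salvage flux diverted through Sph to the kinase branch), and the
de novo/backbone enzymes SPT, CERS and DEGS touch more metabolites in
the enzyme sensitivity network than the branch-specific CERK and
SGPL1.  Passing these tests shows the *code* reproduces the expected
mechanistic signatures on the packaged parameterization; it says
nothing about any particular laboratory's fitted rates.

What the generator deliberately does not emulate: the upstream
stimulus-response mechanism behind the driver curves (they are
phenomenological), replicate-correlated measurement error, values
below a detection limit, and microarray-level noise in the enzyme
fold-change tables (FCs are generated at the enzyme level directly).

## Numerical and design notes

* Driver interpolation is exact at knots and continuous; property-
  tested against a hand-written interpolation oracle.
* The closed conversion subnetwork (production, clearance and the S1P
  exit removed) conserves total backbone mass along trajectories to
  integrator tolerance.
* SBML export is not provided; the model file interface is the
  YAML/JSON layout with an exact read → write → read round trip.
* GraphML output is validated as well-formed XML plus an exact
  networkx round trip.
* Random-number contract: `numpy` SeedSequence spawning everywhere;
  identical seeds give bit-identical datasets, SSA trajectories and
  multistart draws.
* The CLI (`cersim simulate|fit|perturb|sensitivity|synth`) is a thin
  layer over the library; every capability is available as a function.

## Known limitations

* Mass action only; saturation effects at high substrate are not
  representable.
* No identifiability analysis (profile likelihood) — the fit reports
  trajectory match and the per-start table, not parameter confidence.
* The SSA is exact (no tau-leaping); runs at scaling factors well
  below 10 on the full network become expensive.
* Downstream insulin-signalling readouts (Akt/PP2A/GLUT4) are outside
  the model boundary; conclusions stop at the lipid pools.
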