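# Methods

This note documents the models, numerical choices, and protocols behind
`pulmoflow`, in the order data flows through the package.

## 1. The poromechanical data generator

### Physical model

The generator solves finite-strain poroelasticity on a spherically
symmetric thick shell — a desk-scale lung analogue.  The parenchyma is a
porous solid saturated by alveolar gas; both constituents are treated as
incompressible, inertia and body forces are neglected.  With deformation
map `phi(R, t)`, deformation gradient `F`, and Jacobian `J = det F`, the
governing equations in material form are

* quasi-static momentum balance: `Div P_tot = 0`,
* gas mass balance: `dJ/dt + Div Q = 0`,
* Darcy flow: `Q = -k J F^{-1} F^{-T} Grad p_alv`,

where `p_alv` is the alveolar (pore) pressure and `k` the lumped mobility
(intrinsic permeability over gas viscosity, mm²/(kPa·s)); the single
coefficient in the Darcy law is the sampled `k` because its units are those
of the ratio and the viscosity never appears separately.  The mass balance
is stated with `dJ/dt` (volume-rate) as the storage term, the only form
consistent with incompressible constituents.

The solid is a Blatz-Ko-type hyperelastic material,

    W = c (I1 - 3) + (c/beta)(I3^(-beta) - 1)
      + c1 (I1 I3^(-1/3) - 3)^d1 + c3 (I3^(1/3) - 1)^d3,

with `E = 4c(1 + nu)` and `nu = beta/(1 + 2 beta)`.  The exponents are
fixed (`d1 = 3`, `d3 = 6`); the response is insensitive to them and fixing
them avoids a redundant sampling dimension.  Since `d1` is odd, the
deviatoric term is implemented as a sign-preserving power.  Total stress
follows a Terzaghi-type split, `P_tot = P_eff - J p_alv F^{-T}`, the
standard choice for incompressible-constituent poromechanics; it is
isolated in one place in the residual assembly so an alternative
effective-stress convention would be a one-line change.

### Boundary conditions and ventilation

The inner surface (`r_inner`, the airway analogue) carries a
pressure-controlled ventilation waveform `Pbar(t)`: pore pressure is
prescribed (`p_alv = Pbar`) and the total traction is the follower pressure
load `-Pbar` on the *current* inner surface.  The outer (pleural) surface
is impermeable and tethered by distributed linear springs of stiffness
`Ks` (a Robin condition, `T = -Ks u` per unit reference area, restoring).
The spring boundary is what lets the shell inflate under a spatially
uniform pore pressure: at the plateau steady state the interior stress
state is hydrostatic and the outer displacement is set by the chest-wall
spring.

The PCV waveform ramps linearly from zero to PIP over `t_ramp = 0.3 s`
(the ramp duration is a modelling choice; clinical rise times are a few
tenths of a second), holds the plateau to the end of the 1 s inspiration,
and is zero during the 2 s expiration; two cycles are simulated over 120
uniform stored steps (`dt = 0.05 s`, the first stored state being the
reference at `t = 0`).  Pressures cross the interface in cmH2O
(1 cmH2O = 0.0980665 kPa); all internal mechanics are in kPa/mm/s.

### Parameter space

Sampled inputs are `xi = [PIP, c, beta, c1, c3, k, Ks]` with baselines
6 cmH2O, 0.3567 kPa, 1.075, 0.2782 kPa, 5766 kPa, 1e4 mm²/(kPa·s),
0.08 kPa/mm, each sampled uniformly over ±50% of its baseline by Latin
hypercube designs (independent designs for the two fidelities).

### Discretization and solver

Linear finite elements in the radial coordinate, two-point Gauss
quadrature, backward-Euler time stepping.  Each step solves the coupled
momentum/mass residual by damped Newton iteration: residual rows are
nondimensionalized by per-block scales, the Jacobian is assembled by
colored finite differences (with linear elements, nodes three apart do not
interact, so six residual evaluations suffice), and steps use halving line
search.  Convergence requires a scaled residual below `max(1e-10,
1e-9 * |F0|)` within 25 iterations; on failure the step is bisected in
time (up to depth 5) with the stored grid unchanged and the reported
boundary influx dt-averaged, so the discrete mass balance
`(V_k - V_{k-1})/dt = influx_k` holds exactly to solver tolerance at every
stored step.  Non-positive Jacobians or non-monotone radii raise
immediately.

The fidelity split is mesh resolution: high fidelity uses 64 radial
elements and a 2000-node observation cloud, low fidelity 8 elements and
150 nodes.  The LF/HF gap is therefore genuine discretization error —
convergence of the radial displacement is monotone under refinement — and
the two levels are strongly correlated across the parameter box, which is
the premise the multi-fidelity surrogate exploits.  Observation nodes are
sampled uniformly in the shell volume (r³ law) once per dataset and shared
by all simulations of that fidelity; fields are interpolated to the cloud
radially (piecewise linear, exact at mesh nodes) and displacement vectors
point along the node's radial direction.  Two geometry presets ("right":
5–50 mm, "left": 4.5–45 mm) stand in for anatomical left/right lungs as
independent instances; the default experiment uses one.

### What the generator does and does not emulate

It reproduces the *structure* of patient-specific lung simulations — the
same governing equations, constitutive law, boundary-condition types,
two-fidelity mesh split, parameter box, and output format (4 fields x K
nodes x 120 steps) — at interactive cost.  It does not emulate anatomical
geometry, regional heterogeneity, gravity, airway-tree resistance, or
hysteresis.  Passing tests therefore demonstrate that the reduction +
multi-fidelity pipeline recovers the response manifold of a nonlinear,
history-dependent poromechanical system with the study's sample sizes; they
do not certify accuracy on anatomical lungs.  One visible consequence of
the radial symmetry is that the synthetic response manifold is lower
dimensional than the anatomical one: the 99% variance threshold is reached
with k = 2 components here versus 2–3 in the patient-geometry setting, and
surrogate R² values are correspondingly higher.

### Global signals

Lung volume is the quadrature of `J - 1` over the reference shell
(reported in mL), flow its centered finite-difference derivative, and
airway pressure the prescribed waveform.  Compliance and resistance come
from ordinary least squares on the single-compartment equation of motion
`Paw = V/Crs + R V' + P0`; the intercept absorbs offsets.

## 2. Dimensionality reduction

Each quantity (ux, uy, uz, palv) and fidelity yields an output matrix
`Z` of shape `(N, K*T)`; rows are time-major flattenings (snapshot at t1,
then t2, ...).  The thin SVD `Z = U S W^T` is computed via the `N x N`
Gram matrix (N ≤ 300 while K*T reaches 240 000), followed by a QR
re-orthonormalization of the recovered right singular vectors; singular
values below `sqrt(max(N, M) * eps) * s_max` — the Gram route's noise
floor — are treated as numerical zeros.  Scores are `Y = Z W`; truncation
keeps the smallest k whose cumulative variance ratio `sum s_i^2 / sum s^2`
reaches the threshold (0.99 default); reconstruction is `Y_k W_k^T`.

Two conventions worth stating explicitly:

* **No mean-centering by default.**  The factorization acts on the raw
  matrix and only surrogate *inputs* are standardized; `center=True` is
  available for sensitivity checks.  On uncentered data PC1 is close to
  the ensemble mean shape and carries ~99% of the variance here.
* **Deterministic signs.**  Each basis vector is flipped so its
  largest-magnitude entry is positive, making scores reproducible across
  linear-algebra backends.

Bases are fitted per quantity, per fidelity, per geometry instance; no
basis is shared across fidelities.  Out-of-sample rows are projected with
the training basis unchanged, which is what surrogate inference requires.

## 3. The surrogate models

`MultiFidelityRegression` is a composite of three fully connected
networks sharing one flat parameter vector:

* `NN_L(x)` — trained on the abundant LF scores (fixed architecture:
  5 hidden layers of 60 neurons, L2 rate 1e-3);
* `NN_H1(x || y_L)` — no activations anywhere, hence affine end to end:
  the linear fidelity correlation;
* `NN_H2(x || y_L)` — the nonlinear correction (activation shared with
  `NN_L`, width/depth/L2 from the grid search, with the two HF subnets
  sharing one L2 rate).

The prediction is `y_H = NN_H1 + NN_H2`, and all parameters minimize
jointly

    L = MSE_L + MSE_H + lam_L |th_L|^2 + lam_H1 |th_H1|^2 + lam_H2 |th_H2|^2.

MSEs average over samples *and* output components so the loss is
comparable across truncation levels k; the L2 sums run over all weights
and biases.  `SingleFidelityRegression` keeps only the nonlinear subnet on
`x`, trained on HF data alone.

Optimization is full-batch Adam (lr 1e-3, 5000 epochs, last-epoch weights;
the datasets are at most 300 rows so batching would add noise without
saving memory), deterministic given the seed, with uniform fan-in
initialization (`U(-1/sqrt(fan_in), +1/sqrt(fan_in))`).  Joint training is
the default — the loss couples all three subnets — with optional staged
pre-training of `NN_L` behind `pretrain_low_epochs`.

**Target standardization.**  Inputs are standardized (zero mean, unit
population sd, fitted on the union of LF and HF training inputs).  Score
targets are additionally standardized per component inside the model and
predictions mapped back.  This is an optimization necessity, not a
modelling choice: Adam's per-step parameter displacement is bounded by
roughly the learning rate, so with raw principal-component scores of
magnitude 10²–10³ the prescribed budget (lr 1e-3, 5000 epochs) cannot move
output-layer weights to the target scale — on a synthetic benchmark with a
known linear fidelity link, the unscaled model stalls (PC1 R² ≈ 0.5) where
the scaled model reaches R² ≈ 0.98.  `scale_targets=False` restores raw
targets.  The truncation levels of the two fidelities are independent
(`NN_L` outputs k_L components, the HF subnets map `7 + k_L -> k_H`).

## 4. Evaluation protocol

* R² = 1 - RSS/TSS with N-normalized sums; per-quantity test scores pool
  all retained components (PC1-only scores are also reported); model
  selection uses PC1 of ux only.
* Grid search: lambda in {1e-1, 1e-3} (tied across HF subnets), neurons in
  {30, 60}, layers in {3, 6}, activation in {tanh, relu} — 16 combinations,
  each scored by 3-fold cross-validation on the 15 HF training samples
  (folds of 10 train / 5 validation, seeded random assignment).  Ties break
  to fewer parameters, then to the lower-index lambda.  The winning ux
  architecture is reused for uy, uz, palv.
* Peak-inspiration spatial errors: per-node relative error in percent at
  100 seeded landmark nodes, with a floor of 1e-6 times the field maximum
  guarding near-zero truth values (the equation divides by the true value,
  which crosses zero near the rigid end of the displacement range).
* Cost model: `C_eq = N_H + N_L T_L / T_H`.  Wall times are measured by
  default; passing `cost_times=(2.9, 162.0)` (minutes) pins the arithmetic
  to the reference hardware ratio so cost comparisons are
  hardware-independent.
* Reported ± values are sample standard deviations (ddof = 1).

## 5. Default experiment and problem sizes

The packaged default (`ExperimentConfig()`) runs N_H = 25 and N_L = 300
simulations, splits the HF set 15/10 by a seeded permutation (the SVD
bases are fitted on all 25 HF rows *before* the split, matching the
protocol's order of operations — the basis, not the surrogate, sees the
test rows), truncates at 99%, grid-searches both model kinds, trains one
surrogate per quantity, and reports test metrics plus equivalent costs.
On one CPU core the full protocol takes roughly 15 minutes, dominated by
the 48 cross-validation trainings of the multi-fidelity grid search; the
simulations themselves take about 3 minutes.  All randomness derives from
one master seed through named `SeedSequence` children, so a config hash
identifies a reproducible run.

The cost-accuracy sweep retrains both surrogates at HF training sizes of
10–15 and LF sizes of 0/50/100/300 across seeds, reporting the RMSE of ux
score predictions against `C_eq`.

## 6. Known limitations

* The generator's radial symmetry makes the response manifold nearly
  two-dimensional; compression and surrogate accuracy are therefore upper
  bounds on what anatomical geometries yield.
* The Gram-route SVD cannot resolve components below ~1e-8 of the leading
  singular value; irrelevant at the 99% threshold.
* Measured wall-time ratios on the shell generator (~0.4) do not reproduce
  the two-order-of-magnitude LF/HF cost gap of 3D anatomical FE models;
  cost-model conclusions should use pinned `cost_times`.
* The effective-stress convention of the original 3D formulation is not
  printed in the reference material; the Terzaghi split used here is
  standard but an alternative would change the momentum residual.
* The equation-of-motion fit assumes a single compartment; it is exact for
  the generator's topology but approximate for real lungs.
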