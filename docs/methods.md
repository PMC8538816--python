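# Methods

## Model structure and assumptions

Both models are closed, well-mixed compartment systems: no production or
degradation of toxin, carrier or albumin, uniform concentrations within
each compartment, and transporters distributed evenly over the membrane.
The basolateral membrane carries the OAT1 pool; the apical membrane
carries the BCRP efflux pump. The fitting model has two compartments
(well medium ↔ cell) because the uptake experiments it represents are run
in albumin-free medium in a 96-well plate, with effluxed toxin returning
to the same well. The standard model has three (blood ↔ cell ↔
dialysate) and adds albumin: free IS must first form an IS–HSA complex,
and the complex — not free IS — is the substrate the carrier sees, with
albumin released back to the blood on carrier binding. Efflux into the
dialysate is irreversible (one-way pump, no back-diffusion), which makes
the dialysate toxin content monotone non-decreasing.

### Units and conversion factors

Volumetric species are stored in µM, membrane species in molecules µm⁻²,
time in seconds — the units in which every parameter is conventionally
reported. Membrane reactions produce surface flux densities (molecules
µm⁻² s⁻¹); each volumetric balance receives a flux multiplied by the
conversion factor of its *own* compartment,

u = A / (N_A · V) · 10⁶  [µM per (molecule µm⁻² s⁻¹)],

with A the membrane area in µm² and V the compartment volume in liters.
Membrane species evolve directly in molecules µm⁻² s⁻¹ with no volumetric
conversion. This convention is not a free choice: it is the only
assignment under which total toxin molecules, total carrier and total
albumin are conserved identically (the RHS functions conserve them to
round-off by construction, and the test suite audits every trajectory).
With the 96-well geometry, the cell monolayer volume (0.32 µL) is ~300×
smaller than the well volume (100 µL), so intracellular concentrations
respond ~300× more strongly to the same membrane flux — the reason the
model is stiff and is integrated with an implicit solver.

### Rate laws

* OAT1 uptake (default, "case 1"): mass action, `J = kf_uptake · C ·
  [OAT1]`, where C is free IS (fitting model) or the IS–HSA complex
  (standard model). Three saturable variants (cases 2–4) are available
  for model comparison: a bare Michaelis–Menten flux, MM × [OAT1], and
  MM × C × [OAT1].
* Carrier release into the cytosol: first order, `kf_dissociation ·
  [OAT1·IS]`.
* BCRP efflux: Michaelis–Menten in intracellular IS, saturating at
  24 000 molecules µm⁻² s⁻¹ with half-saturation at 69 µM.
* Albumin binding: pseudo-first-order in free IS with the
  albumin-saturable rate `KfComplex = B_max·[HSA]/(K_D+[HSA])`; at 1 mM
  albumin this is 2.46 s⁻¹, so blood IS complexes within seconds and the
  albumin pool (1 mM vs ≤180 µM toxin) is always in excess.
* Uremic albumin conformational changes: `f1` multiplies `KfComplex`,
  `f2` multiplies the uptake rate; (1, 1) is healthy albumin.

### Parameters that matter

| symbol | meaning | unit | default |
|---|---|---|---|
| `kf_uptake` | IS(-complex) binding to OAT1 | s⁻¹ µM⁻¹ | 1.75e-5 |
| `kf_dissociation` | release from OAT1 into cytosol | s⁻¹ | 4.18e-4 |
| `oat1_density_0` | initial free-carrier surface density | µm⁻² | 1.15e7 |
| `vmax_efflux`, `k_efflux` | BCRP pump capacity / half-saturation | µm⁻²s⁻¹, µM | 24 000, 69 |
| `hsa_0` | initial albumin | mM | 1 |
| `bmax`, `kd_hsa` | albumin-binding amplitude / half-saturation | s⁻¹, µM | 2.70, 97.92 |
| `f1`, `f2` | uremic conformational-change factors | – | 1, 1 |

Scenarios: `standard` (25 µM IS), `physiological` (2.5 µM), `uremic`
(180 µM), `uremic_conformational` (180 µM with f1 = 1e-5, f2 = 0.044).

## Numerical choices

* Integration: `scipy.solve_ivp` with LSODA at rtol 1e-9 / atol 1e-12;
  fitting model sampled every 0.5 s over 45 min, standard model every
  50 s. Endpoints are insensitive to a tenfold tolerance tightening
  (relative change < 1e-6, tested). A precompiled closure of each RHS is
  used on the solver hot path and is checked against the reference
  implementation in the tests.
* Negative states: genuinely negative inputs to the RHS raise; values
  within solver tolerance of zero are clipped to zero both inside the
  RHS and in stored trajectories.
* Clearance endpoint: earliest time at which the dialysate holds ≥99.5%
  of the initial toxin molecules, linearly interpolated between samples.
  "Complete removal" has no unique operational definition; the 0.995
  fraction was calibrated once against the two observed removal times
  (17.5 h at 25 µM, 35 h at 180 µM), which it reproduces within 2%
  (17.23 h / 33.97 h); a 0.99 fraction would give 15.4 h / 32.0 h. The
  threshold is an explicit argument everywhere.
* Sensitivity: S = (|ΔIS_D|/IS_D)/|δ| × 100 at the 17.5 h endpoint with
  δ = −0.20. The normalization — relative response over relative
  perturbation — is adopted because it is the only reading that spans the
  observed range (0% for inert albumin in the saturated standard
  scenario, ~94% for the rate-limiting carrier density in the
  conformational-change scenario). Perturbing the carrier density or the
  albumin concentration rescales the corresponding initial-state entry,
  not just the parameter. The albumin-binding entry perturbs `B_max`
  (the rate amplitude), not `K_D`. The conformational-change panel uses
  the same 17.5 h endpoint as the others (exposed as a setting).
* Scan grids: f1 log-spaced on [1e-6, 1] (two points per decade by
  default), f2 linear on [0, 1] with 0.004 steps — fine enough to resolve
  the optimum near f2 = 0.044. Failed grid points are recorded as NaN and
  skipped by the pair selection.

## Parameter estimation

The objective is the RMSE between replicate-mean intracellular IS and the
simulated curve at the nine sampling times (1–45 min) of a single
25 µM dataset; replicate variance is available but unweighted. The
optimizer is evolutionary programming: population 20, one offspring per
parent by Gaussian mutation of log10-transformed parameters with
per-parameter self-adaptive step sizes (initial 0.3 decades, log-normal
update, floor 1e-3 decades), survivor selection by wins against q = 10
random opponents among parents + offspring, light elitism (the incumbent
best is never lost), 200 generations by default, deterministic for a
given seed, optional independent repeat runs with the best objective kept
and the run-to-run spread reported.

The mutation includes one additional self-adaptive step along the
dominant covariance axis of the current population. The RMSE surface has
a narrow curved valley — kf_uptake, kf_dissociation and the carrier
density can partially compensate at a single test concentration — and the
surviving population stretches along exactly that direction, so this axis
gives the search a learned valley-following move (in the spirit of
main-vector-adaptation evolution strategies). Without it, axis-aligned
mutations stall partway along the valley regardless of budget; with it,
noiseless synthetic data re-yields all three generating parameters to a
few percent at 300–500 generations.

Cases 2–4 free (Vmax, Km) with `kf_dissociation` and the carrier density
fixed at their case-1 values; bounds span the physically sensible decades
(Km ∈ [1e-6, 1e4] µM; Vmax per-case scales). Case selection simulates
each fitted law forward at 25/50/100/500 µM and ranks by mean RMSE
against the replicate means, ties to the simpler law.

**Known limitation — nested rate laws.** Case 4
(`Vmax·C/(Km+C)·C·OAT1`) contains case-1 mass action as its Km → 0 limit
with `Vmax → kf_uptake`. On data generated under case 1, a well-converged
case-4 fit therefore matches (and, having fewer free parameters exposed
to noise, can out-validate) the generating case; selecting "case 1 first"
on case-1 data is not guaranteed by RMSE ranking alone. The selection
report exposes the full per-case RMSE table so this near-equivalence is
visible rather than hidden.

## Synthetic data and what passing tests show

The generator reproduces the uptake experimental design — initial IS at
25/50/100/500 µM, sampling at 1, 2, 5, 10, 15, 20, 25, 30, 45 min, six
replicates — by forward simulation plus replicate noise. Default noise is
multiplicative Gaussian with a 10% coefficient of variation, truncated at
zero, a typical replicate variability for LC-MS/MS quantification; an
additive-Gaussian alternative is available. The generator does not
emulate chromatographic drift, limits of quantification, batch effects or
non-Gaussian outliers, so recovery results bound what the *model and
optimizer* can do under idealized noise, not what any particular assay
would deliver.

Recovery experiments fit the 25 µM dataset only (matching the original
estimation design). Two regimes are tested: noiseless data with a deep
optimizer budget (500 generations, 3 runs) recovers all three mass-action
parameters within 5%; noisy data (10% CV, 10 seeds) is fitted at a
deliberately shallow budget of 50 generations, because noise displaces
the RMSE minimum along the compensation valley and a deeper fit chases
that displaced minimum — early stopping acts as regularization. Under
those conditions the median relative error per parameter stays below
25%. The single-concentration design is the identifiability bottleneck;
fitting several concentrations jointly would break the valley but would
no longer correspond to the original estimation protocol.

## Problem sizes

The shipped analyses are desk-scale: clearance endpoints integrate one
stiff ODE system for 30–450 model-hours (≤ 0.3 s each), sensitivity
panels need two simulations per coefficient, the acceptance scan uses a
5 × 5 grid around the reported factor pair, and the recovery studies run
in a few minutes in total.

## Other limitations

Single toxin, single uptake transporter: no OAT3, no toxin–toxin
competition or OAT1 inhibition at high IS, no drug interactions. No
spatial or flow effects (well-plate geometry, not a perfused fiber), no
albumin or transporter turnover, no time-varying parameters or dosing.
The conformational-change factors are phenomenological reductions, not a
structural model of glycation.
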