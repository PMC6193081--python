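# Methods

## The model

`hiis` implements a deterministic compartmental ODE model of the human
innate immune response to a massive, systemic, surgery-scale insult, with
alkaline phosphatase (AP) as the central anti-inflammatory effector.  The
body is reduced to three well-mixed compartments — blood (5 L), tissue
(15 L interstitial volume, standing in for "the whole body" since the
insult is systemic), and the liver as an AP store — linked by transport
across the endothelial barrier whose permeability responds to
pro-inflammatory cytokine levels.

Twenty state variables: inflammation-triggering moieties (ITMs — LPS,
extracellular nucleotides) in blood and tissue; endogenous and supplemented
AP in blood and tissue; ITM–AP complexes in blood; resting/activated
macrophages; resting (blood) and activated (tissue) neutrophils; apoptotic
and necrotic neutrophil debris; pro- (CH, compared against IL-6) and
anti-inflammatory (ACH, compared against IL-10) cytokines; a cumulative
tissue-damage mediator D; the liver AP store; and a three-stage linear
delay chain.

Mechanisms, in the order they fire after surgery onset:

1. **Insult.** The surgical ITM load (`itm_insult`, default 4×10⁹
   molecules/mm³) appears in blood at t = 0.  Local surgical-site ITM
   release is treated as negligible against the circulating load and is
   not modelled.
2. **Blood-side neutralization.** AP is the only blood-side effector:
   mass-action 1:1 irreversible complexation (`k_bind`), complexes cleared
   by Kupffer cells (`k_kupffer`).  In tissue, AP dephosphorylates ITMs
   catalytically (enzyme not consumed, `k_dephos`).  The asymmetry is a
   modelling choice: the circulating complex is a transported object with
   its own clearance route, whereas tissue detoxification is enzymatic.
3. **Liver flush and recovery.** The store (5,300 IU) tracks an
   insult-dependent target level `L₀·(1−H(ITM_blood))` where `H` is a
   steep (4th-order Hill) switch: under insult the target collapses and
   the excess is released into blood at `k_flush` (40 h⁻¹, i.e. within
   minutes); once blood ITMs fall, the store is re-synthesised toward the
   rising target at `k_refill` (0.6 h⁻¹).  Release and refill are mutually
   exclusive by construction — an earlier formulation with independent
   flush/refill gates leaked re-synthesised AP through a half-open flush
   gate and produced a spurious early AP rebound.  De-novo supply to blood
   is gated by a smooth switch on the store fraction (midpoint 50% of
   capacity), which places the post-trough recovery of blood AP at ≈2 h
   after onset.  The supply constant is derived, not tuned: it is the
   unique value making the zero-insult state an exact fixed point.
4. **Cellular response.** ITMs activate resting macrophages (mass-action,
   with a small direct contribution from blood ITMs sensed at the
   endothelium, and inhibition by ACH).  Activated macrophages secrete CH
   and ACH; CH raises endothelial permeability (2nd-order Hill, baseline
   `perm_base` = fenestrae-level transport at CH = 0, saturating at
   `perm_max`); permeability above baseline recruits blood neutrophils into
   tissue (diapedesis), where they are activated by definition.
5. **Dual death pathway.** Activated neutrophils die by first-order
   apoptosis (anti-inflammatory: debris is phagocytosed by macrophages,
   producing ACH) or — under sustained tissue-ITM pressure, gated by the
   delay chain — by necrosis (pro-inflammatory: debris releases fresh ITMs
   linearly, secretes CH, and drives the damage mediator D, which feeds a
   small ITM source back into tissue).  This apoptosis/necrosis split and
   its feedback is what makes supplementation protective.
6. **Supplementation.** The treated arm receives a 1,000 IU bolus
   (delivered as a fast first-order input with rate 60 h⁻¹, i.e. >95%
   within 3 min — solver-friendly rather than a Dirac impulse) plus an 8-h
   infusion totalling 8,000 IU (piecewise-constant source with a solver
   restart at switch-off).  Supplemented AP obeys the same kinetics as
   endogenous AP except a much faster intrinsic clearance (`k_aps_deg`,
   9 h⁻¹) reflecting the short circulating half-life of the bovine enzyme.
7. **TNAP induction** — the mechanism under study.  Supplemented AP drives
   additional endogenous AP release at rate
   `r_peak / (1 + exp(r·(t − t_delay))) · (APs_blood + APs_tissue)`:
   a reverse sigmoid in time, centred at `t_delay` = 1 h (the lag of the
   recuperating liver), proportional to the supplemented pools.  The
   ablation switch (`induction_enabled=False`) zeroes this term
   identically; because it is multiplicative in supplemented AP, placebo
   trajectories are bit-identical with the switch on or off.

Delays (necrosis onset, cytokine production) are realised as a linear
chain of three first-order stages driven by a saturating function of
tissue ITMs; the chain mean (`tau_delay`, 1.5 h) is the effective lag, and
the system stays a pure ODE rather than a DDE.

## Units

Internal units are hours, molecules/mm³ (molecular species), cells/mm³
(cells), and IU-equivalents for the liver store.  Clinical I/O converts at
the boundary only: AP activity via 1 IU ≙ 1.506×10¹² molecules (from a
specific activity of 2,500 U/mg and a 160 kDa dimer), cytokines via a
21 kDa interleukin molar mass; both constants live in `hiis.dosing` as the
single source of truth.  These are order-of-magnitude biochemical
anchors — every comparison in the package is invariant to them because
data generation and fitting use the same linear maps.

## Parameters

All 48 parameters live in one table (`hiis.model.PARAM_TABLE`) with
nominal value, bounds and a default free/fixed flag.  The nominal values
are this package's calibration: they were chosen so the simulated treated
arm reproduces the clinically described dynamics — an onset AP spike from
the liver flush, disappearance of the bolus footprint within 20 minutes,
a blood-AP trough with recovery beginning ≈2 h after onset, an induced AP
elevation in the treated arm, IL-6 peaking in the low hundreds of pg/mL
several hours post-surgery, and a necrosis/apoptosis balance that shifts
toward apoptosis under supplementation.  The default free set for fitting
is the induction triple (`r_induce_peak`, `r_induce`, `t_ap_delay`) plus
the AP turnover rates (`k_ap_deg`, `k_aps_deg`): these are the parameters
the observed series can actually identify; cell-kinetic rates stay fixed
at nominal.

## Numerics

LSODA (stiff-capable, adaptive) with rtol 10⁻⁶ and a per-species absolute
tolerance of 10⁻⁹ × a characteristic magnitude (molecule pools sit at
10⁸–10⁹ molecules/mm³, delay stages at 1, so a scalar atol would control
them inconsistently).  Dense output on a 5-minute grid over a 36-h
horizon; integration restarts exactly at the infusion switch-off.
Halving both tolerances changes no component by more than 10⁻⁴ in
relative sup-norm; identical inputs give bit-identical trajectories.  The
right-hand side evaluates fluxes on the state clipped at zero, so
tolerance-level negative excursions (observed < 10⁻⁹ in scaled units)
cannot propagate.  The trough detector (`liver_resupply_time`) takes the
argmin of total blood AP after t = 0.25 h and requires an interior,
non-shallow trough followed by one hour of monotone recovery, with depth
measured against the settled late-time level (the onset flush spike would
otherwise dominate the scale).

The bolus-decay feature is defined on the *supplemented* AP pool: the
with/without-bolus difference of total blood AP would also contain the
endogenous TNAP the bolus induces over the following hours, which is not
what "the bolus effect disappears" describes.

## Calibration

The objective is MAE-weighted least squares,
Σ ((model − median)/MAE)², with model output converted to clinical units
per observable; the reported dispersion is the only uncertainty the data
carry, so it is the weight.  Fitting is differential evolution (seeded,
bounded, Sobol' initialisation, ~55% of the evaluation budget) followed by
two Nelder–Mead runs (the restart re-inflates the simplex and reliably
carries the polish from ~10⁻¹ to machine-level loss on noiseless data).
Integration failures during search return +∞ so the optimizer routes
around them.  On noiseless synthetic data the induction triple is
recovered to ~10⁻¹⁰ relative with a 1,500-evaluation budget; the
acceptance suite asserts the much weaker 10% bound.

## Synthetic cohorts

`hiis.synth` emulates the reporting surface of the motivating trial:
10 sparse sampling times over 36 h, cohort medians of 25 multiplicative-
Gaussian-noise replicates (σ = 25% of the latent value, draws clipped at
zero), MAE = replicate median absolute deviation floored at the assay
detection level (1 IU/L for AP, 0.5 pg/mL for cytokines).  For a normal
noise model the MAD/median ratio concentrates at 0.6745·σ, which the test
suite checks.  Not emulated: inter-patient kinetic heterogeneity, dropout,
covariates — passing tests therefore demonstrate pipeline correctness
under the stated noise model, not robustness to real-cohort structure.
The secondary-insult generator emits a Gaussian ITM pulse whose integral
is a configurable multiple (default 1×) of the primary surgical load,
centred 6 h post-onset with 1 h width; the default multiple is a choice,
since the referenced septic-shock ITM proxy has no printed magnitude.

## Sensitivity analysis

Variance-based Sobol' indices via `scipy.stats.sobol_indices`
(Saltelli-2010 estimator, base sample rounded up to a power of two,
bootstrap confidence intervals).  Default outputs: peak CH, AUC of tissue
ITMs, peak necrotic neutrophils, and the blood-AP trough value.  Failed
integrations are imputed with the mean of successful runs and counted;
more than 5% failures aborts the analysis.  The estimator is validated
against the closed-form indices of an additive linear toy model.

## Problem sizes

Analyses and tests run at the scale of the study itself: 36-h horizons,
433-point dense grids, 10-point observation series, 700–1,500-evaluation
fit budgets, 64–256 Sobol' base samples.  The recovery and ablation
studies use single seeds in the test suite and report multi-seed behaviour
through `parameter_recovery_suite` when asked.

## Known limitations

* The equation set is this package's own realisation of the described
  mechanisms; alternative functional forms (e.g. Michaelis–Menten
  dephosphorylation, reversible binding) would calibrate to the same
  qualitative behaviour but different rate values.
* One latent trajectory per arm: medians are treated as a single
  representative patient, mirroring the analysis it reproduces; no
  patient-level inference.
* The induced TNAP enters circulation directly; routing it through the
  liver store would couple induction to the flush/refill machinery and is
  not identifiable from median AP series alone.
* IL-10 dynamics are driven by apoptotic-debris clearance and peak late in
  the window; real post-surgical IL-10 often peaks earlier.
* No spatial structure, no adaptive immunity, no AP pools at barriers
  other than the liver.
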