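# Methods

`lngpbpk` is a whole-body physiologically-based pharmacokinetic (PBPK)
model of levonorgestrel (LNG), alone and co-formulated with ethinyl
estradiol (EE), built to quantify how plasma-protein-binding interplay
(albumin and sex-hormone binding globulin, SHBG), CYP3A4-mediated
drug-drug interactions (DDIs) and body-mass-index (BMI) effects shape
total and unbound LNG exposure.

## Model structure

**Circulation.** Twelve organs (adipose, bone, brain, gut, heart, kidney,
liver, lung, muscle, skin, spleen, lumped rest) exchange drug with a
central plasma pool under perfusion-limited kinetics, with an optional
permeability-surface (PS) limitation: the effective exchange clearance per
organ is `Q·PS/(Q+PS)`.  At the published organ permeabilities both
steroids have PS an order of magnitude above plasma flow, so distribution
is effectively perfusion-limited.  Gut and spleen drain portally into the
liver.  Drug is restricted to plasma within blood (blood:plasma ratio 1
for the plasma-referenced quantities reported).

**Tissue partitioning.** Tissue-to-plasma partition coefficients follow
the Rodgers–Rowland composition scheme for neutral compounds,
`Kpu = f_EW + f_IW + P·f_NL + (0.3·P + 0.7)·f_NP`, with the
vegetable-oil:water partition (`log P_vo = 1.115·logP − 1.35`) replacing
octanol in adipose.  Both steroids are treated as neutral: no
ionized-species or acidic-phospholipid terms.  The packaged composition
table is transcribed from the Rodgers–Rowland publications; the "rest"
compartment uses muscle-like generic fractions.

**Plasma protein binding.** LNG binds albumin (Kd 6 µmol/L, high
capacity) and SHBG (Kd 0.5 nmol/L, low capacity).  The coupled
equilibrium is solved exactly (quadratic closed form) with albumin
treated as non-depletable (~10^5-fold molar excess) and SHBG explicitly
depletable, so the unbound fraction rises as nanomolar LNG saturates
SHBG.  The published dissociation rates (6.5/min albumin, 17.4/min SHBG)
equilibrate three orders of magnitude faster than any pharmacokinetic
process here, so the binding reactions are applied as an exact
quasi-equilibrium inside the ODE right-hand side rather than as stiff
kinetic states; the reported free/albumin-bound/SHBG-bound series satisfy
free + bound = total identically.  At zero ligand the unbound fraction is
defined by its continuous dilute limit `1/(1 + Alb/Kd_alb + SHBG/Kd_shbg)`.
Tissue partitioning is tied to the *current* plasma unbound fraction, so a
rising SHBG pool (EE or rifampicin induction) pulls drug into plasma and
lowers clearance, and the reduced SHBG of the obese scenario does the
opposite - the central binding-interplay mechanism of the analysis.
EE does not bind SHBG; its unbound fraction is constant (1.5%,
"nonspecific" binding read as an unbound fraction, consistent with
literature EE fu of 1.5-3%).

**Absorption.** One stomach, four small-intestine transit segments and a
colon; first-order gastric emptying (t1/2 15 min fasted), small-intestine
transit ~3.3 h, first-order dissolution `k = ln(5)/T80` (exact at the
defining 80% point) capped by solubility (aqueous in the stomach, FaSSIF
in the intestine - the cap is what limits the 1.5 mg strength), and
absorption flux = permeability x segment area x luminal concentration.
Formulation lag times are implemented as dose-arrival shifts.  The
small-intestine area constant contains the single global
mucosal-amplification calibration of the absorption model; it was fixed
once so that a low-dose oral LNG dose is nearly completely absorbed
(F_a ≈ 0.95, matching LNG's clinically near-complete bioavailability) and
frozen.

**Metabolism.** LNG hepatic clearance splits into a CYP3A4 pathway
(unbound-referenced intrinsic clearance = specific clearance 1.45
µL/min/pmol x hepatic CYP3A4 amount, scaled by the dynamic enzyme pool
and the competitive-inhibition factor) and a lumped non-CYP3A4 (phase II)
pathway.  The published table lists the non-CYP3A4 pathway as
"0.10 L/h/kg", a platform-specific quantity whose reference scale does
not reproduce the analysis' own back-calculated CYP3A4 contribution under
any unit reading we tested; the package therefore follows the published
*procedure* instead and anchors the non-CYP3A4 intrinsic clearance to the
telithromycin-derived fm_CYP3A4 of 47% for the LNG-only product
(`CLint_other = CLint_CYP3A4 · (1/0.47 − 1)` at the individual's baseline
enzyme abundance).  Gut-wall CYP3A4 (1% of hepatic) contributes a small
first-pass component and responds to induction/inactivation like the
hepatic pool.  EE is cleared by a lumped total hepatic plasma clearance
(4.1 mL/min/kg) converted to an unbound-referenced intrinsic clearance by
inverting the well-stirred relation, so the assembled model's systemic EE
clearance equals the published value exactly; EE has no explicit
CYP3A4-mediated clearance, hence perpetrators do not act on EE.

**Regulation.** SHBG and CYP3A4 (liver and gut) are zero-order-synthesis
/ first-order-degradation turnover pools.  SHBG half-life is 7 days (from
postpartum decay); CYP3A4 half-lives are 36 h (liver) and 23 h (gut),
standard values the source analysis does not itself report.  Inducers
multiply the synthesis rate by `1 + (Emax_fold − 1)·c/(EC50 + c)` of
their *unbound* plasma concentration; multiple inducers combine
multiplicatively.  The published SHBG "Emax 2.3" is interpreted as the
maximal *fold-change* of the steady state (so a saturating driver gives
exactly 2.3x baseline), matching its description as the observed net
~2.3-fold effect; the EE-alone alternative (2.25) is selected
automatically for EE-only regimens, and the two are mutually exclusive.
Mechanism-based inactivation adds `kinact·c/(KI + c)` to CYP3A4
degradation; competitive inhibitors scale the CYP3A4-mediated metabolic
rate by `1/(1 + Σ c_u/Ki)` and never touch the pool.  The EE Ki default
is the tabulated 2 pmol/L (the accompanying text derives 10 pmol/L from
the 30%-reduction calibration target; the value is exposed as an
override).

**Perpetrators.** Rifampicin, carbamazepine, efavirenz, itraconazole and
clarithromycin run as reduced one-compartment models (ka, V, CL, F, fu)
whose unbound plasma concentrations drive the interaction terms.  PK
constants were set to reproduce published steady-state exposures at the
standard regimens, and interaction potencies were transcribed once from
the open perpetrator-model literature; none were adjusted against DDI
outcomes.  Rifampicin additionally stimulates SHBG synthesis
(Emax_fold 2, per the observed ~twofold effect).  Itraconazole is
parent-only: the hydroxy/keto/N-desalkyl metabolite cascade that adds
CYP3A4 inhibition in full network models is not represented, which makes
the predicted itraconazole interaction conservative (smaller AUC
increase).

**Physiology and populations.** The reference woman is an ICRP-89-style
60 kg / 163 cm female (packaged organ-volume/flow table).  BMI scaling
allocates excess mass to adipose (75%), muscle (15%) and skin (10%),
scales cardiac output and plasma volume with body surface area, and
scales the flows of the enlarged organs with their volumes.  Populations
draw BMI (hence weight) first - positioning each woman on the
deterministic scaling curve, which induces the weight-mediated
correlation structure - then apply independent lognormal variability:
volumes 10%, flows 15%, CYP3A4 abundance 60%, the phase-II pathway 60%
(an independent scale - the two enzyme systems do not covary, so
fm_CYP3A4 itself varies across individuals), SHBG baseline 30%, albumin
5% CV.  The source analysis does not print its variability magnitudes;
the enzyme CVs were calibrated once so the *predicted* clearance
variability lands near the reported ~35% CV (documented calibration, not
ground truth; 60% is within the wide published range for hepatic CYP3A4
protein abundance) and are configurable.  The obese scenario combines
BMI ≥ 30 with the reduced SHBG baseline (27.6 vs. 55.4 nmol/L) as an
explicit flag,
because the source treats the SHBG decrease as an explored scenario
rather than an automatic covariate.

## Numerics

Amounts in µmol, volumes L, time h.  LSODA (stiffness-switching)
integrates piecewise between dose events (state jumps, integrator
restarted at each discontinuity); default rtol 1e-6 / atol 1e-14, relaxed
to rtol 1e-5 for population scenario grids (moves a 21-day steady-state
AUC by <0.4%, far inside every tolerance used).  Negative-state guards
clamp saturable terms.  Mass balance (GI + body + eliminated + fecal vs.
dosed) closes to <0.1% and is audited on every run.  NCA uses
linear-up/log-down trapezoids, a log-linear terminal fit (last five
points or three terminal half-lives, whichever is longer),
`Vss = D·AUMC/AUC²` (apparent for oral data) and `CL = D/AUC_inf`; a
non-positive terminal slope flags t1/2 as undefined rather than erroring.
Local sensitivities are central differences over ±10%; the
"fraction-unbound" sensitivity parameter is a multiplicative scale applied
as a reciprocal scaling of binding capacities (fu is a derived quantity,
so a scale factor is the only coherent way to perturb it).

## Scenario conventions

DDI scenarios pre-dose the perpetrator for 8 days (>5 CYP3A4 half-lives)
before a 21-day victim cycle and evaluate AUC over the final dosing
interval, in µmol·min/L.  The efavirenz replication uses the single
0.75 mg LNG dose of the replicated study design with AUC over 96 h
post-dose.  The triphasic cycle is packaged as the standard 6/5/10-day
50/75/125 µg LNG + 30/40/30 µg EE sequence (the replicated study's exact
per-phase strengths are not printed; this is a documented assumption).
Steady-state endpoints carry a warning flag when the last-interval AUC
drifts more than 2% from the preceding cycle.

## Synthetic data

The generator emulates the sparse clinical concentration-time datasets
used for model building: seeded virtual populations, reconstructed
dense-early/sparse-late sampling (0.25-96 h; the true schedules are
unpublished), lognormal proportional residual error (default 15% CV) and
LLOQ censoring.  It does not emulate assay drift, batch effects, dropout
or real between-study heterogeneity, so passing recovery tests
demonstrates internal consistency of the estimation machinery, not
fidelity to any particular clinical assay.

## Known limitations

* Absolute exposures depend on the packaged physiology, the
  Rodgers-Rowland implementation and the fm-anchored clearance split;
  they cannot reproduce the source platform's internal databases exactly.
  In particular the model's steady-state combined-contraceptive LNG
  exposure runs below the published absolute prediction (the published
  grid implies a combined-product clearance lower than the tabulated
  parameters support under this model), while DDI *ratios*, Vss,
  half-life, sensitivity and variability endpoints reproduce well.
* Itraconazole inhibition is conservative (parent-only, see above).
* No enterohepatic recirculation, no transporters, no EE gut-wall
  conjugation (EE bioavailability is therefore on the high side of
  clinical estimates), no menstrual-cycle or circadian SHBG variation.
* Perpetrator kinetics are deliberately reduced; they are adequate for
  driving interaction terms at steady state, not for describing the
  perpetrators' own PK in detail.
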