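# Methods

This note documents the models, parameter choices and numerical decisions
behind `methadone_qivive`, and what the synthetic data used in testing can
and cannot show about real data.

## Scope and model chain

The package predicts inter-individual and inter-ethnic variation in the
internal exposure to R- and S-methadone and translates an in vitro
cardiotoxicity readout (FPDc prolongation in hiPSC-cardiomyocytes) into
population dose-response curves. The chain is:

1. **Microsomal kinetics.** Apparent Vmax and Km of EDDP formation are
   fitted per microsome donor by unweighted nonlinear least squares on the
   Michaelis-Menten equation; catalytic efficiency is Vmax/Km (uL/min/mg).
   Packaged descriptive statistics of 25 Caucasian and 25 Chinese donors
   anchor the population profiles.
2. **Recombinant-CYP scaling.** Supersome Vmax values for CYP2B6, CYP2C19
   and CYP3A4 are scaled to the microsomal level with inter-system
   extrapolation factors (ISEF) and hepatic CYP abundances,
   `Vmax_HLM = Vmax_CYP * ISEF * abundance`. Packaged ISEF constants are
   used for modelling; `compute_isef` re-derives ISEFs from the total
   microsomal clearance and f_m,CYP for audit. With the packaged inputs
   the Caucasian R ISEFs are reproduced to within ~5%, the S values less
   closely; the packaged constants presumably trace to per-isoform
   clearance tables that are not part of the packaged summaries, so both
   routes are kept and the packaged values win for simulation.
3. **PBK model.** Flow-limited compartments: liver, heart, fat, richly and
   slowly perfused tissue, arterial and venous blood. Oral absorption is
   first-order (ka 0.59/h) from a gut depot into the liver (portal
   routing); only Fa = 0.88 of the dose enters the depot, the rest never
   enters the system. Hepatic EDDP formation is saturable and evaluated on
   the venous-equilibrium liver blood concentration (C_liver/P_liver:blood,
   total rather than unbound - the choice is isolated behind the rate-law
   interface). Renal clearance (1.8 and 1.1 L/h for R and S) acts on total
   venous blood. In vivo Vmax = microsomal Vmax x MPPGL x liver mass x
   60/1000 (umol/h), with MPPGL 32 mg/g (Caucasian) and 39.46 mg/g
   (Chinese). The readout is the Cmax in blood leaving the heart
   compartment (C_heart/P_heart:blood) over the final dosing interval;
   unbound Cmax multiplies by fu_b = fu_p / (blood:plasma ratio).
4. **Population variability.** Two routes: 25 individual PBK models per
   population (donor-specific Vmax/Km), and Monte Carlo sampling of
   lognormal CYP abundances stratified by CYP2B6 phenotype (EM/PM), with
   optional additional variation ("multifactor") of body weight, Fa and
   fu_p at CV 0.3. Lognormal transforms use mu_omega = ln(mu/sqrt(1+CV^2))
   and sigma_omega^2 = ln(1+CV^2); draws beyond +/-3 SD of the mean on the
   untransformed scale are rejected and redrawn (Fa is additionally capped
   at 1). CSAF = upper percentile / geometric mean, within a population or
   with the Caucasian GM as reference for the combined (Chinese-sensitive)
   basis.
5. **Reverse dosimetry and BMD.** The rac in vitro curve is split 1:3.5
   (R:S) in effect at half the nominal rac concentration per enantiomer;
   unbound medium concentration (fu_medium 0.79) is equated to unbound
   steady-state Cmax and inverted to an external daily dose by secant
   iteration (relative tolerance 1e-4). Sensitive-population curves divide
   doses by the 99th-percentile multifactor CSAF. BMD10 is the dose at 10%
   FPDc prolongation from the lower-AIC of a Hill and an exponential fit;
   BMDL10 = BMD10/3 by convention (enantiomer-level confidence intervals
   cannot be inherited from the racemate data). MOS = sensitive BMDL10 /
   therapeutic rac dose (10 mg/day initial, 60 mg/day maintenance).

## Parameters that matter

| Parameter | Value (R / S) | Units | Note |
|---|---|---|---|
| ka, Fa | 0.59, 0.88 | /h, - | shared between enantiomers |
| fu_p | 0.16 / 0.12 | - | plasma unbound fraction |
| blood:plasma | 0.7 | - | shared |
| logP, pKa | 3.93, 9.2 | - | monoprotic base |
| RCL | 1.8 / 1.1 | L/h | renal clearance, blood basis |
| MW | 309.45 | g/mol | free base |
| BW | 70 / 58.5 | kg | Caucasian / Chinese |
| MPPGL | 32 / 39.46 | mg/g | Caucasian / Chinese |
| dose | 30 per enantiomer | mg/day | study condition, 30 days |

Partition coefficients are derived from tissue composition
(water/neutral-lipid/phospholipid) with Henderson-Hasselbalch ionisation
suppressing adipose neutral-lipid partitioning and tissue protein binding
taken as half the plasma binding outside adipose; tissue:blood = tissue:
plasma / 0.7. Caucasian compartment volumes and flows follow the standard
reference-man compilation; Chinese values follow national reference survey
data with arterial/venous volumes and heart flow copied from the Caucasian
set (non-influential parameters). Cardiac output is 15 x BW^0.74 L/h.

## Numerical choices

- **Reference integrator:** LSODA (stiff-capable) with rtol 1e-8, atol
  1e-10, dense output at 0.1 h; the daily bolus is applied by restarting
  the integrator at dose times so no dose is smeared across a step.
  Mass balance holds to <1e-12 relative in practice.
- **Monte Carlo integrator:** all draws of a stratum advance together
  through a fixed-step classical RK4 scheme; the step derives from the
  fastest blood-compartment turnover in the batch with a safety margin
  inside the RK4 stability interval (typically ~0.008 h). Agreement with
  the reference path is 0.01-0.5% on Cmax and is asserted in the tests.
- **Root finds:** dose inversion by secant iteration from the
  linear-kinetics estimate (the dose-to-Cmax map is nearly linear at
  therapeutic exposures); BMD inversion by Brent bracketing on the fitted
  family.
- **Steady state:** simulations run 30 days (>10 terminal half-lives); a
  >2% difference between the last two dosing-interval Cmax values raises a
  warning rather than an error.
- **Degenerate inputs:** all-zero incubation rates, non-positive
  concentrations/frequencies, unreachable reverse-dosimetry targets and
  >50% truncation rejection raise typed errors with messages.

## Two-site enantiomer interaction

EDDP formation from one enantiomer is competitively inhibited by the
other; the paired simulation raises the apparent Km by (1 + C_other/Ki)
with Ki defaulting to the opposite enantiomer's Km (rapid-equilibrium,
shared-site assumption, because no independent inhibition constants are
packaged). At the 30 mg/day therapeutic dose the liver exposure is far
below Km and the interaction changes predicted blood kinetics by <0.5%,
so the plain Michaelis-Menten models are used everywhere else.

## Synthetic data: what it shows and what it does not

The incubation generator draws (Vmax, Km) independently from lognormals
matched to the packaged 25-donor means and CVs, evaluates rates at the
seven enantiomer concentrations of the racemate design (12.5-750 uM,
half the nominal 25-1500 uM rac series) and applies 10% multiplicative
noise per duplicate (5% in recovery experiments when stated). The in vitro
effect curve is a Hill function (Emax 60%, EC50 1.1 uM rac, slope 1.5)
whose scale was chosen once so that the average-Caucasian reverse-dosimetry
output lands on the reference benchmark-dose scale; it is a synthetic
stand-in, and real concentration-response data can be supplied as CSV.
Passing tests therefore demonstrate correct propagation of variability and
correct inversion arithmetic under the assumed lognormal/Hill structure -
they do not validate the lognormality of real donor kinetics, possible
Vmax-Km correlation (ignored), assay-specific ISEFs, or toxicodynamic
variability (out of scope by design).

## Problem sizes used in the checks

Monte Carlo defaults to 15,000 draws per CYP2B6 phenotype stratum, the
reference analysis size. The packaged test profile and the acceptance
script use 2,000 draws per stratum, at which the 99th-percentile CSAFs are
stable to a few percent (a 4x smaller run moves them by <10%, asserted).
Individual-model runs use 25 donors per population. Recovery and
large-sample checks use 100 and 10,000 synthetic donors respectively.

## Known limitations

- Phenotype structure only for CYP2B6; CYP2C19/CYP3A4 enter through a
  single population distribution (EM distribution for Chinese), without
  star-allele resolution and without abundance correlations.
- fu_p variation feeds the unbound-Cmax conversion but partitions are kept
  at their mean-fu_p values, mirroring the fixed partition table of the
  reference analysis.
- The BMDL10 = BMD10/3 convention replaces a model-averaged lower
  confidence bound; absolute BMD values inherit the synthetic curve's
  scale and are meaningful mainly in ratios (average/sensitive, MOS).
- Flow-limited distribution; no lung compartment, no protein-binding
  kinetics, no biliary route.
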