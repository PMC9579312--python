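# Methods

## Scope and model structure

The package simulates the disposition of a single oral (or intravenous
bolus) dose of propylthiouracil in a virtual human and extrapolates the
adult model to elderly and pediatric groups. The whole-body model is a
deliberate reduction of the four-sub-compartment organ structure used by
commercial PBPK platforms: each organ is one well-stirred tissue space
(vascular space merged in) connected by blood flows, because the
sub-compartment permeabilities and surface areas of those platforms are not
public. The reduction preserves every quantity the package reports — plasma
concentration-time profiles, organ exposure ordering, clearance behaviour
and all derived statistics.

Compartments: gut lumen (dosing), arterial and venous blood pools, lung (in
series with the whole cardiac output), and liver, kidney, brain, heart,
muscle, spleen, stomach, gut and a rest-of-body lump in parallel. Spleen,
stomach and gut drain through the portal vein into the liver, so orally
absorbed drug meets hepatic elimination before reaching systemic blood —
first-pass extraction is structural, not a fitted bioavailability factor.
Amounts are integrated in micrograms with volumes in litres, so
concentrations are ng/mL without conversion. The system is linear; dose
linearity of AUC and Cmax is therefore exact up to solver tolerance, and is
used as a verification property rather than an assumption.

The brain is the one permeability-limited organ: a small vascular space
(4% of brain volume) exchanges with brain tissue across a
permeability–surface-area product PS = P_org × SA_eff. With the specific
organ permeability P_org = 3.18×10⁻³ cm/min, SA_eff = 1600 cm² gives an
equilibration time constant of roughly 2.5 h, which reproduces the
characteristic hours-late brain peak; SA_eff is an effective calibration
area, not an anatomical blood-brain-barrier area.

## Physiology

Organ volumes and flow fractions of cardiac output come from a bundled
age- and sex-resolved reference table (ICRP-89-style reference persons,
tabulated at 0, 1, 5, 10, 15, 25, 70 and 85 years; linear interpolation in
age). For a requested individual, volumes scale linearly with body weight
relative to the reference person of that age and sex, and flows scale
through cardiac output with weight^0.75 — standard PBPK practice that keeps
template demographics exact while physiology stays plausible. Flow
fractions are renormalised after interpolation so systemic flows balance
cardiac output by construction (enforced to 1%).

Unprinted whole-body defaults are explicit and overridable: hematocrit 0.45
for both sexes, liver intracellular fraction 0.60, blood/plasma
concentration ratio 1.0 (the neutral choice for a hydrophilic, low-binding
drug). Plasma albumin follows P(age) = 1.1287·ln(age years) + 33.746 g/L.

Virtual cohorts sample age uniformly on the group's closed interval
(newborn ages floored at 6 h of life so the albumin ontogeny is defined),
assign exactly round(n × proportion_female) females, and draw weight and
height log-normally around the group template with geometric CVs of 15% and
4% respectively, truncated at ±3 log-SD. The CVs are package choices —
no published values exist for this cohort — exposed as arguments. One
seeded generator drives each cohort; the seed is recorded.

The six group templates (adult 25.7 y/60.98 kg, elderly 70.5 y/58.04 kg,
term infant 13.5 d/4.28 kg, infant 1 y/10.66 kg, children 6.5 y/21.46 kg,
adolescent 14.5 y/51.37 kg) carry the study-population means. The children
group's default age span is 1–11 y; the alternative 2–11 y convention is
available through the `age_range` argument.

## Compound parameters

The bundled PTU file carries the model-optimised lipophilicity (logP 0.43),
DrugBank fraction unbound (0.18) — chosen over the alternative database
values because they are the ones the disposition model was anchored on —
molecular weight, pKa set, solubility, specific intestinal permeability
3.92×10⁻⁶ cm/min, specific organ permeability 3.18×10⁻³ cm/min, and plasma
clearances (total 0.147, hepatic 0.09, renal 0.05 L/h/kg). The hepatic+renal
split understates the printed total by ~5%; the clearance container accepts
a 10% reconciliation margin and the simulation uses the split values. The
formulation is treated as fully dissolved: solubility is stored but no
dissolution model runs.

### Specific clearances

Specific clearances (min⁻¹, referenced to eliminating-organ volume) and
whole-body plasma clearances (L/h/kg) interconvert through the well-stirred
organ model, with the kidney flow-limited by effective renal plasma flow
Q_kid(1−HCT) and the liver by total hepatic blood flow Q_liv+Q_pve with the
blood/plasma ratio and intracellular liver fraction in the denominator. The
conversions are implemented in dimensionally consistent L-and-minutes form
(clearances converted L/h → L/min before evaluation), which yields min⁻¹
directly; forward and inverse compose to identity at 1×10⁻⁹ relative, a
property-tested invariant. Conversions refuse inputs at or beyond the flow
limit, where no intrinsic rate can reproduce the requested clearance.

With the bundled physiology the adult PTU conversions give hepatic
0.60 min⁻¹ and renal 1.19 min⁻¹ — within a factor of two of the platform
-computed reference values (0.36 and 0.70), the agreement attainable
without that platform's proprietary organ volumes and flows.

In the ODE, hepatic elimination removes drug at
k_hep·fu·f_cell·V_liv·C_liv/Kp_liv and renal at k_ren·fu·V_kid·C_kid/Kp_kid,
which reproduces the hepatic conversion exactly at steady state. The renal
conversion is referenced to plasma flow while the kidney compartment is
perfused with blood; with HCT 0.45 this mismatch inflates apparent renal
clearance by ~4% (≈1.5% of total clearance), far inside the 2-fold
qualification band, and is accepted rather than papered over with a hybrid
flow basis.

### Distribution and absorption

Tissue:plasma partition coefficients use the non-adipose Poulin–Theil
composition equation — octanol:water partitioning into neutral lipid plus
30% of phospholipid, aqueous partitioning into water plus 70% of
phospholipid, corrected by the plasma:tissue unbound-fraction ratio with
tissue binding approximated as half the plasma binding. The composition
table is bundled as package data; the method name is recorded in simulation
metadata and swappable behind `partition_coefficients`. For PTU all Kp
values fall near 0.5–0.6, so every tissue AUC sits below plasma — the
qualitatively correct pattern for this hydrophilic drug.

Oral absorption maps the specific intestinal permeability to a first-order
ka through an effective lumen surface-to-volume ratio calibrated so the
adult value is 2.0 h⁻¹, the value consistent with the observed ~1 h plasma
peak. For other ages the ratio scales with weight^(−1/4) (a narrower gut has
more surface per volume); the scaling can be disabled. This simple mapping
does not capture gastric emptying, so pediatric peak-time shifts are not
quantitatively reproduced.

## Numerics

LSODA integration with analytic Jacobian (the system matrix), rtol 1×10⁻⁸,
atol 1×10⁻¹⁰ µg, recorded in result metadata. The amounts ledger (gut lumen,
body, cumulative hepatic and renal elimination) is checked against the dose
at every output time; drift beyond 0.1% raises. Output grids default to the
clinical sampling schedule (0–12 h, 18 points) merged with a dense 1-minute
grid; AUC comparisons use the dense grid so the trapezoid error is
negligible. Sub-tolerance negative excursions are clipped to zero on output.
Halving the tolerances moves the plasma AUC by far less than 0.01%.

For verification the builder can emit degenerate models: a one-compartment
collapse (total body volume, plasma clearance directly) whose numerical
solution is checked against the closed-form first-order-absorption solution
to 0.1%, and Kp-override/elimination-off variants whose equilibrium is the
dose over total volume. One verification subtlety: in the full multi-organ
model the terminal log-slope equals CL/Vβ, not CL/Vss — Vβ exceeds Vss in
any mammillary system (measured ratio ≈0.96 here) — so the slope-vs-moments
check is asserted at 5%, not at a tolerance only a one-compartment model
could meet.

## Extrapolation

Total clearance scales as CL_ad·(W_tar/W_ad)^0.75 from the adult anchor
(9 L/h at 60.98 kg); the hepatic:renal split keeps the adult per-kg
proportion (0.09:0.05) because no elimination-pathway ontogeny is modelled.
The fraction unbound scales through albumin with the adult reference age
25.7 y. Both equations reproduce the published group table cells at printed
precision (the term-infant fu computes to 21.48% against a printed 21.47% —
a rounding-level difference). Group specific clearances are then recomputed
for the group template physiology; since the bundled physiology differs from
any proprietary database, those min⁻¹ values are documented as approximate.

## Evaluation statistics

NCA uses linear trapezoidal AUC on the sampled grid (linear-up/log-down
available for sparse clinical grids), first-occurrence Tmax on ties, and a
terminal log-linear fit over the last three points for λz — extrapolation to
infinity is withheld unless the tail declines monotonically with r² ≥ 0.9.
MFE is predicted/observed with the open (0.5, 2) qualification window.
TOST analyses ln-scale parameters of a 2×2 crossover by least squares with
subject, period and formulation effects (sequence is absorbed by the subject
effects; residual df = n−2), forms the 90% CI of the formulation contrast
with the t distribution and back-transforms to the GMR scale; equivalence
requires the CI inside 80.00–125.00%. Report display rounds to 2 decimals;
full precision is kept internally.

## Synthetic crossover data

The generator emulates the anchoring trial design: 24 subjects (balanced
TR/RT sequences), single 50 mg doses, the 18-point 0–12 h schedule. Each
subject's concentrations follow a one-compartment oral model with CL, V and
ka drawn log-normally around the adult point estimates (9 L/h, 24 L,
2 h⁻¹); default geometric CVs are 25% between subjects on CL and V, 10% on
ka, 15% within subject on concentrations — values chosen to resemble the
published trial's individual CVs, exposed as arguments, not claimed from any
source. The test formulation multiplies bioavailability by the configured
true GMR, so the estimand is known exactly. Optional censoring reports
concentrations under 1 ng/mL as zero, mimicking an assay quantification
limit (off by default).

What passing tests show: the TOST machinery is calibrated (type-I error ≈5%
at the 80% boundary over 2,000 replicates; GMR recovery bias <1%) *under
the generator's one-compartment, log-normal world*. Real crossover data add
assay error structure, covariate effects and model misspecification the
generator deliberately omits.

## Problem sizes

Default verification runs use the single adult template for the MFE
qualification (sub-second), 12–100-subject cohorts for population
behaviour, and 2,000-replicate Monte-Carlo batches for the estimator
calibration checks — sizes at which every reported statistic is stable to
well inside its acceptance band.

## Known limitations

* Physiology is an open published reference table, not any platform's
  internal database; all comparisons with platform-computed specific
  clearances are approximate by construction (2-fold band).
* Single-dose only; no enterohepatic recirculation, metabolite kinetics,
  transporter or enzyme-level (UGT1A9) detail, nonlinear protein binding,
  dissolution or gastric-emptying model, and no disease-state
  (hyperthyroid, organ-impairment) physiology.
* Pediatric absorption scaling is a geometric argument, not a validated
  ontogeny; pediatric Tmax values should be read qualitatively.
* The brain's effective surface area is a calibration constant tied to the
  delayed-peak behaviour, not an anatomical measurement.
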