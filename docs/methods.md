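# Methods

## Scope and model structure

The package implements a reverse-dosimetry chain for acute oral exposure to
fenitrothion (FNT): in vitro enzyme kinetics → physiologically based
kinetic (PBK) model → in vitro AChE inhibition → predicted in vivo
dose–response → benchmark dose.  Three compounds are tracked: the parent
FNT, its bioactivated oxon FNO (the toxicologically active species) and the
terminal metabolite MNP.  Side products of the two conversions (DMTP, DMP)
are not modeled; neither are demethylated metabolites, MNP conjugation,
intestinal metabolism, enterohepatic recirculation, or a dynamic AChE
submodel — the endpoint is read from the in vitro inhibition curve at the
predicted internal concentration.

Each compound's submodel is flow-limited with six compartments (liver,
kidney, fat, rapidly perfused, slowly perfused, blood) linked by cardiac
output:

    dA_T/dt = Q_T (C_blood − C_T / P_T),   C_T = A_T / V_T

The parent additionally has a two-compartment GI tract: the stomach drains
to liver (ka_s) and intestine (ks_i), the intestine to liver (ka_i).  The
fraction absorbed Fa is applied to the dose at t = 0, so the unabsorbed
remainder never enters the system (the alternative — a competing fecal
first-order loss — would change early absorption kinetics slightly but not
the dose metric, and is not implemented).

Metabolism is Michaelis–Menten in the **unbound** local concentration,
C_u = (fup/BPr)·(C_T/P_T) in the liver and C_u = (fup/BPr)·C_blood in
blood; fup/BPr converts the plasma-referenced unbound fraction to the
whole-blood reference used by the partition coefficients.  This convention
is isolated in one place in the right-hand side so it can be swapped.
Four reactions are modeled: FNT→FNO and FNT→MNP in liver (CYP450),
FNO→MNP in liver and in blood (PON1).  Metabolites formed in liver enter
the liver compartment of their submodel; blood-formed MNP enters blood.

Renal elimination of all three compounds is glomerular filtration times
the **total** venous kidney concentration (GFR·C_kidney/P_kidney); passive
reabsorption of the lipophilic species is a documented, unmodeled caveat
that would lower effective renal clearance.

All amounts are carried in μmol, so parent→metabolite transfer conserves
moles without molecular-weight ratios; every simulation audits
|Σ amounts + Σ urine − administered| at each output time and the result
carries the maximum residual.

## IVIVE scaling

In vitro Vmax (nmol/min/mg protein) scales to whole-compartment μmol/h:

* liver microsomes: × microsomal yield (rat 35, human 32 mg/g liver)
  × liver mass × 60/1000;
* plasma: × plasma protein (rat 59, human 66 mg/mL) × plasma volume (blood
  volume × (1 − hematocrit)) × 60/1000.

Km is assumed identical in vitro and in vivo.  Catalytic efficiency is
always the derived ratio Vmax/Km (mL/min/mg in vitro, L/h in vivo).

## Parameters and provenance

Absorption (Fa 0.9 rat / 0.7 human; ka_s 0.1 / 0.32 h⁻¹; ka_i 0.59 h⁻¹;
ks_i 0.48 h⁻¹), GFR (5.2 / 1.8 mL/min/kg), the scaling factors above and
the 60 kg human reference weight are literature values.  Volume and flow
fractions, cardiac output and hematocrit are standard reference physiology
(Brown et al.-style); rat body weight defaults to 0.25 kg.  Molecular
weights (FNT 277.23, FNO 261.17, MNP 153.14 g/mol) are standard chemical
reference values.

Compound binding (fup) and tissue:blood partition coefficients are
**synthetic stand-ins**: in the source analysis they come from in silico
structure-based predictions that are out of scope here, so the packaged
files carry plausible values for each compound's lipophilicity class
(lipophilic parent with a large fat coefficient; moderately lipophilic
oxon; ionized phenol with near-unity coefficients), converted from
plasma to blood reference by dividing by BPr = 0.55 for all three
compounds.  Likewise the Michaelis–Menten constants are a synthetic
stand-in table constrained by the qualitative findings: the rat:human
bioactivation efficiency ratio is exactly 6.4, detoxification efficiencies
are comparable between species, bioactivation is faster than
detoxification, PON1 hydrolysis is faster in rats, and hydrolysis Km
values sit in the thousands of μM so the velocity curves do not plateau
below the 5000 μM solubility limit.  Every value is overridable via the
TOML schema; replacing these two blocks with measured values is the
intended path to quantitative reproduction of published PODs.  Because the
stand-ins fix shapes and ratios but not absolute magnitudes, downstream
absolute quantities (Cmax per dose, BMDL10) are internally consistent but
not literature-comparable; directional and ratio results are.

## Curve fitting

* **Michaelis–Menten**: pooled replicates, unweighted SSE, multi-start
  (Vmax₀ = max velocity; Km₀ ∈ {0.1, 1, 10} × median concentration), best
  SSE wins, ties to the smallest Km.  r² is computed against replicate
  means.  For designs that do not reach saturation, Vmax and Km are
  individually ill-determined while their ratio (the initial slope) is the
  identifiable quantity; tests assert accordingly.
* **AChE inhibition**: four-parameter log-logistic on the raw
  concentration axis (controls at c = 0 enter the SSE directly), top
  estimated with an upper bound of 110% to absorb control noise, bottom
  bounded at 0.  If the replicate-mean activity never crosses half the
  control level within the tested range, the IC50 is censored and reported
  as "greater than the highest tested concentration" — the fit is not
  forced.  Whether the original analysis fitted a parametric curve or read
  IC50 nonparametrically is unstated; the censoring rule mirrors its
  wording.

## Reverse dosimetry

The dose metric is Cmax of blood FNO within 24 h of a single oral dose
(horizon configurable).  Cmax is extracted from a dense grid (≥ 2000
points/24 h) with local quadratic refinement.  The forward map is strictly
increasing (saturable but monotone metabolism), so inversion uses Brent's
method on a geometrically expanded bracket, to 1e-6 relative tolerance,
with a 1000 mg/kg ceiling; unreachable in vitro concentrations are dropped
and recorded.  Nominal in vitro concentrations are used directly as
effective in vivo blood concentrations — no protein-binding correction —
so measured activities transfer to the dose axis unchanged.  Both curve
modes are provided: measured points only, or (default) 40 log-spaced
concentrations through the fitted curve, which gives the low-dose density
that benchmark-dose fitting needs.

## Benchmark dose

EFSA-style continuous endpoint: BMR is a 10% relative deviation from the
fitted model's dose-0 response (not the raw control mean).  Families:
exponential-3 (a·e^(−b·d^g)), exponential-4 (plateau) and Hill-4, selected
by AIC; BMD has a closed form in each family (a numeric root-finding path
exists as a cross-check).  BMDL10/BMDU10 default to a parametric bootstrap
(n = 1000, seeded): residual-SD Gaussian noise on the fitted curve,
single-start warm refits, 5th/95th BMD percentiles; refit failure above
10% is recorded as a warning.  A profile-likelihood bound at the 90%
two-sided level (n·ln(RSS ratio) against χ²₁) is available as the
alternative.  When the QIVIVE curve comes from the fitted-grid mode its
points are nearly noise-free, so BMDL ≈ BMD; measured-point curves carry
the experimental scatter into the interval.

## Sensitivity and evaluation

Normalized sensitivity coefficients are one-at-a-time forward differences
(δ = 5%, central available) of Cmax blood FNO, normalized by the
unperturbed value; the default parameter set is every scalar model
parameter, addressed by dotted path.  Perturbing a flow fraction
intentionally breaks the sum-to-one constraint (validation is bypassed for
the perturbed copy), as one-at-a-time analysis requires.  When in vitro
kinetics are supplied, Vmax scaling is re-derived per perturbation so the
scaling factors show their real influence.  Model evaluation uses the WHO
2-fold rule, inclusive at the threshold, with an optional quantile
relaxation.

## Synthetic data

The generators emulate the stated experimental world: three replicates;
additive Gaussian noise at 5% of Vmax for incubation velocities (a
proportional-noise option exists for relative-error analyses); 5
percentage points for AChE activity; multiplicative log-normal error with
30% CV (unit median) for in vivo time courses.  Concentration designs span
sub-Km to saturating levels for the CYP450 assays and run to the 5000 μM
solubility limit for hydrolysis.  CR presets: `rat_like` (IC50 0.95 μM,
Hill 3 — resistant then fast-dropping) and `human_like` (IC50 0.84 μM,
Hill 1 — progressive decline).  What synthetic data do **not** carry:
real inter-experiment variability, matrix effects, correlated errors, or
the authors' raw values — a green test establishes that the machinery
recovers what generated the data at the stated noise, not that published
numbers are reproduced.

## Numerical choices

LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10; dense output ≥ 2000
points per 24 h; multiple doses as instantaneous stomach refills with the
integration restarted at each dose time; negative states beyond
max(1e-6 × administered, 100·atol) raise an error.  Tightening tolerances
10× moves Cmax by < 0.01% (tested).  Seeds: every stochastic routine takes
an explicit seed; pipeline stage seeds are derived deterministically from
the run seed and kept below 2³¹.

## Known limitations

* Quantitative POD reproduction requires the measured kinetic constants,
  partitioning and raw AChE data, which are not part of the package; the
  packaged world reproduces mechanisms, ratios and directions.
* The unbound-fraction convention in metabolism and the pooled (single
  well-mixed) blood compartment are stated choices where the original
  implementation details are not public; both are isolated behind single
  functions.
* Renal clearance by total GFR filtration likely overestimates elimination
  of the lipophilic species (no reabsorption term).
* The grid-mode QIVIVE curve understates BMD uncertainty (see above); use
  points mode to propagate experimental scatter.
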