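# Methods

This note documents the model, its parameterisation, the numerical
choices, and what the shipped tests do and do not demonstrate. Internal
canonical units are minutes, millilitres, kilograms of body weight,
nanograms (amounts) and ng/mL (concentrations); loaders and the CLI
convert at the boundary (doses in µg or mg, AUC reported in µg·min/mL).

## In-vitro kinetics and IVIVE

Substrate depletion is treated as first-order: the rate k is the negated
ordinary-least-squares slope of ln C versus t over all sampled time
points (a single-point fallback, using only t = 0 and one later sample,
reproduces screen-style estimates). The unbound microsomal intrinsic
clearance is computed as

    CLint,u = k / (Mic · fu,mic)

with Mic the microsomal protein concentration (mg/mL) and fu,mic the
measured unbound fraction in the incubation. Note the division by Mic:
a first-order rate (1/min) divided by a protein concentration is the only
dimensionally consistent way to obtain a per-mg-protein clearance, and it
reproduces the reference recombinant-UGT2B7 value (40.2% remaining at
60 min, Mic = 0.25 mg/mL, fu,mic = 0.60 → 101 µL/min/mg). Formulations
that *multiply* by Mic appear in the literature but are dimensionally
inconsistent with that worked value.

Organ scaling multiplies CLint,u by the organ's microsomal protein
content (MPPGL 44.8/63.6/48.8 mg/g, MPPGK 17.9/44.0/17.8, MPPGI
9.7/6.5/0.54 for rat/dog/human) and an organ weight in g/kg. The organ
weights used for scaling are a configuration field separate from the
anatomical tissue volumes: the scaling weights implied by the tabulated
in-vivo clearances differ from tissue volume / body weight for several
organs (e.g. human liver 25.7 g/kg vs 24.1 from the volume; rat intestine
22.4 vs 40.0). We ship the back-calculated scaling weights as per-species
defaults — rat liver 36.6 and intestine 22.4; dog liver 32.9 and kidney
5.50; human liver 25.7, kidney 4.39, intestine 14.4 g/kg — so the scaled
clearance table is reproducible to print precision; organs without an
override fall back to tissue volume × 1 g/mL ÷ body weight. Tissue
density is fixed at 1 g/mL throughout.

Blood clearance per organ uses the well-stirred model with
fu,b = fu,p/Rb computed once per species (rat 0.2870/1.10, dog
0.2577/0.92, human 0.3264/0.92). Organ fractions are CLb,i / ΣCLb and
extraction ratios CLb/Q. UGT phenotyping follows the relative activity
factor convention with β-estradiol (UGT1A1) and zidovudine (UGT2B7) as
probe substrates.

## The whole-body model

State vector: 11 perfusion-limited tissue concentrations (lung, heart,
brain, muscle, skin, kidney, spleen, stomach, liver, intestine, rest of
body), two adipose pools, arterial and venous blood, plus three
bookkeeping states accumulating the amount eliminated by liver, kidney,
and intestine (18 states). Topology: the lung receives the entire
cardiac output from the vein and feeds the artery; the liver receives the
hepatic artery plus the venous outflows of spleen, stomach, and
intestine; every other tissue is fed arterially; the vein collects heart,
brain, muscle, skin, kidney, rest-of-body, the adipose vascular pool, and
the total hepatic outflow. Venous blood leaving a tissue carries
concentration C_t/(K_t:pl/Rb). The "rest of body" and the stomach and
intestine carry K_t:pl = 1.00 as tabulated.

Elimination is written as CLint,in vivo,u · W · fu,p · C_t/K_t:pl, i.e.
the scaled intrinsic clearance acting on the unbound plasma-equivalent
concentration in the organ. This is algebraically the well-stirred model:
with outflow concentration C_out = C_t/(K/Rb) the rate equals
CLint·W·(fu,p/Rb)·C_out = CLint·W·fu,b·C_out, and the steady-state organ
balance Q(C_in − C_out) = CLint·W·fu,b·C_out collapses to
rate = C_in · Q·fu,b·CLint/(Q + fu,b·CLint). A corollary used as a test
oracle: for this topology the venous and arterial zeroth moments are
equal, so dose/AUC∞ of the *blood* profile equals ΣCLb exactly, and of
the *plasma* profile equals Rb·ΣCLb (human ≈ 0.92 × 26.6 ≈ 24.5
mL/min/kg).

**Plasma convention.** Model blood spaces are whole blood; observed data
are plasma. The reported plasma trace is C_venous/Rb. This is stated
explicitly because the model itself never contains a "plasma"
compartment.

**Adipose.** Distribution into fat is permeability-limited: a vascular
pool V₁ exchanging with an extravascular pool V₂ through a
permeability–surface product PS (mL/min), with V₁/V₂ = 2.66/16.34 mL
(rat), 210/1290 (dog), 1800/8200 (human). The exact PS → ∞ limit is a
single pool of volume V₁+V₂ whose outflow concentration is
amount/(V₁ + V₂·K/Rb); the perfusion-limited comparison model used in the
convergence tests is this exact reduction (a naive single compartment
with the raw K and total volume differs from the true limit by a finite
amount because the vascular sub-volume carries no partitioning).

**PS calibration.** PS is not measurable in vitro here; the rat value is
calibrated so that the simulated single-dose rat terminal half-life
(0.5 mg/kg IV bolus, the 5–240 min rat sampling schedule, log-linear fit
on the last three samples) equals the reference 58.2 min, and dog/human
values follow PS_i = PS_rat·W_i/W_rat. Two caveats are documented rather
than hidden. First, the constraint is weak: the rat terminal phase mixes
slow skin and adipose washout, so t½(PS) varies only between ~58 and
~61 min over three orders of magnitude of PS and the target is crossed
more than once; the calibration brackets the search to PS between ~5% and
~35% of rat adipose blood flow (0.25–2 mL/min) — the permeability-limited
regime consistent with the pronounced adipose accumulation that motivated
the two-pool model — where the crossing is unique, giving
PS_rat ≈ 0.706 mL/min. Second, this weakness is benign: across
PS_rat ∈ [0.05, 5] the human 10 mg predictions move by under 5% (Cmax
68–72 ng/mL), so no downstream conclusion rests on the branch choice.
PS remains a user-overridable configuration value, and `calibrate_ps`
also supports direct least-squares fitting to adipose concentration data
on log scale (deterministic grid-plus-bounded search; ties resolve to the
lower PS).

**Dosing and integration.** Boluses deposit dose/V_vein into the venous
compartment instantaneously (femoral/forearm IV); infusions are constant
venous inputs over their duration. The clinical human schedule helper
encodes: single dose at t = 0, multi-dose starting 48 h later, every 12 h
for 7 days, last dose on the morning of day 9. Integration is
segment-wise between dose events with LSODA, rtol 1e-8 / atol 1e-10
(profiles span four orders of magnitude); output is sampled on a uniform
grid union any requested times. Mass balance (amount in compartments +
eliminated vs administered) holds to ~1e-4 relative in routine runs and
is asserted below 5e-4 in tests.

**Sampling schedules.** Rats 5–240 min and dogs 5–300 min as designed in
the in-vivo studies; the human post-dose schedule is not printed in the
source material, so the package uses a conventional 5–720 min grid
(5, 15, 30, 45, 60, 75, 90, 120, 180, 240, 360, 480, 720) spanning one
12 h dosing interval. NCA endpoints quoted for humans are computed on
that grid; AUC_last therefore means AUC to 720 min.

## Noncompartmental analysis

Cmax/tmax by direct grid maximum; AUC by linear trapezoid on the given
grid (uniform across rising and falling limbs — the simplest defensible
default); λz by log-linear least squares on the last n points (default 3,
configurable); AUC∞ = AUC_last + C_last/λz; CL = dose/AUC∞. Whether an
AUC is truncated or extrapolated is therefore an explicit caller choice.
For IV-bolus profiles the early venous spike decays on a sub-minute
timescale; AUC comparisons against analytic identities use log-spaced
grids for this reason, and the trapezoid converges at O(h²) (verified).

Fold errors are predicted/observed with the inclusive 2-fold acceptance
band [0.5, 2.0] (the boundary counts as a pass). GMFE is implemented
with *signed* logs, 10^(mean log₁₀(Cpred/Cobs)): systematic
under-prediction yields GMFE < 1 and under-/over-predictions can cancel.
This differs from the |log| convention common elsewhere; it is the only
reading under which method-comparison GMFEs below 1 are reachable, and
the cancellation behaviour is tested explicitly so nobody mistakes it for
the absolute version. RMSE is in concentration units.

## Virtual populations and sensitivity

The variability structure of the reference population simulations is not
specified anywhere, so the package makes its own conventional choice:
independent median-one lognormal multipliers per subject with default CVs
of 30% on organ intrinsic clearances, 20% on fu,p and on each K_t:pl, and
15% on blood flows — magnitudes in line with common PBPK
inter-individual-variability practice. All CVs are configurable and
seed-controlled. After flow sampling, hepatic outflow is re-derived from
its sampled inflows and cardiac output from the sum of systemic flows, so
every virtual subject conserves flow exactly. fu,p samples are capped at
1. Bands are pointwise empirical percentiles (default 5th–95th) with the
population mean; coverage of observations is evaluated with the band
linearly interpolated to observation times. Passing the nominal-coverage
test (≈90% of self-generated observations inside the band) shows the
machinery is calibrated against its own generating model — it says
nothing about how well the default CVs match real inter-individual
variability.

Sensitivity scenarios multiply one parameter group and report
change/control ratios of Cmax, AUC_last, CL, and t½ on the single-dose
human regimen (10 mg, 1 h infusion). "Metabolic velocity" multiplies the
organ's total CLint,in vivo,u (UGT and CYP jointly). Hepatic-blood-flow
scenarios scale the hepatic artery and all portal inflows jointly; the
change is absorbed by the rest-of-body flow so cardiac output is
preserved where feasible — for a 2-fold increase in human hepatic flow
(+1.5 L/min) the rest-of-body flow (0.59 L/min) cannot absorb it, so
rest-of-body floors at zero and the remainder raises cardiac output.
A fold of 1 reproduces the reference exactly (ratios are identically 1).

## Dedrick interspecies scaling

Normalisation: t′ = t/W^(β1−β2), C′ = C/(D/W^β1). Variants: SSS_rat and
SSS_dog fix (β1, β2) = (1.00, 0.75); Elementary TS fixes β1 = 1.00 and
takes β2 from the rat–dog log-log fit of CL; Complex TS fits both
exponents (β1 from Vss, β2 from CL). Per-species CL and Vss come from
each species' own two-compartment fit (CL = k10·V1,
Vss = V1·(1 + k12/k21)); fits use single-dose data. The pooled
normalized data are fitted to the IV-bolus biexponential implied by
(k10, k12, k21, V1) by nonlinear least squares on log concentrations,
unweighted (profiles span decades, and log residuals are the natural
scale). The fit is multi-start over a fixed grid — the slow rate
anchored on the data's terminal slope, fast-rate multipliers {3, 10, 30}
and partition ratios k12/k21 ∈ {0.2, 1, 5} — with best-residual
selection, so it is deterministic for given data. A k12 collapse toward
zero (mono-exponential data) is permitted and flagged. Back-
transformation divides rates by W_h^(β1−β2) and multiplies V1 by W_h^β1;
the human infusion profile is then evaluated analytically with
superposition across doses. Units compose so that fitting observed
ng/mL data with doses in µg yields human predictions directly in ng/mL.

The observed rat/dog profiles of the source study exist only as figures;
the package never digitises figures. The scaling machinery is exercised
on synthetic families constructed to obey exact allometry (on which
Elementary TS recovers the human truth with GMFE < 1.005), and users
supply real CSVs where they have them.

## Synthetic data

Generators emulate each measured input: triplicate depletion time courses
on the 0/10/20/30/45/60 min incubation schedule; equilibrium-dialysis
assays at 75–600 ng/mL and blood-partitioning assays at 100–900 ng/mL
(triplicate); plasma tables from analytic two-compartment truths on the
per-species schedules; tissue tables from PBPK simulation at the
5/30/90 min sacrifice times. Noise is multiplicative lognormal with
median 1 (concentrations are positive and assay CVs scale-proportional),
default CV 10% — typical bioanalytical precision. Every generator is a
pure function of its seed (byte-identical reruns), and with noise_cv = 0
each generator's output fed through its matching estimator returns the
true parameters to numerical precision; these round trips are the
backbone of the test suite. What the generators do *not* emulate:
calibration curves, carryover, LLOQ censoring, correlated
inter-occasion variability, or real biological covariance between
parameters — so green tests demonstrate estimator correctness, not
field performance on real bioanalytical data.

Human "observed-style" fixtures are parameterised from published summary
statistics rather than digitised curves and are labelled synthetic
wherever they appear.

## Problem sizes

The shipped tests and the acceptance script run the chain at the sizes
the methods themselves prescribe: 100-subject bands (the coverage
property uses 200 + 100 subjects, since empirical 5th–95th percentiles of
a 100-subject band systematically undercover by 1–2% and the asymptotic
statement is about large n), single- and triple-dose simulations over
240–6000 min horizons, and steady-state AUC checks on ~800-point
log-spaced grids. The full suite completes in well under a minute of CPU
apart from the population tests (a few hundred ODE solves, ~30 s total).

## Known limitations

- IV routes only; no oral absorption model (the compound's high hepatic
  extraction makes oral dosing impractical anyway) and no transporter or
  nonlinear-binding kinetics; depletion kinetics are strictly first-order
  (no Km/Vmax saturation).
- K_t:pl values are consumed as tabulated; the package does not compute
  them from tissue composition.
- The adipose PS is identified only up to the documented calibration
  choice; users with tissue data should fit it directly.
- Physiology scales between the three reference body weights only; no
  covariate-based (age/weight/renal-function) population models.
- The population variability structure is an assumption, not an estimate.
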