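# Methods

This note documents the models, estimators, numerical choices and known
limitations behind qhtskit. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Assay forward model and what the generator emulates

The screen is a cell-free coupled-fluorescence enzyme assay: the target
enzyme hydrolyses its lipid substrate at a Michaelis–Menten rate
v = Vmax·S/(Km+S), a product of that reaction is converted stoichiometrically
through a multi-enzyme detection cascade to a fluorophore, and the plate
reader reports RFU = background + gain × product. The generator linearises
product accumulation over the incubation (the assay is run in its linear
range) and guards the approximation with a hard error when accumulated
product would exceed 10% of substrate; substrate depletion and the cascade's
own kinetics are not modelled (stoichiometric proportionality is assumed).

Default conditions reproduce the validated screening setup: 0.1 µg/µL enzyme
(rates scale linearly in enzyme load), 20 µM substrate, 2 h incubation,
Km = 20 µM, Vmax = 1 µM/h at reference enzyme load. Gain (2381 RFU/µM) and
background (119 RFU) are set so an uninhibited well reads 2500 RFU and
signal/background is 21. Well noise is multiplicative lognormal with
configurable CV (default 5%); lognormal keeps RFU positive and reproduces a
Z′ near 0.8 under the default separation. Noise enters once per well on the
final RFU, so control wells and compound wells share one error model.

Plate geometry is 32 rows (A–AF) × 48 columns. Column 1 carries the
positive-inhibitor dose series — 16 doses, 1:2 dilution from 285 µM, two
wells per dose, IC50 27 µM — column 2 the no-enzyme background, column 3 the
saturating positive control, columns 4–48 the test field. The printed
description of the control series' bottom concentration is internally
inconsistent with a strict 1:2/16-dose ladder; the generator fixes the count
(16) and the top (285 µM), which puts the bottom near 8.7 nM, and exposes
both knobs in configuration.

The compound library plants four ground-truth classes: genuine inhibitors
(IC50 log-uniform 0.03–3 µM, efficacy 85–100%, Hill 1), detection-cascade
false positives (they suppress the readout, not the enzyme; counter-IC50
log-uniform 0.1–50 µM, an assumption — their mechanism distribution is not
observable), flagged promiscuous actives (apparent IC50 1–30 µM; the flag
stands in for structural promiscuity analysis, which is out of scope), and
an inactive majority. Dose schemes: 4-dose primary (57 µM top, 1:5 — the
primary source states two different primary dose sets in different sections;
the Methods-style 1:5 ladder is the default and both are configurable) and a
7-dose confirmation/counter design (57 µM top, 1:3; the original count is
stated but not its spacing — 1:3 was chosen to span 0.078–57 µM).

What passing tests on this generator do **not** show about real screens:
real libraries contain partial-efficacy and steep-Hill actives, aggregation
artefacts, plate-position drifts and batch effects that the generator omits;
the noise model is a single i.i.d. multiplicative term. Recovery statistics
on synthetic screens are therefore upper bounds on real-campaign behaviour.

## Dose–response fitting and curve-response classes

Percent inhibition is 100 × (1 − rate_I/rate_0), clipped to [−10, 110] for
reporting. The printed formula in the source protocol lacks the "100 −"
complement (as written it is percent activity); the complement is
implemented so that inhibition increases with effect.

The 4PL model is fit on log10 dose by bounded least squares
(`scipy.optimize.curve_fit`, dogbox with an analytic Jacobian, multi-start
over midpoint guesses). Four-dose primary data are fit with bottom fixed at
0 and Hill ∈ [0.5, 3] to avoid overfitting; richer designs free all four
parameters with soft bounds (bottom ∈ [−30, 60], top ∈ [−20, 120],
log10 IC50 within the dose range ± 3 logs, Hill ∈ [0.5, 3]). The Hill window
covers single-site inhibition with moderate cooperativity; it also prevents
a shallow complete-curve solution from mimicking a truncated curve, which is
what makes classification stable under noise. Non-convergence returns a
result with NaN parameters that can only classify as single-dose activity
(−3) or inactive (4).

Curve-response classes follow the qHTS convention. Two choices differ from
the most literal reading of their usual description, both for estimator
stability, verified by the classifier regression suite:

* **Asymptote detection** uses the fitted curve's end slopes: an asymptote is
  reached at a range end when |dy/dlog10 d| ≤ 10 percent-points/decade at the
  extreme dose, and a flat low end only counts as the *lower* plateau when it
  sits within 10 points of the fitted baseline (a saturated curve is
  flat-high at its lowest dose). Plateau-proximity rules based on the fitted
  top/bottom parameters are unstable because those parameters are weakly
  identified for incomplete curves, while fitted end slopes and end values
  track the data directly.
* **Efficacy** is the fitted inhibition reached *within the tested range*
  relative to the fitted baseline (the observed-maximal-response convention),
  not the extrapolated top-minus-bottom span, for the same identifiability
  reason. For complete curves the two coincide.

Class assignment: inactive (4) when efficacy < 30%; single-dose activity
(−3) when the fit fails or r² < 0.9 (with any dose ≥ 50% response), or when
no asymptote is in range *and* the midpoint lies outside the tested doses;
otherwise class 1 (both asymptotes) or 2 (one asymptote, or none with an
in-range midpoint — a well-fit graded curve on a sparse design is an
incomplete curve, not single-point activity); subclass .1 when efficacy
≥ 80%, else .2; an IC50 more than one log outside the tested range flags the
fit as extrapolated and demotes .1 → .2. All thresholds live in
configuration; the numeric cut-offs are package defaults, not values asserted
by the original classification scheme, whose exact numbers are not public.

The classifier regression population (`synth.CRC_EXEMPLAR_REGIONS`) draws
clear exemplars of classes −1.1, −1.2, −2.1, −2.2 and 4 on the 7-dose
design — parameter regions chosen so the planted label is unambiguous at
noise zero. Curves straddling a class boundary are excluded by construction:
any threshold classifier flips on boundary curves with probability
approaching one half, so boundary-straddling draws measure the draw, not the
classifier. Class −3 has no stable generative exemplar under this fitting
machinery (data a 4PL fits well never classify −3 by design) and is covered
by constructive unit tests instead.

IC50 confidence intervals are residual-bootstrap percentile intervals;
residuals are inflated by √(n/(n−p)) because raw residuals of a p-parameter
fit underestimate the noise scale.

## Triage cascade

Stages and defaults: primary selection (top-dose response strictly > 50% and
CRC ∈ {−1.1, −1.2, −2.1, −2.2}), promiscuity-flag removal, confirmation
(7-dose refit retains a selectable class), counter screen (inactive by curve
class 4 by default, or by a response floor at the top dose under the
`threshold` rule — the original criterion is not stated, so both are
implemented), differential rescue (counter-active but pIC50 gap ≥ 1 log or
counter efficacy < 50%), and an inclusive potency gate (IC50 ≤ 10 µM on the
confirmation fit). Every removal appends a machine-readable reason code, and
the stage counts satisfy the conservation identities checked in the suite.
`TriageReport.from_stage_counts` reproduces the funnel arithmetic from stage
totals alone; there "counter false positives" counts all counter-screen
actives before rescue (the published convention), whereas verdict-level
reports count differential rescues separately.

## Inhibition kinetics

Per-inhibitor-level Michaelis–Menten fits report Vmax and Km with standard
errors; Km is flagged ill-determined when its SE exceeds the estimate or the
substrate design does not straddle it (below saturation only the ratio
Vmax/Km is identified). The global fit runs all four textbook rate laws over
the substrate × inhibitor grid and selects by AICc; a gap smaller than
2 AICc units to the runner-up marks the diagnosis ambiguous. Because the
mixed model nests the pure modes, noise-free data would let AICc chase
floating-point rounding; the RSS entering AICc is floored at the numerical
precision of the data scale so that ties on fit are decided by the parameter
penalty. Noncompetitive data produce the diagnostic signature the module
exists to detect: apparent Vmax halves at I = Ki while apparent Km stays
flat, and the global Ki equals the fixed-substrate IC50.

## Non-compartmental PK

Profiles are composite-design (destructive sampling, one animal per sample);
per-time means are naively pooled — the original analysis software is named
but not its pooling convention, and destructive sampling forces pooling.
AUC(0–t) uses lin-up/log-down by default (the common default of the named
software; plain linear available), with C = 0 prepended at dose time for
extravascular profiles. λz regresses log concentration on the last three
quantifiable post-peak points by default; a best-adjusted-r² window search
is available. AUC(0–∞) adds Clast/λz. `time_above` reports the last downward
crossing of the linearly interpolated mean profile.

Generator defaults: one-compartment first-order absorption
C(t) = A(e^(−ke·t) − e^(−ka·t)) with ka = 3.2/h, ke = 0.8/h and A set so the
analytic plasma AUC(0–∞) is 10 µM·h; brain = 0.26 × plasma; sampling at
0.25–6 h, n = 3 per time, 10% CV. These defaults were chosen by constraint
analysis before any test was run: they fix the analytic AUC, a sampled Tmax
of 0.5 h, the 0.26 exposure ratio, and keep the trapezoid discretisation
bias of AUC(0–∞) under the 6-point design below 3% (computed analytically:
≈ −2.6%). The printed peak concentration is not simultaneously attainable
with that AUC under a strict one-compartment model (AUC/Cmax pins the
elimination scale), so exposure, Tmax and the ratio were privileged over
Cmax; the simulated profile also stays above the 30 nM potency threshold in
brain slightly longer than the original narrative (≈ 5.8 h vs "up to 4 h"),
a direct consequence of the same compromise.

Microsomal stability fits first-order decay to percent-remaining
(normalised to t = 0); a decay constant within 1.96 SE of zero (or
numerically nil) reports "stable" with infinite half-life, and a
significantly increasing trend is flagged and clipped.

## Biomarker statistics

2^−ΔΔCt: per-sample ΔCt = Ct_target − Ct_reference, ΔΔCt versus the control
group's mean ΔCt per gene, folds as 2^−ΔΔCt with the SD of ΔΔCt as the
dispersion; the estimator is invariant to plate-wide Ct offsets. Percent
reduction is 100(1 − mean_t/mean_r) with delta-method propagation of the two
group SEMs by default (bootstrap optional) — the original ± convention is
unstated. One-way ANOVA is computed from sums of squares directly, with
Tukey–Kramer pairwise comparisons using `scipy.stats.studentized_range`
(identical groups with zero within-variance are reported as F = 0, p = 1).
EV dose–response reuses the 4PL machinery on percent inhibition of the
vehicle-mean count, so "EC50/Emax" come back as `ic50_um`/`efficacy`.

## Problem sizes and determinism

Every generator and the pipeline are pure functions of (parameters, seed);
plate seeds are spawned from the run seed, and rerunning a configuration
reproduces `summary.json` byte for byte. The test suite and acceptance
script use scaled-down study sizes chosen to estimate each property well:
screens of a few hundred compounds (the funnel logic is size-independent;
the real campaign's stage counts enter only as inputs to the arithmetic
identities), 1000-curve classification populations, 500-study Monte-Carlo
loops for PK bias and kinetic signatures, 150–300 bootstrap resamples, and
biomarker effects averaged over 25 simulated studies of the original n = 5
design.

## Known limitations

* The detection cascade is a gain factor, not a kinetic model; counter-assay
  signal strength is assumed comparable to the main assay.
* Promiscuity is a ground-truth flag, not a structural computation.
* CRC cut-offs are defensible defaults, not the original algorithm's
  (non-public) constants; classifications near any threshold are unstable
  under noise for any such scheme.
* PK is one-compartment with lognormal noise; no absorption variability,
  below-quantification-limit censoring, or per-animal covariance.
* The ANOVA/Tukey path assumes homoscedastic groups (pooled variance).
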