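# Methods

This note documents the statistical model, the numerical choices and the
known limitations of the package, in the order the pipeline runs.

## Severity categorisation

Tumour endpoints are ordered into five severity categories
(1 preneoplastic, 2 benign, 3 single-organ malignant, 4 metastasizing
malignant, 5 tumour-bearing animals).  A 10% increase in hyperplasia is
not equipotent to a 10% increase in carcinomas, so potency estimation runs
per category, over categories 2–5 only, and results are pooled afterwards.
The packaged lesion-term table maps common rodent pathology nomenclature
to categories by whole-word matching (longest matching term wins, so
"metastatic carcinoma" resolves through "metastatic" to category 4 rather
than through "carcinoma" to 3).  The table is a reconstruction from the
category definitions, intended as a reasonable default for common terms,
not an authoritative pathology reference: users with their own
pathologist-curated list should pass it as a CSV, and unknown terms always
raise rather than defaulting.

Datasets qualify for potency estimation only when the exposure period
exceeds 96 weeks (strictly), approximating lifetime exposure in rodents.
Study-duration differences beyond that cutoff are ignored — a known source
of bias when durations range much beyond ~100 weeks, and a candidate for a
time-to-tumour extension out of scope here.

## Dose-response model

Incidence follows the quantal exponential (Weibull-type) model

    p(d) = c + (1 − c) · (1 − exp(−(d/β)^g)),     c ∈ [0,1), β > 0, g > 0,

with the benchmark response defined on the extra-risk scale
ER(d) = (p(d) − c)/(1 − c), so BMD = β·(−ln(1 − BMR))^{1/g} in closed
form.  This family was chosen because it satisfies every property the
method relies on: curves sharing `g` are parallel on log-dose; the BMD
ratio of two compounds under shared `g` equals β_ref/β_i at *any* BMR; and
extra risk corrects for the widely differing background rates of rodent
bioassays.  Default BMR: 0.10.

Fitting maximises the binomial log-likelihood over (logit c, log β, log g)
— an unconstrained-scale parameterisation that keeps the optimiser away
from boundary pathologies — with L-BFGS-B from five deterministic starts
(a moment-based (c, β) initialiser crossed with steepness offsets; the β
initialiser exploits ER(β) = 1 − 1/e regardless of `g`).  Convergence
tolerance is 1e-13 relative on the objective; the fit is seedless and
deterministic.  Flat or non-monotone datasets are not errors: the BMD and
its upper bound are reported as infinite when the likelihood never closes
on the upper side, and the lower bound stays finite and informative.

## Confidence bounds

All intervals in the pipeline are two-sided 90%, end to end, so the
Monte-Carlo calibration (below) can treat every input uniformly.
Dose-response bounds come from profile likelihood at a log-likelihood drop
of ½·χ²₁(0.90) = 1.3528: the parameter of interest (log BMD in single
fits; each log RPF = log β_ref − log β_i in the joint fit) is fixed on a
expanding grid while all other parameters are re-optimised (warm-started),
and the crossing is located by Brent root-finding to 1e-5 on the log
scale.  A profile that has not reached the threshold within 30 log units
is declared open on that side (reported as 0 or ∞).  Profiling the log RPF
directly — rather than combining per-compound BMD intervals — is the
statistically correct construction and is what makes the BMR-invariance of
the RPF intervals exact rather than approximate.

The joint ("covariate") fit shares one steepness across compounds, one
background per dataset and one log location per compound.  Data-poor
compounds thereby borrow steepness information from data-rich ones and
still receive finite, usable intervals.  The parallelism assumption this
rests on is checked in retrospect by a likelihood-ratio test against
per-compound steepness (df = n_compounds − 1); the check is advisory — a
rejection warns that the dose-addition reading is strained but does not
block the pipeline.

## Pooling across severity categories

Each severity-specific 90% RPF interval is read as a lognormal (the same
calibration as Step 5) and the combined interval is the 5th/95th
percentile pair of the equal-weight mixture.  The quantiles are computed
exactly from the mixture CDF by root-finding rather than by sampling — a
deterministic implementation of the same definition (a sampling
cross-check sits in the test suite).  Intervals with a zero lower bound
cannot calibrate a lognormal; at the sampling stage such bounds are
floored at 10⁻⁶ of the upper bound, far below where they could matter in a
potency-weighted sum, and the substitution is logged.

## Emission intervals

Replicate per-stick emissions vary multiplicatively, so the mean is
summarised as a geometric mean with a t-interval on the log scale:
exp(m̄ ± t_{0.95,n−1}·s/√n).  At n = 2 this is honest and brutally wide
(t = 6.31), which is the point — few replicates should propagate as large
uncertainty.  Non-detects are substituted at LOD/√2 (user-overridable) and
logged; mixed smoking regimes between products trigger a warning since
only same-regime ratios are meaningful.  A scalar consumption factor
(sticks consumed relative to the baseline product) multiplies the
alternative product's bounds when usage differs.

## Monte-Carlo propagation

Every bounded quantity is given a lognormal with
μ = (ln lb + ln ub)/2, σ = (ln ub − ln lb)/(2·z₀.₉₅); its 5th/95th
percentiles then reproduce the bounds exactly.  Per draw, each compound's
cigarette emission, alternative emission and RPF are sampled
independently, with the *same* RPF value used in numerator and denominator
— it describes the same compound in both products, and this sharing is
what makes the reference-compound invariance of the CCE hold draw by draw.
No further correlation structure is imposed (none is identifiable from
bound tables alone).  Defaults: n = 10⁶ draws, seed 17; both recorded in
every output.  Percentiles are empirical order statistics with linear
interpolation.  The compound iteration order and the per-compound draw
order are fixed, so results are bit-reproducible for a given (inputs, n,
seed), and point-mass inputs bypass the exp/log round-trip so exact
algebraic identities (e.g. common RPF rescaling) hold bitwise.

Contribution shares — each compound's fraction of the potency-weighted sum
— are averaged over draws per product and reported alongside the CCE; they
identify which compounds the conclusion actually rests on.

## Health translation

The CCE interval is converted to effect-size halvings
h = ln(CCE)/ln(F), with F the dose ratio that halves the effect size
(BMD10/BMD05).  For continuous endpoints F is typically close to or below
2 (default 2.0; rat time-to-tumour data suggest 2–2.6).  The qualitative
rubric: CCE = 1, no change; CCE ≥ 10 across the interval, substantial
reduction in harm; CCE < 1, increase in harm.

## Synthetic data

The generator draws binomial incidence from the same quantal exponential
family with configured true RPFs (parallel curves by construction),
steepness 1.2, background 0.05, four dose groups of 50 animals per
compound placed at {0, β/2, β, 2β} of each compound's own location — a
design whose response runs from background to ~90% incidence, like a
well-placed bioassay.  Emissions are lognormal around configured geometric
means (GSD 1.3, 5 replicates).  The default scenario has eight compounds
with potencies spanning four orders of magnitude and an alternative
product emitting 12-fold less of everything (true CCE exactly 12).

What passing recovery tests show is that the machinery is consistent:
when the parallelism and lognormality assumptions hold exactly, RPF
intervals achieve near-nominal coverage and the CCE interval covers the
true ratio.  Real bioassay data violate these assumptions in ways the
generator deliberately does not emulate (non-parallel curves, litter
effects, dose selection near the MTD, historical-control drift), so
simulation results bound optimism, not realism.

## Problem sizes used in validation

The validation suite runs the case-study reproduction at n = 10⁶ draws,
profile-CI coverage over 200 simulated four-compound studies (true RPFs
{1, 0.5, 10, 50}, 50 animals/group), and full-pipeline recovery over 100
replicates (5 emission replicates, 2·10⁴ CCE draws each) — sizes at which
the binomial noise on a coverage estimate is ~2 percentage points.

## Known limitations

- RPFs from rodent inhalation bioassays are assumed to transfer to humans;
  the method inherits this assumption from dose addition generally.
- The severity-pooling step (equal-weight lognormal mixture) is one
  defensible reading of "combine the categories"; weighting by data
  quality or category severity would be equally defensible and is not
  implemented.
- Open-ended RPF intervals (0 or ∞) are handled conservatively at the
  sampling stage but a compound whose interval is open *above* cannot be
  sampled at all and must be excluded or capped by the user.
- No model averaging across dose-response families, no time-to-tumour
  modelling, no population-level (prevalence/dual-use) modelling.
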