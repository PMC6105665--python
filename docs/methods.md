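# Methods

This note documents the statistical procedures implemented in `cinscore`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Marker panel and arm model

The packaged panel (`panel_gc22.yaml`, hg19) carries 22 AI-scoring
microsatellite markers over 17 chromosomal regions — 19 in four multiplex
PCR groups plus the three dinucleotide repeats (D2S123, D5S346, D17S250)
shared with the MSI screen — along with BAT25/BAT26 for MSI and the eleven
markers dropped during assay optimisation (kept with `excluded: true` so
panel provenance is auditable rather than silently deleted). Five regions
(8q24, 9p21, 12p12, 17q12, 18q21) carry two markers; a region is called AI
when either member shows AI. Each marker stores its cytogenetic band,
fragment-size range, population heterozygosity, and calibrated
(lower, upper) AI thresholds; thresholds must satisfy lower < 1 < upper.

The arm model is BED-like text with a declared build (packaged: hg19,
boundaries at the UCSC centromere gap; p = [0, gap start), q = [gap end,
chromosome end)). The evaluable set for the arm-level classifier drops the
five acrocentric short arms, which carry no assayable unique sequence, and
18p/18q/21q, which are so frequently altered in gastric tumours that they
are uninformative for a CIN call — leaving the 36-arm denominator of the
alteration ratio. Chromosome names are accepted with or without a `chr`
prefix and normalized to unprefixed.

## Threshold calibration

For each marker, allele ratios (shorter/longer peak area) of heterozygous
non-tumorous samples are divided pairwise in both directions, giving
n(n−1) quotients closed under reciprocal. Symmetrization is deliberate:
which of two samples sits in the numerator is arbitrary, and ordered pairs
make the calibrated bounds reciprocal-consistent (log lower ≈ −log upper),
matching the multiplicative nature of amplification noise.

Thresholds are percentile-bootstrap confidence-interval bounds: the lower
bound of the two-sided 95% CI of the 2.5% quantile and the upper bound of
the CI of the 97.5% quantile, with B = 10,000 replicates by default and
linear-interpolation empirical quantiles. The percentile bootstrap was
chosen as the minimal-assumption flavour. By default the quotients are
resampled directly; because quotients sharing a sample are dependent, this
understates CI width, so a sample-level resampling mode (resample the
per-sample ratios, rebuild the quotients) is provided as an option.
Degenerate (constant) inputs return lower = upper = the constant with a
`degenerate` flag; a configurable floor (default 20 quotients) guards
against meaningless calibrations. Seeds are recorded in the output, each
marker gets an independent child seed so results do not depend on
evaluation order, and thresholds are rounded (2 decimals) only at report
time, never internally.

A Monte-Carlo coverage harness (`calibration_coverage`) measures the
false-positive AI rate implied by any threshold set under the generator's
noise model; with CI-bound thresholds the rate is slightly conservative
relative to the nominal 5% of the raw 2.5%/97.5% quantiles.

## AI calling and two-step classification

The AI value is the quotient of normal and tumour allele ratios and obeys
AI(N,T)·AI(T,N) = 1. Threshold comparison is strict (<, >): a value exactly
on a bound is not AI, matching the convention in which thresholds are
printed as "<0.82 / >1.29". A marker is informative only if the normal is
heterozygous and the matched tumour genotype is evaluable with the same two
alleles (0.5 bp tolerance); non-informative markers enter neither numerator
nor denominator of the AI ratio. Zero informative markers yields a
`not_evaluable` sentinel, never a zero ratio.

MSI screening precedes AI evaluation: a Bethesda marker is unstable when
the tumour shows an allele length absent from the matched normal, and MSI
requires at least two unstable markers of five. The exact band-scoring
protocol of the original assay is not public; this standard band-shift
definition is adopted and flagged as such. MSI cases receive no AI profile.
The CIN cut-off is inclusive: AI ratio ≥ 0.2 → CIN-H. A configurable
25%-cellularity warning is attached when sample cellularity metadata is
provided.

## Dilution model and limit of detection

DNA mixing is modelled linearly in peak-area space with equal per-allele
amplification efficiency: each allele's mixture area is f·area_T +
(1−f)·area_N. This is the simplest model consistent with a DNA-mixing
design; it makes the AI value exactly 1 at f = 0, the pure-tumour value at
f = 1, and monotone in between. Consequently even complete loss of one
allele yields an observable AI value of only 1/(1−f) at tumour fraction f,
which is what bounds the limit of detection. `lod_scan` evaluates the full
profile on a fraction grid and reports, per tumour, the smallest grid
fraction from which the CIN-H call is stable for all larger fractions.

## Arm-level classification

Segment files use the 1-based inclusive SEG convention and are converted
internally to 0-based half-open. Arm coverage is the length of the union of
non-neutral segments clipped to the arm over the arm length — the
disjunctive reading of "lost, gained or demonstrated AI" — so duplicated
and overlapping segments never inflate coverage, and segments crossing the
centromere are effectively split by clipping. Per-call-type fractions are
reported alongside. An arm is altered at coverage ≥ 0.8 (inclusive);
CIN-H requires ≥ 1 altered evaluable arm; the alteration ratio divides by
36. Whether a single coherent event type should have to cover the 80% is
not decidable from the assay description; the union reading was chosen and
the per-call fractions allow the stricter analysis downstream.

`compare_methods` reports locus concordance (PCR AI call vs presence of a
non-neutral segment at the marker position — by default the midpoint of the
marker's arm, a deliberately coarse mapping at arm-level resolution, with
an explicit per-marker position mapping accepted), Pearson correlation of
the per-tumour AI ratio with the alteration ratio (≥ 3 shared samples,
else NaN), and CIN-class concordance. `cutoff_scan` evaluates all candidate
cut-offs (distinct ratios and neighbour midpoints) against an arm-based
reference and decomposes errors into false-H and false-L.

## Heterogeneity and crossing probability

`estimate_components` uses the standard one-way layout: s_w is the root of
the mean per-patient unbiased variance, s_b the unbiased SD of per-patient
means, x̄ the mean of means. Note the SD of patient means includes a
s_w²/r contribution; at the default design (5 areas, s_w ≈ 0.05) this
inflates s_b by ~1% and is accepted rather than bias-corrected, keeping the
estimator exactly as defined.

The crossing probability integrates the flip probability of the mean of r
measurements over the patient distribution. The defining expression is
implemented with the *normalized* Normal(x̄, s_b²) density — written with a
bare φ((x−x̄)/s_b) the integral would not be a probability; the 1/s_b
Jacobian is required and is included here. Quadrature runs over x̄ ± 8 s_b
(absolute tolerance 1e−8, break points at c and x̄); widening to ± 12 s_b
changes results by < 1e−9. Limits are handled analytically: s_w = 0 gives
CP = 0 (no measurement noise; 0.5 in the measure-zero case x̄ = c with
s_b = 0), s_b = 0 collapses to 1 − Φ(|x̄ − c|√r/s_w). The 1/√r scaling of
the measurement SD is exact in this model, and the implementation
reproduces it to quadrature tolerance. A 10⁶-draw simulation oracle
(`crossing_probability_mc`) provides the independent cross-check.

## Synthetic-data generator

The generator emulates the measurement process, not any particular patient
cohort. Defaults are the assay's establishment conditions and are fixed:
58 calibration normals; 100 tumour cases; 10% MSI; 78% CIN-H among MSS
cases; tumour purity uniform on [0.4, 0.9].

* **Noise.** Allele ratios carry multiplicative lognormal amplification
  noise with log-SD σ_m = 0.06 per amplification (so null AI values are
  lognormal with log-SD σ_m√2). σ_m was set so that thresholds calibrated
  under this noise fall within the packaged panel's 0.64–1.56 range;
  per-marker σ can be supplied. Total yield varies lognormally (σ = 0.3)
  and cancels in ratios.
* **Truth structure.** Alterations are planted arm-wise: a CIN-H tumour
  alters 4–10 marker-bearing evaluable arms (plus 0–3 without markers);
  any tumour may additionally alter 18q (p = 0.3) — common in GI tumours
  and the reason that arm is excluded from the arm-level call. CIN-L
  tumours alter nothing else, keeping truth consistent between the PCR
  and segment views by construction. Markers on altered arms are AI-true
  with pure-tumour effect |log AI| ~ U(log 2, log 6), random direction,
  attenuated by purity through the same linear mixing model used for
  dilution.
* **Segments.** Altered arms receive one non-neutral segment covering
  80–100% of the arm; non-altered arms occasionally (p = 0.15) receive
  sub-threshold segments (5–50%) so the 80% rule is actually exercised.
* **MSI.** MSI cases gain novel in-range alleles at 2–5 Bethesda markers.
* **Heterogeneity / dilution series.** Repeated-area tables draw patient
  truth from Normal(x̄, s_b²) and areas from Normal(truth, s_w²) with
  defaults x̄ = 0.3, s_w = 0.05, s_b = 0.1 on a 9 × 5 design; the dilution
  module builds four strongly altered tumours with stated initial contents
  {0.6, 0.7, 0.7, 0.9}.

All randomness flows from one recorded seed; fixed seeds reproduce outputs
bit-identically.

**What passing tests do not show.** The generator omits stutter artifacts,
dye pull-up, PCR dropout, size-calibration drift, contamination, and any
spatial structure of tumour heterogeneity; real peak tables violate the
clean lognormal noise model to varying degrees. Results on synthetic
cohorts therefore validate the statistical machinery and its
self-consistency, not the wet-lab performance of an assay.

## Problem sizes and numerical conventions

The default test and acceptance runs use cohorts of 40–200 tumours,
calibration sets of 58 normals, bootstrap sizes of 1,000 (batch
calibrations) to 10,000 (single calibrations), 20,000-draw coverage
simulations averaged over 8 independent null cohorts, 10⁶-draw
crossing-probability oracles, and 1,000 random segment sets against the
per-base counting oracle — sizes at which every reported quantity is
stable to well within its tolerance. Fragment sizes within 0.5 bp are the
same allele; ties in area-concordance majorities resolve towards CIN-H
(the inclusive side of the cut-off); empty segment sets give zero
coverage; file outputs carry `#`-prefixed provenance headers.

## Known limitations

* Quotient-level bootstrap dependence (above) — sample-level mode provided.
* The arm-midpoint default for marker positions makes locus concordance an
  arm-level statement unless explicit positions are supplied.
* The MSI band-shift rule is a generic Bethesda-style scoring; laboratory
  protocols differ in stutter handling.
* Peak areas are trusted as called; no stutter correction is applied
  (a minimum-area floor is configurable upstream of genotyping).
* The hg19 arm table is packaged; other builds require a user-supplied
  table (the format declares its build in the header).
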