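# cinscore

Microsatellite allelic-imbalance (AI) scoring and chromosomal-instability
(CIN) classification for matched tumour/normal fragment-analysis data.

## The problem

Chromosomal instability — here, as in the TCGA tumour taxonomies, a static
measure of the extent of copy-number change and allelic imbalance in a
tumour, not a rate — defines a clinically relevant subclass of gastric and
other carcinomas. Genome-wide SNP/MIP arrays measure it directly but are
costly and poorly suited to routine FFPE material. A multiplex PCR panel of
microsatellite markers offers a cheap surrogate: at a locus where the
patient is heterozygous, the relative peak areas of the two alleles shift
when the tumour has gained or lost chromosomal material.

`cinscore` implements that surrogate end to end for people running or
evaluating such assays: threshold calibration from non-tumorous tissue, AI
calling, two-step MSI → CIN classification, an arm-level classifier for
array segment calls, the misclassification model for intra-tumour
heterogeneity, and purity/limit-of-detection analysis — together with a
synthetic-cohort generator so every stage is testable without patient data.

## The model

At a heterozygous marker the **allele ratio** is area(shorter allele) /
area(longer allele). The **AI value** compares normal (N) and tumour (T):

    AI value = [area(N, s) / area(N, l)] × [area(T, l) / area(T, s)]

Balanced tumours give 1.0. Each marker carries calibrated thresholds
(lower, upper) around 1; values strictly outside call AI. Thresholds are
estimated from pairwise allele-ratio quotients of heterozygous non-tumorous
samples, as the lower/upper bounds of bootstrapped two-sided 95% confidence
intervals of the 2.5% and 97.5% quantiles.

Per tumour:

    AI ratio = (markers with AI) / (informative markers)      ∈ [0, 1]

with *informative* = heterozygous in the normal and evaluable in the
tumour. Tumours with AI ratio ≥ 0.2 are **CIN-H**, below **CIN-L**.
Microsatellite-unstable tumours cannot be scored this way, so cases are
screened first with the 5-marker Bethesda panel (MSI iff ≥ 2 unstable
markers) and MSI cases are excluded from AI evaluation.

For genome-wide segment calls (gain/loss/AI/neutral), a chromosome arm is
altered when ≥ 80% of its length carries non-neutral calls; a tumour is
CIN-H when ≥ 1 evaluable arm is altered, and

    alteration ratio = altered evaluable arms / 36

where the 36 evaluable autosomal arms exclude the acrocentric short arms
(13p, 14p, 15p, 21p, 22p) and 18p/18q/21q.

For repeated measurements (r tumour areas), the probability that
measurement noise flips a patient across the cut-off c is

    CP(r) = ∫ [1 − Φ(|x − c|√r / s_w)] · N(x; x̄, s_b²) dx

with s_w the within-tumour and s_b the between-patient SD of the AI ratio.

## Worked example

Simulate a small cohort, calibrate thresholds on its 58 non-tumorous
samples, and classify:

```sh
cinscore simulate --seed 7 --out-dir demo --n-normals 58 --n-tumours 12
cinscore calibrate demo/calibration_normals.tsv --seed 1 --out demo/thresholds.tsv
cinscore classify demo/cohort_peaks.tsv --thresholds demo/thresholds.tsv \
    --out demo/profiles.tsv --summary-out demo/regions.tsv
```

which reports `12 cases: 1 MSI, 9 CIN_H, 2 CIN_L, 0 not evaluable` and
writes per-tumour profiles:

```
tumour_id  n_informative  n_AI  ai_ratio  cin_class
GC001      19             12    0.6316    CIN_H
GC004      0              0               not_evaluated_MSI
GC005      19             2     0.1053    CIN_L
GC010      19             5     0.2632    CIN_H
```

GC004 was gated out by the MSI screen (step 1) and never scored for AI.
GC005 has 2 of 19 informative markers with AI (ratio 0.11 < 0.2 → CIN-L);
GC010 sits just above the cut-off (0.26 ≥ 0.2 → CIN-H). The calibrated
thresholds table gives, per marker, the number of heterozygous normals, the
quotient count, and the (lower, upper) AI bounds, e.g. D12S1682:
(0.847, 1.180) from 48 heterozygous samples. The region summary lists the
percentage of informative tumours with AI per chromosomal region
(two-marker regions count AI when either marker shows it).

The same operations are available as library functions
(`cinscore.calibrate_markers`, `cinscore.run_two_step`,
`cinscore.profile_sample`, `cinscore.crossing_probability`, ...); see the
module docstrings and `docs/methods.md`.

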