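# Methods

## The analysis model

The pipeline targets single-channel miRNA microarrays that carry, besides
the 1212 miRNA probes, a population of blank spots (features without probe)
whose fluorescence estimates the array's background. All signal processing
is per array and uses only that array's blanks, so arrays scanned at
different gains remain comparable:

1. **Trimmed blank statistics.** Blanks are ranked by intensity and
   `floor(trim_fraction * n)` spots are removed from each tail
   (`trim_fraction` = 0.05). The mean and sample SD (n−1 denominator) of
   the remainder define the detection threshold `mean + 2·SD`. The floor
   rule means fewer than 20 blanks trim nothing; at least 3 blanks must
   survive. These are the conventional readings of an otherwise
   underspecified trimming rule; both constants are configurable
   (`NormalizationConfig`).
2. **Presence call.** A probe is present iff its raw signal strictly
   exceeds the threshold. Presence is monotone in intensity.
3. **Background subtraction** of the trimmed blank mean, applied only to
   present probes (guaranteed positive: present implies signal >
   mean + 2·SD ≥ mean).
4. **Global median normalization** to a target median of 25, computed over
   present probes only. Absent probes are stored as 0 (policy
   `set_zero`; `set_missing` writes NA instead) and never enter the
   median — with 30% of probes absent, including structural zeros would
   make the target unreachable. Even-count medians average the two central
   values.

The whole composition is invariant under rescaling an array by any c > 0,
and the median of the present normalized signals equals the target exactly
(to floating-point tolerance); both properties are tested.

**Screening** works on arithmetic group means over all samples, absent
zeros included — a miRNA absent-called in every patient thereby drags its
case mean toward 0, which is how very low case-group averages arise. The
control/case ratio of means is the screen's effect measure (the ratio of
means, not the mean of ratios). A case mean of exactly 0 with positive
control mean is reported as an infinite sentinel: it counts in the
down-regulation census at every threshold, but is not eligible for the
signature, which requires a finite, quantifiable fold — an all-absent case
group is a detection failure, not a fold measurement. 0/0 is undefined and
excluded from all ratio statistics. The census keeps the full probe count
as denominator; signature selection is restricted to reliably detected
miRNAs, i.e. those passing the display filter (control- or case-group mean
strictly greater than 5). Ratios are printed at two decimals in reports;
comparisons always use full precision. No multiple-testing correction is
applied in the screen — it is descriptive by design.

**qPCR validation** uses single-delta relative quantification against the
U6 reference: `rel = E^-(Ct_target − Ct_U6)` with efficiency E fixed at 2.0
(configurable). No calibrator sample is assumed (so this is ΔCt, not
ΔΔCt); technical replicates are averaged on the Ct scale. Group comparison
is a two-sided Mann–Whitney U test: exact enumeration when the pooled
sample has ≤ 12 observations and no ties, otherwise the normal
approximation with tie and continuity corrections. The reported U is the
smaller of the two U statistics, as most statistics packages print.
Significance is α = 0.05 uncorrected, replicating the study design;
Benjamini–Hochberg is available opt-in. Assays with fewer than two
samples in a group are skipped with a logged warning, which is how
per-assay missingness (mixed n of 9 and 11 in the published correlation
table) is supported.

**Clinical statistics** are computed within the patient group only, since
the severity instruments (FIQ 0–100; MFI subscales 0–20) are informative
there. Spearman's rho uses midranks; its p-value is exact by full
permutation for n ≤ 9 and the t approximation above that. Correlation
cells use pairwise-complete deletion and report their own n; cells with
fewer than 3 pairs or a constant vector are flagged not computable rather
than erroring the batch. The published correlation table contains several
rho/p pairs that are mutually inconsistent under any standard Spearman
inference (e.g. rho = −0.76 with p = 0.63 at n = 9); this pipeline computes
standard p-values and makes no attempt to match those cells. The
outlier-patient report flags the case sample with the lowest mental-fatigue
score (ties broken by sample id, logged) and compares its signature-miRNA
levels against the case-group maximum and the lowest control level.

## The synthetic-cohort generator

The generator's defaults are the study conditions: 11 patients vs 10
controls, 1212 probes and 100 blanks per array, a five-miRNA signature
implanted at folds {6.31, 13.47, 11.62, 11.15, 10.39} with control-group
levels anchored at the published normalized averages, three mild comparison
miRNAs at {3.88, 1.15, 1.36}, a broad slab of 20% of miRNAs downregulated
2–4.5-fold (log-uniform; ~3% of all probes land at ≥ 4-fold, matching the
published census structure), 30% absent probes, patient clinical scores at
FIQ 74.11±13.32, GF 18.64±1.63, PF 17.64±1.50, MF 14.27±2.90 (RA, RM and
all control-group scores are unpublished; plausible values are used),
scores truncated to their instrument ranges by resampling and MFI subscales
rounded to integers, and small-RNA mass fractions at 14.0±3.4% (controls)
vs 16.1±10.2% (patients). One seed drives all randomness; cohorts are
reproducible field for field.

Design choices worth knowing about, all adopted so that the generator's
stated recovery properties actually hold and all configurable:

- **Additive background.** Spot intensity is signal plus a nonspecific
  background drawn from the blank distribution (log-normal, mean 10), the
  whole spot scaled by a per-array gain (log-normal, SD 0.25). Blank-mean
  subtraction therefore recovers the signal without bias; in the
  zero-noise limit the pipeline returns the implanted folds exactly (a
  tested closed-form limit). Modeling intensity as pure signal instead
  would make background subtraction remove fluorescence the signal never
  contained and systematically inflate the measured fold of
  near-background probes.
- **Below-median broad downregulation.** Median normalization is
  compositional: if the downregulated 20% straddled the array median, the
  case arrays' medians would drop and every recovered ratio would be
  biased low by that factor. The broad slab is therefore implanted in
  probes below the baseline median (biologically: the broadly suppressed
  species are the low-abundance ones), which leaves the present-probe
  median invariant by order statistics and the recovered ratios unbiased.
- **Detectability floor and attenuated absent class.** Expressed baselines
  are truncated below 300 (30× background); species below detection belong
  to the explicit absent class, which has zero signal and background
  attenuated by 0.7 so it stays sub-threshold with high probability while
  the presence boundary remains stochastic. Without the attenuation,
  ~5% of absent measurements per sample would cross the threshold and the
  cohort would sprout dozens of spurious infinite ratios.
- **Noise scale.** Per-measurement multiplicative noise defaults to 5%
  (log-scale SD 0.05), the order of technical replicate variability for
  this array class. This is deliberate: the weakest signature member
  (6.31-fold) sits only 5% above the 6-fold selection threshold, so the
  default conditions are calibrated for the screen to re-identify the
  implanted set reliably. The generator does **not** model inter-subject
  biological spread, PBMC composition differences, probe-specific
  hybridization efficiency or scanner saturation — so a passing recovery
  test demonstrates correctness of the pipeline arithmetic under the
  stated model, not robustness of the biomarkers in real cohorts.
- **qPCR.** Ct values derive from the same per-sample true expression as
  the arrays: `Ct = Ct_ref + 5 − log2(expr/baseline) + ε`, with the U6
  reference at 20±0.5 cycles and ε at 0.8 cycles SD — typical
  between-subject RT-qPCR variability, under which a 1.15-fold shift
  (0.2 cycles) behaves as a negative control while a 6.3-fold shift
  (2.66 cycles) is detected with power ≈ 1 at n = 11 vs 10. Because the
  noise is uniform across assays, a ~4-fold shift is also usually
  significant here, whereas real studies can lose such intermediate
  effects to assay-specific variability.

## Numerical and interface choices

- Delimiters are sniffed from the header (tab or comma); writers emit
  tabs; missing values are the explicit token `NA`.
- Blank spots are identified by the `spot_class` column, never by probe-id
  pattern matching.
- Parsing never drops rows silently: every data row becomes a record or a
  validation error naming the 1-based row.
- Signature members sort by descending ratio with ties broken by miRNA id;
  all tie handling elsewhere uses midranks.
- The pipeline (`run_all`) is deterministic given inputs and config; a
  failed stage removes the partial outputs it wrote and raises an error
  naming the stage.

## Problem sizes in the shipped checks

The test suite and the acceptance script run full-size cohorts (21 arrays ×
1312 spots) for recovery checks, five such cohorts (105 arrays) for the
normalization-median invariant, 200 random small instances per brute-force
oracle comparison (Mann–Whitney enumeration at pooled n ≤ 12, Spearman
permutation at n ≤ 7, per-array normalization at ≤ 10 probes), and 300–1000
reduced null cohorts (10 probes, 5 blanks, full sample sizes) for the
rejection-rate estimate; these sizes give Monte-Carlo error well inside the
asserted bands while keeping a laptop run in tens of seconds.

## Known limitations

- The blank-spot count and intensity distribution of the real platform are
  unpublished; defaults (100 blanks, log-normal around 10 fluorescence
  units) are assumptions, exposed in `SimulationConfig`.
- Whether the original extraction software stored absent probes as 0 or as
  missing is unknown; `absent_policy` reproduces either.
- The published fold table prints one ratio (11.62) that disagrees in the
  last digit with the quotient of its own printed group means (11.61 at
  two decimals); the table evidently rounded from unrounded means. Checks
  against that table therefore use a one-unit-in-the-last-digit tolerance.
- Quantile/loess normalization, batch correction, moderated-variance
  differential expression and Ct calling from amplification curves are out
  of scope.
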