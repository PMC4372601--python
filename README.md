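# mirsig

Blank-spot-calibrated miRNA microarray analysis for case/control biomarker
discovery, with qPCR validation and clinical-score correlation. The package
implements, as a tested and reusable pipeline, the analysis design used in
PBMC miRNA profiling studies of fibromyalgia (FM): a genome-wide microarray
screen (1212 miRNA probes plus a blank-spot population per array) identifies
a small set of strongly downregulated miRNAs, which is then validated on an
independent RT-qPCR assay and checked for correlation with symptom-severity
scores. A synthetic-cohort generator with known ground truth makes every
stage testable end to end without any external data.

It is aimed at researchers who want to reproduce, stress-test or adapt this
class of fold-change screening analyses — not at re-deriving any biological
claim about FM itself.

## Method

Per array, with blank-spot intensities $b_1,\dots,b_m$:

1. **Trimmed blank statistics.** Rank the blanks, drop the top and bottom 5%
   ($\lfloor 0.05m \rfloor$ per tail), and compute mean $\bar b$ and sample
   SD $s_b$ of the remainder.
2. **Presence call.** Probe $i$ is *present* iff its raw signal
   $x_i > \bar b + 2 s_b$ (strict).
3. **Background subtraction.** For present probes, $y_i = x_i - \bar b$.
4. **Global median normalization.** Rescale so the median present signal is
   25: $\tilde y_i = 25\, y_i / \mathrm{median}(y)$. Absent probes are
   recorded as 0 and never enter the median.

Screening compares arithmetic group means: for each miRNA the control/case
ratio $R = \bar{y}_C / \bar{y}_{FM}$, a census at $R \ge 2$ ("inhibition of
at least 50%") and $R \ge 4$, induction at $\bar y_{FM}/\bar y_C > 1.5$, and
a signature of miRNAs with $R \ge 6$ among reliably detected probes (group
mean > 5). Validation uses single-delta relative quantification against the
U6 reference, $2^{-\Delta C_t}$ with $\Delta C_t = C_t - C_t^{U6}$, compared
between groups with the two-sided Mann–Whitney U test (exact for pooled
n ≤ 12 without ties, tie/continuity-corrected normal approximation
otherwise) at α = 0.05 uncorrected. Clinical association uses Spearman's
rank correlation (midranks; exact permutation p for n ≤ 9) between each
signature miRNA and the FIQ total plus the five MFI fatigue subscales,
within the patient group, with pairwise-complete deletion.

## Worked example

Simulate a cohort (11 FM vs 10 controls, 1212 probes, 100 blanks per array,
an implanted 5-miRNA signature at 6.31–13.47-fold downregulation and a broad
20% slab of 2–4.5-fold downregulated miRNAs) and run the whole pipeline:

```sh
mirsig simulate --out cohort --seed 42
mirsig run-all --scans cohort/scans --sample-sheet cohort/sample_sheet.tsv \
    --qpcr cohort/qpcr.tsv --out out
```

which prints

```
signature (5): hsa-miR-451a, hsa-miR-338-3p, hsa-miR-143-3p, hsa-miR-145-5p, hsa-miR-223-3p
census: 248/1212 miRNAs down >= 2-fold
```

The screen recovered exactly the five implanted biomarkers; 248/1212 ≈ 20%
of miRNAs measure ≥ 2-fold down, matching the implanted broad slab.
`out/group_summary.tsv` holds the per-miRNA group means and ratios, e.g.

```
miRNA_ID          control_mean  fm_mean   ratio_c_over_fm
hsa-miR-223-3p    52784.36      8341.88   6.33
hsa-miR-451a      3671.89       279.03    13.16
```

(ratios 6.33 and 13.16 against implanted folds 6.31 and 13.47 — the
per-measurement noise at n = 11 vs 10 leaves a few percent of spread).
`out/validation.tsv` shows the qPCR stage confirming all five signature
members (p ≈ 1e-4 each) while the mildly shifted comparison assays stay
non-significant (hsa-miR-1908-5p p = 0.22, hsa-miR-1260b p = 0.75), and
`out/correlations.tsv` and `out/outlier_report.json` hold the patient-group
score correlations and the lowest-mental-fatigue patient report. Every
stage is also callable as a library function (`normalize_scan`,
`summarize_groups`, `select_signature`, `validate_mirnas`,
`correlate_clinical`, ...) or as separate subcommands (`normalize`,
`screen`, `qpcr`, `correlate`).

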