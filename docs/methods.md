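# Methods

## The signal and the model

Cell-free DNA in a body fluid from a patient with malignancy is a
mixture: a fraction *f* (the tumor fraction) derives from the malignant
clone, the rest from diploid host cells. Over a genomic region where the
clone carries *p* copies instead of 2, the expected copy number of the
mixture is

    c(f, p) = 2(1 − f) + f·p,

so the expected log2 depth ratio against a diploid reference is
log2(c/2). Inverting this relation for an observed segment mean *r*
under an assumed ploidy gives the tumor-fraction estimator

    f̂ = (1 − 2^r) / (1 − p/2),

clamped to [0, 1]. Gains are assumed trisomic (p = 3) and losses
monosomic (p = 1) — a single-copy-change assumption; a double-copy event
would be reported at roughly double its true fraction (see
Limitations). The sample-level tumor fraction is the maximum event
fraction, on the rationale that the largest consistent deviation tracks
the dominant clone.

## Pipeline

Per specimen, counts over fixed 0-based half-open bins are processed as:

1. **QC.** Specimens whose total read count falls below a floor are
   flagged and not interpreted. The floor defaults to 6% of the
   reference specimen's total, the ratio of a 450,000-read minimum to a
   7.6M-read cohort median; an absolute `min_reads` can override it.
2. **Normalization.** `r_b = log2((s_b/S)/(ref_b/R))` against a single
   healthy reference. S and R are totals over unmasked *autosomal* bins
   only, because sex-chromosome content differs by sex and sex is not
   modeled (normalizing one genome against a single reference of fixed
   sex). Masked bins and bins with zero sample or reference coverage
   become missing (NaN), never 0-filled.
3. **GC correction** (optional, on by default). A rolling-median trend
   of log2 ratio versus GC, fitted on unmasked autosomal non-noise bins
   (window: 10% of fit bins, minimum 31, forced odd) and interpolated at
   each bin's GC, is subtracted. If fewer than 80% of unmasked bins
   carry GC, the step is skipped with a warning.
4. **Centering.** The median over unmasked autosomal bins *excluding the
   noise chromosome* is subtracted, so the diploid majority defines
   zero and a noisy chr19 cannot shift the baseline. Median centering
   assumes more than half the baseline genome is copy-neutral.
5. **Segmentation.** Circular binary segmentation per chromosome (below).
6. **Calling and tumor fraction.** The interpretation rule (below)
   yields called CNVs, a positivity flag, a capped count rendered
   "0".."4"/"5+", and the tumor-fraction estimate.

## Circular binary segmentation

Each chromosome's unmasked bins are treated as an independent series
(no cross-chromosome segments). The scan statistic is the two-sample t
between an arc `x[i:j]` and its complement on the circularized series;
scanning all 0 ≤ i < j ≤ n with the complement covers wrapping arcs.
Pooled within-group variance is used (df = n − 2); an arc with zero
pooled variance but unequal means scores +inf. Ties in the maximum break
toward the leftmost start, then the shortest arc, making the scan
deterministic.

Significance is assessed by permutation: the observed maximum is
compared with the maxima of seeded random permutations of the window,
p = (e + 1)/(N + 1). Evaluation stops early once the exceedance count
can no longer come in under alpha (each permutation row also
short-circuits at its first qualifying arc). If the split is accepted,
both interior breakpoints are cut and the sub-windows are re-tested
recursively.

A final merge pass undoes weak boundaries: adjacent segments are merged
while |Δmean| < 3 × s_p / sqrt(n_h), with s_p the pooled within-segment
SD of their bins and n_h the harmonic mean of the two bin counts — a
pruning rule in the spirit of classical CBS "undo" heuristics, not a
reimplementation of any specific one.

Defaults are alpha = 0.01 with n_perm = 10,000 on the `cbs_segment`
surface, matching common CBS practice. The packaged per-sample pipeline
(`PipelineParams`) uses n_perm = 1,000 — a p-value resolution of 0.001
against alpha = 0.01, which leaves the accept/reject decision essentially
unchanged while keeping a full cohort run fast.

## Interpretation rule

A segment is called a CNV iff all of:

* autosomal, and not on the noise chromosome;
* size (end − start) strictly greater than `min_size` — 10 Mbp at real
  scale, 20 kb after desk scaling;
* |mean log2| ≥ max(`abs_floor`, k·MAD/√n_bins), defaults
  `abs_floor` = 0.1 and k = 3. The published criterion — at least one
  *significant* CNV judged against background noise — was a human
  reader's call; this is our reproducible surrogate. The per-bin noise
  MAD is divided by √n_bins to put it on the scale of a segment mean
  (a per-bin threshold of 3 MAD would be uncrossable for real low-f
  events whose segment means are known far more precisely than any
  single bin); both knobs are exposed.
* abrupt, not gradual: on each side the segment either abuts a
  chromosome end or differs from its neighbour's mean by at least
  `abs_floor`. A monotone staircase (slow waviness, e.g. residual GC or
  batch trend) is thereby excluded wholesale, while an isolated event
  flanked by baseline passes on both sides.

The noise metric is the scaled MAD (×1.4826) of the noise chromosome's
bin ratios about their median — chr19 is GC-rich and consistently the
noisiest autosome, making it a usable per-sample noise gauge precisely
because it is excluded from calling. With fewer than 10 usable noise
bins the metric falls back to the genome-wide MAD of residuals about
per-chromosome medians (logged, not an error).

## Synthetic cohorts

The generator emulates what the real assay yields *after* alignment,
deduplication and binning; no read-level simulation. Study conditions
are encoded in the defaults:

| parameter | default | why |
|---|---|---|
| genome | hg38/500, 1 kb bins (≈6,200 bins, ≈5,800 autosomal) | preserves relative chromosome sizes; matches the ~5–6k bins of the real assay |
| `mean_reads_per_bin` | 1,500 | ≈8.7M reads genome-wide, the scale of the 7.6M-read cohort median |
| `dispersion` (NB size) | 600 | per-bin log2-ratio noise ≈0.10 after dividing by a same-depth reference — typical shallow-WGS scatter; ∞ degenerates to Poisson |
| `noise_chr_extra_sd` | 2 (cohort presets) | chr19 count CV doubled by re-parameterizing the NB size per bin, so its log2 MAD is ≈2× the genome's |
| GC bias | quadratic multiplier peaking at GC 0.45, floor 0.7 reached at ±0.2 | a correctable ~30% depth swing across the occupied GC range; applied to fluid samples, not to the reference, so the correction step has work to do |
| per-bin GC | clipped normal(0.41, 0.05); noise chromosome +0.07 | genome-average GC with a GC-rich chr19 analogue |
| case-control preset | 36 malignant + 59 infectious controls | the published case-control design; positive tumor fractions resampled from the 19 published nonzero values (0.056–0.96), 1–6 clonal events of 20–75 Mbp weighted toward high event counts as in the published table |

All randomness flows from explicit integer seeds; identical seeds give
identical cohorts. What the simulator does **not** model: multi-clone
mixtures (one dominant clone per specimen, as the published cases
show), focal amplifications beyond integer ploidies, mappability and
repeat structure, within-cohort batch effects, microbial reads, or
fragment-length signal. Passing the synthetic recovery tests therefore
demonstrates that the estimator and decision rule are correct for the
depth model — not that the assay performs identically on real fluids,
whose printed cohort statistics enter only through their counts.

## Numerical choices

* Trailing partial bins are kept but masked when narrower than 25% of
  the bin width, so no genome is lost and no tiny bin drives a call.
* Bins >50% ambiguous sequence are masked at GC annotation.
* Zero-variance windows: a constant window scores t² = 0 (no split); a
  noiseless step scores +inf and the permutation test still decides, so
  degenerate inputs cannot force a split.
* Segments are defined over unmasked bin indices; coordinates come from
  the flanking retained bins, never interpolated across gaps.
* Quartiles are type-7 (linear interpolation); the IQR convention of the
  published summaries is unstated, so tests pin medians only. The
  published "median 30% (IQR 1.4–56%)" for the 29 cytology-negative
  cases does not equal the plain median (26%) of the printed per-sample
  column under standard conventions; we surface this and do not encode
  it as an expected value. The 32% median of the 19 nonzero printed
  values does reproduce and is pinned.
* Display percentages round half away from zero, matching the printed
  values (88.9→89, 65.5→66, 86.1→86).
* Clopper–Pearson intervals use scipy beta quantiles with the exact
  closed forms at x = 0 and x = n.

## Problem sizes

The test suite and acceptance script run everything at desk scale:
parameter recovery uses 50 replicates per tumor fraction (25 in the
acceptance script) at ≈6,200 bins; segmentation oracle equivalence
sweeps every noiseless single-step series up to length 60 against an
independent exhaustive search; breakpoint localization uses 100 noisy
replicates; interval coverage uses 10,000 binomial draws.

## Limitations

* The positivity surrogate (k·MAD/√n with an absolute floor) encodes
  the published criterion's intent, not the blinded human reader; real
  read-outs also weighed plot morphology that has no algorithmic
  counterpart here.
* Tumor fractions are biased for events violating the single-copy
  assumption (e.g. homozygous deletions, high-level amplifications).
* One reference specimen, as in the published design: reference noise
  propagates into every profile rather than averaging out as a pooled
  reference would.
* Whole-genome doubling and CNVs covering more than half the baseline
  genome would defeat median centering.
* The desk-scale genome divides coordinates by 500; rules stated in
  physical units scale with it, but bin-count granularity near the
  10 Mbp boundary is coarser than at real scale.
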