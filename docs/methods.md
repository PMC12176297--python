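# Methods

This note records the models, conventions and parameter choices behind
each pipeline, and what the synthetic generators do and do not emulate.

## 3D focus counting (`xiquant.foci`)

**Nucleus segmentation.** The DAPI channel is processed slice by slice:
Gaussian blur (`blur_sigma_px = 2` laterally), Otsu threshold, and
morphological hole filling per slice; the per-slice masks are then linked
into 3D objects by connected components (26-connectivity by default).
Objects smaller than `min_nucleus_volume_vox = 500` voxels or touching
the lateral (XY) image border are discarded — border nuclei are
truncated and would bias per-nucleus counts.

Each slice's Otsu threshold is floored at the Otsu threshold of the whole
DAPI volume. Without the floor, a slice containing only background noise
has a threshold inside the noise distribution, marking roughly half of
the slice as foreground and welding all nuclei into one border-touching
component. A genuinely constant slice is a degenerate histogram; its
threshold equals the single value and the slice contributes no
foreground.

**Otsu threshold.** Implemented directly on the histogram: the threshold
maximizes the between-class variance `w0 * w1 * (mu0 - mu1)^2` over all
cut points, with foreground defined as intensity strictly greater than
the threshold. Ties resolve to the lowest maximizing value; a
single-valued histogram yields that value (empty foreground). The
implementation is cross-checked in the tests against an exhaustive scan
and against `skimage.filters.threshold_otsu`.

**Focus segmentation and assignment.** The FISH channel is thresholded
once over the full 3D volume (`fish_threshold_mode = "global"`); a
per-slice mode exists but the global default is appropriate because
focus brightness does not vary systematically with z the way nuclear
staining does. Components of at least `min_focus_volume_vox = 2` voxels
become foci. Each focus is assigned to the nucleus with which it shares
the most voxels (ties to the smaller nucleus label; zero overlap leaves
it `unassigned`); a centroid-containment rule is available as an option.

**Summaries.** Per nucleus: focus count, total focus volume, integrated
intensity, and mean nearest-neighbour distance between focus centroids.
All physical quantities honour anisotropic voxel spacing `(dz, dy, dx)`,
default `(0.2, 0.1, 0.1)` µm — a 0.2 µm z-step with 0.1 µm pixels.

## FRAP fitting (`xiquant.frap`)

Traces are background-subtracted (when a background series is supplied)
and normalized once to a pre-bleach mean of 1. The post-bleach segment is
fit by least squares to the single-exponential recovery

```
F(t) = F_inf - (F_inf - F0) * exp(-k * (t - t_bleach))
```

with time measured from the first post-bleach frame. Reported kinetics
are `t_half = ln 2 / k` and the immobile fraction
`(1 - F_inf) / (1 - F0)`, clipped to [0, 1] — the fitted-plateau
definition, which uses all points rather than the last frame alone.
Initialization is deterministic (F0 from the first post-bleach point,
F_inf from the tail mean, k from a log-linear fit of the residual
decay), so fits are reproducible; non-convergence is flagged on the
result instead of silently replaced. Condition summaries report
per-cell means and SDs and a point-wise mean ± SD recovery curve;
traces on ragged time grids are linearly resampled onto the first
trace's grid and the count of resampled traces is recorded.

## Allele-specific analysis (`xiquant.allelic`)

Counts are per-SNP `a`/`b` haplotype totals (positions 1-based). The
filters mirror standard allele-specific practice:

1. **SNP validation (DNA library):** drop SNPs with a zero count on
   either allele, then compute per-SNP bias `a / (a + b)` on the
   remaining set and drop SNPs deviating from the mean bias by more than
   one standard deviation (sample SD, `ddof = 1`; with two conventions
   differing only in `ddof`, the filtering outcome is identical for any
   realistic input, and the strict inequality keeps exact-boundary SNPs).
2. **Gene aggregation:** retained SNP counts are summed per gene;
   unmapped SNPs are tallied and excluded.
3. **Coverage filters:** expression/accessibility tables keep genes with
   total count strictly greater than 10; antibody-directed (CUT&RUN
   style) tables are first corrected by subtracting the IgG library's
   per-gene allele counts (missing IgG genes count as zero), requiring
   both corrected counts non-negative and a corrected total strictly
   greater than 5.
4. **Ratios:** a gene enters the replicate-averaged ratio table only if
   it passes the coverage filter in every replicate; averages are taken
   on proportions `a / (a + b)` (the odds form `a / b` is reported but
   can be infinite and is flagged, not averaged).

**Reactivation screen.** Replicate counts are pooled within each
condition; for each gene the 2×2 table (allele × condition) is tested
with a two-sided conditional exact test (Fisher), the effect is the log2
fold-change of the a:b odds with a 0.5 pseudocount on every cell, and
Benjamini–Hochberg FDR is computed across tested genes. By default the
screen is restricted to chrX genes via a supplied gene→chromosome map.
On simulated data the screen shows ≤ 5% positives at FDR 0.05 under the
null and ≥ 90% sensitivity for a planted skew shift from 0.95 to 0.6.

## k-mer enrichment (`xiquant.kmers`)

Overlapping k-mers are counted on the given strand only (the analysis
targets RNA-side motifs, where the transcribed strand is the relevant
one). Windows containing non-ACGT characters are skipped and tallied.
The enrichment score is the log2 ratio of pseudocounted,
position-normalized frequencies:

```
score = log2( (c_exp + p) / (N_exp + p * 4^k)
            / ((c_ctrl + p) / (N_ctrl + p * 4^k)) )
```

where `N` is the total number of counted windows and `p = 1` by default.
Normalizing by windows (positions) rather than by sequences makes the
score robust to unequal sequence lengths between sets; the score is
antisymmetric under swapping the sets and finite for any input. Hexamers
(`k = 6`) are the default; rankings are concordant for k from 5 to 8 on
planted-motif data.

## Statistics (`xiquant.stats`)

**Superplots.** Per-cell values are summarized at the biological-
replicate level: the group location is the mean of replicate means
(invariant to within-replicate duplication of cells) and the spread is
the SD across replicate means.

**ANOVA/Tukey.** Group comparisons use a one-way ANOVA over per-cell
values followed by all-pairs Tukey HSD. Per-cell ANOVA is the default
(rather than ANOVA on replicate means) because focus-count comparisons
are conventionally reported per cell; the superplot summary provides the
replicate-level complement. A `bonferroni_tukey_p` column multiplies the
Tukey p-values by the number of pairwise comparisons (capped at 1). The
combination is statistically redundant — Tukey HSD already controls the
family-wise error rate — so both columns are emitted, clearly labelled.

**Percent-positive.** Binary per-cell calls are aggregated to replicate
percentages and compared with an unpaired two-sided t-test on the
replicate percentages (Welch by default).

**Fold change.** Ratio of means with a seeded bootstrap percentile
confidence interval (10,000 resamples, 95% by default).

## Synthetic generators (`xiquant.simulate`)

### Image stacks

Each stack is 64×256×256 voxels at `(0.2, 0.1, 0.1)` µm with two
channels. Nuclei are random ellipsoids (semi-axes 3.0–4.0 µm) placed
without overlap and clear of the XY border; the DAPI channel is the
blurred, filled ellipsoid. XIST transcripts are point puncta: a fraction
`dispersed_fraction` is scattered uniformly through the nucleus and the
rest concentrates in a compact territory (radius 0.35 µm) — the XIST
cloud. The FISH channel renders each punctum as a 3D Gaussian
(`psf_sigma = (0.12, 0.16)` µm axial/lateral at amplitude
`photon_scale = 3000`), sums overlaps, applies Poisson photon noise plus
Gaussian read noise over a constant background, and clips at a 12-bit
full well (4095).

**Ground truth.** A "resolvable focus" is a single-linkage cluster of
puncta at cutoff `2 * psf_sigma_lateral`: puncta closer than twice the
lateral PSF sigma cannot be separated after blurring and count as one
focus. The cluster count per nucleus is the ground-truth focus number.

**Operating regime.** The defaults model a realistic single-molecule
FISH acquisition in which the detector, not the display range, limits
bright features, and they keep the image consistent with the geometric
truth definition:

- *Saturating gain* (`photon_scale` near the full well): the dense
  territory sums tens of transcripts and saturates, so its voxels and
  those of isolated single transcripts fall in the same (clipped)
  intensity class. With low gain instead, Otsu splits the histogram
  between the very bright cloud and everything else, and dispersed
  single transcripts drop below threshold — the pipeline would
  undercount exactly the phenotype of interest.
- *Near-isotropic PSF*: the truth cutoff is lateral; a strongly
  elongated axial PSF would merge in z what the lateral rule calls
  resolvable.
- *Compact territory*: at radius 0.35 µm the cloud's transcript density
  is high enough that it forms exactly one truth cluster and one image
  blob; a looser cloud sheds geometric "stragglers" that the saturated
  image cannot separate.

The generators do **not** emulate optical aberrations, chromatic shift,
uneven illumination, autofluorescence, nuclear texture, or segmentation-
confounding nuclear shapes; they are designed to validate the counting
logic, not to benchmark segmentation robustness.

**Presets.** `wt` uses `dispersed_fraction = 0.05`. `depleted` raises
only the dispersed fraction, calibrated by bisection (common random
numbers, fixed internal seed, 400 nuclei) so that the depleted
ground-truth mean resolvable count is 2.0× the wild-type's; the
calibrated value is ≈ 0.124 and the calibration is cached per process.

### FRAP traces

The closed-form recovery model above with wild-type defaults
`t_half = 2.58 s`, immobile fraction 0.18, bleach depth `F0 = 0.2`, and
the acquisition protocol of 10 pre-bleach frames, 65 ms frame interval,
30 s of post-bleach imaging; Gaussian noise (SD 0.03) is added to the
normalized intensities.

### Allele tables

A gene catalog of autosomal (`p_a = 0.5`), Xi-silenced (`p_a = 0.95`)
and escape (`p_a = 0.5`) genes, three SNPs per gene. Per-library totals
are negative-binomial (mean 200, dispersion 0.3) split binomially
between alleles at the gene's proportion. The DNA validation table draws
at proportion 0.5 except for a small planted set of technically biased
SNPs shifted by 5 binomial SDs. Reactivation data re-draws a chosen set
of Xi genes at `p_a = 0.6` in the treated condition.

### Sequences

Uniform-random ACGT sequences; an exact `round(fraction * n)` subset of
the experimental set has one motif copy overwritten at a random
position.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical outputs.
- Sample standard deviations use `ddof = 1` throughout (replicate SDs,
  SNP bias filter); point-wise curve SDs likewise.
- Strict inequalities at filter boundaries: gene total must exceed 10
  (a total of exactly 10 is removed), corrected CUT&RUN total must
  exceed 5, and SNPs exactly one SD from the mean bias are kept.
- Standard numerical steps are delegated to established libraries
  (scipy `curve_fit`, `fisher_exact`, `f_oneway`, `tukey_hsd`, ndimage
  labeling/filling, statsmodels `multipletests`, Bio.SeqIO, tifffile);
  the study-specific logic above is implemented here and tested against
  independent oracles.
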