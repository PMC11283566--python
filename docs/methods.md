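# Methods notes

This document records the modelling assumptions, default parameters, and
numerical choices behind `rhizoactive`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Activity classification

**Model.** The 16S rRNA : rRNA gene count ratio is used as a per-sample,
per-taxon proxy for metabolic activity.  Ratios are computed on rarefied
integer counts of both libraries at equal depth, so the ratio is a pure
count ratio with no further normalization.  A cell is active when
`cDNA > 0` and `cDNA/DNA >= ratio_threshold`; the tie at exactly the
threshold counts as active.  After classification, the *DNA* counts of
active cells (not the cDNA counts) carry forward to all ecology, because
per-taxon transcription rates vary too much for cDNA counts to be
comparable abundances.

**Parameters.**

| parameter | default | meaning / rationale |
|---|---|---|
| `depth` | 15,000 reads | rarefaction depth; samples below it are dropped and logged |
| `ratio_threshold` | 1.0 | activity cutoff; published analyses use 0.5–2, with 5 regarded as overly conservative; exposed for sensitivity analysis |
| `phantom_prevalence` | 0.05 | fraction of samples above which a taxon's phantom detections are rescued |
| `prevalence_mode` | `"phantom"` | prevalence counts phantom cells (cDNA>0, DNA=0); `"cdna"` counts any cDNA detection (the wording "detected in >5% of samples" admits either reading) |

**Phantom handling.** A phantom detection (cDNA without DNA) can be a real
low-abundance active organism that the DNA library missed, or cDNA noise.
Taxa whose phantom detections recur in more than `phantom_prevalence` of
samples get those cells recoded `DNA := 1` (the smallest defensible count)
and are treated as active; isolated phantom cells are excluded.  Phantom
prevalence is computed globally over all retained (post-rarefaction)
samples; a per-group computation is possible by subsetting before
classification.  The `DNA := 1` substitution happens after rarefaction, on
the rarefied table, which is why active-table row sums vary across samples.

**Degenerate inputs.** A sample observing no taxa reports a missing
percent-active rather than 0.  The classifier distinguishes
`INACTIVE` (DNA > 0, cDNA = 0) from `UNDETECTED` (both zero) because the
heatmap coding needs the distinction (0 vs NA).

## Rarefaction

Subsampling without replacement is drawn from the multivariate
hypergeometric distribution, so each retained row sums exactly to the
requested depth and per-taxon relative abundances are unbiased (verified
against the closed-form hypergeometric expectation and by a 1,000-resample
3-SE check).  Richness is reported as the mean observed-taxon count over
100 re-samples by default.

## Decontamination

The prevalence screen builds, per taxon, the 2x2 presence/absence table
(detected vs not x negative control vs biological sample) and computes a
one-sided Fisher exact p-value for over-representation in controls;
presence means count > 0 with no normalization.  A taxon is flagged when
p < alpha (default 0.05) **and** its control prevalence exceeds its sample
prevalence.  The Fisher test was chosen over a composite score because it
is transparent, directional, and exactly testable by hypergeometric
enumeration.  Frequency-based (DNA-concentration regression) scoring is out
of scope.  Organelle lineages matching "Mitochondria" or "Chloroplast" are
removed regardless of the test when a taxonomy is supplied.

## Community ecology

**Bray-Curtis** follows `1 - 2*sum(min)/sum(total)`; a pair of all-zero
samples is defined as distance 0 with a warning (such samples should
normally be dropped upstream).

**PCoA** double-centers `-D^2/2` and eigendecomposes.  Negative eigenvalues
(expected for non-Euclidean dissimilarities) are reported and their axes
excluded; percent variance is taken over positive eigenvalues only.  The
full imaginary-axis correction is out of scope; the dropped negative mass
is exposed so its magnitude can be checked.

**PERMANOVA** partitions the Gower-centered matrix by sequential (Type I)
sums of squares with user-controlled term order — the classical behaviour
of distance-based multivariate ANOVA — using projection hat matrices, which
are computed once per design and reused across permutations.  p-values use
the `(b+1)/(B+1)` estimator (default B = 999) under free row permutation;
an exact mode enumerates all n! orders for n <= 9.  Term order matters for
unbalanced designs and is deliberately explicit in the API.  Aliased
(rank-deficient) terms raise rather than silently absorbing each other.

**PERMDISP** embeds samples by PCoA (positive axes), measures distances to
each group's spatial center, and permutes group labels around the one-way
ANOVA F of those distances, recomputing centers per permutation.  The
default center is the geometric median (Weiszfeld iteration, tolerance
1e-10, coincident-point guard); a centroid mode is provided and is the one
cross-checked against an independent implementation.

**Indicator analysis** uses the abundance-based phi coefficient with
group-equalizing weights `w_i = N/(K * n_g(i))`, which reduces to the
point-biserial correlation for equal group sizes.  Candidate target sets
default to singleton groups; proper unions are opt-in and the all-groups
set is never a target.  The permutation null shuffles samples against the
fixed design and tracks the maximum phi over target sets (one-sided, large
phi); BH-FDR is applied across taxa within one run.  Negative "avoider"
associations are reported but never flagged as indicators.

**Baseline similarity** is the mean of `1 - d` to the baseline sample set
(mean rather than median or nearest — exposed as an option since any of the
three is defensible); slopes/intercepts come from ordinary least squares.
DNA-yield trends reuse `linear_fit` on metadata `dna_concentration` vs day.

## Chemometrics

Pipeline order is fixed: presence filter (max across samples >= 500 counts,
inclusive) -> IQR filter (drop features whose IQR is below the 0.25
quantile of all IQRs; the fraction mirrors the common web-tool default) ->
log10 with half-minimum zero replacement -> pareto scaling
(`(x - mean)/sqrt(sd)`).  PLS-DA fits a NIPALS PLS regression on the
one-hot class matrix (2 components by default); VIP is computed from the
weight vectors and per-component explained-Y sums of squares and satisfies
`sum_j VIP_j^2 = p` to machine precision.  The top-VIP heatmap matrix is
log-transformed, divided by the per-feature maximum (intensities are
assumed count-like, >= 1 where detected), and ordered by Ward linkage on
squared Euclidean distances (the "Ward.D" Lance-Williams variant).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a factorial greenhouse drought
study: two crop-legacy soil pools x planted/unplanted x (pre-drought day 0
baseline + drought/watered x days 2-6) x 5 replicate tubes, with paired
DNA/cDNA libraries per sample and extraction negative controls.

Generative model, per sample:

1. a log-normal base composition per soil pool (sigma 0.8 core, sigma 1.0
   soil tilt) gives the heavy rare tail typical of 16S surveys;
2. responder taxa (10% planted, 10% drought, 5% planted-x-drought by
   default) are shifted 2-fold in qualifying samples; the drought shift
   scales with day/max(day) severity unless `drought_severity_scaling` is
   off;
3. per-sample log-normal noise (sigma 0.3) creates replicate variability;
4. cDNA composition is the DNA composition reweighted by latent per-taxon
   activity multipliers `a_t` and renormalized — activity is *defined* into
   the simulation, making classifier truth exact;
5. both libraries are drawn multinomially at negative-binomial depths
   (mean 20,000, dispersion 30), so the rarefaction sample-dropping path is
   exercised by a realistic minority of shallow libraries.

Activity multipliers are bimodal log-normal: half the taxa (the active
fraction) around median 1.75, half (dormant) around median 0.15, both with
sigma 0.4.  The medians are placed so the abundance-weighted mean
multiplier is ~1: because cDNA composition is renormalized, the observable
count ratio for taxon t is `a_t / sum_s(p_s * a_s)`, and centering that
denominator at 1 keeps the ratio-1 threshold meaningfully between the two
modes.  This choice also reproduces the 40-60% per-sample percent-active
range reported for rhizosphere soils.  Phantom taxa (2%) are pinned below
one expected DNA read (relative abundance 0.5/depth) with multiplier 40, so
they surface in cDNA only.  Contaminants appear in 90% of controls and 5%
of samples by default, at ~20 reads' worth of material in samples.

**Not emulated:** sequence-level error (chimeras, denoising artefacts),
taxon-taxon correlations, compositional spurious correlation beyond the
multinomial constraint, phylogenetic structure, and transcription-rate
heterogeneity within the active class.  Passing recovery tests therefore
shows the *procedures* are correct and well-calibrated under their own
assumptions — not that a ratio threshold of 1 is biologically optimal for
any particular soil.

The metabolome generator draws log-normal feature intensities (log10 mean
~ N(4, 0.8), sd ~ U(0.15, 0.45)) for two groups of 7 samples (matching a
typical pooled-replicate design) and shifts 10 of 200 features by 2 log-sd
between groups.

## Problem sizes in tests and the acceptance script

Oracle tests run at hand-checkable sizes (3-6 samples).  Stochastic
checks use 10-50 seeds at the default generator scale (500 taxa, ~220
samples) for recovery metrics, and 200 seeds at reduced scale (12-22
samples, 40-100 taxa, 99 permutations) for type-I calibration — sizes at
which each check completes in seconds while binomial error on a rejection
rate of 0.05 stays within the asserted [0.01, 0.10] band.  The acceptance
script averages classification metrics over 5 simulated studies and uses
499-permutation PERMANOVA/PERMDISP runs.

## Known limitations

- Multi-factor PERMANOVA reports sequential SS only; marginal (Type II/III)
  distance-based partitions are not implemented.
- PERMDISP ignores imaginary PCoA axes (logged magnitude available); for
  strongly non-Euclidean matrices the dispersion estimates are approximate.
- Weighted UniFrac and any phylogeny-aware metric are out of scope (no tree
  handling).
- The BIOM dialect is a minimal HDF5 2.1 reader/writer (ids + CSR matrix);
  rich observation/sample metadata inside BIOM files is not preserved.
- The Fisher-based contaminant screen is not numerically comparable to
  composite prevalence scores from other tools, though it targets the same
  signal.
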