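# rhizoactive

Analysis of the **active** fraction of rhizosphere bacterial communities from
paired 16S rRNA (cDNA) and 16S rRNA gene (DNA) amplicon count tables, plus the
multivariate ecology and metabolomics chemometrics that typically accompany
such studies.

## Who this is for

Microbial ecologists who sequence both the DNA and the RNA (as cDNA) of the
same soil or rhizosphere samples and want to separate metabolically active
taxa from the large dormant background before community analysis — for
example when studying how drought, plant presence, or their interaction
reshapes the *active* rhizobiome rather than the total DNA pool.

## The method

For each sample, both libraries are rarefied to a common depth
(default 15,000 reads).  A taxon *t* in sample *s* is classified from the
count ratio

```
r(s, t) = cDNA(s, t) / DNA(s, t)
```

- **active** when `cDNA > 0` and `r >= 1` (the threshold is configurable;
  ties count as active),
- **inactive** when DNA is detected but the ratio falls short (or cDNA = 0),
- **phantom** when `DNA = 0` but `cDNA > 0`.  Phantom taxa whose phantom
  detections occur in more than 5% of samples have those cells recoded
  `DNA := 1` and are treated as active ("rescued"); all other phantom cells
  are excluded.

The DNA counts of active cells (with the 1-substitution) form the active
community table; because inactive taxa are masked out, its row sums vary
across samples even though the inputs were evenly rarefied.  Downstream,
the package provides:

- prevalence-based contaminant screening against extraction negative
  controls (one-sided Fisher exact test),
- Bray-Curtis dissimilarity, principal coordinates (PCoA), multi-term
  sequential-SS PERMANOVA with free permutation, pairwise post-hoc tests
  with BH correction, and PERMDISP (spatial-median dispersion),
- indicator-taxon analysis via the group-equalized ("r.g.") abundance-based
  phi coefficient with permutation p-values and FDR,
- baseline-similarity regressions over time, Kruskal-Wallis,
  sum-contrast type-III ANOVA, Shapiro-Wilk screening,
- LC-MS feature-table chemometrics: presence and IQR filters, log/pareto
  normalization, PCA, PLS-DA with VIP scores
  (`VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a)`),
  and the top-VIP Ward-ordered heatmap matrix,
- a ground-truthed synthetic generator (`simulate_paired_assay`,
  `simulate_metabolome`) that emulates the factorial greenhouse design
  (soil legacy x planted x drought x day) with latent per-taxon activity
  multipliers, phantom taxa, reagent contaminants, and negative controls.

## Worked example

```python
import rhizoactive as ra

cfg = ra.SimulationConfig(rng_seed=7)
assay, metadata, truth = ra.simulate_paired_assay(cfg)

reports = ra.prevalence_contaminant_test(assay.dna, metadata)
dna = ra.remove_contaminants(assay.dna, reports)
cdna = ra.remove_contaminants(assay.cdna, reports)

real = [s for s in dna.sample_ids if not metadata.loc[s, "is_negative_control"]]
dna_r = ra.rarefy(dna.select_samples(real), depth=15_000, seed=1)
cdna_r = ra.rarefy(cdna.select_samples(real), depth=15_000, seed=2)
common = sorted(set(dna_r.sample_ids) & set(cdna_r.sample_ids))
aligned = ra.pair_assays(dna_r.select_samples(common), cdna_r.select_samples(common))

at = ra.classify_activity(aligned, ra.ActivityParams(depth=15_000))
summary = ra.activity_summary(at)

dm = ra.bray_curtis(at.active_counts.relative_abundance())
res = ra.permanova(dm, metadata.loc[common],
                   ["crop", "planted", "drought"], n_perm=999, seed=3)
```

Output:

```
flagged 5 contaminant taxa
193 samples retained after rarefaction
percent active taxa: mean 41.8%, range 37.1-45.5%
     crop: F= 508.71  R2=0.701  p=0.001
  planted: F=  19.97  R2=0.028  p=0.001
  drought: F=   4.38  R2=0.012  p=0.004
 Residual: F=    nan  R2=0.259  p=nan
```

All 5 injected reagent contaminants are recovered by the prevalence screen;
the share of active taxa per sample sits in the 40-60% range typical of
rhizosphere soils; and the PERMANOVA partition attributes most structure to
the soil/crop pool, with smaller but significant planted and drought terms —
exactly the latent effects the generator planted.

There is also a thin CLI mirroring the modules:

```bash
rhizoactive simulate --seed 7 --out-dir sim/
rhizoactive activity --dna sim/dna.tsv --cdna sim/cdna.tsv \
    --metadata sim/metadata.tsv --depth 15000 --seed 1 --out-dir act/
```

## Layout

```
src/rhizoactive/
  core_io.py         count tables, metadata, pairing, TSV/BIOM I/O, moisture
  synthetic.py       ground-truthed generators
  decontam.py        prevalence contaminant screen
  activity.py        rarefaction + activity classification + heatmap coding
  diversity.py       Bray-Curtis, PCoA, PERMANOVA, PERMDISP, richness
  indicators.py      group-equalized phi, permutation tests, Venn partitions
  stats_dynamics.py  baseline-similarity trends, KW/ANOVA/Shapiro/BH
  chemometrics.py    filters, normalization, PCA, PLS-DA + VIP, heatmap
  cli.py             click subcommands over the above
docs/methods.md      modelling assumptions, defaults, and their rationale
```
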