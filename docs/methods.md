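# Methods

## The analysis model

`plaquesig` implements a screening pipeline for two related bulk RNA-seq
designs in APP transgenic mice:

1. **Whole-cortex progression.** Two strains (Tg2576, TgCRND8) sampled at
   five ages each, transgenic vs wild-type littermates. The question is
   which genes change with genotype at each age, and which track age
   itself.
2. **Plaque-niche vs distal (LCM).** Laser-captured tissue around amyloid
   plaques vs distal non-plaque tissue from the same transgenic cortex
   (12 vs 12 samples at 6 months). The question is which of the
   progression changes are spatially concentrated at the plaque.

The statistical machinery is deliberately classical — the aim is a
faithful, tested implementation of the published screening recipe, not a
modernization of it:

- **Detection**: gene g is detected iff some treatment group (the finest
  design cell, strain × genotype × age × tissue) has ≥ `min_count`
  (default 10) counts in ≥ `group_fraction` (default 0.5, inclusive) of
  its samples. Inclusivity at exactly 50% is asserted by a boundary test.
- **Normalization**: FPKM (1e9 · count / (libsize · length)), then per
  gene a ratio to the mean of a **configured** reference group, with a
  symmetric pseudocount (default 0.01 FPKM) so zeros stay finite in
  log10. The reference group is required configuration rather than a
  hard-coded group because the sensible reference differs by design
  (age-matched wild type for cortex cohorts; distal non-plaque tissue for
  the LCM comparison). All testing and scoring operates on log10 ratios.
- **Screen**: equal-variance two-sample Student's t per gene (two-sided,
  df = n₁+n₂−2), fold change 10^(Δ mean log10). Zero-pooled-variance
  genes report t = 0, p = 1 so uninformative rows cannot become
  significant through division artifacts. The age screen is a plain
  Pearson correlation against age in months; constant genes report ρ = 0
  (logged) since the sample correlation is 0/0 there.
- **Plug-in FDR**: FDR% = min(100, round(100 · N_detected · α / n_sig)),
  rounded half away from zero, 100 when n_sig = 0. This rounding
  convention uniquely reproduces all six printed comparison-level values
  (37, 38, 18, 100, 27% for the Tg2576 ages on 15,857 detected genes and
  15% for the LCM screen on 12,461) from their printed counts, which is
  the evidence that the published FDR was this estimator.
- **Overlap statistics**: exact hypergeometric upper tail P(X ≥ k),
  inclusive of the observed k (the standard over-representation
  convention), computed through log-gamma arithmetic; naive summation of
  binomial products underflows at the magnitudes these screens produce
  (the cross-study overlap is ~2e−56). Pathway annotation uses a
  Bonferroni correction over the tested collection, e = min(1, m·p),
  significant at e < 0.1 (strict). Backgrounds are always explicit
  detected-gene sets; for cross-experiment overlaps, the intersection of
  the two detected universes.
- **Signature scores**: per sample, mean of log10 ratios over the set's
  present genes, with SD taken **across genes within the sample** (the
  error bar describes within-set spread). Log10 rather than linear ratios
  are averaged, matching the scale on which the data are displayed.
- **Threshold signatures** (the disease-associated-microglia style
  definition) use strict inequalities (fold > 1.5, p < 1e−5), as printed.
- **Heatmap ordering**: agglomerative clustering on 1 − Pearson
  correlation with average linkage (configurable). Constant profiles get
  distance 0 to each other and 1 to varying profiles. Leaf order is
  deterministic given the input and is treated as presentation, never as
  an analysis output.

## The cohort simulator

Counts follow a log-linear negative-binomial model:

    mu_gs = lib_s · 2^( b_g + a_g·age_s + t_g·age_s·[TG] + d_g·[plaque] )
    count_gs ~ NB(mean = mu_gs, size = r),  Var = mu + mu²/r

with gene baselines b_g ~ Normal(5, 2) on the log2 scale (median ~32
counts), library factors lib_s lognormal with 0.15 log2-SD, and a single
genome-wide dispersion r (default 10; 20 in the LCM preset, giving
CV ≈ 0.22 at high counts). Each gene belongs to exactly one module:

| module | effect | default size (LCM preset) |
|---|---|---|
| null | none | remainder |
| aging | a_g = 0.12 log2/month (cortex preset) | 100 |
| progressive_tg | t_g = 0.2 log2/month, TG only (~4× by 10 mo) | 296 |
| niche | d_g ~ U(log2 1.5, log2 8) | 21 |
| progressive_and_niche | both t_g and d_g | 46 |

The 296/46/21 split reproduces the proportions of the published
cross-study Venn (342 progression-up, 67 niche-up, 46 shared), so the
nesting of the niche signature inside the progression signature is a
structural property of the generator, exactly realized in its truth sets.
Designs mirror the printed cohorts: TgCRND8 WT n = 6,6,4,5,6 and TG
n = 4,6,3,5,7 at 1.5, 3, 4.5, 6, 10 months; Tg2576 n = 4 per group at
3–15 months; LCM 12 vs 12 at 6 months. Age acts linearly on log2
expression — the simplest monotone model consistent with a progressive,
robust induction. Dispersion and baseline spread are engineering
defaults, not estimates from the real data, which report none.

What the simulator does **not** emulate: read-level data, gene-length
variation (lengths default to 1 kb, so FPKM is a depth normalization),
batch and sex effects (the real cohorts were single-sex and confounded by
design), correlated co-expression within modules, and realistic
heavy-tailed dispersion heterogeneity. Passing recovery tests therefore
demonstrates that the pipeline's inference is correct under its own
assumptions, not that the biological effect sizes are attainable in real
tissue.

## Calibration and recovery experiments

The test suite and the reproduction script run four simulation
experiments, at sizes chosen to keep the whole suite under a minute:

- **Null calibration**: 2,000 genes, zero effects, 12 vs 12, through the
  full count → FPKM → ratio → t path; rejections at p < 0.001 must stay
  within the 95% binomial envelope (≤ 6).
- **Estimator consistency**: 20,000 genes, 10% perturbed 3-fold, plug-in
  FDR within a factor of two of the realized FDR at p < 0.001. This
  cohort is simulated at constant sequencing depth with depth
  normalization skipped: with a large unidirectional perturbed fraction,
  total-count normalization shifts every null gene by ~log10(1.2) and the
  realized FDR would measure that composition bias (a genuine, known
  failure mode of FPKM-style normalization under asymmetric change)
  rather than the estimator. The caveat is worth remembering when
  interpreting the real design, where 10%-scale unidirectional induction
  is plausible in aged transgenics.
- **Recovery**: the default LCM design with both niche modules pinned at
  3-fold, 12,500 genes, five seeds. ≥ 90% of detected niche-truth genes
  must be recovered at p < 0.001 (recovery is measured against detected
  truth genes — genes failing the presence filter are invisible to any
  screen), and the recovered set's overlap with the progression truth set
  must reach p < 1e−10. Observed values are ~99% recovery and overlap
  tails below 1e−48.
- **Realized fold change**: a 3-fold niche module at dispersion 20 yields
  a median realized plaque/distal fold change within [2.5, 3.5].

## Numerical and design choices

- Rounding of FDR and percentages is half-away-from-zero; Python's
  banker's rounding would print 38% where 37.75% is expected to read 38
  but 14.5 as 14.
- Delimiters are auto-detected between tab and comma (ties → tab); gene
  identifiers are case-sensitive everywhere, with case normalization an
  explicit opt-in only during ortholog projection, where mouse/human
  symbol casing conventions differ (Trem2/TREM2).
- Many-to-many ortholog entries expand to all targets then deduplicate;
  set semantics downstream make the expansion lossless.
- Direction ties (a gene significant up at one age and down at another,
  equally often) resolve to up, logged.
- Empty truth modules are omitted from the truth-set collection rather
  than emitted as empty sets; analysis entry points reject empty sets at
  the point of use.
- The `fdr_curve` used for histogram overlays counts passers with p ≤ t
  along its grid; the significance partition itself is strict (p < α).
  For continuous p-values the distinction is immaterial.

## Known limitations

- The plug-in FDR is a point estimate with no uncertainty; at small
  significant counts it is dominated by integer rounding (hence the
  printed 100% cap at 11/15,857).
- The pipeline tests one gene at a time; no moderation or shrinkage is
  applied, so power at n = 3–4 per group (the youngest cortex cells) is
  weak, exactly as in the original screen.
- Pathway content (GeneGo/Ingenuity/KEGG-style collections), human
  network signatures and DAM gene lists are consumed as user-supplied GMT
  files; the package ships none, and the published enrichment p-values
  that depend on unprinted set sizes are reproducible in machinery only.
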