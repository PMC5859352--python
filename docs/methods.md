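# Methods

`epiconcord` implements an integrative transcriptome + promoter-chromatin
analysis for a two-group (control vs SLE) study across three immune cell
types (B cells, T cells, monocytes), together with a planted-truth
simulator that generates every input the analysis consumes. This note
records the statistical models, the defaults and why they were chosen, and
the choices made where the design was genuinely open.

## Promoter quantification

Aligned ChIP reads are filtered on SAM-derived fields — mapping quality
(default `min_mapq = 20`), flag bits (unmapped 0x4, secondary 0x100,
duplicate 0x400 excluded by default), and CIGAR cleanliness (a single
ungapped `<n>M` run; clips and indels rejected) — then extended to 200 bp
at their 3′ end: a `+` read keeps its start, a `−` read keeps its end and
grows upstream, clamped at position 0. Extension is idempotent.

Promoter windows are 1 kb, TSS-centred (`[TSS − 500, TSS + 500)`), strand
ignored. The symmetric convention was chosen over a strand-aware upstream
window so that the promoter analysis and the ±500 bp SNP windows share one
geometry end-to-end; `anchor="upstream"` is available. A read counts in a
window on ≥ 1 bp overlap, and a read spanning two windows counts in both
(no fractional assignment). Counting uses a vectorized searchsorted scheme
over windows sorted by start, exact for any bounded-length window set, and
is oracle-tested against an all-pairs brute force. SNP windows receive
mean per-base depth (summed overlap ÷ window width) instead of counts.

All coordinates are 0-based half-open. Reads travel as BED6 plus optional
flag/CIGAR columns, so a plain BED file also parses.

## Normalization and differential testing

Count matrices are moved to `log2(count + 1)` (pseudocount configurable)
and normalized per cell type by one MA-loess pass against the row-mean
reference: for each sample, the loess trend (span 0.3, one robustifying
iteration) of `M = sample − reference` on `A = (sample + reference)/2` is
subtracted. Samples with zero variance are left unchanged with a warning.
Features with zero counts in every sample are dropped first (logged).

Each feature is tested with an empirical-Bayes moderated t. Per feature:
`logFC = mean(SLE) − mean(control)`, pooled residual variance `s_g²` with
`d_g = n − 2` df. The prior `(d0, s0²)` is estimated by moment matching on
`log s_g²`: the mean and the excess of its variance over the
`trigamma(d_g/2)` sampling noise identify a scaled-inverse-χ² prior, with
the trigamma inverted by Newton iteration. The shrunken variance is
`s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)` and
`t̃ = logFC / (s̃_g·√(1/n1 + 1/n2))` is referred to a t distribution with
`d0 + d_g` df (normal when `d0 = ∞`). The two limits are asserted
numerically: `d0 → 0` reproduces the ordinary pooled t; `d0 → ∞` a
constant-variance z statistic. Features constant across all samples get
`t = 0, p = 1` and a flag.

Gene lists use the unadjusted `p < 0.05` with at least twofold change
(`|logFC| ≥ 1`); Benjamini–Hochberg FDR is computed and reported alongside
but does not gate the lists. BH itself delegates to statsmodels and is
property-tested against the step-up definition.

## PAGE gene-set enrichment

For scores with global mean μ and *population* SD δ, a set of size m
(after intersecting with the scored genes) with mean S_m gets
`Z = (S_m − μ)·√m/δ`, two-sided normal p, and signed enrichment score
`S_m − μ`. Scores default to logFC rather than −log p so the enrichment
sign is the direction of change. Defaults `min_size = 10`,
`max_size = 2000` avoid degenerate Z; unscored set members are dropped,
not imputed. Z is affine-invariant in the scores, and over any partition
of the genes Σ m·(S_m − μ) = 0 — both asserted as properties.

## Promoter states

Control-sample promoter depth (log2 of counts + 1) is trimodal: inactive /
poised / active. Each control sample is fit separately with a
three-component univariate Gaussian mixture by EM (best of 5 seeded
restarts; restart 0 starts from data quantiles; convergence at log-
likelihood gain < 1e-8, max 500 iterations). Components are relabeled
ascending by mean. Component SDs are floored at
`max(1e-6, 1e-3·SD(data))`; a fit that hits the floor is a point-mass
singularity — it is flagged and a non-degenerate restart is preferred even
at lower likelihood. Promoters take the maximum-posterior state per
sample (exact posterior ties break toward the lower-mean class, a
measure-zero convention); the consensus across control samples keeps the
state only when unanimous, otherwise `unclassified`.

Association between baseline state and SLE-related change uses Fisher's
exact test on (state s vs other classified states) × (changed vs not),
where "changed" defaults to moderated-test `p < 0.05` with no fold filter
(the association question concerns any change, not large change; the
thresholds are configurable). The Fisher p sums hypergeometric
probabilities of tables at most as probable as the observed one, computed
in exact integer arithmetic so probability ties need no floating-point
tolerance; the odds ratio is `ad/bc`, Haldane-corrected (+0.5) when a cell
is zero. Every 2×2 test in the package routes through this one function.

## TF target analysis

PWMs are 4×W column-stochastic probability matrices (JASPAR text I/O via
biopython parsing). Scoring uses log2 odds against a uniform background
with pseudocount 0.01 added to probabilities (renormalized) before the
log. A promoter's best match is the maximum windowed score over both
strands; windows containing ambiguous bases are skipped; ties prefer the
forward strand, then the smallest offset. Per PWM, the top-N genes by best
match (default N = 1,300; 300 in the synthetic study where only 2,000
genes exist) form its target set, with boundary ties broken by
lexicographically smaller gene id so sets are deterministic.

Target sets are tested with PAGE. Chromatin-derived scores are first
detrended for promoter GC content — loess residuals of score on GC
fraction, span 0.5, linear fallback below 50 genes — because H3K4me3
signal and motif content both track GC; expression scores run unadjusted
and the result then equals a plain PAGE scan exactly. The adjustment is
required to kill a planted `2·GC` trend to |corr| < 0.05 while preserving
rank order within GC deciles (Spearman ≥ 0.95).

## Integration

PCA runs on centered features with samples as observations. Cross-cell-
type sharing uses direction-stratified 2×2 tables per ordered cell-type
pair — up(A)×up(B) and down(A)×down(B) for the same direction, the mixed
pairings for the opposite direction — each with Fisher OR and p, plus a
geometric-mean OR summary. (The contingency construction behind a single
"x times more likely" summary is underdetermined; this stratified form is
the package's documented interpretation.) Identical lists give an
infinite OR, reported capped at 1e6 and flagged.

The eight-cluster view selects genes with differential `p < 0.01` in ≥ 1
cell type, builds per-gene profiles of mean log2 value per (cell type ×
group) (6 dimensions), row-standardizes them, and runs k-means (k = 8,
20 restarts, fixed seed; Ward linkage available). Labels are renumbered by
descending cluster size. A cluster is called concordant when its mean
SLE − control difference has the same sign **and** magnitude ≥ 0.25
standardized units in all three cell types; the magnitude guard exists
because a bare sign rule lets noise flips mislabel cell-specific clusters
(difference ≈ 0 in the other two cell types) as concordant. RNA and
chromatin clusterings are crossed with Fisher tests and BH FDR over the
k×k grid; RNA-vs-chromatin direction concordance reuses the stratified
2×2 construction within each cell type and reports the fraction of
differential genes with a same-direction significant chromatin change.

## GWAS cross-referencing

SNP tables merge by (chrom, pos): labels union, association p takes the
minimum, first id wins on conflict (logged); the merge is idempotent.
Each SNP maps to the gene with the nearest TSS on its chromosome (exact
ties → lexicographically smaller gene id, flagged; gene-free chromosomes
→ unmapped, reported). Association-p bins are half-open `[lo, hi)` with
default inner edges 1e-8, 1e-5, 1e-3 (last bin closed at 1), so a
boundary p falls in the less-significant bin; the named source sets
(GWAS95 / LD46 / META25) also pass through as their own groups.

Signal near variants is contrasted against background by a label
permutation test: `delta = mean(focal) − mean(background)`, null from
redrawing |focal| ids without replacement (default 2,000 permutations in
the pipeline; 10,000 in the standalone power check),
`p = (1 + #{|null| ≥ |delta|})/(n_perm + 1)`; a Welch t is reported for
reference, the permutation p is primary because gene-level statistics are
heavy-tailed. Four modes: baseline expression and SLE−control expression
change at SNP-nearest genes (focal = nearest genes of the merged set), and
baseline / SLE−control change of window coverage (focal = SNP windows in
the most-significant association bin, background = the remaining SNP
windows, mirroring the binned-coverage comparison). Coverage matrices are
log2-transformed (pseudocount 0.5) and loess-normalized across samples
within each cell type before contrasting. Linkage-disequilibrium
expansion of variants is out of scope; the window half-width is
configurable.

## Synthetic data generator

The generator defines the study conditions; every default is stated here
and fixed.

* **Design**: 3 cell types × (6 control + 6 SLE) per assay; 2,000 genes on
  4 chromosomes of 1.5 Mb with TSSs ≥ 2 kb apart (so 1 kb promoter
  windows never overlap and never clamp).
* **Expression**: negative binomial with variance μ + αμ², α = 0.1
  (typical bulk RNA-seq overdispersion); baseline log2 means N(5, 1.5).
  Planted effects use eight direction archetypes: shared up / shared down
  (±2 log2 units in all three cell types) and up / down specific to each
  cell type. Fractions 0.11 shared + 0.09 cell-specific put ≈ 55% of the
  planted differential genes in the two shared archetypes, matching the
  concordance structure the clustering is meant to recover.
* **ChIP**: per promoter a state from weights (0.4, 0.3, 0.3) and a
  promoter-level log2 depth from N(mean_state, 0.8) with state means
  (2, 5, 8) — about 4 / 32 / 256 reads per promoter per sample, spanning
  the dynamic range of promoter H3K4me3 at moderate sequencing depth with
  ≈ 3 SD separation between classes. Samples add lognormal noise
  (SD 0.3 log2) and draw Poisson read counts; reads are 36 bp (so the
  200 bp extension is consequential), uniform within the promoter window.
  SLE changes of ±2 log2 units hit 15% of promoters with 3× odds in the
  poised class; half the changes are shared across cell types, half
  cell-specific. A 5% decoy fraction of low-mapq, clipped, partly
  secondary/duplicate reads scattered genome-wide makes the SAM-field
  filter consequential.
* **Sequences**: one 1 kb promoter per gene, per-gene GC uniform in
  [0.35, 0.60]; planted PWM consensus occurrences are embedded at random
  offsets (the simulator plants the two most
  information-rich library PWMs — one in shared-up promoters, one in
  chromatin-up promoters — so the TF path has a recoverable, specific
  motif to find). PWM library: 30 matrices, widths 8–14, Dirichlet concentration
  0.5.
* **SNPs**: 143 variants with three overlapping source sets sized 95/46/25
  proportionally. Half are placed within ±2 kb of the TSS of
  higher-expressed shared-down genes (well inside the 10 kb proximity
  definition, and close enough that nearest-TSS mapping recovers the
  anchor despite neighbouring genes); their association p is drawn below
  1e-8, background SNPs log-uniform over (1e-8, 1]. Anchoring to
  higher-baseline downregulated genes makes the baseline contrast positive
  and the differential contrast negative, the joint pattern the analysis
  is designed to detect.
* All randomness flows from one master seed through named substreams
  (CRC32 of the generator name folded into the seed sequence), so
  regenerating one data type does not perturb the others, and a fixed
  seed reproduces every file byte-identically.

**What the simulator does not emulate** — and hence what green tests do
not establish about real data: mappability and alignment artefacts,
GC-dependent sequencing depth (GC affects only sequence composition, not
coverage), fragment-length distributions, gene length and isoform
structure, correlated genes/co-expression modules, linkage disequilibrium
beyond point positions, batch effects, and patient-level covariates.
Recovery results show the estimators are correct and adequately powered
under the assumed generative model, not that the model captures any
particular cohort.

## Pipeline

Stages (simulate, quantify, diffexp, diffchip, page, states, tftargets,
integrate, gwas) run in order, each writing TSVs into its own
subdirectory and registering parameters plus SHA-256 output hashes in
`manifest.json`; reruns of an unchanged config are bit-identical for every
stage. The report step summarizes each results theme (DE counts, top gene
sets, state associations, top PWMs, GWAS contrasts) and marks missing
sections explicitly rather than emitting zeros. The `epiconcord` CLI
exposes `run` plus one subcommand per stage; stage commands rehydrate
upstream results from the run directory so they work standalone.

Default problem sizes were chosen as the smallest that leave every
planted effect comfortably detectable: 2,000 genes give ≈ 400 selected
differential genes for the eight-cluster analysis, ≈ 600 poised promoters
for the state association, and 143 SNPs with ≈ 120 distinct nearest
genes for the GWAS contrasts.

## Known limitations

* The loess span (0.3 for MA normalization, 0.5 for GC detrending) is a
  fixed default; no cross-validation is attempted.
* Hyperparameter estimation for the moderated t assumes a common residual
  df across features (true here by design: no missing values).
* The exact-integer Fisher p is O(min(row sum, column sum)) per table with
  large-integer arithmetic; for tables with margins in the tens of
  thousands a normal approximation would be cheaper — not needed at this
  study size.
* `unclassified` promoters are excluded from state associations rather
  than modelled; with few control samples the unanimity rule is lenient,
  with many it becomes strict.
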