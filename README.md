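# epiconcord

Integrative analysis of gene expression (RNA-seq) and promoter H3K4me3
(ChIP-seq) across immune cell types in a case–control design, built for
studies asking how much of a disease signature — here systemic lupus
erythematosus (SLE) in B cells, T cells and monocytes — is shared between
cell types and between the transcriptome and the chromatin layer, and how
it cross-references with GWAS risk variants.

The package provides, as a library plus a pipeline CLI:

* **Promoter quantification** — SAM-field read filtering (mapq / flag /
  CIGAR), 3′ extension to 200 bp, counting into 1 kb TSS-centred windows,
  and mean-depth coverage of ±500 bp SNP windows.
* **Differential testing** — log2 + MA-loess normalization and an
  empirical-Bayes moderated t: per-gene variances `s_g²` (df `d_g`) are
  shrunk toward a moment-matched prior `(d0, s0²)`,
  `s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)`, and
  `t̃ = logFC/(s̃_g·√(1/n1+1/n2))` gets `d0 + d_g` df. Gene lists use
  ≥ twofold change with p < 0.05; BH FDR is reported alongside.
* **PAGE gene-set enrichment** — `Z = (S_m − μ)√m/δ` against the global
  score distribution, signed enrichment scores, GMT I/O.
* **Promoter states** — per-sample three-component Gaussian mixture on
  log2 depth (inactive / poised / active), unanimous-consensus calls,
  and exact-test association between baseline state and disease change.
* **TF targets** — log2-odds PWM scanning of promoter sequences on both
  strands (JASPAR I/O), top-N best-match target sets, GC detrending of
  chromatin scores, PAGE over target sets.
* **Integration** — PCA, direction-stratified cross-cell-type sharing
  odds, eight-cluster k-means profiles with concordant-cluster calls,
  RNA×ChIP cluster overlap and direction concordance (one oracle-tested
  Fisher exact test behind every 2×2).
* **GWAS cross-referencing** — SNP-set merging, nearest-TSS mapping,
  association-p binning, and permutation contrasts of baseline/differential
  signal near variants.
* **Synthetic data** — a planted-truth simulator (negative-binomial
  expression with shared and cell-specific effects, trimodal promoter
  depth emitted as BED read intervals, promoter FASTA with planted
  motifs, JASPAR PWMs, overlapping SNP sets) that exercises every stage
  end-to-end with recorded ground truth.

## Worked example

Run the full pipeline on the default synthetic study (2,000 genes,
3 cell types, 6 control + 6 SLE samples per assay):

```bash
epiconcord run --outdir run --seed 1
```

or from Python:

```python
from epiconcord import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(outdir="run", seed=1))

for ct, lists in res.rna_de_lists.items():
    print(ct, len(lists["up"]), "up,", len(lists["down"]), "down")
assoc = res.state_assoc["Bcell"].query("direction == 'either'")
print(assoc[["state", "odds_ratio", "pvalue"]].to_string(index=False))
```

which prints (seed 1):

```
Bcell 144 up, 129 down
Monocyte 142 up, 123 down
Tcell 143 up, 127 down
   state  odds_ratio   pvalue
inactive    0.830527 0.223382
  poised    1.935079 0.000070
  active    0.706696 0.032883
```

Reading: each cell type yields ~270 twofold differential genes, and
promoters that start **poised** (intermediate H3K4me3) are about twice as
likely as background to change in disease (OR 1.94, Fisher p = 7 × 10⁻⁵),
while active and inactive promoters are slightly depleted of change —
exactly the planted structure (changes planted at 3× odds in the poised
class). The run directory gains one subfolder per stage
(`differential/`, `states/`, `tftargets/`, `gwas/`, ...), a `report/`
summary, and a `manifest.json` with parameters and SHA-256 output hashes;
rerunning the same config reproduces every hash.

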