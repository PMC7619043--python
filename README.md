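# ocrpipe

Desk-scale analysis of open-chromatin regions (OCRs) mapped by ATAC-seq in
bulk tissue and sorted nuclei, and their intersection with human genetics.
The package reimplements, as a tested and reusable pipeline, the downstream
statistics of a typical fetal-brain open-chromatin study:

1. **Consensus peak reconciliation** — high-confidence OCRs are the pooled
   peak calls (ENCODE-blacklist–excluded) supported by peaks in at least 2
   of 3 biological replicates, with each OCR attributed to NeuN+ and/or
   NeuN− nuclei fractions by overlap.
2. **Matched-region permutation enrichment** — OCR overlap with chromatin
   states is compared against null region sets matched on per-chromosome
   counts and region sizes; an overlap requires >50 % of the peak's bases,
   fold = observed / mean simulated, and one-/two-sided empirical p-values
   use the (r + 1)/(n + 1) convention.
3. **Partitioned SNP-heritability enrichment** — a simplified stratified
   LD-score regression: E[χ²ⱼ] = N Σ_c τ_c ℓ(j,c) + 1 is fit by weighted
   least squares (optionally a two-step feasible GLS over LD blocks), with
   delete-one-block jackknife standard errors. Enrichment is
   fold = (proportion of SNP h² in the annotation) / (proportion of SNPs in
   it); peaks are expanded by 500 bp on each side before SNPs are annotated.
4. **LD-aware SNP prioritization** — SNPs inside unextended OCRs that are
   genome-wide significant (p < 5 × 10⁻⁸) and in strong LD (r² > .8) with
   their locus index SNP, annotated with histone-mark membership, NeuN
   attribution and fetal-brain eQTL evidence (p < 5 × 10⁻⁵, plus r² to each
   implicated transcript's top eQTL).

Real peak calls, annotation maps, GWAS summary statistics and LD panels
plug in as plain BED/TSV files. Because the original sequencing data are
not required, a first-class synthetic-study generator (`ocrpipe.synth`)
produces every input with known ground truth — planted true peaks,
replicate noise, state anchoring, LD-block genotypes, a GWAS architecture
with a chosen heritability enrichment, and planted causal regulatory SNPs —
so that every stage is scored against truth in the test-suite.

## Worked example

```bash
ocrpipe synth --out study/ --seed 1
ocrpipe consensus \
    --replicate study/rep1.bed --replicate study/rep2.bed --replicate study/rep3.bed \
    --pooled study/pooled.bed --blacklist study/blacklist.bed \
    --neun-pos study/neun_pos.bed --neun-neg study/neun_neg.bed \
    --out-dir run/
ocrpipe perm-enrich --target run/high_confidence.bed --states study/states.tsv \
    --genome study/chrom.sizes --n-sim 1000 --seed 1 --out run/enrich.tsv
```

The synthetic study (three 2-Mb chromosomes, 390 true peaks) yields

```
380 high-confidence OCRs
{"both": 273, "neun_pos_only": 47, "neun_neg_only": 41, "neither": 19}
Promoter    fold=18.7    p_over=0.000999
Enhancer    fold=10.4    p_over=0.000999
Quiescent   fold=0.993   p_over=0.58
```

— the consensus stage recovers 97.4 % of the planted true peaks with no
noise peaks admitted, the two chromatin states the generator anchors on
true peaks (Promoter, Enhancer) show large fold enrichments at the
empirical-p floor 1/(n_sim + 1), and unanchored states sit at fold ≈ 1.
Two numbers from the heritability arithmetic are worth knowing by heart:
an annotation holding 3.3 % of SNPs but 23.9 % of SNP heritability is
7.2-fold enriched, and a .05 significance level Bonferroni-corrected over
seven traits is p < .0071.

Library use mirrors the CLI: see `ocrpipe.consensus.high_confidence`,
`ocrpipe.perm_enrich.permutation_enrichment`, `ocrpipe.h2.fit_partitioned`
/ `fold_enrichment`, and `ocrpipe.prioritize.prioritize`. The model and
all defaults are documented in `docs/methods.md`.

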