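# Methods

This note documents the statistical models implemented by `ocrpipe`, the
choices made where the underlying procedures are genuinely open, and what
the synthetic-data generator does and does not emulate.

## Coordinate conventions

All intervals are 0-based half-open `[start, end)` (BED convention)
throughout; merging at `gap=0` joins bookended intervals, matching
bedtools-merge semantics. GWAS and eQTL tables carry 1-based SNP
positions; `pos − 1` is the variant's 0-based coordinate, and a SNP is
"within" an interval iff `start ≤ pos − 1 < end`. Strand is ignored for all
peak operations (ATAC-seq peaks are unstranded) and honoured only when
building gene TSS windows: `[tss − upstream, tss + downstream)` on the +
strand, mirrored to `[tss − downstream, tss + upstream)` on the − strand.
Peak-set overlap means ≥ 1 bp unless the majority (>50 %) rule is
explicitly invoked, which happens only in the permutation-enrichment test.

## Consensus OCR definition

Replicate support is counted DiffBind-style on the merged union of all
replicate peaks: a union interval is "supported" by a replicate if any of
that replicate's peaks overlaps it by ≥ 1 bp (the minimum-overlap choice is
exposed as a parameter since peak-caller conventions differ). The
high-confidence set consists of the *pooled-sample* peaks — not the union
intervals — that (i) do not touch the blacklist and (ii) overlap a
≥ `min_count`-supported union interval; pooled coordinates are retained so
the output is a genuine subset of the pooled call. Attribution to NeuN+ /
NeuN− fractions is by ≥ 1 bp overlap with each fraction's peak set,
yielding a strict partition {both, pos-only, neg-only, neither}.

## Matched-region permutation enrichment

Null sets match the observed peak set exactly in per-chromosome interval
counts and interval lengths; each interval is placed uniformly over its
valid start positions, independently of the others (self-overlap allowed,
no blacklist exclusion — both available as options). An observed overlap
with a chromatin state requires strictly more than half the peak's bases to
intersect the merged state set; by default intersected bases are *summed*
across nearby same-state regions (a peak split across two state segments
counts if the sum exceeds half), with a stricter single-region-maximum mode
available. Enrichment is `fold = observed / mean(simulated)`; when the
simulated mean is zero the fold is reported as NA (observed 0) or +inf
(observed > 0) rather than aborting. Empirical tails include the observed
value (`≥` / `≤`) and add one to numerator and denominator:
`p_over = (#{sim ≥ obs} + 1)/(n_sim + 1)`. The two-sided p adds the
complement of the opposite tail to the relevant one-sided p (over-enriched:
`p_over + 1 − p_under`), is capped at 1, and is defined as 1 when the fold
is exactly 1 or undefined. Simulation is batched with a fixed internal
batch size, so results are bit-reproducible given `(seed, n_sim)`.

## Partitioned SNP-heritability

The estimator fits the stratified LD-score model

E[χ²ⱼ] = N Σ_c τ_c ℓ(j,c) + 1,  ℓ(j,c) = Σ_{k ∈ c, |pos_k − pos_j| ≤ w} r²(j,k),

with the intercept fixed at 1 (a free-intercept option absorbs confounding
inflation). LD is block-diagonal; r² comes from the panel's true block
correlation matrices when available, otherwise from squared sample
correlations of the dosages with the standard small-sample debiasing
`r² − (1 − r²)/(n − 2)`. The default fit is weighted least squares with
weights `1 / max(ℓ_base(j), 1)`; standard errors for τ and for all derived
quantities come from a delete-one-block jackknife over contiguous SNP
blocks (default 20).

Because χ² statistics within an LD block are strongly correlated, the
scalar-weight WLS is unbiased but noisy. `fit_partitioned_gls` therefore
refines it with a two-step feasible GLS: the first-pass τ̂ gives per-SNP
variances σ² = Aτ̂ (clipped at 0), the model-implied block covariance
Cov(χ²) = 2 (Σ ∘ Σ) with Σ = N R diag(σ²) R + R is inverted per block, and
the jackknife deletes whole groups of LD blocks so resampling respects the
dependence. On the default synthetic architecture this roughly halves the
sampling SD of the fold estimate; it is the estimator used by the
acceptance checks.

Enrichment of an annotation is `fold = prop_h² / prop_SNPs`, where
`prop_h²` is the share of Σⱼ Σ_c τ_c 1[j ∈ c] carried by SNPs in the
annotation (clipped at 0 for the ratio) and `prop_SNPs` its SNP share.
Peaks are expanded by 500 bp on each side (and re-merged) before SNP
membership is evaluated. The per-category significance test is the
conditional coefficient Z = τ̂_c / SE_jack(τ̂_c) with a two-tailed normal
p-value; the Bonferroni display threshold for m traits is α/m rounded to
two significant figures (.05 over 7 traits → .0071). This is deliberately a
simplified stratified LD-score regression — block LD, no MAF-stratified
reference weights, no iterative reweighting, no 53-annotation baseline
(the generator's 3 covariate categories exercise the conditioning) — whose
contract is parameter recovery on synthetic architectures, not numeric
replication of the genome-scale published software; the published
software's own enrichment p-value is not reproduced.

## SNP prioritization

Risk loci are reconstructed from summary statistics by greedy distance
clumping: repeatedly take the most significant unassigned genome-wide
significant SNP as index (ties broken leftmost) and absorb all unassigned
significant SNPs within ±500 kb on the same chromosome. This is a stated
deviation from inheriting locus definitions from each source GWAS, which
are not inputs here. r² is the squared Pearson correlation of genotype
dosages from the supplied panel (population choice = panel choice), and the
r² filter is applied per-locus against that locus's index. All cutoffs are
strict inequalities (p < 5 × 10⁻⁸, r² > .8, eQTL p < 5 × 10⁻⁵); OCR
membership uses the unextended intervals (the ±500 bp expansion is a
heritability-regression step only). For each surviving SNP, every
transcript with a sub-threshold eQTL is reported together with the r²
between the SNP and that transcript's top (smallest-p) eQTL SNP; no
reporting cutoff is applied to those r² values. SNPs absent from the panel
cannot be assessed and are excluded with a log entry.

## Synthetic-study generator

Defaults (all configurable): three 2-Mb chromosomes; 400 drawn true peaks
with lognormal lengths (median 250 bp, σ_log 0.3; overlapping draws
discarded, so ~390 realized); three biological replicates observing each
true peak with probability .95 under ±≤50 bp boundary jitter plus 60
uniform noise peaks each; a pooled call with detection .98 and 80 noise
peaks; NeuN labels per true peak (both .70 / pos-only .12 / neg-only .12 /
neither .06) echoing the large shared fraction seen in real fractionated
data; 20 blacklist regions of 1 kb sampled away from true peaks; eight
chromatin states of 150 regions each, of which Promoter (50 %) and Enhancer
(30 %) are anchored covering true peaks and the rest placed uniformly; two
histone marks anchored analogously; 80 genes with random TSS/strand and
5–30 kb bodies; 5 000 SNPs in 50-SNP compound-symmetric LD blocks
(ρ = 0.6) with dosages for 200 individuals obtained by thresholding two
correlated latent Gaussian haplotypes at allele frequencies uniform in
[.1, .9].

GWAS statistics follow the generative model the estimator assumes: per
block, β ~ N(0, diag(Aτ)), z = √N Rβ + ε with ε ~ MVN(0, R), χ² = z². With
GWAS N = 1000 and total h² = 0.4 over 5 000 SNPs the mean χ² is ≈ 2.5,
comparable in signal-to-noise to a well-powered GWAS at genome scale. τ is
solved so the extended-peak annotation carries a target 5-fold share of
heritability given its realized SNP share. Three planted causal SNPs
inside true peaks (one per chromosome) are made index SNPs of their loci
(association p overridden to ~10⁻¹⁵), given a perfect-LD twin in the same
peak and block where available (dosage column duplicated), and written into
the eQTL table as the top eQTL of one or two transcripts; 300 background
eQTL rows with log-uniform p complete the table. A single master seed fans
out through named `numpy.random.SeedSequence` children in fixed order, so
every output is byte-reproducible and adding draws to one stage never
perturbs another.

What the generator does *not* emulate: read-level data (no FASTQ/BAM, no
duplicate or mappability structure), realistic human LD (no MAF/LD/distance
coupling, no inter-block LD), GC or gap content, and real GWAS phenotypes.
Passing tests therefore demonstrate that the set logic, the resampling
test's calibration, and the heritability estimator's parameter recovery are
correct under the stated models — not that the pipeline reproduces any
real-data peak counts or trait enrichments, which require the original
sequencing data and full GWAS reference panels.

## Numerical and testing choices

Interval arithmetic is validated against a per-base boolean-mask oracle
(1000 random toy instances) and against the bedtools CLI; the majority
counter against an independent per-base implementation. Empirical-p
conventions make all reported p-values lie in [1/(n_sim+1), 1]. Ties in
locus clumping break by position (leftmost); ties for top eQTL break by
smallest p then SNP id. Degenerate inputs (empty peak sets, states absent
from a chromosome, blacklist empty) return empty/identity results rather
than raising. Monte-Carlo test sizes were chosen to keep the default suite
under ~10 s and the acceptance script under ~10 s: 1000 oracle instances,
200 null-calibration runs at n_sim = 300, 100 GWAS replicates for fold
recovery, 10⁴ placement draws (pooled over 10 streams) for the uniformity
GOF. Statistical assertions use fixed seeds; uniformity checks pool counts
across independent streams so a single unlucky stream cannot dominate the
statistic.

## Known limitations

- The heritability estimator assumes the panel's block structure is the
  truth; model misspecification (real, leaky LD) is not handled.
- Simulated null regions are not excluded from blacklist or assembly gaps
  by default (no gaps exist on the synthetic genome; for real genomes the
  options exist but matching remains chromosome-and-size only, with no
  GC/covariate matching).
- Locus clumping is distance-based only; LD-aware clumping and
  conditional/joint fine-mapping are out of scope.
- The eQTL integration reports evidence; it does not model colocalization.
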