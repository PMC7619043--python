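"""Synthetic study generator: every input of the pipeline, with ground truth.

The generator emulates the structure of a bulk ATAC-seq study of fetal
frontal cortex: a set of "true" open-chromatin peaks on a small genome,
observed imperfectly in three biological replicates and one pooled call
(boundary jitter, missed detections, replicate-private noise peaks);
NeuN+/NeuN- fraction peak sets that are overlapping subsets of the bulk
truth; chromatin-state and histone-mark maps whose regions are
preferentially anchored on true peaks; an LD-block genotype panel; GWAS
summary statistics whose per-SNP heritability is elevated inside the
(extended) true-peak annotation; and a fetal-brain eQTL table with planted
causal regulatory SNPs.

Everything is a deterministic function of the master seed: the seed fans
out to one child ``numpy.random.SeedSequence`` per named stage, in a fixed
order, so adding draws to one stage never perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .intervals import (
    GenomeModel,
    GenomicInterval,
    PeakSet,
    write_bed,
    write_genes,
    GeneModel,
)
from .h2 import SnpPanel, GwasSummary

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "StudyBundle",
    "PlantedSnp",
    "generate_study",
    "simulate_gwas",
    "write_study",
    "solve_tau",
]

_STAGES = (
    "true_peaks",
    "replicates",
    "pooled",
    "neun",
    "blacklist",
    "states",
    "histones",
    "genes",
    "snps",
    "genotypes",
    "covariates",
    "gwas",
    "planted",
    "eqtl",
)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the reference conditions
    used throughout the test-suite."""

    # genome: three 2-Mb chromosomes — small enough for fast resampling,
    # large enough that peaks are sparse (~2% coverage, as in real ATAC data)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    # true peaks: lognormal lengths centred near 250 bp
    n_true_peaks: int = 400
    peak_len_log_mean: float = math.log(250.0)
    peak_len_log_sd: float = 0.3
    min_peak_gap: int = 300
    # replicate observation model
    n_replicates: int = 3
    detect_prob: float = 0.95
    pooled_detect_prob: float = 0.98
    jitter_bp: int = 50
    noise_peaks_per_replicate: int = 60
    pooled_noise_peaks: int = 80
    # NeuN fraction membership of each true peak
    neun_shared_frac: float = 0.70
    neun_pos_only_frac: float = 0.12
    neun_neg_only_frac: float = 0.12
    # blacklist
    n_blacklist: int = 20
    blacklist_len: int = 1000
    # chromatin states: anchored fraction = probability a region is placed
    # covering a true peak rather than uniformly
    state_labels: tuple[str, ...] = (
        "Promoter",
        "Enhancer",
        "Bivalent",
        "Transcribed",
        "RegPermissive",
        "Quiescent",
        "FacultativeHet",
        "ConstitutiveHet",
    )
    state_regions_per_label: int = 150
    state_len_log_mean: float = math.log(400.0)
    state_len_log_sd: float = 0.4
    state_anchor_frac: dict[str, float] = field(
        default_factory=lambda: {"Promoter": 0.5, "Enhancer": 0.3}
    )
    histone_regions: int = 200
    histone_anchor_frac: dict[str, float] = field(
        default_factory=lambda: {"H3K4me1": 0.4, "H3K4me3": 0.5}
    )
    # genes
    n_genes: int = 80
    gene_body_min: int = 5_000
    gene_body_max: int = 30_000
    # SNP panel
    n_snps: int = 5000
    n_individuals: int = 200
    ld_block_size: int = 50
    ld_rho: float = 0.6
    maf_low: float = 0.1
    maf_high: float = 0.9
    # GWAS architecture
    n_gwas: int = 1000  # sample size N
    h2_total: float = 0.4
    target_fold: float = 5.0
    snp_flank: int = 500
    n_covariate_categories: int = 3
    covariate_coverage: float = 0.2
    # prioritization truth
    n_planted: int = 3
    n_eqtl_background: int = 300
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["state_labels"] = list(self.state_labels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def validate(self) -> None:
        for p in (
            self.detect_prob,
            self.pooled_detect_prob,
            self.neun_shared_frac,
            self.covariate_coverage,
        ):
            if not (0 <= p <= 1):
                raise ValueError(f"probability {p} outside [0, 1]")
        max_len = math.exp(self.peak_len_log_mean + 5 * self.peak_len_log_sd)
        if max_len >= min(self.chrom_lengths.values()):
            raise ValueError("peak length distribution incompatible with chromosome sizes")
        if self.neun_shared_frac + self.neun_pos_only_frac + self.neun_neg_only_frac > 1:
            raise ValueError("NeuN fraction probabilities sum to > 1")


@dataclass(frozen=True)
class PlantedSnp:
    """A planted causal regulatory SNP with its LD twin and eQTL targets."""

    snp_id: str
    twin_id: str | None
    chrom: str
    pos: int
    peak_index: int
    transcripts: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator, sufficient to score every
    pipeline stage."""

    true_peaks: PeakSet
    replicate_detected: list[list[bool]]
    pooled_detected: list[bool]
    neun_labels: list[str]
    state_anchor_frac: dict[str, float]
    tau: np.ndarray
    category_names: list[str]
    expected_prop_snps: float
    expected_prop_h2: float
    expected_fold: float
    realized_prop_h2: float
    planted: list[PlantedSnp]

    def to_json(self, path: str | Path) -> None:
        data = {
            "n_true_peaks": len(self.true_peaks),
            "true_peaks": [
                [iv.chrom, iv.start, iv.end] for iv in self.true_peaks
            ],
            "replicate_detected": self.replicate_detected,
            "pooled_detected": self.pooled_detected,
            "neun_labels": self.neun_labels,
            "state_anchor_frac": self.state_anchor_frac,
            "tau": self.tau.tolist(),
            "category_names": self.category_names,
            "expected_prop_snps": self.expected_prop_snps,
            "expected_prop_h2": self.expected_prop_h2,
            "expected_fold": self.expected_fold,
            "realized_prop_h2": self.realized_prop_h2,
            "planted": [asdict(p) for p in self.planted],
        }
        Path(path).write_text(json.dumps(data, indent=1))


@dataclass
class StudyBundle:
    """All generated inputs, in memory, plus the truth record."""

    config: SyntheticConfig
    genome: GenomeModel
    truth: SyntheticTruth
    replicates: list[PeakSet]
    pooled: PeakSet
    neun_pos: PeakSet
    neun_neg: PeakSet
    blacklist: PeakSet
    states: dict[str, PeakSet]
    histones: dict[str, PeakSet]
    genes: list[GeneModel]
    panel: SnpPanel
    annotations: np.ndarray
    category_names: list[str]
    gwas: pd.DataFrame
    eqtl: pd.DataFrame


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _lognormal_lengths(rng, n, log_mean, log_sd, lo=50) -> np.ndarray:
    return np.maximum(lo, np.round(rng.lognormal(log_mean, log_sd, size=n))).astype(np.int64)


def _sample_chroms(rng, genome: GenomeModel, n: int) -> np.ndarray:
    lengths = np.array([genome.length(c) for c in genome.chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    return rng.choice(len(lengths), size=n, p=probs)


def _true_peaks(rng, cfg: SyntheticConfig, genome: GenomeModel) -> PeakSet:
    """Sparse non-overlapping true peaks; overlapping draws are discarded,
    so the realized count can fall slightly below the target."""
    chrom_idx = _sample_chroms(rng, genome, cfg.n_true_peaks)
    lens = _lognormal_lengths(rng, cfg.n_true_peaks, cfg.peak_len_log_mean, cfg.peak_len_log_sd)
    names = list(genome.chrom_names)
    draws: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for ci, L in zip(chrom_idx, lens):
        chrom = names[ci]
        start = int(rng.integers(0, genome.length(chrom) - L + 1))
        draws[chrom].append((start, start + int(L)))
    out = []
    for chrom in names:
        prev_end = -(10**9)
        for s, e in sorted(draws[chrom]):
            if s >= prev_end + cfg.min_peak_gap:
                out.append(GenomicInterval(chrom, s, e))
                prev_end = e
    return PeakSet(out, label="true_peaks", merged=True)


def _jitter(rng, iv: GenomicInterval, jitter_bp: int, genome: GenomeModel) -> GenomicInterval:
    L = genome.length(iv.chrom)
    s = iv.start + int(rng.integers(-jitter_bp, jitter_bp + 1))
    e = iv.end + int(rng.integers(-jitter_bp, jitter_bp + 1))
    s = max(0, min(s, L - 1))
    e = max(s + 1, min(e, L))
    return GenomicInterval(iv.chrom, s, e)


def _noise_peaks(rng, cfg: SyntheticConfig, genome: GenomeModel, n: int) -> list[GenomicInterval]:
    chrom_idx = _sample_chroms(rng, genome, n)
    lens = _lognormal_lengths(rng, n, cfg.peak_len_log_mean, cfg.peak_len_log_sd)
    names = list(genome.chrom_names)
    out = []
    for ci, L in zip(chrom_idx, lens):
        chrom = names[ci]
        start = int(rng.integers(0, genome.length(chrom) - L + 1))
        out.append(GenomicInterval(chrom, start, start + int(L)))
    return out


def _observed_set(
    rng,
    true_peaks: PeakSet,
    detect_prob: float,
    n_noise: int,
    cfg: SyntheticConfig,
    genome: GenomeModel,
    label: str,
    subset: Sequence[bool] | None = None,
) -> tuple[PeakSet, list[bool]]:
    detected: list[bool] = []
    out: list[GenomicInterval] = []
    for i, iv in enumerate(true_peaks):
        eligible = subset[i] if subset is not None else True
        hit = bool(eligible and rng.random() < detect_prob)
        detected.append(hit)
        if hit:
            out.append(_jitter(rng, iv, cfg.jitter_bp, genome))
    out.extend(_noise_peaks(rng, cfg, genome, n_noise))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakSet(out, label=label), detected


def _anchored_regions(
    rng,
    cfg: SyntheticConfig,
    genome: GenomeModel,
    true_peaks: PeakSet,
    n_regions: int,
    anchor_frac: float,
    log_mean: float,
    log_sd: float,
    label: str,
) -> PeakSet:
    """Regions placed either covering a random true peak (with margin, so
    the peak's majority-overlap criterion is met) or uniformly at random."""
    out: list[GenomicInterval] = []
    n_anchored = int(round(anchor_frac * n_regions))
    if n_anchored > 0 and len(true_peaks) > 0:
        picks = rng.integers(0, len(true_peaks), size=n_anchored)
        for pi in picks:
            peak = true_peaks[int(pi)]
            L = genome.length(peak.chrom)
            s = max(0, peak.start - int(rng.integers(0, 101)))
            e = min(L, peak.end + int(rng.integers(0, 101)))
            out.append(GenomicInterval(peak.chrom, s, e))
    out.extend(
        _noise_region
        for _noise_region in _uniform_regions(
            rng, genome, n_regions - len(out), log_mean, log_sd
        )
    )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakSet(out, label=label)


def _uniform_regions(rng, genome, n, log_mean, log_sd) -> list[GenomicInterval]:
    chrom_idx = _sample_chroms(rng, genome, n) if n > 0 else []
    lens = _lognormal_lengths(rng, n, log_mean, log_sd) if n > 0 else []
    names = list(genome.chrom_names)
    out = []
    for ci, L in zip(chrom_idx, lens):
        chrom = names[ci]
        start = int(rng.integers(0, genome.length(chrom) - L + 1))
        out.append(GenomicInterval(chrom, start, start + int(L)))
    return out


def _blacklist(rng, cfg, genome, true_peaks) -> PeakSet:
    """Artifact regions sampled away from true peaks (rejection sampling),
    mimicking blacklisted repeats that real peak sets avoid."""
    arrays = true_peaks.by_chrom()
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < cfg.n_blacklist and attempts < 100 * cfg.n_blacklist:
        attempts += 1
        chrom = list(genome.chrom_names)[int(_sample_chroms(rng, genome, 1)[0])]
        start = int(rng.integers(0, genome.length(chrom) - cfg.blacklist_len + 1))
        end = start + cfg.blacklist_len
        if chrom in arrays:
            s, e = arrays[chrom]
            j = int(np.searchsorted(e, start, side="right"))
            if j < len(s) and s[j] < end:
                continue
        out.append(GenomicInterval(chrom, start, end))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakSet(out, label="blacklist")


def _genes(rng, cfg, genome) -> list[GeneModel]:
    names = list(genome.chrom_names)
    chrom_idx = _sample_chroms(rng, genome, cfg.n_genes)
    genes = []
    for i, ci in enumerate(chrom_idx):
        chrom = names[int(ci)]
        L = genome.length(chrom)
        body_len = int(rng.integers(cfg.gene_body_min, cfg.gene_body_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = int(rng.integers(0, L - body_len))
            body = GenomicInterval(chrom, tss, tss + body_len)
        else:
            tss = int(rng.integers(body_len, L))
            body = GenomicInterval(chrom, tss - body_len + 1, tss + 1)
        genes.append(GeneModel(f"GENE{i + 1}", chrom, strand, tss, body))
    genes.sort(key=lambda g: (g.chrom, g.tss))
    return genes


def _snp_map(rng, cfg, genome) -> tuple[list[str], np.ndarray, np.ndarray, list[tuple[int, int]]]:
    names = list(genome.chrom_names)
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    counts = np.floor(cfg.n_snps * lengths / lengths.sum()).astype(int)
    counts[0] += cfg.n_snps - counts.sum()
    chroms: list[str] = []
    pos: list[int] = []
    for c, n_c in zip(names, counts):
        p = np.sort(rng.choice(genome.length(c) - 1, size=n_c, replace=False) + 1)
        chroms.extend([c] * n_c)
        pos.extend(int(x) for x in p)
    snp_ids = [f"rs{i + 1}" for i in range(cfg.n_snps)]
    bounds: list[tuple[int, int]] = []
    offset = 0
    for n_c in counts:
        start = offset
        while start < offset + n_c:
            stop = min(start + cfg.ld_block_size, offset + n_c)
            bounds.append((start, stop))
            start = stop
        offset += n_c
    return snp_ids, np.array(chroms, dtype=object), np.array(pos, dtype=np.int64), bounds


def _genotypes(rng, cfg, bounds, n_snps) -> tuple[np.ndarray, list[np.ndarray]]:
    """Dosages with compound-symmetric within-block LD: two latent Gaussian
    haplotypes per individual, thresholded at per-SNP allele frequencies."""
    G = np.zeros((cfg.n_individuals, n_snps), dtype=np.int8)
    block_R: list[np.ndarray] = []
    chol_cache: dict[int, np.ndarray] = {}
    for lo, hi in bounds:
        k = hi - lo
        R = np.full((k, k), cfg.ld_rho)
        np.fill_diagonal(R, 1.0)
        block_R.append(R)
        if k not in chol_cache:
            chol_cache[k] = np.linalg.cholesky(R)
        L = chol_cache[k]
        freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=k)
        thresh = stats.norm.ppf(freqs)
        for _hap in range(2):
            latent = rng.standard_normal((cfg.n_individuals, k)) @ L.T
            G[:, lo:hi] += (latent < thresh).astype(np.int8)
        # guard against monomorphic columns (possible at extreme frequencies)
        for j in range(lo, hi):
            while G[:, j].std() == 0:
                G[:, j] = rng.integers(0, 3, size=cfg.n_individuals).astype(np.int8)
    return G, block_R


def solve_tau(prop_snps: float, target_fold: float, h2_total: float, n_snps: int) -> tuple[float, float]:
    """Solve (tau_base, tau_annot) so the annotation carries target_fold
    times its SNP share of heritability and total h2 matches.

    With p = prop_snps, mean per-SNP h2 hbar = h2_total / n_snps and fold
    F: in-annotation per-SNP h2 is u = F * hbar and the base coefficient is
    tau_base = (1 - F p) hbar / (1 - p); the annotation coefficient is the
    increment u - tau_base.
    """
    p, F = prop_snps, target_fold
    if not (0 < p < 1):
        raise ValueError("annotation must cover a strict subset of SNPs")
    if F * p >= 1:
        raise ValueError(f"target fold {F} infeasible at prop_snps={p:.3f}")
    hbar = h2_total / n_snps
    u = F * hbar
    tau_base = (1 - F * p) * hbar / (1 - p)
    return tau_base, u - tau_base


def simulate_gwas(
    panel: SnpPanel,
    annotations: np.ndarray,
    tau: np.ndarray,
    N: float,
    rng,
) -> tuple[GwasSummary, np.ndarray, dict[str, float]]:
    """Simulate GWAS z-scores under the stratified-architecture model.

    Per LD block with correlation matrix R: effect sizes
    beta_j ~ Normal(0, sum_c tau_c 1[j in c]); then
    z = sqrt(N) R beta + eps with eps ~ MVN(0, R), and chi2 = z^2.
    Returns the summary, the realized betas, and realized/expected
    heritability bookkeeping.
    """
    if panel.block_R is None:
        raise ValueError("GWAS simulation needs the panel's true block LD matrices")
    A = np.asarray(annotations, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(A @ tau < 0):
        raise ValueError("negative per-SNP variance implied by tau")
    z = np.zeros(panel.n_snps)
    beta = np.zeros(panel.n_snps)
    for b, (lo, hi) in enumerate(panel.block_bounds):
        R = panel.block_R[b]
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ValueError(f"block {b} LD matrix is not positive semi-definite") from None
        sigma2 = A[lo:hi] @ tau
        beta_b = rng.standard_normal(hi - lo) * np.sqrt(sigma2)
        eps = L @ rng.standard_normal(hi - lo)
        z[lo:hi] = math.sqrt(N) * (R @ beta_b) + eps
        beta[lo:hi] = beta_b
    gwas = GwasSummary.from_z(z, N)
    b2 = beta**2
    total = float(b2.sum())
    shares = {}
    for c in range(A.shape[1]):
        mask = A[:, c] == 1
        shares[f"realized_share_cat{c}"] = float(b2[mask].sum() / total) if total > 0 else float("nan")
    return gwas, beta, shares


def generate_study(config: SyntheticConfig | None = None) -> StudyBundle:
    """Generate the full synthetic study (in memory) from the master seed."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    genome = GenomeModel(dict(cfg.chrom_lengths))
    rngs = _stage_rngs(cfg.seed)

    true_peaks = _true_peaks(rngs["true_peaks"], cfg, genome)

    replicates = []
    rep_detected = []
    for r in range(cfg.n_replicates):
        ps, det = _observed_set(
            rngs["replicates"],
            true_peaks,
            cfg.detect_prob,
            cfg.noise_peaks_per_replicate,
            cfg,
            genome,
            label=f"rep{r + 1}",
        )
        replicates.append(ps)
        rep_detected.append(det)
    pooled, pooled_detected = _observed_set(
        rngs["pooled"],
        true_peaks,
        cfg.pooled_detect_prob,
        cfg.pooled_noise_peaks,
        cfg,
        genome,
        label="pooled",
    )

    rng_neun = rngs["neun"]
    probs = [
        cfg.neun_shared_frac,
        cfg.neun_pos_only_frac,
        cfg.neun_neg_only_frac,
        1 - cfg.neun_shared_frac - cfg.neun_pos_only_frac - cfg.neun_neg_only_frac,
    ]
    draw = rng_neun.choice(4, size=len(true_peaks), p=probs)
    neun_labels = [("both", "neun_pos_only", "neun_neg_only", "neither")[d] for d in draw]
    pos_subset = [lab in ("both", "neun_pos_only") for lab in neun_labels]
    neg_subset = [lab in ("both", "neun_neg_only") for lab in neun_labels]
    neun_pos, _ = _observed_set(
        rng_neun, true_peaks, 1.0, cfg.noise_peaks_per_replicate // 2, cfg, genome,
        label="neun_pos", subset=pos_subset,
    )
    neun_neg, _ = _observed_set(
        rng_neun, true_peaks, 1.0, cfg.noise_peaks_per_replicate // 2, cfg, genome,
        label="neun_neg", subset=neg_subset,
    )

    blacklist = _blacklist(rngs["blacklist"], cfg, genome, true_peaks)

    rng_states = rngs["states"]
    states = {}
    anchor_truth = {}
    for label in cfg.state_labels:
        frac = cfg.state_anchor_frac.get(label, 0.0)
        anchor_truth[label] = frac
        states[label] = _anchored_regions(
            rng_states, cfg, genome, true_peaks, cfg.state_regions_per_label, frac,
            cfg.state_len_log_mean, cfg.state_len_log_sd, label,
        )
    rng_hist = rngs["histones"]
    histones = {
        label: _anchored_regions(
            rng_hist, cfg, genome, true_peaks, cfg.histone_regions, frac,
            cfg.state_len_log_mean, cfg.state_len_log_sd, label,
        )
        for label, frac in cfg.histone_anchor_frac.items()
    }

    genes = _genes(rngs["genes"], cfg, genome)

    snp_ids, snp_chrom, snp_pos, bounds = _snp_map(rngs["snps"], cfg, genome)
    genotypes, block_R = _genotypes(rngs["genotypes"], cfg, bounds, cfg.n_snps)
    panel = SnpPanel(
        snp_ids=snp_ids,
        chrom=snp_chrom,
        pos=snp_pos,
        block_bounds=bounds,
        genotypes=genotypes,
        block_R=block_R,
    )

    from .h2 import annotate_snps

    ocr_col = annotate_snps(panel, true_peaks, flank=cfg.snp_flank, genome=genome)
    rng_cov = rngs["covariates"]
    covariates = [
        (rng_cov.random(cfg.n_snps) < cfg.covariate_coverage).astype(np.int64)
        for _ in range(cfg.n_covariate_categories)
    ]
    A = np.column_stack([np.ones(cfg.n_snps, dtype=np.int64), ocr_col, *covariates])
    category_names = ["base", "ocr"] + [
        f"cov{k + 1}" for k in range(cfg.n_covariate_categories)
    ]

    prop_snps = float(ocr_col.mean())
    tau_base, tau_ocr = solve_tau(prop_snps, cfg.target_fold, cfg.h2_total, cfg.n_snps)
    tau = np.array([tau_base, tau_ocr] + [0.0] * cfg.n_covariate_categories)

    gwas_summary, beta, shares = simulate_gwas(panel, A, tau, cfg.n_gwas, rngs["gwas"])
    pvals = stats.chi2.sf(gwas_summary.chisq, df=1)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    # plant causal regulatory SNPs: each becomes the index SNP of its locus,
    # with an optional perfect-LD twin inside the same peak/block
    rng_pl = rngs["planted"]
    peak_arrays = true_peaks.by_chrom()
    snp_peak = np.full(cfg.n_snps, -1, dtype=np.int64)
    peak_offset = {}
    off = 0
    for chrom in sorted(peak_arrays):
        peak_offset[chrom] = off
        off += len(peak_arrays[chrom][0])
    # map global peak index in true_peaks order
    peak_index_of = {
        (iv.chrom, iv.start, iv.end): i for i, iv in enumerate(true_peaks)
    }
    for j in range(cfg.n_snps):
        chrom = snp_chrom[j]
        if chrom not in peak_arrays:
            continue
        s, e = peak_arrays[chrom]
        p0 = snp_pos[j] - 1
        k = int(np.searchsorted(s, p0, side="right")) - 1
        if k >= 0 and p0 < e[k]:
            snp_peak[j] = peak_index_of[(chrom, int(s[k]), int(e[k]))]
    in_peak = np.flatnonzero(snp_peak >= 0)
    planted: list[PlantedSnp] = []
    used_chroms: set[str] = set()
    order = rng_pl.permutation(in_peak)
    block_of = np.zeros(cfg.n_snps, dtype=np.int64)
    for b, (lo, hi) in enumerate(bounds):
        block_of[lo:hi] = b
    for j in order:
        if len(planted) >= cfg.n_planted:
            break
        chrom = snp_chrom[j]
        if chrom in used_chroms:
            continue
        used_chroms.add(chrom)
        twin_id = None
        same = [
            k
            for k in in_peak
            if k != j and snp_peak[k] == snp_peak[j] and block_of[k] == block_of[j]
        ]
        if same:
            k = int(same[0])
            genotypes[:, k] = genotypes[:, j]
            twin_id = snp_ids[k]
            pvals[k] = 1e-12
        n_tr = 1 + int(rng_pl.random() < 0.5)
        transcripts = tuple(
            f"{genes[int(g)].gene_id}.t1" for g in rng_pl.choice(len(genes), size=n_tr, replace=False)
        )
        pvals[j] = 1e-15 * (1 + len(planted))
        planted.append(
            PlantedSnp(
                snp_id=snp_ids[j],
                twin_id=twin_id,
                chrom=str(chrom),
                pos=int(snp_pos[j]),
                peak_index=int(snp_peak[j]),
                transcripts=transcripts,
            )
        )

    gwas_df = pd.DataFrame(
        {
            "snp": snp_ids,
            "chr": snp_chrom,
            "pos": snp_pos,
            "z": np.sqrt(gwas_summary.chisq) * np.sign(rng_pl.standard_normal(cfg.n_snps)),
            "chisq": gwas_summary.chisq,
            "p": pvals,
            "N": cfg.n_gwas,
        }
    )

    # eQTL table: planted SNPs are the top eQTL of their transcripts;
    # background rows are random SNP/transcript pairs with larger p
    rng_eq = rngs["eqtl"]
    eq_rows = []
    for p_snp in planted:
        for t in p_snp.transcripts:
            eq_rows.append((p_snp.snp_id, t, 1e-8))
            if p_snp.twin_id is not None:
                eq_rows.append((p_snp.twin_id, t, 5e-7))
    for _ in range(cfg.n_eqtl_background):
        j = int(rng_eq.integers(0, cfg.n_snps))
        g = int(rng_eq.integers(0, len(genes)))
        p = float(10 ** rng_eq.uniform(-6, 0))
        eq_rows.append((snp_ids[j], f"{genes[g].gene_id}.t1", p))
    eqtl_df = pd.DataFrame(eq_rows, columns=["snp", "transcript", "p"])

    truth = SyntheticTruth(
        true_peaks=true_peaks,
        replicate_detected=rep_detected,
        pooled_detected=pooled_detected,
        neun_labels=neun_labels,
        state_anchor_frac=anchor_truth,
        tau=tau,
        category_names=category_names,
        expected_prop_snps=prop_snps,
        expected_prop_h2=cfg.target_fold * prop_snps,
        expected_fold=cfg.target_fold,
        realized_prop_h2=shares.get("realized_share_cat1", float("nan")),
        planted=planted,
    )
    return StudyBundle(
        config=cfg,
        genome=genome,
        truth=truth,
        replicates=replicates,
        pooled=pooled,
        neun_pos=neun_pos,
        neun_neg=neun_neg,
        blacklist=blacklist,
        states=states,
        histones=histones,
        genes=genes,
        panel=panel,
        annotations=A,
        category_names=category_names,
        gwas=gwas_df,
        eqtl=eqtl_df,
    )


def write_study(bundle: StudyBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every generated input as plain-text files; returns a manifest
    of logical name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _reg(key: str, path: Path) -> Path:
        manifest[key] = str(path)
        return path

    bundle.genome.write_chrom_sizes(_reg("chrom_sizes", out / "chrom.sizes"))
    for i, rep in enumerate(bundle.replicates, start=1):
        write_bed(rep, _reg(f"replicate_{i}", out / f"rep{i}.bed"))
    write_bed(bundle.pooled, _reg("pooled", out / "pooled.bed"))
    write_bed(bundle.neun_pos, _reg("neun_pos", out / "neun_pos.bed"))
    write_bed(bundle.neun_neg, _reg("neun_neg", out / "neun_neg.bed"))
    write_bed(bundle.blacklist, _reg("blacklist", out / "blacklist.bed"))
    states_dir = out / "states"
    states_dir.mkdir(exist_ok=True)
    with open(_reg("states_manifest", out / "states.tsv"), "w") as fh:
        for label, ps in bundle.states.items():
            bed = states_dir / f"{label}.bed"
            write_bed(ps, bed)
            fh.write(f"{label}\t{bed.relative_to(out)}\n")
    for label, ps in bundle.histones.items():
        write_bed(ps, _reg(label.lower(), out / f"{label.lower()}.bed"))
    write_genes(bundle.genes, _reg("genes", out / "genes.tsv"))

    panel = bundle.panel
    block_col = np.zeros(panel.n_snps, dtype=np.int64)
    for b, (lo, hi) in enumerate(panel.block_bounds):
        block_col[lo:hi] = b
    meta = pd.DataFrame(
        {"snp": panel.snp_ids, "chr": panel.chrom, "pos": panel.pos, "block": block_col}
    )
    doses = pd.DataFrame(
        panel.genotypes.T,
        columns=[f"i{i + 1}" for i in range(panel.genotypes.shape[0])],
    )
    pdf = pd.concat([meta, doses], axis=1)
    pdf.to_csv(_reg("panel", out / "panel.tsv"), sep="\t", index=False)

    bundle.gwas.to_csv(_reg("gwas", out / "gwas.tsv"), sep="\t", index=False)
    bundle.eqtl.to_csv(_reg("eqtl", out / "eqtl.tsv"), sep="\t", index=False)
    bundle.truth.to_json(_reg("truth", out / "truth.json"))
    write_bed(bundle.truth.true_peaks, _reg("true_peaks", out / "true_peaks.bed"))
    relative = {k: str(Path(v).relative_to(out)) for k, v in manifest.items()}
    Path(out / "manifest.json").write_text(json.dumps(relative, indent=1))
    return manifest
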