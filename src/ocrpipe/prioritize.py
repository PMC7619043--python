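"""LD-aware prioritization of GWAS SNPs inside open-chromatin regions.

The filter chain keeps a SNP iff it (i) lies within a high-confidence OCR
(unextended), (ii) is genome-wide significant (p < 5e-8, strict), and
(iii) is in strong LD (r^2 > .8, strict) with the index SNP of its risk
locus. Loci are reconstructed from the summary statistics by greedy
distance clumping around successively most-significant SNPs. Surviving
SNPs are annotated with histone-mark membership, the NeuN attribution of
their containing OCR, and fetal-brain eQTL evidence including r^2 to the
top eQTL of each implicated transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .h2 import SnpPanel

__all__ = [
    "SnpRecord",
    "Locus",
    "EqtlHit",
    "PrioritizedSnp",
    "Thresholds",
    "r_squared",
    "define_loci",
    "prioritize",
]


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS SNP: identifier, 1-based position, association p-value."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    gwas_p: float
    trait: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.gwas_p <= 1):
            raise ValueError(f"{self.snp_id}: gwas_p must be in (0, 1]")


@dataclass
class Locus:
    """A genome-wide significant risk locus with its index (most
    significant) SNP."""

    locus_id: str
    members: list[SnpRecord]
    index_snp: SnpRecord


@dataclass(frozen=True)
class EqtlHit:
    transcript: str
    p: float
    top_snp: str
    r2_top: float  # nan when the top eQTL SNP is absent from the panel


@dataclass
class PrioritizedSnp:
    """A SNP passing all mandatory filters, with its regulatory annotation."""

    snp_id: str
    locus_id: str
    chrom: str
    pos: int
    gwas_p: float
    r2_index: float
    in_ocr: bool
    in_h3k4me1: bool
    in_h3k4me3: bool
    neun_label: str | None
    eqtls: list[EqtlHit] = field(default_factory=list)


@dataclass(frozen=True)
class Thresholds:
    """Filter cutoffs; all inequalities are strict."""

    gwas_p: float = 5e-8
    r2: float = 0.8
    eqtl_p: float = 5e-5
    locus_window: int = 500_000


def r_squared(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation between two genotype dosage vectors."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or g1.size < 2:
        raise ValueError("dosage vectors must be 1-D, equal length >= 2")
    if g1.std() == 0 or g2.std() == 0:
        raise ValueError("monomorphic SNP: zero variance dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(min(1.0, r * r))


def define_loci(sig_snps: Sequence[SnpRecord], window_bp: int = 500_000) -> list[Locus]:
    """Greedy distance clumping of genome-wide significant SNPs.

    Repeatedly takes the smallest-p unassigned SNP as an index (ties broken
    by chromosome then leftmost position) and absorbs all unassigned SNPs
    within +/- window_bp on the same chromosome.
    """
    remaining = sorted(sig_snps, key=lambda s: (s.gwas_p, s.chrom, s.pos))
    assigned: set[str] = set()
    loci: list[Locus] = []
    for snp in remaining:
        if snp.snp_id in assigned:
            continue
        members = [
            s
            for s in remaining
            if s.snp_id not in assigned
            and s.chrom == snp.chrom
            and abs(s.pos - snp.pos) <= window_bp
        ]
        assigned.update(s.snp_id for s in members)
        members.sort(key=lambda s: (s.chrom, s.pos))
        loci.append(Locus(locus_id=f"locus_{len(loci) + 1}", members=members, index_snp=snp))
    return loci


def _point_in_set(chrom: str, pos_1based: int, peaks: PeakSet) -> int | None:
    """Index of the interval (in peaks order) containing the SNP, else None."""
    p0 = pos_1based - 1
    for i, iv in enumerate(peaks):
        if iv.chrom == chrom and iv.start <= p0 < iv.end:
            return i
    return None


def prioritize(
    gwas: Sequence[SnpRecord],
    ocrs: PeakSet,
    panel: SnpPanel,
    h3k4me1: PeakSet | None = None,
    h3k4me3: PeakSet | None = None,
    attribution: tuple[PeakSet, Sequence[str]] | None = None,
    eqtl: pd.DataFrame | None = None,
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[PrioritizedSnp], list[str]]:
    """Run the full prioritization filter chain.

    Returns the prioritized SNPs (sorted by chromosome and position) and a
    log of SNPs that could not be assessed (absent from the LD panel).
    ``attribution`` is the (bulk OCR set, per-OCR NeuN label) pair from the
    consensus stage; ``eqtl`` has columns snp, transcript, p.
    """
    log: list[str] = []
    sig = [s for s in gwas if s.gwas_p < thresholds.gwas_p]
    loci = define_loci(sig, window_bp=thresholds.locus_window)

    top_eqtl: dict[str, tuple[str, float]] = {}
    if eqtl is not None and len(eqtl):
        best = eqtl.sort_values(["p", "snp"], kind="stable").groupby("transcript").first()
        top_eqtl = {t: (row["snp"], float(row["p"])) for t, row in best.iterrows()}

    out: list[PrioritizedSnp] = []
    for locus in loci:
        g_index = panel.dosages(locus.index_snp.snp_id)
        if g_index is None:
            log.append(f"index SNP {locus.index_snp.snp_id} of {locus.locus_id} absent from panel")
            continue
        for snp in locus.members:
            ocr_idx = _point_in_set(snp.chrom, snp.pos, ocrs)
            if ocr_idx is None:
                continue
            g = panel.dosages(snp.snp_id)
            if g is None:
                log.append(f"SNP {snp.snp_id} absent from panel; excluded (r2_index = NA)")
                continue
            r2 = r_squared(g, g_index)
            if not (r2 > thresholds.r2):
                continue
            neun_label = None
            if attribution is not None:
                bulk, labels = attribution
                idx = _point_in_set(snp.chrom, snp.pos, bulk)
                if idx is not None:
                    neun_label = labels[idx]
            hits: list[EqtlHit] = []
            if eqtl is not None and len(eqtl):
                rows = eqtl[(eqtl["snp"] == snp.snp_id) & (eqtl["p"] < thresholds.eqtl_p)]
                for transcript, grp in rows.groupby("transcript"):
                    p_best = float(grp["p"].min())
                    top_snp, _ = top_eqtl[transcript]
                    g_top = panel.dosages(top_snp)
                    r2_top = r_squared(g, g_top) if g_top is not None else float("nan")
                    hits.append(EqtlHit(str(transcript), p_best, top_snp, r2_top))
                hits.sort(key=lambda h: h.p)
            out.append(
                PrioritizedSnp(
                    snp_id=snp.snp_id,
                    locus_id=locus.locus_id,
                    chrom=snp.chrom,
                    pos=snp.pos,
                    gwas_p=snp.gwas_p,
                    r2_index=r2,
                    in_ocr=True,
                    in_h3k4me1=(
                        _point_in_set(snp.chrom, snp.pos, h3k4me1) is not None
                        if h3k4me1 is not None
                        else False
                    ),
                    in_h3k4me3=(
                        _point_in_set(snp.chrom, snp.pos, h3k4me3) is not None
                        if h3k4me3 is not None
                        else False
                    ),
                    neun_label=neun_label,
                    eqtls=hits,
                )
            )
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out, log


def write_prioritized_tsv(snps: Sequence[PrioritizedSnp], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "snp\tlocus\tchrom\tpos\tgwas_p\tr2_index\tin_h3k4me1\tin_h3k4me3\t"
            "neun_label\teqtl_transcripts\teqtl_p\tr2_top_eqtl\n"
        )
        for s in snps:
            transcripts = ",".join(h.transcript for h in s.eqtls) or "."
            eqtl_ps = ",".join(f"{h.p:.3g}" for h in s.eqtls) or "."
            r2s = ",".join(f"{h.r2_top:.3g}" for h in s.eqtls) or "."
            fh.write(
                f"{s.snp_id}\t{s.locus_id}\t{s.chrom}\t{s.pos}\t{s.gwas_p:.3g}\t"
                f"{s.r2_index:.4g}\t{int(s.in_h3k4me1)}\t{int(s.in_h3k4me3)}\t"
                f"{s.neun_label or '.'}\t{transcripts}\t{eqtl_ps}\t{r2s}\n"
            )
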