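"""Consensus open-chromatin region (OCR) definition from replicate peak calls.

High-confidence OCRs are the pooled-sample peaks (blacklist-excluded) that
are supported by peaks in at least ``min_count`` of the biological
replicates, DiffBind-style: support is counted on the merged union of all
replicate peaks, and any >= 1 bp overlap by a replicate counts as support.
The surviving pooled peaks keep their original pooled coordinates.

Each bulk OCR can then be attributed to the NeuN+ (neuronal) and/or NeuN-
(non-neuronal) nuclei fractions by overlap with the fraction-specific peak
sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    PeakSet,
    _hit_flags,
    merge,
    subtract,
)

__all__ = [
    "ATTRIBUTION_LABELS",
    "ReplicateDesign",
    "occupancy_consensus",
    "high_confidence",
    "attribute_fractions",
    "histone_subset",
]

ATTRIBUTION_LABELS = ("both", "neun_pos_only", "neun_neg_only", "neither")


@dataclass
class ReplicateDesign:
    """Peak calls for one experiment: one set per biological replicate plus
    the pooled (merged/downsampled) call."""

    biological_replicates: list[str]
    peak_sets: list[PeakSet]
    pooled: PeakSet

    def __post_init__(self) -> None:
        if len(self.biological_replicates) != len(self.peak_sets):
            raise ValueError("one peak set per biological replicate required")
        if len(self.peak_sets) < 2:
            raise ValueError("at least 2 biological replicates required")


def occupancy_consensus(replicates: Sequence[PeakSet], min_count: int) -> PeakSet:
    """Union intervals supported by >= min_count distinct replicates.

    The union of all replicate peaks is merged; each merged interval is
    retained iff peaks from at least ``min_count`` distinct replicates
    overlap it by >= 1 bp.
    """
    if len(replicates) == 0:
        raise ValueError("empty replicate list")
    if not (1 <= min_count <= len(replicates)):
        raise ValueError(f"min_count must be in [1, {len(replicates)}]")
    union = merge(PeakSet([iv for ps in replicates for iv in ps]))
    support = np.zeros(len(union), dtype=np.int64)
    for rep in replicates:
        support += _hit_flags(union, rep)
    kept = [iv for iv, n in zip(union, support) if n >= min_count]
    return PeakSet(kept, label="consensus", merged=True)


def high_confidence(
    pooled: PeakSet,
    replicates: Sequence[PeakSet],
    blacklist: PeakSet | None = None,
    min_count: int = 2,
) -> PeakSet:
    """High-confidence OCRs: blacklist-excluded pooled peaks supported by
    the replicate occupancy consensus.

    A pooled peak touching the blacklist by >= 1 bp is dropped outright.
    Surviving pooled peaks are kept (with their original coordinates) iff
    they overlap the min_count-of-n replicate consensus by >= 1 bp.
    """
    clean = pooled
    if blacklist is not None and len(blacklist) > 0:
        clean = subtract(pooled, blacklist, mode="drop_if_touch")
    if len(clean) == 0:
        return PeakSet([], label="high_confidence", merged=pooled.merged)
    cons = occupancy_consensus(replicates, min_count)
    flags = _hit_flags(clean, cons)
    kept = [iv for iv, f in zip(clean, flags) if f]
    return PeakSet(kept, label="high_confidence", merged=pooled.merged)


def attribute_fractions(
    bulk_hc: PeakSet,
    neun_pos: PeakSet,
    neun_neg: PeakSet,
) -> tuple[list[str], dict[str, int]]:
    """Attribute each bulk OCR to the NeuN+/NeuN- fractions by >= 1 bp overlap.

    Returns one label per bulk OCR (in input order) from
    {both, neun_pos_only, neun_neg_only, neither}, plus counts per label;
    the counts always partition the bulk set.
    """
    in_pos = _hit_flags(bulk_hc, neun_pos)
    in_neg = _hit_flags(bulk_hc, neun_neg)
    labels = []
    for p, n in zip(in_pos, in_neg):
        if p and n:
            labels.append("both")
        elif p:
            labels.append("neun_pos_only")
        elif n:
            labels.append("neun_neg_only")
        else:
            labels.append("neither")
    counts = dict.fromkeys(ATTRIBUTION_LABELS, 0)
    counts.update(Counter(labels))
    return labels, counts


def histone_subset(ocrs: PeakSet, histone: PeakSet, label: str = "") -> PeakSet:
    """OCRs overlapping a histone-mark set, merged with the overlapping
    histone intervals (one record per connected component)."""
    ocr_hit = _hit_flags(ocrs, histone)
    hist_hit = _hit_flags(histone, ocrs)
    selected = [iv for iv, f in zip(ocrs, ocr_hit) if f] + [
        iv for iv, f in zip(histone, hist_hit) if f
    ]
    return merge(PeakSet(selected), label=label or f"{ocrs.label}+{histone.label}")


def write_attribution(
    bulk_hc: PeakSet,
    labels: Sequence[str],
    path,
) -> None:
    """Write the attribution table: ocr_id, chrom, start, end, label."""
    with open(path, "w") as fh:
        fh.write("ocr_id\tchrom\tstart\tend\tlabel\n")
        for i, (iv, lab) in enumerate(zip(bulk_hc, labels), start=1):
            name = iv.name if iv.name is not None else f"OCR_{i}"
            fh.write(f"{name}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")


def read_attribution(path) -> tuple[PeakSet, list[str]]:
    """Read the attribution table written by :func:`write_attribution`."""
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    from pathlib import Path

    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("ocr_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path} line {i}: expected 5 columns")
        intervals.append(GenomicInterval(fields[1], int(fields[2]), int(fields[3]), name=fields[0]))
        labels.append(fields[4])
    return PeakSet(intervals, label="bulk_hc"), labels
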