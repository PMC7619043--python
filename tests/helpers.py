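"""Shared test utilities: per-base boolean-mask oracles for interval logic.

The oracle represents a toy chromosome as a boolean numpy array with one
entry per base, so every interval-set operation has an obvious, independent
reference implementation against which the production sweep-line code is
checked.
"""

from __future__ import annotations

import numpy as np

from ocrpipe.intervals import GenomeModel, GenomicInterval, PeakSet


def mask_of(peaks: PeakSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chrom_names}
    for iv in peaks:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def peaks_of(masks: dict[str, np.ndarray], label: str = "") -> PeakSet:
    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return PeakSet(out, label=label, merged=True)


def random_peaks(
    rng: np.random.Generator,
    genome: GenomeModel,
    n: int,
    max_len: int = 200,
) -> PeakSet:
    out = []
    names = list(genome.chrom_names)
    for _ in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        L = genome.length(chrom)
        length = int(rng.integers(1, min(max_len, L) + 1))
        start = int(rng.integers(0, L - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return PeakSet(out)


def majority_overlap_count_oracle(
    target: PeakSet, state: PeakSet, genome: GenomeModel
) -> int:
    """Per-base oracle for the >50% summed-overlap counting rule."""
    masks = mask_of(state, genome)
    n = 0
    for iv in target:
        covered = int(masks[iv.chrom][iv.start : iv.end].sum())
        if 2 * covered > iv.length:
            n += 1
    return n
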