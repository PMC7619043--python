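"""Genomic interval model, BED I/O, and interval-set arithmetic.

All coordinates are BED-convention 0-based half-open ``[start, end)``.
GWAS/eQTL tables use 1-based SNP positions; those are converted at
ingestion (``pos - 1`` is the 0-based coordinate of the variant base) so
that a single convention holds everywhere downstream.

Strand is ignored for all peak-level operations (ATAC-seq peaks are
unstranded); it is honoured only when building gene TSS windows.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BedParseError",
    "ValidationError",
    "GenomeModel",
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "normalize_chrom",
    "read_bed",
    "write_bed",
    "read_genes",
    "write_genes",
    "merge",
    "intersect",
    "subtract",
    "extend",
    "count_overlapping",
    "annotate_vs_genes",
    "assign_to_tss_windows",
]


class BedParseError(ValueError):
    """Raised when a BED/TSV line cannot be parsed."""


class ValidationError(ValueError):
    """Raised when an interval or genome invariant is violated."""


def normalize_chrom(name: str, style: str | None = None) -> str:
    """Normalise chromosome-name dialects ("chr1" vs "1").

    style=None leaves names untouched; "chr" forces the prefix; "plain"
    strips it.
    """
    if style is None:
        return name
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "plain":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chromosome-name style: {style!r}")


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths; bounds for clipping and simulation."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if not isinstance(length, int) or length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} absent from genome") from None

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, chrom_style: str | None = None) -> "GenomeModel":
        """Read a two-column (name, length) chrom-sizes file."""
        lengths: dict[str, int] = {}
        for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path} line {i}: expected 2 columns, got {len(fields)}")
            name = normalize_chrom(fields[0], chrom_style)
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(f"{path} line {i}: length {fields[1]!r} is not an integer") from None
            if name in lengths:
                raise ValidationError(f"{path} line {i}: duplicate chromosome {name!r}")
            lengths[name] = length
        return cls(lengths)

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chrom_lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValidationError(
                f"start >= end in {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class PeakSet:
    """A collection of :class:`GenomicInterval`, the pipeline's universal currency.

    ``merged`` flags sets known to be sorted and pairwise non-overlapping
    per chromosome (the postcondition of :func:`merge`).
    """

    __slots__ = ("intervals", "label", "merged", "_arrays")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        for iv in self.intervals:
            if not isinstance(iv, GenomicInterval):
                raise TypeError(f"expected GenomicInterval, got {type(iv).__name__}")
        self.label = label
        self.merged = merged
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<PeakSet{lab} n={len(self)}>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [(iv.chrom, iv.start, iv.end) for iv in self.intervals] == [
            (iv.chrom, iv.start, iv.end) for iv in other.intervals
        ]

    @property
    def total_length(self) -> int:
        """Sum of interval lengths (bases are counted once only if merged)."""
        return sum(iv.length for iv in self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays sorted by (start, end)."""
        if self._arrays is None:
            grouped: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
            arrays = {}
            for chrom, pairs in grouped.items():
                pairs.sort()
                arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
                arrays[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
            self._arrays = arrays
        return self._arrays

    # thin method aliases onto the module-level operations
    def merge(self, gap: int = 0) -> "PeakSet":
        return merge(self, gap=gap)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS and body; strand matters only for TSS windows."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValidationError(
                f"gene {self.gene_id}: TSS {self.tss} outside body "
                f"[{self.body.start},{self.body.end})"
            )

    def tss_window(self, upstream: int, downstream: int) -> tuple[int, int]:
        """Strand-aware promoter window on the genomic axis, clipped at 0."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream, self.tss + upstream
        return max(0, lo), hi


# ---------------------------------------------------------------------------
# BED / TSV I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(
    path: str | Path,
    label: str | None = None,
    chrom_style: str | None = None,
) -> PeakSet:
    """Read BED3/BED5 into a PeakSet, preserving file order.

    Lines starting with '#', 'track' or 'browser' are skipped; every other
    non-blank line must have >= 3 tab/whitespace-delimited columns.
    """
    intervals: list[GenomicInterval] = []
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise BedParseError(f"{path} line {i}: expected >=3 columns, got {len(fields)}")
        chrom = normalize_chrom(fields[0], chrom_style)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError(f"{path} line {i}: non-integer coordinates {fields[1:3]}") from None
        if start < 0:
            raise BedParseError(f"{path} line {i}: negative start {start}")
        name = fields[3] if len(fields) > 3 else None
        score: float | None = None
        if len(fields) > 4:
            try:
                score = float(fields[4])
            except ValueError:
                raise BedParseError(f"{path} line {i}: non-numeric score {fields[4]!r}") from None
        try:
            intervals.append(GenomicInterval(chrom, start, end, name=name, score=score))
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from None
    return PeakSet(intervals, label=label if label is not None else Path(path).stem)


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED3, or BED5 if any interval carries a name or score."""
    five = any(iv.name is not None or iv.score is not None for iv in peaks)
    with open(path, "w") as fh:
        for iv in peaks:
            if five:
                name = iv.name if iv.name is not None else "."
                score = _format_score(iv.score) if iv.score is not None else "0"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes(path: str | Path, chrom_style: str | None = None) -> list[GeneModel]:
    """Read a minimal gene TSV: gene_id, chrom, strand, tss, body_start, body_end."""
    genes: list[GeneModel] = []
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("gene_id"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            raise BedParseError(f"{path} line {i}: expected 6 columns, got {len(fields)}")
        gene_id, chrom, strand = fields[0], normalize_chrom(fields[1], chrom_style), fields[2]
        try:
            tss, b0, b1 = int(fields[3]), int(fields[4]), int(fields[5])
        except ValueError:
            raise BedParseError(f"{path} line {i}: non-integer coordinates") from None
        genes.append(GeneModel(gene_id, chrom, strand, tss, GenomicInterval(chrom, b0, b1)))
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tbody_start\tbody_end\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.body.start}\t{g.body.end}\n")


# ---------------------------------------------------------------------------
# Set arithmetic
# ---------------------------------------------------------------------------


def _merge_arrays(starts: np.ndarray, ends: np.ndarray, gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Sweep-merge sorted intervals; joins pairs separated by <= gap bases."""
    if starts.size == 0:
        return starts, ends
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + gap:
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge(a: PeakSet, gap: int = 0, label: str | None = None) -> PeakSet:
    """Minimal sorted interval set covering the same bases.

    With gap=0, bookended intervals ([a,b),[b,c)) are joined, matching
    bedtools-merge semantics; gap>0 additionally joins intervals separated
    by at most ``gap`` bases.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: list[GenomicInterval] = []
    arrays = a.by_chrom()
    for chrom in sorted(arrays):
        s, e = _merge_arrays(*arrays[chrom], gap)
        out.extend(GenomicInterval(chrom, int(x), int(y)) for x, y in zip(s, e))
    return PeakSet(out, label=label if label is not None else a.label, merged=True)


def intersect(a: PeakSet, b: PeakSet, label: str = "") -> PeakSet:
    """Exactly the bases present in both sets (base-level intersection)."""
    am, bm = merge(a), merge(b)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am.by_chrom()) & set(bm.by_chrom())):
        a_s, a_e = am.by_chrom()[chrom]
        b_s, b_e = bm.by_chrom()[chrom]
        i = j = 0
        while i < len(a_s) and j < len(b_s):
            lo = max(a_s[i], b_s[j])
            hi = min(a_e[i], b_e[j])
            if lo < hi:
                out.append(GenomicInterval(chrom, int(lo), int(hi)))
            if a_e[i] < b_e[j]:
                i += 1
            else:
                j += 1
    return PeakSet(out, label=label, merged=True)


def subtract(a: PeakSet, blacklist: PeakSet, mode: str = "clip") -> PeakSet:
    """Remove blacklist overlap from ``a``.

    mode="drop_if_touch" removes any a-interval overlapping the blacklist
    by >= 1 bp (the ENCODE-blacklist exclusion rule); mode="clip" removes
    only the overlapped bases, possibly splitting intervals.
    """
    if mode not in ("drop_if_touch", "clip"):
        raise ValueError(f"unknown subtract mode {mode!r}")
    bm = merge(blacklist)
    b_arrays = bm.by_chrom()
    if mode == "drop_if_touch":
        kept = []
        for iv in a:
            if iv.chrom not in b_arrays:
                kept.append(iv)
                continue
            b_s, b_e = b_arrays[iv.chrom]
            j = np.searchsorted(b_e, iv.start, side="right")
            if j < len(b_s) and b_s[j] < iv.end:
                continue
            kept.append(iv)
        return PeakSet(kept, label=a.label, merged=a.merged)
    out: list[GenomicInterval] = []
    for iv in a:
        if iv.chrom not in b_arrays:
            out.append(iv)
            continue
        b_s, b_e = b_arrays[iv.chrom]
        lo = int(np.searchsorted(b_e, iv.start, side="right"))
        hi = int(np.searchsorted(b_s, iv.end, side="left"))
        cursor = iv.start
        for k in range(lo, hi):
            if b_s[k] > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, int(b_s[k]), name=iv.name, score=iv.score))
            cursor = max(cursor, int(b_e[k]))
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, name=iv.name, score=iv.score))
    return PeakSet(out, label=a.label)


def extend(a: PeakSet, flank: int, genome: GenomeModel) -> PeakSet:
    """Expand every interval by ``flank`` bp on each side, clip to the
    chromosome, and re-merge."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for iv in a:
        length = genome.length(iv.chrom)
        out.append(
            GenomicInterval(
                iv.chrom, max(0, iv.start - flank), min(length, iv.end + flank),
                name=iv.name, score=iv.score,
            )
        )
    return merge(PeakSet(out, label=a.label))


def _hits(
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
    min_bp: int,
) -> np.ndarray:
    """For each a-interval: does any single b-interval overlap it by >= min_bp?

    b intervals are sorted by start internally; a cumulative-max of ends
    handles non-merged b sets.
    """
    order = np.argsort(b_starts, kind="stable")
    bs, be = b_starts[order], b_ends[order]
    cummax_be = np.maximum.accumulate(be)
    hits = np.zeros(a_starts.size, dtype=bool)
    for k in range(a_starts.size):
        s, e = a_starts[k], a_ends[k]
        lo = int(np.searchsorted(cummax_be, s, side="right"))
        hi = int(np.searchsorted(bs, e, side="left"))
        if lo >= hi:
            continue
        ov = np.minimum(e, be[lo:hi]) - np.maximum(s, bs[lo:hi])
        if (ov >= min_bp).any():
            hits[k] = True
    return hits


def _hit_flags(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean flag per a-interval (in a.intervals order): overlaps b by >= min_bp."""
    flags = np.zeros(len(a), dtype=bool)
    b_arrays = b.by_chrom()
    by_chrom_idx: dict[str, list[int]] = {}
    for idx, iv in enumerate(a):
        by_chrom_idx.setdefault(iv.chrom, []).append(idx)
    for chrom, idxs in by_chrom_idx.items():
        if chrom not in b_arrays:
            continue
        s = np.array([a[i].start for i in idxs], dtype=np.int64)
        e = np.array([a[i].end for i in idxs], dtype=np.int64)
        h = _hits(s, e, *b_arrays[chrom], min_bp)
        for i, flag in zip(idxs, h):
            flags[i] = flag
    return flags


def count_overlapping(a: PeakSet, b: PeakSet, min_bp: int = 1) -> tuple[int, int, int]:
    """Symmetric peak-overlap counts and the conservative Venn overlap.

    Returns (n_a_hit, n_b_hit, venn_overlap) where n_a_hit is the number of
    a-peaks overlapping any single b-peak by >= min_bp (and vice versa) and
    venn_overlap = min(n_a_hit, n_b_hit) — the "minimum number of
    overlapping peaks" convention used for Venn diagrams of peak sets.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    n_a = int(_hit_flags(a, b, min_bp).sum())
    n_b = int(_hit_flags(b, a, min_bp).sum())
    return n_a, n_b, min(n_a, n_b)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def annotate_vs_genes(
    a: PeakSet,
    genes: Sequence[GeneModel],
    tss_window: int = 5000,
) -> tuple[list[str], dict[str, float]]:
    """Label each peak TSS-proximal / gene body / distal (priority order).

    TSS-proximal means any-overlap with a symmetric +/- ``tss_window``
    window around any TSS (strand-ignored); gene body means >= 1 bp overlap
    with any gene body. Returns per-peak labels (input order) and the
    fraction of peaks per category.
    """
    if tss_window <= 0:
        raise ValueError("tss_window must be > 0")
    tss_set = PeakSet(
        [
            GenomicInterval(g.chrom, max(0, g.tss - tss_window), g.tss + tss_window)
            for g in genes
        ]
    )
    body_set = PeakSet([g.body for g in genes])
    near_tss = _hit_flags(a, tss_set) if len(tss_set) else np.zeros(len(a), bool)
    in_body = _hit_flags(a, body_set) if len(body_set) else np.zeros(len(a), bool)
    labels = [
        "tss_proximal" if t else ("gene_body" if b else "distal")
        for t, b in zip(near_tss, in_body)
    ]
    counts = Counter(labels)
    n = max(len(a), 1)
    summary = {
        cat: counts.get(cat, 0) / n for cat in ("tss_proximal", "gene_body", "distal")
    }
    return labels, summary


def assign_to_tss_windows(
    a: PeakSet,
    genes: Sequence[GeneModel],
    upstream: int = 30_000,
    downstream: int = 100,
) -> list[list[str]]:
    """Map each peak to every gene whose strand-aware TSS window it overlaps.

    The window is [tss - upstream, tss + downstream) on the + strand and
    its mirror image [tss - downstream, tss + upstream) on the - strand;
    >= 1 bp overlap assigns the peak to the gene.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        lo, hi = g.tss_window(upstream, downstream)
        if lo < hi:
            windows.setdefault(g.chrom, []).append((lo, hi, g.gene_id))
    for chrom in windows:
        windows[chrom].sort()
    result: list[list[str]] = []
    for iv in a:
        assigned: list[str] = []
        for lo, hi, gene_id in windows.get(iv.chrom, ()):
            if lo < iv.end and iv.start < hi:
                assigned.append(gene_id)
        result.append(sorted(assigned))
    return result
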