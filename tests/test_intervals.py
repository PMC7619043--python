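"""Interval model, BED I/O and set arithmetic against per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocrpipe.intervals import (
    BedParseError,
    GenomeModel,
    GenomicInterval,
    GeneModel,
    PeakSet,
    ValidationError,
    annotate_vs_genes,
    assign_to_tss_windows,
    count_overlapping,
    extend,
    intersect,
    merge,
    read_bed,
    read_genes,
    subtract,
    write_bed,
    write_genes,
)
from helpers import mask_of, peaks_of, random_peaks


def P(*triples, **kw):
    return PeakSet([GenomicInterval(c, s, e) for c, s, e in triples], **kw)


class TestBedIO:
    def test_three_column_line_maps_directly(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\n")
        ps = read_bed(bed)
        assert len(ps) == 1
        iv = ps[0]
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 200)

    def test_empty_file_gives_empty_set(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert len(read_bed(bed)) == 0

    def test_inverted_coordinates_rejected_with_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t20\nchr1\t200\t100\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_bed(bed)

    def test_malformed_line_named(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t20\nchr1\tten\t20\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(bed)

    def test_comment_and_track_lines_skipped(self, tmp_path):
        bed = tmp_path / "c.bed"
        bed.write_text("# header\ntrack name=x\nchr1\t0\t5\n")
        assert len(read_bed(bed)) == 1

    @pytest.mark.parametrize(
        "content",
        [
            "chr1\t100\t200\nchr2\t0\t50\n",
            "chr1\t100\t200\tpeak1\t100\nchr1\t300\t400\tpeak2\t5\n",
        ],
        ids=["bed3", "bed5"],
    )
    def test_round_trip_bit_exact(self, tmp_path, content):
        src = tmp_path / "in.bed"
        src.write_text(content)
        out = tmp_path / "out.bed"
        write_bed(read_bed(src), out)
        assert out.read_text() == content

    def test_chrom_style_normalisation(self, tmp_path):
        bed = tmp_path / "n.bed"
        bed.write_text("1\t0\t10\nchr2\t0\t10\n")
        ps = read_bed(bed, chrom_style="chr")
        assert [iv.chrom for iv in ps] == ["chr1", "chr2"]

    def test_gene_tsv_round_trip(self, tmp_path):
        genes = [
            GeneModel("G1", "chr1", "+", 100, GenomicInterval("chr1", 100, 500)),
            GeneModel("G2", "chr1", "-", 899, GenomicInterval("chr1", 400, 900)),
        ]
        path = tmp_path / "genes.tsv"
        write_genes(genes, path)
        assert read_genes(path) == genes


class TestMerge:
    @pytest.mark.parametrize(
        "triples,gap,expected",
        [
            ([("c", 100, 200), ("c", 150, 250)], 0, [(100, 250)]),
            ([("c", 100, 200), ("c", 200, 300)], 0, [(100, 300)]),  # bookended join
            ([("c", 0, 10), ("c", 20, 30)], 5, [(0, 10), (20, 30)]),  # distance 10 > 5
            ([("c", 0, 10), ("c", 15, 30)], 5, [(0, 30)]),
        ],
    )
    def test_examples(self, triples, gap, expected):
        got = [(iv.start, iv.end) for iv in merge(P(*triples), gap=gap)]
        assert got == expected

    def test_idempotent(self, rng):
        g = GenomeModel({"chrA": 5_000})
        ps = random_peaks(rng, g, 40)
        m = merge(ps)
        assert merge(m) == m

    def test_genome_invariant_intervals_nonoverlapping_sorted(self, rng):
        g = GenomeModel({"chrA": 5_000, "chrB": 1_000})
        m = merge(random_peaks(rng, g, 60))
        for chrom, (s, e) in m.by_chrom().items():
            assert np.all(s[1:] > e[:-1])  # gaps between merged intervals


class TestIntersectSubtractExtend:
    def test_intersect_examples(self):
        assert intersect(P(("c", 100, 200)), P(("c", 150, 250))) == P(("c", 150, 200))
        assert len(intersect(P(("c", 0, 10)), P(("c", 20, 30)))) == 0

    def test_intersect_self_is_merge(self, rng):
        g = GenomeModel({"chrA": 3_000})
        a = random_peaks(rng, g, 30)
        assert intersect(a, a) == merge(a)

    def test_subtract_modes(self):
        a, bl = P(("c", 0, 100)), P(("c", 50, 60))
        assert len(subtract(a, bl, mode="drop_if_touch")) == 0
        assert subtract(a, bl, mode="clip") == P(("c", 0, 50), ("c", 60, 100))
        assert subtract(a, PeakSet(), mode="clip") == a

    def test_subtract_self_clip_is_empty(self, rng):
        g = GenomeModel({"chrA": 3_000})
        a = random_peaks(rng, g, 30)
        assert len(subtract(a, a, mode="clip")) == 0

    def test_extend_examples(self):
        g = GenomeModel({"c": 10_000})
        assert extend(P(("c", 1000, 2000)), 500, g) == P(("c", 500, 2500))
        g2 = GenomeModel({"c": 400})
        assert extend(P(("c", 100, 200)), 500, g2) == P(("c", 0, 400))
        a = P(("c", 5, 10), ("c", 8, 20))
        assert extend(a, 0, g) == merge(a)

    def test_extend_unknown_chromosome_errors(self):
        with pytest.raises(ValidationError, match="absent"):
            extend(P(("nope", 0, 10)), 5, GenomeModel({"c": 100}))

    def test_extend_already_clipped(self, rng):
        g = GenomeModel({"chrA": 2_000})
        ext = extend(random_peaks(rng, g, 25), 300, g)
        for iv in ext:
            assert 0 <= iv.start < iv.end <= g.length(iv.chrom)


class TestRandomOracle:
    """merge/intersect/subtract/extend vs the per-base boolean-mask oracle."""

    def test_agrees_with_mask_oracle(self):
        rng = np.random.default_rng(7)
        g = GenomeModel({"chrA": 1_500, "chrB": 800})
        for _ in range(300):
            a = random_peaks(rng, g, int(rng.integers(0, 15)))
            b = random_peaks(rng, g, int(rng.integers(0, 15)))
            ma, mb = mask_of(a, g), mask_of(b, g)
            assert merge(a) == peaks_of(ma)
            assert intersect(a, b) == peaks_of({c: ma[c] & mb[c] for c in ma})
            assert merge(subtract(a, b, mode="clip")) == peaks_of(
                {c: ma[c] & ~mb[c] for c in ma}
            )
            flank = int(rng.integers(0, 50))
            ext_mask = {c: np.zeros_like(m) for c, m in ma.items()}
            for iv in a:
                ext_mask[iv.chrom][max(0, iv.start - flank) : iv.end + flank] = True
            assert extend(a, flank, g) == peaks_of(ext_mask)


class TestCountOverlapping:
    def test_min_convention(self):
        a = P(("c", 0, 100))
        b = P(("c", 50, 60), ("c", 70, 80))
        assert count_overlapping(a, b) == (1, 2, 1)

    def test_disjoint_and_identical(self):
        a = P(("c", 0, 10), ("c", 20, 30))
        assert count_overlapping(a, P(("c", 50, 60))) == (0, 0, 0)
        assert count_overlapping(a, a) == (2, 2, 2)

    def test_min_bp_threshold(self):
        a = P(("c", 0, 100))
        b = P(("c", 95, 200))  # 5 bp overlap
        assert count_overlapping(a, b, min_bp=5) == (1, 1, 1)
        assert count_overlapping(a, b, min_bp=6) == (0, 0, 0)


class TestGeneAnnotation:
    GENES = [
        GeneModel("G+", "c", "+", 50_000, GenomicInterval("c", 50_000, 70_000)),
        GeneModel("G-", "c", "-", 150_000, GenomicInterval("c", 130_001, 150_001)),
    ]

    def test_category_priority(self):
        peaks = P(("c", 49_900, 50_100), ("c", 60_000, 60_500), ("d", 0, 100))
        labels, summary = annotate_vs_genes(peaks, self.GENES, tss_window=5000)
        assert labels == ["tss_proximal", "gene_body", "distal"]
        assert summary["tss_proximal"] == pytest.approx(1 / 3)

    def test_plus_strand_window_assignment(self):
        # 20000-25000 bp upstream of the + TSS lies inside the 30 kb window
        hits = assign_to_tss_windows(P(("c", 25_000, 26_000)), self.GENES, 30_000, 100)
        assert hits == [["G+"]]

    def test_minus_strand_window_is_mirrored(self):
        # mirrored window on the genomic axis: [tss - 100, tss + 30000)
        hits = assign_to_tss_windows(P(("c", 160_000, 161_000)), self.GENES, 30_000, 100)
        assert hits == [["G-"]]
        # peak wholly 5' of the - strand TSS (genomically left) is outside
        assert assign_to_tss_windows(P(("c", 140_000, 149_000)), self.GENES, 30_000, 100) == [[]]

    def test_minus_strand_window_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        gene = self.GENES[1]
        window = np.zeros(300_000, dtype=bool)
        window[gene.tss - 100 : gene.tss + 30_000] = True  # mirrored by hand
        for _ in range(200):
            s = int(rng.integers(0, 299_000))
            e = s + int(rng.integers(1, 1_000))
            got = assign_to_tss_windows(P(("c", s, e)), [gene], 30_000, 100)[0]
            assert (got == ["G-"]) == bool(window[s:e].any())

    def test_peak_spanning_two_windows_gets_both(self):
        genes = [
            GeneModel("A", "c", "+", 10_000, GenomicInterval("c", 10_000, 12_000)),
            GeneModel("B", "c", "+", 11_000, GenomicInterval("c", 11_000, 13_000)),
        ]
        hits = assign_to_tss_windows(P(("c", 9_000, 9_500)), genes, 30_000, 100)
        assert hits == [["A", "B"]]


class TestProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=0, max_size=12
        ),
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=0, max_size=12
        ),
    )
    def test_intersect_commutative_and_bounded(self, xs, ys):
        g = GenomeModel({"c": 1_000})
        a = P(*[("c", s, s + l) for s, l in xs])
        b = P(*[("c", s, s + l) for s, l in ys])
        ab, ba = intersect(a, b), intersect(b, a)
        assert ab == ba
        assert ab.total_length <= min(merge(a).total_length, merge(b).total_length)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=1, max_size=12
        )
    )
    def test_merge_preserves_covered_bases(self, xs):
        g = GenomeModel({"c": 1_000})
        a = P(*[("c", s, s + l) for s, l in xs])
        assert merge(a) == peaks_of(mask_of(a, g))
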