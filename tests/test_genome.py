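"""Annotation parsing, exome binning, read counting and BED12 output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meriphmm import (BinCounts, GeneModel, PeakRegion, bin_transcript,
                      count_reads, load_annotation, read_count_table,
                      write_bed, write_count_table)
from meriphmm.genome import AnnotationError


def make_bam(tmp_path, reads, chrom="chr1", chrom_len=10000):
    """Build a tiny coordinate-sorted indexed BAM from (start, cigar) pairs."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    path = str(tmp_path / "reads.bam")
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, (start, cigar, *flags) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            a.query_sequence = "A" * sum(
                n for n, op in _cigar_query_lengths(cigar))
            a.mapping_quality = 30
            a.flag = flags[0] if flags else 0
            out.write(a)
    pysam.index(path)
    return path


def _cigar_query_lengths(cigar):
    import re
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MIS=X":
            yield int(n), op


class TestBed12Parsing:
    def test_two_block_line(self, tmp_path):
        line = ("chr1\t100\t400\tgeneA\t0\t+\t100\t400\t0\t2\t"
                "100,100\t0,200\n")
        path = tmp_path / "genes.bed"
        path.write_text(line)
        genes = load_annotation(path)
        assert len(genes) == 1
        g = genes[0]
        assert g.exons == [(100, 200), (300, 400)]
        assert g.transcript_length == 200

    def test_empty_file_yields_empty_collection(self, tmp_path, caplog):
        path = tmp_path / "empty.bed"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert load_annotation(path) == []
        assert "no records" in caplog.text

    def test_malformed_line_names_position(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t400\tg\t0\t+\t100\t400\t0\t2\t100\t0,200\n")
        with pytest.raises(AnnotationError, match="line 1"):
            load_annotation(path)


class TestGtfParsing:
    def test_one_based_closed_converted(self, tmp_path):
        gtf = ('chr1\tsrc\texon\t101\t200\t.\t+\t.\t'
               'gene_id "g1"; transcript_id "t1";\n')
        path = tmp_path / "genes.gtf"
        path.write_text(gtf)
        genes = load_annotation(path)
        assert genes[0].exons == [(100, 200)]

    def test_exons_grouped_by_transcript(self, tmp_path):
        gtf = "".join(
            f'chr1\tsrc\texon\t{s}\t{e}\t.\t-\t.\t'
            f'gene_id "g1"; transcript_id "{t}";\n'
            for t, s, e in [("t1", 101, 200), ("t2", 501, 600),
                            ("t1", 301, 400)])
        path = tmp_path / "genes.gtf"
        path.write_text(gtf)
        genes = {g.gene_id: g for g in load_annotation(path)}
        assert genes["t1"].exons == [(100, 200), (300, 400)]
        assert genes["t2"].exons == [(500, 600)]
        assert genes["t1"].strand == "-"


class TestGeneModel:
    def test_rejects_overlapping_exons(self):
        with pytest.raises(AnnotationError):
            GeneModel("g", "chr1", "+", exons=[(0, 100), (50, 150)])

    def test_rejects_zero_exons(self):
        with pytest.raises(AnnotationError):
            GeneModel("g", "chr1", "+", exons=[])


class TestBinTranscript:
    def test_bins_aligned_with_exons(self, two_exon_gene):
        track = bin_transcript(two_exon_gene, 100)
        assert track.n_bins == 2
        assert track.bin_to_blocks[0] == [(100, 200)]
        assert track.bin_to_blocks[1] == [(300, 400)]

    def test_remainder_kept_as_short_last_bin(self):
        gene = GeneModel("g", "chr1", "+", exons=[(0, 250)])
        track = bin_transcript(gene, 100)
        lengths = [sum(e - s for s, e in blocks)
                   for blocks in track.bin_to_blocks]
        assert lengths == [100, 100, 50]

    def test_junction_spanning_bin_splits_into_blocks(self):
        gene = GeneModel("g", "chr1", "+", exons=[(0, 150), (250, 350)])
        track = bin_transcript(gene, 100)
        assert track.bin_to_blocks[1] == [(100, 150), (250, 300)]

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 120)),
                    min_size=1, max_size=6),
           st.integers(1, 130))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_blocks_conserve_exonic_bases(self, gaps_lengths, bin_size):
        # build disjoint exons from (gap, length) pairs
        exons, pos = [], 0
        for gap, length in gaps_lengths:
            start = pos + gap + 1
            exons.append((start, start + length))
            pos = start + length
        gene = GeneModel("g", "chr1", "+", exons=exons)
        track = bin_transcript(gene, bin_size)
        flat = [b for blocks in track.bin_to_blocks for b in blocks]
        # merging adjacent blocks must reproduce the exon set exactly
        merged = [list(flat[0])]
        for s, e in flat[1:]:
            assert s >= merged[-1][1]
            if s == merged[-1][1]:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        assert [tuple(b) for b in merged] == exons
        assert sum(e - s for s, e in flat) == gene.transcript_length


class TestCountReads:
    def test_midpoint_assignment(self, tmp_path, two_exon_gene):
        # 3 reads with midpoints in bin 1, none elsewhere
        bam = make_bam(tmp_path, [(100, "50M"), (110, "50M"), (120, "50M")])
        track = bin_transcript(two_exon_gene, 100)
        np.testing.assert_array_equal(count_reads(bam, track), [3, 0])

    def test_intron_only_read_ignored(self, tmp_path, two_exon_gene):
        bam = make_bam(tmp_path, [(210, "50M")])
        track = bin_transcript(two_exon_gene, 100)
        np.testing.assert_array_equal(count_reads(bam, track), [0, 0])

    def test_junction_read_counted_by_transcript_midpoint(self, tmp_path):
        gene = GeneModel("g", "chr1", "+", exons=[(0, 150), (250, 350)])
        track = bin_transcript(gene, 100)
        # spliced read: 50M100N50M from 100 -> transcript span [100, 200),
        # midpoint 149 -> bin index 1
        bam = make_bam(tmp_path, [(100, "50M100N50M")])
        np.testing.assert_array_equal(count_reads(bam, track), [0, 1, 0])

    def test_secondary_and_supplementary_excluded(self, tmp_path,
                                                  two_exon_gene):
        bam = make_bam(tmp_path, [(100, "50M", 0), (100, "50M", 0x100),
                                  (100, "50M", 0x800)])
        track = bin_transcript(two_exon_gene, 100)
        assert count_reads(bam, track).sum() == 1

    def test_absent_chrom_gives_zero_counts(self, tmp_path, caplog):
        gene = GeneModel("g", "chrX", "+", exons=[(0, 200)])
        track = bin_transcript(gene, 100)
        bam = make_bam(tmp_path, [(100, "50M")])  # header has chr1 only
        with caplog.at_level("WARNING"):
            counts = count_reads(bam, track)
        assert counts.sum() == 0 and "chrX" in caplog.text

    def test_total_counts_match_counted_alignments(self, tmp_path):
        rng = np.random.default_rng(0)
        gene = GeneModel("g", "chr1", "+", exons=[(0, 300), (400, 700)])
        track = bin_transcript(gene, 73)
        starts = rng.integers(0, 800, size=50)
        bam = make_bam(tmp_path, [(int(s), "40M") for s in starts])
        counts = count_reads(bam, track)
        # every read overlapping an exon is counted exactly once
        expected = sum(
            1 for s in starts
            if any(max(s, es) < min(s + 40, ee) for es, ee in gene.exons))
        assert counts.sum() == expected


class TestBedOutput:
    def _peak(self, blocks, score=1.5):
        return PeakRegion(gene_id="g1", bin_start=0, bin_end=len(blocks),
                          peak_score=score, chrom="chr1", strand="+",
                          blocks=blocks, p_value=0.01, fdr=0.02)

    def test_single_block_fields(self, tmp_path):
        path = tmp_path / "peaks.bed"
        write_bed([self._peak([(100, 200)])], path)
        f = path.read_text().strip().split("\t")
        assert (f[1], f[2], f[9], f[10], f[11]) == \
            ("100", "200", "1", "100", "0")
        assert f[4] == "150"  # 100 * peak_score, capped at 1000

    def test_two_block_encoding(self, tmp_path):
        path = tmp_path / "peaks.bed"
        write_bed([self._peak([(100, 150), (250, 300)])], path)
        f = path.read_text().strip().split("\t")
        assert (f[9], f[10], f[11]) == ("2", "50,50", "0,150")

    def test_empty_peak_set_writes_empty_file(self, tmp_path):
        path = tmp_path / "peaks.bed"
        write_bed([], path)
        assert path.read_text() == ""

    def test_peak_without_blocks_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_bed([self._peak([])], tmp_path / "peaks.bed")

    def test_bed12_round_trip_recovers_blocks(self, tmp_path):
        peaks = [self._peak([(100, 150), (250, 300), (320, 420)]),
                 self._peak([(5, 10)])]
        path = tmp_path / "peaks.bed"
        write_bed(peaks, path)
        models = load_annotation(path, format="bed12")
        for pk, model in zip(peaks, models):
            assert model.exons == pk.blocks
            assert (model.chrom, model.strand) == (pk.chrom, pk.strand)


class TestCountTable:
    def test_round_trip(self, tmp_path):
        sets = [BinCounts("gA", [1, 2, 3], [4, 5, 6]),
                BinCounts("gB", [0, 7], [1, 0])]
        path = tmp_path / "counts.tsv"
        write_count_table(sets, path, header_comments=["seed: 42"])
        assert path.read_text().startswith("# seed: 42")
        back = read_count_table(path)
        assert [c.gene_id for c in back] == ["gA", "gB"]
        for a, b in zip(sets, back):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.y, b.y)

    def test_non_consecutive_bins_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tbin\tip\tcontrol\ngA\t0\t1\t1\ngA\t2\t1\t1\n")
        with pytest.raises(ValueError, match="consecutive"):
            read_count_table(path)
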