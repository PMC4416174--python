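"""Annotation, binning, read counting and BED12 output.

Peak calling is done on the *exome projection* of each gene: the exons are
concatenated into a single transcript coordinate system, which is tiled
with fixed-width bins (the read length, ~100 nt).  Working on connected
exons sidesteps isoform-assignment ambiguity and lets a peak span exon
junctions; called peaks are projected back to genomic blocks and written
as BED12.

All internal coordinates are 0-based half-open.  GTF (1-based closed) is
converted at parse time; BED is native.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed annotation record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene's exon structure — the coordinate system peaks are projected
    through.

    ``exons`` are 0-based half-open genomic intervals, sorted ascending and
    non-overlapping; ``transcript_length`` is the total exonic length.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s or s < prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: exons must be sorted and disjoint")
            prev_end = e
        if self.strand not in ("+", "-"):
            self.strand = "+"

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Project a genomic position into transcript coordinates, or None
        if it falls outside the exon model (e.g. in an intron)."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return offset + (gpos - s)
            offset += e - s
        return None

    def transcript_to_blocks(self, tstart: int, tend: int) -> list[tuple[int, int]]:
        """Genomic blocks covered by the transcript interval [tstart, tend)."""
        if not 0 <= tstart < tend <= self.transcript_length:
            raise ValueError("transcript interval out of range")
        blocks = []
        offset = 0
        for s, e in self.exons:
            length = e - s
            lo, hi = max(tstart, offset), min(tend, offset + length)
            if lo < hi:
                blocks.append((s + lo - offset, s + hi - offset))
            offset += length
        return blocks


@dataclass
class BinTrack:
    """Tiling of a gene's concatenated exons into N bins of width L.

    Bins 1..N-1 have length ``bin_size``; the last bin keeps the remainder
    (kept even if short, preserving 3'-end signal).  ``bin_to_blocks[n]``
    lists the genomic intervals bin ``n`` covers (two or more when the bin
    spans an exon junction).
    """

    gene_id: str
    chrom: str
    strand: str
    bin_size: int
    n_bins: int
    bin_to_blocks: list[list[tuple[int, int]]]
    gene: GeneModel = field(repr=False, default=None)


@dataclass
class BinCounts:
    """Per-bin read counts: ``x`` from the IP sample, ``y`` from the
    control; ``t = x + y`` is the combined depth the binomial emission
    conditions on."""

    gene_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("counts must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return self.x + self.y

    def __len__(self) -> int:
        return len(self.x)


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------

def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise AnnotationError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        n_blocks = int(f[9])
        sizes = [int(v) for v in f[10].rstrip(",").split(",")]
        starts = [int(v) for v in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(
            f"line {lineno}: blockCount={n_blocks} does not match block lists")
    exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
    return GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)


def load_annotation(path, format: str = None) -> list[GeneModel]:
    """Read a GTF or BED12 annotation into one :class:`GeneModel` per
    transcript record.

    GTF exon features are grouped by ``transcript_id`` (ensembl dialect)
    and converted from 1-based closed to 0-based half-open coordinates.
    Records without exons are skipped with a warning; an empty file yields
    an empty list.
    """
    path = str(path)
    if format is None:
        low = path.lower()
        format = "bed12" if low.endswith((".bed", ".bed12")) else "gtf"
    if format == "bed12":
        genes = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_parse_bed12_line(line, i))
        if not genes:
            logger.warning("no records parsed from %s", path)
        return genes
    if format != "gtf":
        raise ValueError(f"unknown annotation format: {format}")

    import pyranges  # deferred: slow import

    try:
        df = pyranges.read_gtf(path).df
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc
    if df.empty:
        logger.warning("no records parsed from %s", path)
        return []
    exons = df[df["Feature"] == "exon"]
    if exons.empty:
        logger.warning("GTF %s has no exon features", path)
        return []
    key = "transcript_id" if "transcript_id" in exons.columns else "gene_id"
    genes = []
    for tid, grp in exons.groupby(key, sort=True):
        grp = grp.sort_values("Start")
        ivals = list(zip(grp["Start"].astype(int), grp["End"].astype(int)))
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:  # collapse duplicate/touching exon records
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        genes.append(GeneModel(
            gene_id=str(tid),
            chrom=str(grp["Chromosome"].iloc[0]),
            strand=str(grp["Strand"].iloc[0]),
            exons=[(s, e) for s, e in merged],
        ))
    return genes


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_transcript(gene: GeneModel, bin_size: int) -> BinTrack:
    """Tile the concatenated exons with ``N = ceil(length / bin_size)``
    bins and map every bin to its genomic blocks."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    length = gene.transcript_length
    n_bins = -(-length // bin_size)
    blocks = []
    for n in range(n_bins):
        tstart = n * bin_size
        tend = min(tstart + bin_size, length)
        blocks.append(gene.transcript_to_blocks(tstart, tend))
    return BinTrack(gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                    bin_size=bin_size, n_bins=n_bins, bin_to_blocks=blocks,
                    gene=gene)


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def count_reads(bam, track: BinTrack) -> np.ndarray:
    """Count primary mapped alignments per bin by transcript-coordinate
    midpoint.

    Each alignment's start and last aligned base are projected through the
    exon model; the midpoint of the projected span picks the bin.
    Alignments entirely outside the exon model (e.g. intron-only) are
    ignored, as are secondary/supplementary and unmapped records.

    Parameters
    ----------
    bam : str or pysam.AlignmentFile
        Coordinate-sorted, indexed BAM.
    track : BinTrack

    Returns
    -------
    ndarray of int, one count per bin.
    """
    import pysam

    own = isinstance(bam, str)
    af = pysam.AlignmentFile(bam) if own else bam
    counts = np.zeros(track.n_bins, dtype=int)
    gene = track.gene
    try:
        if track.chrom not in af.references:
            logger.warning("chrom %s absent from BAM header; zero counts for %s",
                           track.chrom, track.gene_id)
            return counts
        span_start = gene.exons[0][0]
        span_end = gene.exons[-1][1]
        for aln in af.fetch(track.chrom, span_start, span_end):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            tstart = _first_exonic_tpos(gene, aln.reference_start,
                                        aln.reference_end)
            if tstart is None:
                continue
            tend = _last_exonic_tpos(gene, aln.reference_start,
                                     aln.reference_end)
            mid = (tstart + tend) // 2
            counts[min(mid // track.bin_size, track.n_bins - 1)] += 1
    finally:
        if own:
            af.close()
    return counts


def _first_exonic_tpos(gene: GeneModel, gstart: int, gend: int) -> int | None:
    offset = 0
    for s, e in gene.exons:
        lo, hi = max(gstart, s), min(gend, e)
        if lo < hi:
            return offset + (lo - s)
        offset += e - s
    return None


def _last_exonic_tpos(gene: GeneModel, gstart: int, gend: int) -> int | None:
    offset = gene.transcript_length
    for s, e in reversed(gene.exons):
        offset -= e - s
        lo, hi = max(gstart, s), min(gend, e)
        if lo < hi:
            return offset + (hi - 1 - s)
    return None


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def _bed_score(peak_score: float) -> int:
    return int(min(1000, max(0, round(100.0 * peak_score))))


def write_bed(peaks, path) -> None:
    """Write peak regions as BED12 (blocks encode exon-spanning structure;
    the score column is the PeakScore scaled into [0, 1000])."""
    with open(path, "w") as fh:
        for pk in peaks:
            if not pk.blocks:
                raise ValueError(f"peak on {pk.gene_id} has no genomic blocks")
            start = pk.blocks[0][0]
            end = pk.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in pk.blocks)
            rels = ",".join(str(s - start) for s, _ in pk.blocks)
            fh.write("\t".join(map(str, [
                pk.chrom, start, end, pk.gene_id, _bed_score(pk.peak_score),
                pk.strand, start, end, "0", len(pk.blocks), sizes, rels,
            ])) + "\n")


def write_peak_table(peaks, path) -> None:
    """Companion TSV carrying the exact scores and significance values."""
    import pandas as pd

    rows = [{
        "gene_id": pk.gene_id,
        "chrom": pk.chrom,
        "start": pk.blocks[0][0] if pk.blocks else pk.bin_start,
        "end": pk.blocks[-1][1] if pk.blocks else pk.bin_end,
        "strand": pk.strand,
        "n_bins": pk.bin_end - pk.bin_start,
        "peak_score": pk.peak_score,
        "p_value": pk.p_value,
        "fdr": pk.fdr,
    } for pk in peaks]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                "n_bins", "peak_score", "p_value", "fdr"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plain count tables (alignment-free input path)
# ---------------------------------------------------------------------------

def read_count_table(path) -> list[BinCounts]:
    """Read a tab-delimited per-bin count table (gene, bin, ip, control).

    Header and ``#`` comment lines are skipped; bins must be consecutive
    from 0 within each gene.  Gene order follows first appearance.
    """
    per_gene: dict[str, list[tuple[int, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "gene" or f[0] == "gene_id":
                continue
            if len(f) < 4:
                raise ValueError(f"line {i}: need 4 columns (gene, bin, ip, control)")
            gene, b, xi, yi = f[0], int(f[1]), int(f[2]), int(f[3])
            if gene not in per_gene:
                per_gene[gene] = []
                order.append(gene)
            per_gene[gene].append((b, xi, yi))
    out = []
    for gene in order:
        rows = sorted(per_gene[gene])
        if [b for b, _, _ in rows] != list(range(len(rows))):
            raise ValueError(f"gene {gene}: bins must be consecutive from 0")
        out.append(BinCounts(gene_id=gene,
                             x=np.array([x for _, x, _ in rows]),
                             y=np.array([y for _, _, y in rows])))
    return out


def write_count_table(count_sets, path, header_comments=()) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("gene\tbin\tip\tcontrol\n")
        for cs in count_sets:
            for b in range(len(cs)):
                fh.write(f"{cs.gene_id}\t{b}\t{cs.x[b]}\t{cs.y[b]}\n")
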