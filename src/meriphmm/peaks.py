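"""Peak regions: posterior log-odds scoring, Gaussian z-test, BH FDR.

Each bin is scored by the log posterior odds of the methylated over the
unmethylated state, ``PeakScore_n = ln[gamma(z_n=2) / gamma(z_n=1)]``.  A
candidate peak is a maximal run of bins decoded as methylated by Viterbi;
its score is the mean of its bins' PeakScores.  Treating the pooled
transcriptome-wide bin scores as a Gaussian reference, each region's mean
score is z-transformed and tested one-sided; Benjamini-Hochberg converts
the p-values into FDRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .hmm import METHYLATED

#: posterior clamp before taking log odds (saturated gammas)
GAMMA_CLAMP = 1e-10

DEFAULT_FDR_THRESHOLD = 0.025


@dataclass
class PeakRegion:
    """A maximal run of methylated bins with its score and significance."""

    gene_id: str
    bin_start: int
    bin_end: int          # half-open bin index range
    peak_score: float
    chrom: str = "."
    strand: str = "+"
    blocks: list[tuple[int, int]] = field(default_factory=list)
    z: float = np.nan
    p_value: float = np.nan
    fdr: float = np.nan


def bin_peak_scores(gamma: np.ndarray) -> np.ndarray:
    """Per-bin log posterior odds of methylation (gamma clamped to
    [1e-10, 1 - 1e-10] so saturated posteriors stay finite)."""
    g = np.clip(np.asarray(gamma, dtype=float), GAMMA_CLAMP, 1.0 - GAMMA_CLAMP)
    return np.log(g[:, 1]) - np.log(g[:, 0])


def _merge_adjacent(blocks):
    merged = []
    for s, e in blocks:
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def call_regions(path: np.ndarray, scores: np.ndarray, track=None,
                 gene_id: str = None) -> list[PeakRegion]:
    """Turn a Viterbi path into maximal methylated-run regions.

    Parameters
    ----------
    path : array of {1, 2}
        Viterbi state per bin.
    scores : array
        Per-bin PeakScores (same length); a region's score is the mean over
        its member bins.
    track : BinTrack, optional
        Supplies the genomic block projection; without it regions carry
        transcript bin indices only.
    """
    path = np.asarray(path)
    scores = np.asarray(scores, dtype=float)
    if path.shape != scores.shape:
        raise ValueError("path and scores must have the same length")
    if gene_id is None:
        gene_id = track.gene_id if track is not None else "."
    regions = []
    n = len(path)
    i = 0
    while i < n:
        if path[i] != METHYLATED:
            i += 1
            continue
        j = i
        while j < n and path[j] == METHYLATED:
            j += 1
        blocks = []
        if track is not None:
            for b in range(i, j):
                blocks.extend(track.bin_to_blocks[b])
            blocks = _merge_adjacent(blocks)
        regions.append(PeakRegion(
            gene_id=gene_id, bin_start=i, bin_end=j,
            peak_score=float(scores[i:j].mean()),
            chrom=track.chrom if track is not None else ".",
            strand=track.strand if track is not None else "+",
            blocks=blocks))
        i = j
    return regions


def test_significance(regions, all_bin_scores, use_region_sem: bool = False):
    """Attach z, one-sided p-value and BH FDR to each region.

    The Gaussian reference uses the mean and (sample, n-1) standard
    deviation of ``all_bin_scores`` pooled over every bin of every gene.
    ``use_region_sem=True`` divides sigma by sqrt(n_bins) per region (the
    sampling distribution of the region mean) instead of using the raw bin
    sigma; the raw reading is the default.
    """
    all_bin_scores = np.asarray(all_bin_scores, dtype=float)
    if all_bin_scores.size < 2:
        raise ValueError("need at least 2 bins to estimate the score spread")
    mu = float(all_bin_scores.mean())
    sigma = float(all_bin_scores.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate score distribution (sigma = 0)")
    regions = list(regions)
    if not regions:
        return regions
    for r in regions:
        s = sigma / np.sqrt(r.bin_end - r.bin_start) if use_region_sem else sigma
        r.z = (r.peak_score - mu) / s
        r.p_value = float(norm.sf(r.z))
    fdr = multipletests([r.p_value for r in regions], method="fdr_bh")[1]
    for r, q in zip(regions, fdr):
        r.fdr = float(q)
    return regions


def filter_peaks(regions, fdr_threshold: float = DEFAULT_FDR_THRESHOLD):
    """Keep regions with FDR strictly below the threshold (default 0.025)."""
    return [r for r in regions if r.fdr < fdr_threshold]
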