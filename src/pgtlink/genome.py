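"""Genome coordinate scaffolding: chromosome sizes, 1 Mb bin grids, GC tracks.

Coordinates are 1-based inclusive throughout the package (VCF convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BIN_SIZE = 1_000_000

# GRCh37/hg19 chromosome lengths (bp).
GENOME_HG19: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

# The target gene's core interval on Xp22.2 (GRCh37-like coordinates).
GENE_CHROM = "chrX"
GENE_START = 20_168_000
GENE_END = 20_285_000


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


def bin_grid(genome: dict[str, int] | None = None, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Tile every chromosome with fixed-width bins.

    The trailing partial bin of each chromosome is dropped so that all bins
    share an identical width (and therefore an identical count expectation).

    Returns a DataFrame with 1-based inclusive ``start``/``end`` columns.
    """
    genome = GENOME_HG19 if genome is None else genome
    rows = []
    for chrom, length in genome.items():
        n_bins = int(length) // bin_size
        if n_bins == 0:
            raise ValueError(f"{chrom}: length {length} shorter than one bin")
        starts = np.arange(n_bins, dtype=np.int64) * bin_size + 1
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_size - 1,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def synthetic_gc_profile(n_bins: int, seed: int = 7) -> np.ndarray:
    """Synthetic per-bin GC fractions in roughly [0.33, 0.60].

    A smoothed random walk (isochore-scale trend) plus independent per-bin
    variation. The independent component matters: every chromosome then
    samples the whole GC range, so a GC-vs-count fit cannot confuse one
    chromosome's copy state with a GC band. The seed defaults to a fixed
    value so the same grid always gets the same track.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 1.0, n_bins)
    walk = np.cumsum(steps)
    # moving-average smoothing over ~20 Mb (odd kernel no wider than the track)
    k = max(1, min(21, n_bins))
    if k % 2 == 0:
        k -= 1
    kernel = np.ones(k) / k
    smooth = np.convolve(walk, kernel, mode="same")
    span = smooth.max() - smooth.min()
    if span == 0:
        smooth = np.zeros(n_bins)
        span = 1.0
    scaled = (smooth - smooth.min()) / span  # 0..1
    jitter = rng.beta(2.0, 2.0, n_bins)  # iid, mean 0.5
    mix = 0.35 * scaled + 0.65 * jitter
    return 0.33 + 0.27 * mix
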