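"""Low-coverage CNV calling and karyotype rendering from 1 Mb bin counts.

Counts are GC-corrected (LOWESS of count on GC, divided out), scaled to a
normalized ratio where 1.0 is the diploid expectation, then segmented per
chromosome by circular binary segmentation: the maximal circular two-sample
t-like statistic over all arcs, accepted by a permutation test and applied
recursively. Integer copy numbers come from the ±50% dose rule (ratio 1.5 →
3 copies, 0.5 → 1), and segments ≥ 4 Mb are reported into a karyotype
string such as ``47, XYY, +Y (×2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import is_autosome
from .synthetic_data import BinCountTrack


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_bins(
    track: BinCountTrack,
    reference: np.ndarray | None = None,
    gc_correct: bool = True,
    lowess_frac: float = 0.3,
) -> BinCountTrack:
    """GC-correct and median-scale raw bin counts to diploid ratios.

    Counts are regressed on GC over autosomal bins by LOWESS and divided by
    the fitted curve; ratios are the corrected counts over the autosomal
    median, so 1.0 is the diploid expectation (self-normalization). An
    optional external per-bin ``reference`` baseline divides bin-wise first.
    """
    df = track.df
    if len(df) < 100:
        raise NormalizationError("need at least 100 bins to normalize")
    counts = df["count"].to_numpy(dtype=float)
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if len(reference) != len(df) or np.any(reference <= 0):
            raise NormalizationError("reference baseline must be positive, one value per bin")
        counts = counts / reference
    if not np.any(counts > 0):
        raise NormalizationError("all-zero track cannot be normalized")

    auto = df["chrom"].map(is_autosome).to_numpy()
    corrected = counts.copy()
    if gc_correct and "gc" in df.columns:
        gc = df["gc"].to_numpy(dtype=float)
        fit_mask = auto & (counts > 0)
        if fit_mask.sum() >= 10:
            smoothed = lowess(
                counts[fit_mask], gc[fit_mask], frac=lowess_frac, it=2, return_sorted=True
            )
            pred = np.interp(gc, smoothed[:, 0], smoothed[:, 1])
            pred = np.maximum(pred, 1e-8)
            corrected = counts / pred * np.median(pred[fit_mask])

    scale = np.median(corrected[auto]) if auto.any() else np.median(corrected)
    if scale <= 0:
        raise NormalizationError("non-positive autosomal median")
    out = track.copy()
    out.df["ratio"] = corrected / scale
    return out


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _max_arc_stat(x: np.ndarray, w: np.ndarray):
    """Maximal |t|-like arc statistic over all (i, j] segments of x.

    w[k] = 1/sqrt(1/k + 1/(n-k)) precomputed for segment length k.
    Returns (stat, i, j): the arc covers indices i..j-1.
    """
    n = x.size
    S = np.empty(n + 1)
    S[0] = 0.0
    for i in range(n):
        S[i + 1] = S[i] + x[i]
    tot = S[n]
    best = -1.0
    bi = 0
    bj = 0
    for i in range(n + 1):
        si = S[i]
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            seg = S[j] - si
            t = abs(seg / k - (tot - seg) / (n - k)) * w[k]
            if t > best:
                best = t
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _perm_exceed(x: np.ndarray, w: np.ndarray, obs: float, n_perm: int, reject_at: int, seed: int):
    """Count permutations whose max arc stat reaches obs.

    Stops early once the count exceeds ``reject_at`` (the split is then
    certainly not significant at the chosen alpha). Returns (exceed, done).
    """
    np.random.seed(seed)
    y = x.copy()
    exceed = 0
    for p in range(n_perm):
        for i in range(y.size - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = y[i]
            y[i] = y[j]
            y[j] = tmp
        s, _, _ = _max_arc_stat(y, w)
        if s >= obs:
            exceed += 1
            if exceed > reject_at:
                return exceed, p + 1
    return exceed, n_perm


@dataclass
class CnvSegment:
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    n_bins: int
    mean_ratio: float
    copy_number: int

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


def call_copy_number(mean_ratio: float) -> int:
    """Integer copies from a normalized ratio: copy = round(2 × ratio).

    An exact half-way tie rounds toward diploid (conservative), so e.g. a
    ratio of 0.75 (2×ratio = 1.5) calls 2 copies, not 1.
    """
    if mean_ratio < 0:
        raise ValueError("ratio must be >= 0")
    c = 2.0 * mean_ratio
    lo = int(np.floor(c))
    hi = lo + 1
    if abs(c - lo) == abs(c - hi):
        return lo if abs(lo - 2) <= abs(hi - 2) else hi
    return lo if abs(c - lo) < abs(c - hi) else hi


def _segment_chromosome(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's ratio vector; returns [i0, i1) spans."""
    reject_at = int(np.floor(alpha * n_perm))
    out: list[tuple[int, int]] = []

    def recurse(s: int, e: int) -> None:
        seg = x[s:e]
        n = e - s
        if n < 2 or np.all(seg == seg[0]):
            out.append((s, e))
            return
        w = np.empty(n + 1)
        w[0] = 1.0
        for k in range(1, n + 1):
            w[k] = 1.0 / np.sqrt(1.0 / k + 1.0 / max(n - k, 1)) if k < n else 1.0
        obs, i, j = _max_arc_stat(seg, w)
        seed = int(rng.integers(0, 2**31 - 1))
        exceed, _ = _perm_exceed(seg, w, obs, n_perm, reject_at, seed)
        if exceed <= reject_at:  # significant: split at the arc
            cuts = sorted({s, s + i, s + j, e})
            for a, b in zip(cuts, cuts[1:]):
                if b - a == e - s:
                    out.append((a, b))  # no progress; stop
                else:
                    recurse(a, b)
        else:
            out.append((s, e))

    recurse(0, len(x))
    out.sort()
    return out


def segment_cbs(
    track: BinCountTrack,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    merge_band: float = 0.2,
    min_bins: int = 3,
) -> list[CnvSegment]:
    """Segment normalized ratios per chromosome into constant-copy segments.

    Splits are accepted at permutation p ≤ ``alpha``; after recursion,
    adjacent segments whose mean ratio lies within ``merge_band`` of diploid
    are merged back to the diploid background, and adjacent segments with
    the same called copy number are merged. Chromosomes with fewer than
    ``min_bins`` bins are skipped with a warning.
    """
    df = track.df
    if "ratio" not in df.columns:
        raise ValueError("track not normalized; run normalize_bins first")
    rng = np.random.default_rng(seed)
    segments: list[CnvSegment] = []
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom]
        x = sub["ratio"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(x) < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} bins, skipped")
            continue
        spans = _segment_chromosome(x, alpha, n_perm, rng)
        # merge near-diploid neighbours back together, then same-copy runs
        merged: list[tuple[int, int]] = []
        for s, e in spans:
            near_dip = abs(float(np.mean(x[s:e])) - 1.0) < merge_band
            if merged:
                ps, pe = merged[-1]
                prev_dip = abs(float(np.mean(x[ps:pe])) - 1.0) < merge_band
                if near_dip and prev_dip:
                    merged[-1] = (ps, e)
                    continue
            merged.append((s, e))
        final: list[tuple[int, int]] = []
        for s, e in merged:
            cn = call_copy_number(float(np.mean(x[s:e])))
            if final:
                ps, pe = final[-1]
                if call_copy_number(float(np.mean(x[ps:pe]))) == cn:
                    final[-1] = (ps, e)
                    continue
            final.append((s, e))
        for s, e in final:
            mean = float(np.mean(x[s:e]))
            segments.append(
                CnvSegment(
                    chrom=str(chrom),
                    start=int(starts[s]),
                    end=int(ends[e - 1]),
                    n_bins=e - s,
                    mean_ratio=round(mean, 4),
                    copy_number=call_copy_number(mean),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# karyotype rendering
# ---------------------------------------------------------------------------


def chromosome_ratios(track: BinCountTrack) -> dict[str, float]:
    """Mean normalized ratio per chromosome."""
    df = track.df
    if "ratio" not in df.columns:
        raise ValueError("track not normalized")
    return {str(c): float(v) for c, v in df.groupby("chrom", sort=False)["ratio"].mean().items()}


def _chrom_label(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def _band_lookup(band_table: pd.DataFrame, chrom: str, pos: int) -> str | None:
    sub = band_table[
        (band_table["chrom"] == chrom)
        & (band_table["start"] <= pos)
        & (band_table["end"] >= pos)
    ]
    if len(sub):
        return str(sub.iloc[0]["band"])
    return None


def karyotype_string(
    segments: list[CnvSegment],
    sex_chrom_ratios: tuple[float, float],
    genome: dict[str, int],
    min_report_bp: int = 4_000_000,
    band_table: pd.DataFrame | None = None,
) -> str:
    """Render a cytogenetics-style karyotype string from CBS segments.

    The leading count is the sum of autosomal whole-chromosome copy numbers
    plus the sex-chromosome copies called from the X and Y mean ratios; the
    designation lists the sex chromosomes; whole-chromosome aneuploidies and
    segmental events ≥ ``min_report_bp`` follow (smaller events are
    suppressed). With a cytoband table (chrom/start/end/band) the event
    range is printed in band coordinates, otherwise in bp.
    """
    x_ratio, y_ratio = sex_chrom_ratios
    n_x = call_copy_number(x_ratio)
    n_y = call_copy_number(y_ratio)

    by_chrom: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    def baseline(chrom: str) -> int:
        """Whole-chromosome copy: a single spanning segment's copy number,
        otherwise the expected copy for the chromosome (segmental events are
        then reported against it)."""
        expected = 2 if is_autosome(chrom) else (n_x if chrom == "chrX" else n_y)
        segs = by_chrom.get(chrom, [])
        if len(segs) == 1:
            return segs[0].copy_number
        return expected

    events: list[str] = []
    total = 0
    for chrom in genome:
        if not is_autosome(chrom):
            continue
        b = baseline(chrom)
        total += b
        if b != 2:
            sign = "+" if b > 2 else "−"
            events.append(f"{sign}{_chrom_label(chrom)} (×{b})")
    total += n_x + n_y

    if n_x == 0 and n_y == 0:
        designation = f"sex ambiguous (X ratio {x_ratio:.2f}, Y ratio {y_ratio:.2f})"
    else:
        designation = "X" * n_x + "Y" * n_y
    if n_y >= 2:
        events.append(f"+Y (×{n_y})")
    if n_x >= 3:
        events.append(f"+X (×{n_x})")

    # segmental events against each chromosome's baseline copy
    for chrom in genome:
        b = baseline(chrom)
        for seg in by_chrom.get(chrom, []):
            if seg.copy_number == b:
                continue
            if seg.size_bp < min_report_bp:
                continue
            sign = "+" if seg.copy_number > b else "−"
            size_mb = round(seg.size_bp / 1e6)
            label = _chrom_label(chrom)
            if band_table is not None:
                b1 = _band_lookup(band_table, chrom, seg.start)
                b2 = _band_lookup(band_table, chrom, seg.end)
                if b1 and b2:
                    arm = b1[0] if b1[0] == b2[0] else ""
                    events.append(
                        f"{sign}{label}{arm} ({b1}→{b2},∼{size_mb} Mb,×{seg.copy_number})"
                    )
                    continue
            events.append(
                f"{sign}{label} ({seg.start}→{seg.end},∼{size_mb} Mb,×{seg.copy_number})"
            )

    out = f"{total}, {designation}"
    if events:
        out += ", " + ", ".join(events)
    return out


def analyze_track(
    track: BinCountTrack,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    min_report_bp: int = 4_000_000,
    reference: np.ndarray | None = None,
    band_table: pd.DataFrame | None = None,
) -> tuple[BinCountTrack, list[CnvSegment], str, tuple[float, float]]:
    """Normalize, segment and karyotype one sample's bin-count track."""
    norm = normalize_bins(track, reference=reference)
    segments = segment_cbs(norm, alpha=alpha, n_perm=n_perm, seed=seed)
    ratios = chromosome_ratios(norm)
    sex_ratios = (ratios.get("chrX", 0.0), ratios.get("chrY", 0.0))
    karyotype = karyotype_string(
        segments, sex_ratios, norm.genome, min_report_bp=min_report_bp, band_table=band_table
    )
    return norm, segments, karyotype, sex_ratios
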