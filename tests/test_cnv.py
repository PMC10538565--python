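"""Normalization, CBS segmentation and karyotype rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pgtlink as pg
from pgtlink.cnv import NormalizationError, _max_arc_stat, chromosome_ratios
from pgtlink.genome import GENOME_HG19
from pgtlink.synthetic_data import BinCountTrack

GEN = {c: GENOME_HG19[c] for c in ("chr1", "chr2", "chr3", "chr21", "chrX", "chrY")}


def brute_force_max_arc(x):
    """Independent O(n^3) oracle for the maximal circular arc t-statistic."""
    n = len(x)
    best = (-1.0, 0, 0)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            t = abs(inside.mean() - outside.mean()) / np.sqrt(1 / k + 1 / (n - k))
            if t > best[0]:
                best = (t, i, j)
    return best


class TestCopyNumberCall:
    @pytest.mark.parametrize(
        "ratio,copies",
        [(1.5, 3), (0.5, 1), (1.0, 2), (0.0, 0), (2.0, 4), (0.97, 2)],
    )
    def test_dose_rule(self, ratio, copies):
        assert pg.call_copy_number(ratio) == copies

    @pytest.mark.parametrize("ratio,copies", [(0.75, 2), (1.25, 2), (0.25, 1), (1.75, 3)])
    def test_halfway_ties_round_toward_diploid(self, ratio, copies):
        # 2*ratio sits exactly between two integers: prefer the one nearer 2
        assert pg.call_copy_number(ratio) == copies

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pg.call_copy_number(-0.1)

    @given(st.floats(0, 4))
    def test_copy_within_half_of_double_ratio(self, ratio):
        assert abs(pg.call_copy_number(ratio) - 2 * ratio) <= 0.5


class TestNormalization:
    def test_flat_diploid_track_ratios_near_one(self):
        track = pg.simulate_bin_counts("XX", 100, gc_bias_strength=0.0, seed=1, genome=GEN)
        norm = pg.normalize_bins(track)
        auto = norm.df[~norm.df["chrom"].isin(["chrX", "chrY"])]
        # per-bin noise CV ≈ 0.105 at 100 reads: the level is 1.0 and no
        # bin strays beyond ~5 sd
        assert abs(auto["ratio"].mean() - 1.0) < 0.01
        assert np.all(np.abs(auto["ratio"] - 1.0) < 0.55)

    def test_gc_bias_removed(self):
        track = pg.simulate_bin_counts("XX", 200, gc_bias_strength=0.3, seed=2, genome=GEN)
        raw = track.df
        auto_mask = ~raw["chrom"].isin(["chrX", "chrY"])
        r_before = np.corrcoef(raw.loc[auto_mask, "count"], raw.loc[auto_mask, "gc"])[0, 1]
        norm = pg.normalize_bins(track)
        r_after = np.corrcoef(
            norm.df.loc[auto_mask, "ratio"], norm.df.loc[auto_mask, "gc"]
        )[0, 1]
        assert abs(r_before) > 0.1  # bias is really there beforehand
        assert abs(r_after) < 0.05

    def test_trisomic_chromosome_ratio_1p5(self):
        track = pg.simulate_bin_counts(
            "XY", 100, seed=3, genome=GEN, cnv_events=[("chr21", 1, 48_000_000, 3)]
        )
        norm = pg.normalize_bins(track)
        assert abs(chromosome_ratios(norm)["chr21"] - 1.5) < 0.05

    def test_all_zero_and_short_tracks_rejected(self):
        df = pg.simulate_bin_counts("XX", 100, seed=4, genome=GEN).df
        zero = BinCountTrack(df=df.assign(count=0), genome=GEN)
        with pytest.raises(NormalizationError):
            pg.normalize_bins(zero)
        short = BinCountTrack(df=df.iloc[:50].copy(), genome=GEN)
        with pytest.raises(NormalizationError):
            pg.normalize_bins(short)

    def test_scale_invariance(self):
        track = pg.simulate_bin_counts(
            "XY", 100, seed=5, genome=GEN, cnv_events=[("chr21", 10_000_001, 30_000_000, 1)]
        )
        scaled = BinCountTrack(df=track.df.assign(count=track.df["count"] * 7), genome=GEN)
        segs_a = pg.segment_cbs(pg.normalize_bins(track), n_perm=1000, seed=9)
        segs_b = pg.segment_cbs(pg.normalize_bins(scaled), n_perm=1000, seed=9)
        assert [(s.chrom, s.start, s.end, s.copy_number) for s in segs_a] == [
            (s.chrom, s.start, s.end, s.copy_number) for s in segs_b
        ]


class TestSegmentation:
    @pytest.mark.parametrize("n", [8, 17, 30])
    def test_max_arc_stat_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.normal(1.0, 0.1, n)
            x[n // 3 : 2 * n // 3] -= 0.5
            w = np.array(
                [1.0] + [1 / np.sqrt(1 / k + 1 / (n - k)) if k < n else 1.0 for k in range(1, n + 1)]
            )
            stat, i, j = _max_arc_stat(x, w)
            b_stat, b_i, b_j = brute_force_max_arc(x)
            assert stat == pytest.approx(b_stat)
            assert (i, j) == (b_i, b_j)

    def test_deletion_boundaries_within_one_bin(self):
        hits = 0
        for seed in range(10):
            track = pg.simulate_bin_counts(
                "XY", 100, gc_bias_strength=0.3, seed=seed, genome=GEN,
                cnv_events=[("chr21", 14_000_001, 41_000_000, 1)],
            )
            norm = pg.normalize_bins(track)
            segs = [
                s for s in pg.segment_cbs(norm, n_perm=2000, seed=seed)
                if s.chrom == "chr21" and s.copy_number == 1
            ]
            if len(segs) == 1 and (
                abs(segs[0].start - 14_000_001) <= 1_000_000
                and abs(segs[0].end - 41_000_000) <= 1_000_000
            ):
                hits += 1
        assert hits >= 9

    def test_pure_diploid_rarely_splits(self):
        false_pos = 0
        for seed in range(10):
            track = pg.simulate_bin_counts("XX", 100, seed=100 + seed, genome=GEN)
            norm = pg.normalize_bins(track)
            segs = pg.segment_cbs(norm, alpha=0.01, n_perm=2000, seed=seed)
            auto = [s for s in segs if s.chrom not in ("chrX", "chrY")]
            if any(s.copy_number != 2 for s in auto):
                false_pos += 1
        assert false_pos <= 1

    def test_no_cross_chromosome_segment(self):
        track = pg.simulate_bin_counts(
            "XY", 100, seed=6, genome=GEN, cnv_events=[("chr2", 1, GENOME_HG19["chr2"], 3)]
        )
        segs = pg.segment_cbs(pg.normalize_bins(track), n_perm=1000, seed=1)
        for s in segs:
            assert s.end <= GENOME_HG19[s.chrom]
        chr2 = [s for s in segs if s.chrom == "chr2"]
        assert len(chr2) == 1 and chr2[0].copy_number == 3

    def test_short_chromosome_skipped_with_warning(self):
        gen = dict(GEN)
        gen["chrTiny"] = 2_000_000
        track = pg.simulate_bin_counts("XX", 100, seed=7, genome=gen)
        norm = pg.normalize_bins(track)
        with pytest.warns(UserWarning):
            segs = pg.segment_cbs(norm, n_perm=500, seed=0)
        assert all(s.chrom != "chrTiny" for s in segs)


class TestKaryotype:
    def _karyo(self, sex, events, seed, genome=None, **kw):
        track = pg.simulate_bin_counts(
            sex, 100, gc_bias_strength=0.3, seed=seed, genome=genome or GENOME_HG19,
            cnv_events=events,
        )
        _, _, karyo, _ = pg.analyze_track(track, n_perm=2000, seed=seed, **kw)
        return karyo

    def test_euploid_male_and_female(self):
        assert self._karyo("XY", [], 11) == "46, XY"
        assert self._karyo("XX", [], 12) == "46, XX"

    def test_double_y_total_47(self):
        karyo = self._karyo("XY", [("chrY", 1, GENOME_HG19["chrY"], 2)], 13)
        assert karyo == "47, XYY, +Y (×2)"

    def test_sub_4mb_event_suppressed(self):
        karyo = self._karyo("XY", [("chr2", 100_000_001, 103_000_000, 1)], 14)
        assert karyo == "46, XY"

    def test_large_segmental_deletion_reported(self):
        karyo = self._karyo("XY", [("chr21", 14_000_001, 41_000_000, 1)], 15)
        assert karyo.startswith("46, XY, −21 (")
        assert "×1" in karyo and "∼27 Mb" in karyo

    def test_monosomy_x_total_45(self):
        track = pg.simulate_bin_counts("XX", 100, seed=16, genome=GENOME_HG19,
                                       cnv_events=[("chrX", 1, GENOME_HG19["chrX"], 1)])
        _, _, karyo, _ = pg.analyze_track(track, n_perm=2000, seed=16)
        assert karyo.startswith("45, X")

    def test_band_table_labels(self):
        bands = pd.DataFrame(
            {
                "chrom": ["chr21"] * 2,
                "start": [1, 13_000_001],
                "end": [13_000_000, 48_129_895],
                "band": ["q11.1", "q21.1"],
            }
        )
        karyo = self._karyo(
            "XY", [("chr21", 14_000_001, 41_000_000, 1)], 17, band_table=bands
        )
        assert "−21q (q21.1→q21.1" in karyo
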