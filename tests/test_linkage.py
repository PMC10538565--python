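"""Informative-SNP selection, marker assignment and embryo diagnosis."""

import numpy as np
import pandas as pd
import pytest

import pgtlink as pg
from pgtlink.linkage import (
    AFFECTED,
    INCONCLUSIVE,
    INCONSISTENT,
    MISSING,
    MUT,
    UNAFFECTED,
    UNINFORMATIVE,
    WT,
    PanelError,
    marker_matrix,
)

from conftest import panel_from_truth

# the published worked example: husband A/, wife AB — the embryo's B allele
# must have come from the wife
M_EXAMPLE = pg.Marker(
    pos=1000, allele_mut="B", allele_wt="A", partner_alleles=("A",),
    side="upstream", distance_bp=5000,
)


def make_panel(markers, mutation_pos=50_000):
    return pg.MarkerPanel(
        markers=markers, chrom="chrX", gene_start=40_000, gene_end=60_000,
        mutation_pos=mutation_pos,
    )


class TestAssignMarker:
    def test_worked_example_xx_subtraction(self):
        # XX embryo observed AB: subtract paternal A → maternal B → mutant hap
        assert pg.assign_marker(("A", "B"), M_EXAMPLE, "XX") == MUT

    def test_xy_hemizygous_readoff(self):
        assert pg.assign_marker(("A",), M_EXAMPLE, "XY") == WT
        assert pg.assign_marker(("B",), M_EXAMPLE, "XY") == MUT

    def test_missing_observation(self):
        assert pg.assign_marker(None, M_EXAMPLE, "XY") == MISSING
        assert pg.assign_marker((None,), M_EXAMPLE, "XY") == MISSING
        assert pg.assign_marker((None, None), M_EXAMPLE, "XX") == MISSING

    def test_single_allele_equal_to_partner_is_ambiguous(self):
        # lone A could be the paternal copy (maternal dropped) or maternal A
        assert pg.assign_marker(("A", None), M_EXAMPLE, "XX") == UNINFORMATIVE

    def test_single_allele_distinct_from_partner_votes(self):
        assert pg.assign_marker(("B", None), M_EXAMPLE, "XX") == MUT

    def test_non_parental_allele_flagged(self):
        assert pg.assign_marker(("C",), M_EXAMPLE, "XY") == INCONSISTENT
        assert pg.assign_marker(("B", "C"), M_EXAMPLE, "XX") == INCONSISTENT


class TestSelectInformativeSnps:
    def _carrier(self, rows):
        return pd.DataFrame(
            rows, columns=["pos", "hap_mut", "hap_wt", "is_mutation", "linked"]
        )

    def test_partner_heterozygous_excluded(self):
        carrier = self._carrier([(1000, "A", "B", False, True), (2000, "C", "T", False, True)])
        partner = {1000: ("A", "B"), 2000: ("C", "C")}
        panel = pg.select_informative_snps(
            carrier, partner, gene_start=40_000, gene_end=60_000, mutation_pos=50_000
        )
        assert panel.positions() == [2000]

    def test_hemizygous_partner_kept(self):
        carrier = self._carrier([(1000, "A", "B", False, True)])
        panel = pg.select_informative_snps(
            carrier, {1000: ("A",)}, gene_start=40_000, gene_end=60_000, mutation_pos=50_000
        )
        assert len(panel) == 1
        assert panel.markers[0].partner_allele == "A"

    def test_nearest_fifteen_per_side_retained(self):
        # 40 upstream candidates at known distances: the 15 closest survive
        rows = [(40_000 - 100 * (i + 1), "A", "G", False, True) for i in range(40)]
        carrier = self._carrier(rows)
        partner = {int(r[0]): ("A",) for r in rows}
        panel = pg.select_informative_snps(
            carrier, partner, gene_start=40_000, gene_end=60_000,
            mutation_pos=50_000, max_per_side=15,
        )
        assert len(panel) == 15
        assert max(m.distance_bp for m in panel.markers) == 1500

    def test_unlinked_markers_excluded(self):
        carrier = self._carrier(
            [(1000, "A", "B", False, False), (2000, "C", "T", False, True)]
        )
        partner = {1000: ("A",), 2000: ("C",)}
        panel = pg.select_informative_snps(
            carrier, partner, gene_start=40_000, gene_end=60_000, mutation_pos=50_000
        )
        assert panel.positions() == [2000]

    def test_no_informative_markers_raises(self):
        carrier = self._carrier([(1000, "A", "B", False, True)])
        with pytest.raises(PanelError):
            pg.select_informative_snps(
                carrier, {1000: ("A", "B")}, gene_start=40_000, gene_end=60_000,
                mutation_pos=50_000,
            )


def _uniform_panel(n=30, allele_mut="B", allele_wt="A"):
    markers = [
        pg.Marker(
            pos=10_000 + 2000 * i if i < n // 2 else 70_000 + 2000 * i,
            allele_mut=allele_mut, allele_wt=allele_wt, partner_alleles=("A",),
            side="upstream" if i < n // 2 else "downstream",
            distance_bp=abs((10_000 + 2000 * i) - 40_000),
        )
        for i in range(n)
    ]
    return make_panel(markers)


class TestClassifyEmbryo:
    def test_unanimous_mutant_vote_is_affected(self):
        panel = _uniform_panel()
        obs = {m.pos: ("B",) for m in panel.markers}
        call = pg.classify_embryo(obs, panel, embryo_sex="XY")
        assert call.diagnosis == AFFECTED
        assert (call.vote_mut, call.vote_wt) == (30, 0)

    def test_all_missing_is_inconclusive_with_reason(self):
        panel = _uniform_panel()
        call = pg.classify_embryo({}, panel, embryo_sex="XY")
        assert call.diagnosis == INCONCLUSIVE
        assert call.reason

    def test_below_vote_floor_is_inconclusive(self):
        panel = _uniform_panel()
        obs = {m.pos: ("B",) for m in panel.markers[:5]}
        call = pg.classify_embryo(obs, panel, embryo_sex="XY", min_votes=10)
        assert call.diagnosis == INCONCLUSIVE

    def test_recombination_block_switch_detected(self):
        # 15 mutant-hap then 15 wt-hap markers in positional order; the
        # switch is downstream of the gene, so votes come from the
        # gene-containing (mutant) block
        panel = _uniform_panel()
        markers = sorted(panel.markers, key=lambda m: m.pos)
        obs = {}
        for i, m in enumerate(markers):
            obs[m.pos] = ("B",) if i < 15 else ("A",)
        call = pg.classify_embryo(obs, panel, embryo_sex="XY", min_votes=10)
        assert call.recombination is not None
        lo, hi = call.recombination
        assert lo == markers[14].pos and hi == markers[15].pos

    def test_vote_conservation(self, small_family, truth_panel):
        pairs = pg.simulate_embryos(small_family, n=20, ado_rate=0.2, seed=11)
        for truth, obs in pairs:
            call = pg.classify_embryo(obs, truth_panel, embryo_sex=truth.sex, min_votes=5)
            assert (
                call.vote_mut
                + call.vote_wt
                + call.n_uninformative
                + call.n_missing
                + call.n_inconsistent
            ) == len(truth_panel)

    def test_ado_monotonicity_toward_inconclusive(self, small_family, truth_panel):
        """Raising ADO may only weaken a diagnosis, never flip it."""
        for seed in range(5):
            previous = None
            for ado in (0.0, 0.2, 0.4, 0.6):
                pairs = pg.simulate_embryos(
                    small_family, n=10, ado_rate=ado, recomb_prob=0.0, seed=seed
                )
                diags = [
                    pg.classify_embryo(o, truth_panel, embryo_sex=t.sex, min_votes=5).diagnosis
                    for t, o in pairs
                ]
                if previous is not None:
                    for before, after in zip(previous, diags):
                        if after != before:
                            assert after == INCONCLUSIVE
                previous = diags

    def test_empty_panel_rejected(self):
        with pytest.raises(PanelError):
            pg.classify_embryo({}, make_panel([]))


class TestClassificationAccuracy:
    def test_truth_recovery_and_misphase_inversion(self, small_family):
        """Correct phase → 100% accuracy; inverted phase → 100% label flips."""
        panel = panel_from_truth(small_family)
        inverted = panel_from_truth(small_family, invert=True)
        pairs = pg.simulate_embryos(
            small_family, n=100, ado_rate=0.10, recomb_prob=0.0, seed=21
        )
        for truth, obs in pairs:
            want = AFFECTED if truth.inherited_carrier_hap == "mut" else UNAFFECTED
            flip = UNAFFECTED if want == AFFECTED else AFFECTED
            call = pg.classify_embryo(obs, panel, embryo_sex=truth.sex)
            anti = pg.classify_embryo(obs, inverted, embryo_sex=truth.sex)
            assert call.diagnosis == want
            assert anti.diagnosis == flip


class TestConcordance:
    def test_agreement_cases(self):
        panel = _uniform_panel()
        obs = {m.pos: ("B",) for m in panel.markers}
        call = pg.classify_embryo(obs, panel, embryo_sex="XY")
        assert pg.concordance(call, "mut") is True
        assert pg.concordance(call, "wt") is False
        assert pg.concordance(call, None) is None

    def test_noiseless_embryos_fully_concordant(self, small_family, truth_panel):
        pairs = pg.simulate_embryos(small_family, n=8, ado_rate=0.0, recomb_prob=0.0, seed=2)
        for truth, obs in pairs:
            call = pg.classify_embryo(obs, truth_panel, embryo_sex=truth.sex)
            assert pg.concordance(call, obs.direct_call) is True


class TestMarkerMatrix:
    def test_layout_and_missing_symbol(self):
        panel = _uniform_panel(n=4)
        obs = {m.pos: ("B",) for m in panel.markers[:2]}
        call = pg.classify_embryo(obs, panel, embryo_sex="XY", min_votes=1, embryo_id="E1")
        df = marker_matrix(panel, [call])
        assert list(df["E1"]) == ["M", "M", "0", "0"]
        assert (df["side"].values[:2] == "upstream").all()
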