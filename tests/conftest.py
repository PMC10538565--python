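import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import pgtlink as pg


@pytest.fixture(scope="session")
def small_family():
    """Compact family: 20 markers in a ±250 kb window, dense phasing scaffold."""
    return pg.simulate_family(n_markers=20, window_bp=250_000, seed=42)


@pytest.fixture(scope="session")
def small_readset(small_family):
    return pg.simulate_long_reads(
        small_family, depth=25.0, mean_len=14_400.0, error_rate=0.0, seed=7
    )


@pytest.fixture(scope="session")
def phased_small(small_family, small_readset):
    kept = pg.qc_filter_reads(small_readset)
    matrix = pg.build_allele_matrix(kept, small_family.site_table())
    phased = pg.phase_region(matrix, seed=3)
    pg.assign_mutation_phase(phased, matrix, small_family.mutation_pos)
    return matrix, phased


@pytest.fixture(scope="session")
def truth_panel(small_family):
    """Marker panel taken directly from the simulation truth (error-free phase)."""
    return panel_from_truth(small_family)


def panel_from_truth(family, invert=False):
    """Build a MarkerPanel straight from FamilyTruth (bypassing read phasing).

    ``invert=True`` deliberately swaps the haplotype orientation, modelling a
    mis-phased carrier.
    """
    markers = []
    for i, pos in enumerate(family.positions):
        pos = int(pos)
        g = family.partner_genotypes[i]
        if len(set(g)) != 1:
            continue
        a_mut, a_wt = str(family.hap_mut[i]), str(family.hap_wt[i])
        if invert:
            a_mut, a_wt = a_wt, a_mut
        side = "upstream" if pos < family.gene_start else "downstream"
        dist = family.gene_start - pos if side == "upstream" else pos - family.gene_end
        markers.append(
            pg.Marker(
                pos=pos,
                allele_mut=a_mut,
                allele_wt=a_wt,
                partner_alleles=tuple(g),
                side=side,
                distance_bp=int(dist),
            )
        )
    return pg.MarkerPanel(
        markers=markers,
        chrom=family.chrom,
        gene_start=family.gene_start,
        gene_end=family.gene_end,
        mutation_pos=family.mutation_pos,
    )
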