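"""Informative-SNP selection and embryo haplotype diagnosis.

An informative marker is heterozygous in the carrier and homozygous (or
hemizygous) in the partner, so the embryo's maternally inherited carrier
haplotype is identifiable after subtracting the obligate paternal allele.
Diagnosis is a majority vote across markers with allele-dropout tolerance:
ambiguous observations abstain rather than vote, so increasing dropout can
only push a call toward inconclusive, never flip it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic_data import EmbryoObservation

MUT, WT, UNINFORMATIVE, MISSING, INCONSISTENT = (
    "mut_hap",
    "wt_hap",
    "uninformative",
    "missing",
    "inconsistent",
)

AFFECTED, UNAFFECTED, INCONCLUSIVE = "affected", "unaffected", "inconclusive"


class PanelError(ValueError):
    """No informative markers available: linkage diagnosis impossible."""


@dataclass
class Marker:
    pos: int
    allele_mut: str  # carrier allele on the mutation-bearing haplotype
    allele_wt: str
    partner_alleles: tuple[str, ...]  # len 1 (hemizygous) or 2 (homozygous)
    side: str  # "upstream" / "downstream"
    distance_bp: int

    @property
    def partner_allele(self) -> str:
        return self.partner_alleles[0]


@dataclass
class MarkerPanel:
    markers: list[Marker]
    chrom: str
    gene_start: int
    gene_end: int
    mutation_pos: int
    x_linked: bool = True

    def __len__(self) -> int:
        return len(self.markers)

    def positions(self) -> list[int]:
        return [m.pos for m in self.markers]


def select_informative_snps(
    carrier: pd.DataFrame,
    partner_genotypes: Mapping[int, tuple[str, ...]],
    gene_start: int,
    gene_end: int,
    mutation_pos: int,
    window_bp: int = 2_000_000,
    max_per_side: int = 15,
    chrom: str = "chrX",
    x_linked: bool = True,
) -> MarkerPanel:
    """Build the linkage marker panel from the phased carrier and the partner.

    ``carrier`` is a phased site table (columns pos, hap_mut, hap_wt,
    is_mutation, linked). Kept markers are carrier-het, partner-homozygous or
    hemizygous, inside ±``window_bp`` of the gene, and phase-linked to the
    mutation; if one side offers more than ``max_per_side``, the closest to
    the gene are retained.
    """
    if max_per_side < 1:
        raise PanelError("max_per_side must be >= 1")
    markers: list[Marker] = []
    for row in carrier.itertuples(index=False):
        pos = int(row.pos)
        if getattr(row, "is_mutation", False) or pos == mutation_pos:
            continue
        if getattr(row, "linked", True) is False:
            continue
        hap_mut, hap_wt = row.hap_mut, row.hap_wt
        if hap_mut is None or hap_wt is None or hap_mut == hap_wt:
            continue  # phase uncalled or not heterozygous
        g = partner_genotypes.get(pos)
        if g is None or len(set(g)) != 1:
            continue  # absent or heterozygous partner: not informative
        if pos < gene_start:
            side, dist = "upstream", gene_start - pos
        elif pos > gene_end:
            side, dist = "downstream", pos - gene_end
        else:
            continue  # inside the gene interval itself
        if dist > window_bp:
            continue
        markers.append(
            Marker(
                pos=pos,
                allele_mut=str(hap_mut),
                allele_wt=str(hap_wt),
                partner_alleles=tuple(g),
                side=side,
                distance_bp=int(dist),
            )
        )
    kept: list[Marker] = []
    for side in ("upstream", "downstream"):
        cand = sorted(
            (m for m in markers if m.side == side), key=lambda m: (m.distance_bp, m.pos)
        )
        kept.extend(cand[:max_per_side])
    kept.sort(key=lambda m: m.pos)
    if not kept:
        raise PanelError("no informative SNP markers in the window")
    return MarkerPanel(
        markers=kept,
        chrom=chrom,
        gene_start=gene_start,
        gene_end=gene_end,
        mutation_pos=mutation_pos,
        x_linked=x_linked,
    )


# ---------------------------------------------------------------------------
# per-marker assignment
# ---------------------------------------------------------------------------


def assign_marker(
    embryo_gt: tuple[str | None, ...] | None,
    marker: Marker,
    embryo_sex: str = "XY",
) -> str:
    """Assign one embryo genotype observation to a carrier haplotype.

    XY embryos at X-linked markers carry a single maternal allele, read off
    directly. XX embryos require subtracting the obligate paternal allele;
    a lone observed allele equal to the paternal allele is ambiguous
    (maternal match vs maternal dropout) and abstains as uninformative.
    Alleles seen in neither parent flag a genotype inconsistency.
    """
    if embryo_gt is None:
        return MISSING
    observed = [a for a in embryo_gt if a is not None]
    if not observed:
        return MISSING
    valid = {marker.allele_mut, marker.allele_wt}

    def call(maternal: str) -> str:
        if maternal == marker.allele_mut:
            return MUT
        if maternal == marker.allele_wt:
            return WT
        return INCONSISTENT

    if embryo_sex == "XY":
        if len(observed) != 1:
            return INCONSISTENT
        return call(observed[0])

    p = marker.partner_allele
    if len(observed) == 2:
        a, b = observed
        if a == p:
            return call(b)
        if b == p:
            return call(a)
        return INCONSISTENT  # obligate paternal allele absent from a full call
    # one allele dropped
    a = observed[0]
    if a == p:
        # could be the paternal copy (maternal dropped) or a maternal match
        return UNINFORMATIVE
    if a not in valid:
        return INCONSISTENT
    return call(a)


# ---------------------------------------------------------------------------
# embryo classification
# ---------------------------------------------------------------------------


@dataclass
class EmbryoCall:
    embryo_id: str
    per_marker: dict[int, str]
    vote_mut: int
    vote_wt: int
    n_uninformative: int
    n_missing: int
    n_inconsistent: int
    diagnosis: str  # affected / unaffected / inconclusive
    reason: str = ""
    recombination: tuple[int, int] | None = None
    direct_call: str | None = None
    concordant: bool | None = None


def _runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """Compress an informative-assignment sequence into (label, i0, i1) runs."""
    runs: list[tuple[str, int, int]] = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1], i)
        else:
            runs.append((lab, i, i))
    return runs


def classify_embryo(
    observation: EmbryoObservation | Mapping[int, tuple[str | None, ...] | None],
    panel: MarkerPanel,
    embryo_sex: str = "XY",
    min_votes: int = 10,
    min_margin_fraction: float = 0.8,
    recomb_min_run: int = 3,
    embryo_id: str | None = None,
) -> EmbryoCall:
    """Diagnose one embryo by majority vote over informative markers.

    The call is *affected* when mutant-haplotype votes reach
    ``min_margin_fraction`` of the informative votes and the total reaches
    ``min_votes`` (symmetrically for *unaffected*); anything else is
    inconclusive with an explicit reason. A contiguous block of
    ≥ ``recomb_min_run`` markers switching haplotype flags a candidate
    recombination, and votes are then restricted to the block spanning the
    mutation; a switch straddling the gene itself is inconclusive.
    """
    if len(panel) == 0:
        raise PanelError("empty marker panel")
    if isinstance(observation, EmbryoObservation):
        genotypes: Mapping = observation.genotypes
        eid = embryo_id or observation.embryo_id
        direct = observation.direct_call
    else:
        genotypes = observation
        eid = embryo_id or "embryo"
        direct = None

    per_marker: dict[int, str] = {}
    for m in panel.markers:
        per_marker[m.pos] = assign_marker(genotypes.get(m.pos), m, embryo_sex)

    counts = {k: 0 for k in (MUT, WT, UNINFORMATIVE, MISSING, INCONSISTENT)}
    for v in per_marker.values():
        counts[v] += 1

    # recombination scan over informative assignments in positional order
    inf_pos = [m.pos for m in panel.markers if per_marker[m.pos] in (MUT, WT)]
    inf_lab = [per_marker[p] for p in inf_pos]
    runs = _runs(inf_lab)
    big = [r for r in runs if r[2] - r[1] + 1 >= recomb_min_run]
    recombination: tuple[int, int] | None = None
    votes_from = set(inf_pos)
    reason = ""
    if len(big) >= 2:
        # breakpoint between consecutive large runs of opposite label
        for r1, r2 in zip(big, big[1:]):
            if r1[0] != r2[0]:
                recombination = (inf_pos[r1[2]], inf_pos[r2[1]])
                break
    if recombination is not None:
        lo, hi = recombination
        if lo < panel.mutation_pos < hi:
            return EmbryoCall(
                embryo_id=eid,
                per_marker=per_marker,
                vote_mut=0,
                vote_wt=0,
                n_uninformative=counts[UNINFORMATIVE],
                n_missing=counts[MISSING],
                n_inconsistent=counts[INCONSISTENT],
                diagnosis=INCONCLUSIVE,
                reason="recombination breakpoint spans the target gene",
                recombination=recombination,
                direct_call=direct,
            )
        # vote only from the gene-containing block: the run whose interval
        # covers the mutation side of the breakpoint
        block = [r for r in big if inf_pos[r[1]] <= panel.mutation_pos <= inf_pos[r[2]]]
        if not block:
            # gene sits between runs; take the run adjacent to the breakpoint
            # on the gene side
            block = [
                min(
                    big,
                    key=lambda r: min(
                        abs(inf_pos[r[1]] - panel.mutation_pos),
                        abs(inf_pos[r[2]] - panel.mutation_pos),
                    ),
                )
            ]
        sel = block[0]
        votes_from = set(inf_pos[sel[1] : sel[2] + 1])
        reason = "recombination detected; votes restricted to gene-side block"

    vote_mut = sum(
        1 for p in inf_pos if p in votes_from and per_marker[p] == MUT
    )
    vote_wt = sum(1 for p in inf_pos if p in votes_from and per_marker[p] == WT)
    total = vote_mut + vote_wt

    if total == 0:
        diagnosis, reason = INCONCLUSIVE, reason or "no informative marker observed"
    elif total < min_votes:
        diagnosis = INCONCLUSIVE
        reason = reason + ("; " if reason else "") + f"only {total} informative votes (< {min_votes})"
    elif vote_mut / total >= min_margin_fraction:
        diagnosis = AFFECTED
    elif vote_wt / total >= min_margin_fraction:
        diagnosis = UNAFFECTED
    else:
        diagnosis = INCONCLUSIVE
        reason = reason + ("; " if reason else "") + "vote margin below threshold"

    return EmbryoCall(
        embryo_id=eid,
        per_marker=per_marker,
        vote_mut=vote_mut,
        vote_wt=vote_wt,
        n_uninformative=counts[UNINFORMATIVE],
        n_missing=counts[MISSING],
        n_inconsistent=counts[INCONSISTENT],
        diagnosis=diagnosis,
        reason=reason,
        recombination=recombination,
        direct_call=direct,
    )


def concordance(call: EmbryoCall, direct_call: str | None) -> bool | None:
    """Agreement between linkage diagnosis and direct mutation detection.

    True/False when both calls are definite; None (undefined) when the
    direct call is missing or the linkage diagnosis is inconclusive.
    Updates ``call`` in place.
    """
    call.direct_call = direct_call
    if direct_call is None or call.diagnosis == INCONCLUSIVE:
        call.concordant = None
        return None
    call.concordant = (call.diagnosis == AFFECTED) == (direct_call == "mut")
    return call.concordant


def marker_matrix(
    panel: MarkerPanel,
    calls: list[EmbryoCall],
    carrier: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker × per-embryo assignment table (0 encodes a missing call).

    Mirrors the usual PGT-M haplotype figure: rows are markers sorted by
    position with their distance to the gene; one column per embryo holding
    M (mutant haplotype), W (wild-type), U (uninformative), X
    (inconsistency) or 0 (missing).
    """
    sym = {MUT: "M", WT: "W", UNINFORMATIVE: "U", MISSING: "0", INCONSISTENT: "X"}
    rows = []
    for m in panel.markers:
        signed = -m.distance_bp if m.side == "upstream" else m.distance_bp
        row: dict[str, object] = {
            "pos": m.pos,
            "side": m.side,
            "distance_kb": round(signed / 1000, 1),
            "carrier_mut_hap": m.allele_mut,
            "carrier_wt_hap": m.allele_wt,
            "partner": "/".join(m.partner_alleles),
        }
        for c in calls:
            row[c.embryo_id] = sym[c.per_marker.get(m.pos, MISSING)]
        rows.append(row)
    return pd.DataFrame(rows)
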