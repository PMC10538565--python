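"""Synthetic family generator for reference-free PGT-M.

Emulates the data structure of a preimplantation genetic test of a de novo
monogenic mutation: a carrier heterozygous for the target mutation whose two
haplotypes differ at ~30 flanking SNP markers inside a ±2 Mb window, long
reads (~14.4 kb mean, ~28X) sampling those haplotypes, embryo biopsy
genotypes subject to allele dropout (ADO) and X-hemizygosity, and shallow
(~100 reads per 1 Mb bin) genome-wide bin counts with GC bias and optional
whole-chromosome or segmental copy-number events.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import (
    GENE_CHROM,
    GENE_END,
    GENE_START,
    GENOME_HG19,
    bin_grid,
    synthetic_gc_profile,
)

_BASES = np.array(list("ACGT"))

# Allele symbols at the mutation site: the wild-type base and the deleted
# allele of the single-base deletion (represented symbolically; base-level
# sequence is out of scope for the generator).
MUTATION_REF = "G"
MUTATION_ALT = "*"


class ParameterError(ValueError):
    """A generator was called with an out-of-range parameter."""


# ---------------------------------------------------------------------------
# family truth
# ---------------------------------------------------------------------------


@dataclass
class FamilyTruth:
    """Ground-truth phased family configuration over the target window.

    ``hap_mut``/``hap_wt`` hold the carrier's allele (one base per marker) on
    the haplotype carrying the de novo mutation and on the wild-type
    haplotype respectively. ``partner_genotypes`` holds one allele per marker
    if the partner is hemizygous (male, X-linked region) and two otherwise.
    """

    chrom: str
    gene_start: int
    gene_end: int
    mutation_pos: int
    window_bp: int
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    hap_mut: np.ndarray
    hap_wt: np.ndarray
    partner_genotypes: tuple[tuple[str, ...], ...]
    x_linked: bool = True
    # dense background of carrier-het SNPs used only for read-backed phasing
    # (the real assay phases on every het site in the window and then picks
    # the informative markers among them); empty arrays are allowed.
    scaffold_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    scaffold_ref: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="<U1"))
    scaffold_alt: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="<U1"))
    scaffold_hap_mut: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="<U1"))
    scaffold_hap_wt: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="<U1"))

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.ref) == len(self.alt) == len(self.hap_mut) == len(self.hap_wt) == n):
            raise ParameterError("marker arrays must have identical length")
        if np.any(self.hap_mut == self.hap_wt):
            raise ParameterError("carrier must be heterozygous at every marker")
        if len(self.scaffold_positions) and np.any(
            self.scaffold_hap_mut == self.scaffold_hap_wt
        ):
            raise ParameterError("carrier must be heterozygous at every scaffold SNP")
        if not (self.gene_start <= self.mutation_pos <= self.gene_end):
            raise ParameterError("mutation must lie inside the gene interval")
        lo = self.gene_start - self.window_bp
        hi = self.gene_end + self.window_bp
        if np.any((self.positions < lo) | (self.positions > hi)):
            raise ParameterError("marker outside the ± window around the gene")
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def site_table(self, include_scaffold: bool = True) -> pd.DataFrame:
        """All carrier-het sites (markers [+ scaffold] + mutation), sorted.

        Columns: pos, ref, alt, hap_mut (allele on the mutant haplotype),
        hap_wt, is_mutation, is_marker.
        """
        parts = [
            pd.DataFrame(
                {
                    "pos": self.positions,
                    "ref": self.ref,
                    "alt": self.alt,
                    "hap_mut": self.hap_mut,
                    "hap_wt": self.hap_wt,
                    "is_mutation": False,
                    "is_marker": True,
                }
            )
        ]
        if include_scaffold and len(self.scaffold_positions):
            parts.append(
                pd.DataFrame(
                    {
                        "pos": self.scaffold_positions,
                        "ref": self.scaffold_ref,
                        "alt": self.scaffold_alt,
                        "hap_mut": self.scaffold_hap_mut,
                        "hap_wt": self.scaffold_hap_wt,
                        "is_mutation": False,
                        "is_marker": False,
                    }
                )
            )
        parts.append(
            pd.DataFrame(
                {
                    "pos": [self.mutation_pos],
                    "ref": [MUTATION_REF],
                    "alt": [MUTATION_ALT],
                    "hap_mut": [MUTATION_ALT],
                    "hap_wt": [MUTATION_REF],
                    "is_mutation": [True],
                    "is_marker": [False],
                }
            )
        )
        out = pd.concat(parts, ignore_index=True).sort_values("pos", kind="mergesort")
        return out.reset_index(drop=True)

    def haplotype_allele(self, pos: int, hap: str) -> str:
        """Carrier allele at a marker (or the mutation site) on ``hap``."""
        if pos == self.mutation_pos:
            return MUTATION_ALT if hap == "mut" else MUTATION_REF
        i = int(np.searchsorted(self.positions, pos))
        if i >= len(self.positions) or self.positions[i] != pos:
            raise KeyError(f"no marker at {pos}")
        return str(self.hap_mut[i] if hap == "mut" else self.hap_wt[i])


def simulate_family(
    n_markers: int = 30,
    window_bp: int = 2_000_000,
    marker_density: float | None = None,
    seed: int = 0,
    x_linked: bool = True,
    partner_het_prob: float = 0.0,
    scaffold_per_mb: float = 400.0,
    chrom: str = GENE_CHROM,
    gene_start: int = GENE_START,
    gene_end: int = GENE_END,
) -> FamilyTruth:
    """Draw a phased carrier + partner configuration around the target gene.

    Markers are biallelic SNPs, heterozygous in the carrier (so every one is
    a phase-informative candidate), split evenly between the upstream and
    downstream flanks. ``partner_het_prob`` controls the fraction of markers
    at which the partner is heterozygous (hence non-informative); the default
    0 reproduces a fully informative panel. When ``marker_density`` (markers
    per Mb) is given and ``n_markers`` is None it sets the panel size.

    ``scaffold_per_mb`` additionally scatters a dense background of
    carrier-het SNPs through the window (no partner/embryo typing): these
    are what long reads actually chain across during phasing, at a spacing
    far below the read length, as in a real individual's het-SNP density.
    """
    if n_markers is None:
        if marker_density is None:
            raise ParameterError("either n_markers or marker_density required")
        n_markers = int(round(marker_density * 2 * window_bp / 1e6))
    if n_markers < 1:
        raise ParameterError("n_markers must be >= 1")
    if window_bp < 1:
        raise ParameterError("window_bp must be >= 1")

    rng = np.random.default_rng(seed)
    n_up = n_markers // 2
    n_down = n_markers - n_up
    up = rng.choice(np.arange(gene_start - window_bp, gene_start), n_up, replace=False)
    down = rng.choice(np.arange(gene_end + 1, gene_end + window_bp + 1), n_down, replace=False)
    positions = np.sort(np.concatenate([up, down]).astype(np.int64))

    ref_idx = rng.integers(0, 4, n_markers)
    alt_idx = (ref_idx + rng.integers(1, 4, n_markers)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    # which haplotype carries the ref allele, per marker
    ref_on_mut = rng.random(n_markers) < 0.5
    hap_mut = np.where(ref_on_mut, ref, alt)
    hap_wt = np.where(ref_on_mut, alt, ref)

    partner: list[tuple[str, ...]] = []
    for i in range(n_markers):
        het = rng.random() < partner_het_prob
        if x_linked:
            # male partner: hemizygous single X allele
            if het:
                raise ParameterError("a hemizygous partner cannot be heterozygous")
            partner.append((str(ref[i]) if rng.random() < 0.5 else str(alt[i]),))
        elif het:
            partner.append((str(ref[i]), str(alt[i])))
        else:
            a = str(ref[i]) if rng.random() < 0.5 else str(alt[i])
            partner.append((a, a))

    mutation_pos = int(rng.integers(gene_start, gene_end + 1))

    # dense carrier-het scaffold across the whole window (incl. the gene)
    n_scaffold = int(round(scaffold_per_mb * (2 * window_bp + gene_end - gene_start) / 1e6))
    if n_scaffold > 0:
        pool = np.arange(gene_start - window_bp, gene_end + window_bp + 1)
        taken = set(positions.tolist()) | {mutation_pos}
        sc_pos = rng.choice(pool, n_scaffold + len(taken), replace=False)
        sc_pos = np.sort(np.array([p for p in sc_pos if p not in taken][:n_scaffold], dtype=np.int64))
        sr_idx = rng.integers(0, 4, len(sc_pos))
        sa_idx = (sr_idx + rng.integers(1, 4, len(sc_pos))) % 4
        sc_ref = _BASES[sr_idx]
        sc_alt = _BASES[sa_idx]
        sc_ref_on_mut = rng.random(len(sc_pos)) < 0.5
        sc_hap_mut = np.where(sc_ref_on_mut, sc_ref, sc_alt)
        sc_hap_wt = np.where(sc_ref_on_mut, sc_alt, sc_ref)
    else:
        sc_pos = np.empty(0, dtype=np.int64)
        sc_ref = sc_alt = sc_hap_mut = sc_hap_wt = np.empty(0, dtype="<U1")

    return FamilyTruth(
        chrom=chrom,
        gene_start=gene_start,
        gene_end=gene_end,
        mutation_pos=mutation_pos,
        window_bp=window_bp,
        positions=positions,
        ref=ref,
        alt=alt,
        hap_mut=hap_mut,
        hap_wt=hap_wt,
        partner_genotypes=tuple(partner),
        x_linked=x_linked,
        scaffold_positions=sc_pos,
        scaffold_ref=sc_ref,
        scaffold_alt=sc_alt,
        scaffold_hap_mut=sc_hap_mut,
        scaffold_hap_wt=sc_hap_wt,
    )


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    read_id: str
    start: int
    end: int  # 1-based inclusive
    qscore: float
    hap: str  # origin haplotype before error injection ("mut"/"wt")
    obs: dict[int, str] = field(default_factory=dict)  # pos -> observed allele

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimReadSet:
    reads: list[SimRead]
    chrom: str
    region_start: int
    region_end: int
    mean_len: float
    depth: float
    error_rate: float

    def __len__(self) -> int:
        return len(self.reads)


def simulate_long_reads(
    truth: FamilyTruth,
    depth: float = 28.0,
    mean_len: float = 14_400.0,
    error_rate: float = 0.01,
    seed: int = 0,
    low_q_frac: float = 0.05,
) -> SimReadSet:
    """Sample long reads over the target window from the two carrier haplotypes.

    Read lengths follow a gamma law with shape 2 (heavy right tail typical of
    size-selected long-read libraries) and the requested mean. Each read
    originates from one haplotype (fair coin) and reports that haplotype's
    allele at every covered site (markers + mutation site), flipped to the
    opposite allele independently with ``error_rate``. Per-read mean quality
    scores are drawn so that ``low_q_frac`` of reads fall below the q=7
    filtering threshold.
    """
    if depth <= 0:
        raise ParameterError("depth must be > 0")
    if not (0 <= error_rate < 0.5):
        raise ParameterError("error_rate must be in [0, 0.5): phase would be unidentifiable")
    if mean_len <= 0:
        raise ParameterError("mean_len must be > 0")

    rng = np.random.default_rng(seed)
    region_start = truth.gene_start - truth.window_bp
    region_end = truth.gene_end + truth.window_bp
    region_len = region_end - region_start + 1
    n_reads = int(round(depth * region_len / mean_len))

    sites = truth.site_table()
    site_pos = sites["pos"].to_numpy()
    allele_mut = sites["hap_mut"].to_numpy()
    allele_wt = sites["hap_wt"].to_numpy()

    lengths = np.maximum(rng.gamma(2.0, mean_len / 2.0, n_reads).astype(np.int64), 200)
    starts = rng.integers(region_start - lengths + 1, region_end + 1)
    haps = np.where(rng.random(n_reads) < 0.5, "mut", "wt")
    low_q = rng.random(n_reads) < low_q_frac
    q_good = np.clip(rng.normal(12.0, 2.0, n_reads), 7.01, None)
    q_bad = rng.uniform(3.0, 6.99, n_reads)
    qscores = np.where(low_q, q_bad, q_good)

    reads: list[SimRead] = []
    for i in range(n_reads):
        s = int(starts[i])
        e = int(starts[i] + lengths[i] - 1)
        lo = np.searchsorted(site_pos, s, side="left")
        hi = np.searchsorted(site_pos, e, side="right")
        obs: dict[int, str] = {}
        for j in range(lo, hi):
            true_allele = allele_mut[j] if haps[i] == "mut" else allele_wt[j]
            other = allele_wt[j] if haps[i] == "mut" else allele_mut[j]
            obs[int(site_pos[j])] = str(other if rng.random() < error_rate else true_allele)
        reads.append(
            SimRead(
                read_id=f"read{i:06d}",
                start=s,
                end=e,
                qscore=float(round(qscores[i], 3)),
                hap=str(haps[i]),
                obs=obs,
            )
        )
    return SimReadSet(
        reads=reads,
        chrom=truth.chrom,
        region_start=region_start,
        region_end=region_end,
        mean_len=mean_len,
        depth=depth,
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# embryos
# ---------------------------------------------------------------------------


@dataclass
class EmbryoTruth:
    embryo_id: str
    inherited_carrier_hap: str  # haplotype at the mutation site: "mut"/"wt"
    sex: str  # "XX" / "XY"
    recombination_breakpoints: tuple[int, ...]
    ado_rate: float
    inherited_partner_allele: dict[int, str]  # per marker; empty for XY on X
    cnv_events: tuple[tuple[str, int, int, int], ...] = ()

    def maternal_allele(self, truth: FamilyTruth, pos: int) -> str:
        """True maternally inherited carrier allele at ``pos`` given crossovers."""
        hap = self.inherited_carrier_hap
        # breakpoints are anchored at the mutation site: the inherited
        # haplotype flips once per crossover lying between pos and the
        # mutation position.
        n_cross = sum(
            1
            for bp in self.recombination_breakpoints
            if (truth.mutation_pos <= bp < pos) or (pos <= bp < truth.mutation_pos)
        )
        if n_cross % 2 == 1:
            hap = "wt" if hap == "mut" else "mut"
        return truth.haplotype_allele(pos, hap)


@dataclass
class EmbryoObservation:
    """What the assay sees: genotype tuples with explicit missing slots.

    ``genotypes[pos]`` is a tuple of observed alleles with ``None`` marking
    an allele lost to dropout — e.g. ``("A", "G")``, ``("A", None)``,
    ``(None, None)`` for a diploid site and ``("A",)`` / ``(None,)`` for a
    hemizygous one. ``direct_call`` is the direct mutation-site assay
    ("mut" / "wt" / None if dropped).
    """

    embryo_id: str
    genotypes: dict[int, tuple[str | None, ...]]
    direct_call: str | None


def _validate_cnv_events(events) -> tuple[tuple[str, int, int, int], ...]:
    out = []
    for ev in events:
        chrom, start, end, cn = ev
        if end < start or cn < 0:
            raise ParameterError(f"bad CNV event {ev}")
        out.append((str(chrom), int(start), int(end), int(cn)))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in out:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ParameterError(f"overlapping CNV events on {chrom}")
    return tuple(out)


def simulate_embryos(
    truth: FamilyTruth,
    n: int = 8,
    ado_rate: float = 0.05,
    recomb_prob: float = 0.02,
    cnv_spec: list | None = None,
    seed: int = 0,
    sexes: list[str] | None = None,
    ado_mode: str = "missing",
) -> list[tuple[EmbryoTruth, EmbryoObservation]]:
    """Draw embryo inheritance truths and their noisy genotype observations.

    Each embryo inherits one carrier haplotype by a fair coin, with at most
    one recombination breakpoint (probability ``recomb_prob``, position
    uniform in the window). Observed alleles drop independently with
    ``ado_rate``; in the default ``"missing"`` mode a dropped allele is an
    explicit missing slot, while ``"homozygote"`` mode silently collapses a
    het to an apparently homozygous call (the classic misdiagnosis signature).
    ``cnv_spec`` is an optional per-embryo list of (chrom, start, end, copy)
    events. X-linked male embryos receive no paternal X allele.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0 <= ado_rate < 1):
        raise ParameterError("ado_rate must be in [0, 1)")
    if ado_mode not in ("missing", "homozygote"):
        raise ParameterError("ado_mode must be 'missing' or 'homozygote'")
    if cnv_spec is not None and len(cnv_spec) not in (0, n):
        raise ParameterError("cnv_spec must give one event list per embryo")

    rng = np.random.default_rng(seed)
    out: list[tuple[EmbryoTruth, EmbryoObservation]] = []
    for k in range(n):
        sex = sexes[k] if sexes else ("XY" if rng.random() < 0.5 else "XX")
        if sex not in ("XX", "XY"):
            raise ParameterError(f"bad sex {sex!r}")
        hap = "mut" if rng.random() < 0.5 else "wt"
        breaks: tuple[int, ...] = ()
        if rng.random() < recomb_prob:
            breaks = (
                int(
                    rng.integers(
                        truth.gene_start - truth.window_bp,
                        truth.gene_end + truth.window_bp,
                    )
                ),
            )
        events = _validate_cnv_events(cnv_spec[k]) if cnv_spec else ()

        paternal: dict[int, str] = {}
        if not (truth.x_linked and sex == "XY"):
            for i, pos in enumerate(truth.positions):
                g = truth.partner_genotypes[i]
                paternal[int(pos)] = g[0] if len(g) == 1 else g[int(rng.integers(0, len(g)))]

        et = EmbryoTruth(
            embryo_id=f"E{k + 1}",
            inherited_carrier_hap=hap,
            sex=sex,
            recombination_breakpoints=breaks,
            ado_rate=ado_rate,
            inherited_partner_allele=paternal,
            cnv_events=events,
        )

        genotypes: dict[int, tuple[str | None, ...]] = {}
        for pos in truth.positions:
            pos = int(pos)
            m = et.maternal_allele(truth, pos)
            alleles: list[str | None] = [m]
            if pos in paternal:
                alleles.append(paternal[pos])
            dropped = [a if rng.random() >= ado_rate else None for a in alleles]
            if ado_mode == "homozygote" and len(dropped) == 2:
                surv = [a for a in dropped if a is not None]
                if len(surv) == 1:
                    dropped = [surv[0], surv[0]]
            genotypes[pos] = tuple(
                sorted(dropped, key=lambda a: (a is None, a))
            )

        true_mut = et.maternal_allele(truth, truth.mutation_pos) == MUTATION_ALT
        direct: str | None = "mut" if true_mut else "wt"
        if rng.random() < ado_rate:
            direct = None
        out.append((et, EmbryoObservation(embryo_id=et.embryo_id, genotypes=genotypes, direct_call=direct)))
    return out


# ---------------------------------------------------------------------------
# bin counts
# ---------------------------------------------------------------------------


@dataclass
class BinCountTrack:
    """Per-1 Mb-bin read counts with GC content (and, post-normalization, ratios)."""

    df: pd.DataFrame  # chrom, start, end, count, gc [, ratio]
    genome: dict[str, int]

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "BinCountTrack":
        return BinCountTrack(df=self.df.copy(), genome=dict(self.genome))


def _gc_bias(gc: np.ndarray, strength: float, gc_opt: float = 0.45, width: float = 0.15) -> np.ndarray:
    """Smooth unimodal amplification-efficiency multiplier, peaked at gc_opt."""
    return np.exp(-strength * ((gc - gc_opt) / width) ** 2)


def _copy_number_per_bin(bins: pd.DataFrame, sex: str, cnv_events) -> np.ndarray:
    cn = np.full(len(bins), 2.0)
    chroms = bins["chrom"].to_numpy()
    cn[chroms == "chrX"] = 2.0 if sex == "XX" else 1.0
    cn[chroms == "chrY"] = 0.0 if sex == "XX" else 1.0
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for chrom, s, e, c in cnv_events:
        mask = (chroms == chrom) & (ends >= s) & (starts <= e)
        cn[mask] = float(c)
    return cn


def simulate_bin_counts(
    karyotype: "EmbryoTruth | str",
    mean_reads_per_bin: float = 100.0,
    gc_profile: np.ndarray | None = None,
    gc_bias_strength: float = 0.0,
    dispersion: float = 0.1,
    seed: int = 0,
    genome: dict[str, int] | None = None,
    cnv_events=None,
) -> BinCountTrack:
    """Simulate shallow-sequencing read counts on the 1 Mb bin grid.

    ``karyotype`` may be an :class:`EmbryoTruth` (sex + CNV events taken from
    it) or a plain sex string with ``cnv_events`` supplied separately. Counts
    are negative binomial with mean μ = (copy/2) × ``mean_reads_per_bin`` ×
    gc_bias(gc) and variance (1 + ``dispersion``) × μ: the dispersion is the
    fractional variance inflation over Poisson contributed by amplification
    noise (0 → pure Poisson). At the defaults (100 reads/bin, d = 0.1) the
    per-bin coefficient of variation is ≈ 0.105, typical of low-pass WGA
    bin-count tracks.
    """
    if mean_reads_per_bin < 1:
        raise ParameterError("mean_reads_per_bin must be >= 1")
    if dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    if isinstance(karyotype, EmbryoTruth):
        sex = karyotype.sex
        events = karyotype.cnv_events
    else:
        sex = str(karyotype)
        events = _validate_cnv_events(cnv_events or ())
    if sex not in ("XX", "XY"):
        raise ParameterError(f"bad sex {sex!r}")

    genome = GENOME_HG19 if genome is None else genome
    bins = bin_grid(genome)
    gc = synthetic_gc_profile(len(bins)) if gc_profile is None else np.asarray(gc_profile, dtype=float)
    if len(gc) != len(bins):
        raise ParameterError("gc_profile length must match the bin grid")

    cn = _copy_number_per_bin(bins, sex, events)
    mu = (cn / 2.0) * mean_reads_per_bin * _gc_bias(gc, gc_bias_strength)

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(bins), dtype=np.int64)
    pos = mu > 0
    if dispersion == 0:
        counts[pos] = rng.poisson(mu[pos])
    else:
        # var = (1 + d) mu  ⇒  NB with r = mu/d, p = 1/(1+d)
        r = mu[pos] / dispersion
        counts[pos] = rng.negative_binomial(r, 1.0 / (1.0 + dispersion))

    df = bins.copy()
    df["count"] = counts
    df["gc"] = np.round(gc, 4)
    return BinCountTrack(df=df, genome=dict(genome))
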