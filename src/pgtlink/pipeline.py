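"""End-to-end orchestration: simulate → phase → panel → diagnose → CNV → report.

Runs every stage deterministically from one seed, writes the intermediate
artifacts (phased VCF, panel TSV, per-marker matrix, SEG files) and renders
a per-embryo summary table with the four result columns of a PGT-M report:
CNV karyotype, haplotype-based mutation identification, direct-detection
result, and concordance.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import linkage, phasing, synthetic_data, vcfio
from .genome import GENOME_HG19

log = logging.getLogger("pgtlink")


@dataclass
class RunConfig:
    """All pipeline thresholds; serializes to/from flat ``key = value`` text."""

    window_bp: int = 2_000_000
    n_markers: int = 30
    depth: float = 28.0
    mean_len: float = 14_400.0
    read_error_rate: float = 0.01
    low_q_frac: float = 0.05
    min_qscore: float = 7.0
    min_len_bp: int = 1000
    crop_bp: int = 50
    min_overlap_reads: int = 2
    min_shared_snps: int = 1
    max_per_side: int = 15
    min_votes: int = 10
    min_margin_fraction: float = 0.8
    n_embryos: int = 8
    ado_rate: float = 0.05
    recomb_prob: float = 0.02
    mean_reads_per_bin: float = 100.0
    gc_bias_strength: float = 0.3
    dispersion: float = 0.1
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    report_min_mb: float = 4.0
    seed: int = 1
    strict: bool = False
    genome_chroms: str = ""  # comma list; empty = full hg19

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def genome(self) -> dict[str, int]:
        if not self.genome_chroms:
            return dict(GENOME_HG19)
        chroms = [c.strip() for c in self.genome_chroms.split(",") if c.strip()]
        return {c: GENOME_HG19[c] for c in chroms}

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str, "bool": lambda s: s == "True"}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[str(types[key])](val)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    family: synthetic_data.FamilyTruth
    phased: phasing.PhasedTargetRegion
    panel: linkage.MarkerPanel
    calls: list[linkage.EmbryoCall]
    karyotypes: dict[str, str]
    truths: list[synthetic_data.EmbryoTruth]


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    cnv_spec: list | None = None,
    sexes: list[str] | None = None,
) -> PipelineResult:
    """Execute the full synthetic PGT-M workflow under one seed.

    Returns the per-embryo report plus all intermediate objects; when
    ``out_dir`` is given the phased VCF, panel TSV, marker matrix, per-embryo
    SEG files and the report TSV are written there. Raises if
    ``config.strict`` and any embryo is inconclusive.
    """
    if config.n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_family, s_reads, s_embryos, s_phase, s_cbs, s_bins = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)
    ]

    t0 = _stage("simulate")
    family = synthetic_data.simulate_family(
        n_markers=config.n_markers, window_bp=config.window_bp, seed=s_family
    )
    reads = synthetic_data.simulate_long_reads(
        family,
        depth=config.depth,
        mean_len=config.mean_len,
        error_rate=config.read_error_rate,
        seed=s_reads,
        low_q_frac=config.low_q_frac,
    )
    embryos = synthetic_data.simulate_embryos(
        family,
        n=config.n_embryos,
        ado_rate=config.ado_rate,
        recomb_prob=config.recomb_prob,
        cnv_spec=cnv_spec,
        seed=s_embryos,
        sexes=sexes,
    )
    truths = [t for t, _ in embryos]
    observations = [o for _, o in embryos]
    _done("simulate", t0)

    t0 = _stage("phase")
    kept = phasing.qc_filter_reads(
        reads, min_qscore=config.min_qscore, min_len_bp=config.min_len_bp, crop_bp=config.crop_bp
    )
    sites = family.site_table()
    matrix = phasing.build_allele_matrix(kept, sites)
    phased = phasing.phase_region(
        matrix,
        min_overlap_reads=config.min_overlap_reads,
        min_shared_snps=config.min_shared_snps,
        seed=s_phase,
        chrom=family.chrom,
    )
    label = phasing.assign_mutation_phase(phased, matrix, family.mutation_pos)
    if label == phasing.UNRESOLVED:
        raise RuntimeError("phase stage: mutation could not be linked to a haplotype")
    carrier_table = phasing.phased_site_table(phased, sites)
    _done("phase", t0)

    t0 = _stage("panel")
    partner = {int(p): g for p, g in zip(family.positions, family.partner_genotypes)}
    panel = linkage.select_informative_snps(
        carrier_table,
        partner,
        gene_start=family.gene_start,
        gene_end=family.gene_end,
        mutation_pos=family.mutation_pos,
        window_bp=config.window_bp,
        max_per_side=config.max_per_side,
        chrom=family.chrom,
        x_linked=family.x_linked,
    )
    _done("panel", t0)

    t0 = _stage("cnv")
    genome = config.genome()
    karyotypes: dict[str, str] = {}
    seg_by_embryo: dict[str, list] = {}
    sex_inferred: dict[str, str] = {}
    bin_rng = np.random.SeedSequence(s_bins).spawn(len(truths))
    cbs_rng = np.random.SeedSequence(s_cbs).spawn(len(truths))
    tracks: dict[str, synthetic_data.BinCountTrack] = {}
    for et, bss, css in zip(truths, bin_rng, cbs_rng):
        track = synthetic_data.simulate_bin_counts(
            et,
            mean_reads_per_bin=config.mean_reads_per_bin,
            gc_bias_strength=config.gc_bias_strength,
            dispersion=config.dispersion,
            seed=int(bss.generate_state(1)[0] % (2**31 - 1)),
            genome=genome,
        )
        _, segments, karyo, (x_ratio, y_ratio) = cnv_mod.analyze_track(
            track,
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            seed=int(css.generate_state(1)[0] % (2**31 - 1)),
            min_report_bp=int(config.report_min_mb * 1e6),
        )
        karyotypes[et.embryo_id] = karyo
        seg_by_embryo[et.embryo_id] = segments
        sex_inferred[et.embryo_id] = (
            "XY" if cnv_mod.call_copy_number(y_ratio) >= 1 else "XX"
        )
        tracks[et.embryo_id] = track
    _done("cnv", t0)

    t0 = _stage("diagnose")
    calls: list[linkage.EmbryoCall] = []
    for et, obs in zip(truths, observations):
        sex = sex_inferred.get(et.embryo_id, et.sex)
        call = linkage.classify_embryo(
            obs,
            panel,
            embryo_sex=sex,
            min_votes=config.min_votes,
            min_margin_fraction=config.min_margin_fraction,
        )
        linkage.concordance(call, obs.direct_call)
        calls.append(call)
    _done("diagnose", t0)

    rows = []
    for et, obs, call in zip(truths, observations, calls):
        flags = []
        if call.recombination:
            flags.append("recombination")
        if call.n_inconsistent:
            flags.append(f"inconsistent:{call.n_inconsistent}")
        if sex_inferred.get(et.embryo_id) and any(
            len(g) == 2 for g in obs.genotypes.values()
        ) != (sex_inferred[et.embryo_id] == "XX"):
            flags.append("sex-mismatch")
        if call.reason:
            flags.append(call.reason)
        rows.append(
            {
                "embryo": et.embryo_id,
                "cnv_result": karyotypes[et.embryo_id],
                "haplotype_mutation": {
                    linkage.AFFECTED: "YES",
                    linkage.UNAFFECTED: "NO",
                    linkage.INCONCLUSIVE: "INCONCLUSIVE",
                }[call.diagnosis],
                "direct_mutation": {"mut": "YES", "wt": "NO", None: "NA"}[obs.direct_call],
                "concordant": {True: "YES", False: "NO", None: "NA"}[call.concordant],
                "flags": ";".join(flags),
            }
        )
    report = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcfio.write_family_vcf(out / "family_phased.vcf", family, phased=phased, embryos=observations)
        vcfio.write_panel_tsv(out / "panel.tsv", panel)
        linkage.marker_matrix(panel, calls).to_csv(out / "marker_matrix.tsv", sep="\t", index=False)
        for eid, segs in seg_by_embryo.items():
            vcfio.write_seg(out / f"{eid}.seg", eid, segs)
            vcfio.write_bins_tsv(out / f"{eid}.bins.tsv", tracks[eid])
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        config.to_file(out / "run_config.txt")

    if config.strict and (report["haplotype_mutation"] == "INCONCLUSIVE").any():
        raise RuntimeError("strict mode: at least one embryo is inconclusive")

    return PipelineResult(
        report=report,
        family=family,
        phased=phased,
        panel=panel,
        calls=calls,
        karyotypes=karyotypes,
        truths=truths,
    )


def render_report(report: pd.DataFrame, format: str = "tsv") -> str:
    """Render the embryo report as TSV or GitHub-style markdown."""
    if len(report) == 0:
        raise ValueError("empty report")
    if format == "tsv":
        return report.to_csv(sep="\t", index=False)
    if format == "markdown":
        cols = list(report.columns)
        lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for _, row in report.iterrows():
            lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")
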