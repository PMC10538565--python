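"""Plain-text interchange formats: VCF, read–allele TSV, bin TSV, SEG.

VCF writing is done directly (header-complete VCF 4.2 text); reading goes
through pysam. The carrier sample is phased with ``|`` and a PS tag (phase
block start); partner and embryos are unphased, with ``.`` marking alleles
lost to dropout and hemizygous X loci written as single-allele calls.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cnv import CnvSegment
from .phasing import ALT, MISSING, REF, PhasedTargetRegion
from .synthetic_data import (
    BinCountTrack,
    EmbryoObservation,
    FamilyTruth,
    SimRead,
    SimReadSet,
)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=pgtlink
##ALT=<ID=DEL,Description="Deletion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set (block start position)">
"""


def _allele_index(allele: str | None, ref: str, alt: str) -> str:
    if allele is None:
        return "."
    if allele == ref:
        return "0"
    if allele == alt:
        return "1"
    return "."


def write_family_vcf(
    path: str | Path,
    family: FamilyTruth,
    phased: PhasedTargetRegion | None = None,
    embryos: list[EmbryoObservation] | None = None,
    carrier_name: str = "carrier",
    partner_name: str = "partner",
) -> None:
    """Write carrier (+partner, +embryos) genotypes over the target window.

    With ``phased`` provided the carrier GT is phased hap1|hap2 with a PS
    tag per phase block; otherwise carrier sites are written unphased 0/1.
    The deletion at the mutation site is encoded with the symbolic ALT
    ``<DEL>``.
    """
    sites = family.site_table()
    embryos = embryos or []
    samples = [carrier_name, partner_name] + [e.embryo_id for e in embryos]
    pos_to_marker = {int(p): i for i, p in enumerate(family.positions)}

    lines = [_VCF_HEADER + f"##contig=<ID={family.chrom},length={999_999_999}>"]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for idx, row in sites.iterrows():
        pos = int(row.pos)
        is_mut = bool(row.is_mutation)
        ref = "N" if is_mut else str(row.ref)
        alt = "<DEL>" if is_mut else str(row.alt)

        if phased is not None:
            col = phased.column_of(pos)
            if col is None:
                continue
            h1, h2 = int(phased.hap1[col]), int(phased.hap2[col])
            if h1 == MISSING or h2 == MISSING:
                gt = "./."
                ps = None
            else:
                gt = f"{h1 - 1}|{h2 - 1}"
                block = int(phased.block_id[col])
                first = int(phased.positions[np.argmax(phased.block_id == block)])
                ps = first
            carrier_field = gt if ps is None else f"{gt}:{ps}"
        else:
            carrier_field = "0/1"

        fields = [carrier_field]
        # partner (untyped at scaffold-only sites)
        if is_mut:
            fields.append("0" if family.x_linked else "0/0")
        elif pos in pos_to_marker:
            g = family.partner_genotypes[pos_to_marker[pos]]
            r, a = str(row.ref), str(row.alt)
            fields.append("/".join(_allele_index(x, r, a) for x in g) if len(g) > 1 else _allele_index(g[0], r, a))
        else:
            fields.append(".")
        # embryos
        for e in embryos:
            gt_obs = e.genotypes.get(pos)
            r, a = (str(row.ref), str(row.alt))
            if is_mut:
                d = e.direct_call
                allele = None if d is None else ("1" if d == "mut" else "0")
                fields.append(allele if allele is not None else ".")
            elif gt_obs is None:
                fields.append(".")
            else:
                fields.append("/".join(_allele_index(x, r, a) for x in gt_obs))

        fmt = "GT:PS" if phased is not None else "GT"
        if phased is not None:
            # pad samples without a phase set with '.'
            fields = [f if ":" in f else f + ":." for f in fields]
        lines.append(
            "\t".join(
                [family.chrom, str(pos), ".", ref, alt, ".", "PASS", ".", fmt] + fields
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a (plain-text) VCF into a long-format genotype table via pysam.

    One row per sample × site with columns chrom, pos, ref, alt, sample,
    alleles (tuple with None for '.'), phased (bool), ps.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else None
            for name, s in rec.samples.items():
                gt = s.get("GT")
                alleles: list[str | None] = []
                for a in gt if gt is not None else ():
                    if a is None:
                        alleles.append(None)
                    else:
                        alleles.append(ref if a == 0 else alt)
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": ref,
                        "alt": alt,
                        "sample": name,
                        "alleles": tuple(alleles),
                        "phased": bool(getattr(s, "phased", False)),
                        "ps": s.get("PS"),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read–allele TSV
# ---------------------------------------------------------------------------


def write_reads_tsv(path: str | Path, readset: SimReadSet) -> None:
    """read_id, chrom, start, end, qscore, obs ("pos:allele,..." pairs)."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tqscore\tobs\n")
        for r in readset.reads:
            obs = ",".join(f"{p}:{a}" for p, a in sorted(r.obs.items()))
            fh.write(f"{r.read_id}\t{readset.chrom}\t{r.start}\t{r.end}\t{r.qscore}\t{obs}\n")


def read_reads_tsv(path: str | Path) -> SimReadSet:
    reads: list[SimRead] = []
    chrom = "chrX"
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, chrom, s, e, q, obs_s = line.rstrip("\n").split("\t")
            obs = {}
            if obs_s:
                for pair in obs_s.split(","):
                    p, a = pair.split(":")
                    obs[int(p)] = a
            reads.append(
                SimRead(read_id=rid, start=int(s), end=int(e), qscore=float(q), hap="?", obs=obs)
            )
    starts = [r.start for r in reads] or [0]
    ends = [r.end for r in reads] or [0]
    return SimReadSet(
        reads=reads,
        chrom=chrom,
        region_start=min(starts),
        region_end=max(ends),
        mean_len=float(np.mean([r.length for r in reads])) if reads else 0.0,
        depth=float("nan"),
        error_rate=float("nan"),
    )


# ---------------------------------------------------------------------------
# bins / SEG / panel
# ---------------------------------------------------------------------------


def write_bins_tsv(path: str | Path, track: BinCountTrack) -> None:
    track.df.to_csv(path, sep="\t", index=False)


def read_bins_tsv(path: str | Path, genome: dict[str, int] | None = None) -> BinCountTrack:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"bin TSV needs columns {sorted(need)}")
    if genome is None:
        genome = {str(c): int(df[df["chrom"] == c]["end"].max()) for c in df["chrom"].unique()}
    return BinCountTrack(df=df, genome=genome)


def write_seg(path: str | Path, sample: str, segments: list[CnvSegment]) -> None:
    """SEG format (log2 ratio in seg.mean), one row per segment."""
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for s in segments:
            log2 = math.log2(max(s.mean_ratio, 1 / 64))
            fh.write(f"{sample}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_bins}\t{log2:.4f}\n")


def write_panel_tsv(path: str | Path, panel) -> None:
    rows = [
        {
            "pos": m.pos,
            "allele_mut": m.allele_mut,
            "allele_wt": m.allele_wt,
            "partner": "/".join(m.partner_alleles),
            "side": m.side,
            "distance_bp": m.distance_bp,
        }
        for m in panel.markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path, chrom: str, gene_start: int, gene_end: int, mutation_pos: int):
    from .linkage import Marker, MarkerPanel

    df = pd.read_csv(path, sep="\t")
    markers = [
        Marker(
            pos=int(r.pos),
            allele_mut=str(r.allele_mut),
            allele_wt=str(r.allele_wt),
            partner_alleles=tuple(str(r.partner).split("/")),
            side=str(r.side),
            distance_bp=int(r.distance_bp),
        )
        for r in df.itertuples(index=False)
    ]
    return MarkerPanel(
        markers=markers,
        chrom=chrom,
        gene_start=gene_start,
        gene_end=gene_end,
        mutation_pos=mutation_pos,
    )
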