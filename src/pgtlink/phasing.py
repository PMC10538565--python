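"""Long-read QC and carrier haplotype phasing over the target window.

QC mirrors the standard long-read pass-filter (mean qscore ≥ 7, post-crop
length ≥ 1 kb, 50 bp cropped from each end). Phasing solves a two-group
minimum-error-correction (MEC) partition of the reads by iterated local
search with deterministic multi-start — under a symmetric per-site flip
error this is likelihood-equivalent to maximum-likelihood bipartitioning.
Adjacent markers are joined into a phase block only when enough reads span
both; the de novo mutation is then assigned to the haplotype whose read
group carries its alternate allele by majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import SimRead, SimReadSet

MISSING, REF, ALT = 0, 1, 2

UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter_reads(
    reads: "SimReadSet | list[SimRead]",
    min_qscore: float = 7.0,
    min_len_bp: int = 1000,
    crop_bp: int = 50,
) -> list[SimRead]:
    """Crop read ends, then drop low-quality and short reads.

    Cropping removes ``crop_bp`` from each end (and any site observation in
    the cropped margin) *before* the length test; a read passes if its mean
    qscore is ≥ ``min_qscore`` and its post-crop length is ≥ ``min_len_bp``.
    """
    items = reads.reads if isinstance(reads, SimReadSet) else list(reads)
    kept: list[SimRead] = []
    for r in items:
        if r.qscore < min_qscore:
            continue
        s = r.start + crop_bp
        e = r.end - crop_bp
        if e - s + 1 < min_len_bp:
            continue
        obs = {p: a for p, a in r.obs.items() if s <= p <= e}
        kept.append(
            SimRead(read_id=r.read_id, start=s, end=e, qscore=r.qscore, hap=r.hap, obs=obs)
        )
    return kept


# ---------------------------------------------------------------------------
# read-allele matrix
# ---------------------------------------------------------------------------


@dataclass
class ReadAlleleMatrix:
    """Reads × heterozygous-site matrix of observed alleles.

    ``data[i, j]`` is 0 (missing), 1 (ref) or 2 (alt) for read ``read_ids[i]``
    at ``positions[j]``; every retained row observes at least one column.
    """

    read_ids: list[str]
    positions: np.ndarray  # sorted, strictly increasing
    data: np.ndarray  # int8, shape (n_reads, n_sites)

    @property
    def n_reads(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def column_of(self, pos: int) -> int | None:
        i = int(np.searchsorted(self.positions, pos))
        if i < len(self.positions) and self.positions[i] == pos:
            return i
        return None


def build_allele_matrix(reads: list[SimRead], het_sites: pd.DataFrame) -> ReadAlleleMatrix:
    """Project QC-passing reads onto the heterozygous site grid.

    ``het_sites`` needs columns pos/ref/alt (the carrier's het sites,
    including the mutation site). Reads observing no site are dropped;
    observed alleles matching neither ref nor alt are recorded missing.
    """
    if len(het_sites) == 0:
        raise ValueError("het_sites must be nonempty")
    sites = het_sites.sort_values("pos")
    pos = sites["pos"].to_numpy(dtype=np.int64)
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    code = {int(p): {str(r): REF, str(a): ALT} for p, r, a in zip(pos, ref, alt)}

    rows = []
    ids = []
    for r in sorted(reads, key=lambda x: x.read_id):
        row = np.zeros(len(pos), dtype=np.int8)
        hit = False
        for p, a in r.obs.items():
            c = code.get(int(p))
            if c is None:
                continue
            v = c.get(str(a), MISSING)
            if v != MISSING:
                j = int(np.searchsorted(pos, int(p)))
                row[j] = v
                hit = True
        if hit:
            rows.append(row)
            ids.append(r.read_id)
    data = np.vstack(rows) if rows else np.zeros((0, len(pos)), dtype=np.int8)
    return ReadAlleleMatrix(read_ids=ids, positions=pos, data=data)


# ---------------------------------------------------------------------------
# MEC phasing
# ---------------------------------------------------------------------------


def mec_cost(data: np.ndarray, groups: np.ndarray) -> int:
    """Minimum-error-correction cost of a read bipartition.

    Per column and group, the minority-allele count (the corrections needed
    to make the group consensus-consistent), summed.
    """
    cost = 0
    for g in (0, 1):
        sub = data[groups == g]
        if sub.size == 0:
            continue
        n_ref = (sub == REF).sum(axis=0)
        n_alt = (sub == ALT).sum(axis=0)
        cost += int(np.minimum(n_ref, n_alt).sum())
    return cost


def _consensus(data: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-group per-column majority allele (ties → ref; empty → missing)."""
    out = np.zeros((2, data.shape[1]), dtype=np.int8)
    for g in (0, 1):
        sub = data[groups == g]
        if sub.size == 0:
            continue
        n_ref = (sub == REF).sum(axis=0)
        n_alt = (sub == ALT).sum(axis=0)
        out[g] = np.where(n_alt > n_ref, ALT, np.where(n_ref > 0, REF, MISSING))
        out[g][(n_ref == n_alt) & (n_ref > 0)] = REF
    return out


@dataclass
class PhasedTargetRegion:
    """Two carrier haplotypes over the window with phase-block structure.

    ``hap1``/``hap2`` are allele codes (0 missing, 1 ref, 2 alt) per column;
    they are complementary wherever called. ``block_id`` labels connected
    runs of columns (same block ⇔ phase between them is supported);
    ``block_support[j]`` counts reads spanning columns j and j+1.
    ``mutation_hap`` ∈ {"hap1", "hap2", "unresolved"}.
    """

    positions: np.ndarray
    hap1: np.ndarray
    hap2: np.ndarray
    block_id: np.ndarray
    block_support: np.ndarray
    read_groups: np.ndarray
    read_ids: list[str]
    mec: int
    chrom: str = "chrX"
    mutation_hap: str = UNRESOLVED
    mutation_pos: int | None = None

    def column_of(self, pos: int) -> int | None:
        i = int(np.searchsorted(self.positions, pos))
        if i < len(self.positions) and self.positions[i] == pos:
            return i
        return None

    def block_of(self, pos: int) -> int | None:
        i = int(np.searchsorted(self.positions, pos))
        if i < len(self.positions) and self.positions[i] == pos:
            return int(self.block_id[i])
        return None

    def linked_to_mutation(self) -> np.ndarray:
        """Boolean mask of columns in the mutation-containing phase block."""
        if self.mutation_pos is None:
            return np.zeros(len(self.positions), dtype=bool)
        b = self.block_of(self.mutation_pos)
        return self.block_id == b


def _exact_partition(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Exhaustive MEC minimization over all read bipartitions (small n only)."""
    n = data.shape[0]
    best_groups = np.zeros(n, dtype=np.int8)
    best_cost = mec_cost(data, best_groups)
    for mask in range(1, 2 ** (n - 1)):  # fix read 0 in group 0 (label symmetry)
        groups = np.array([(mask >> i) & 1 for i in range(n)], dtype=np.int8)
        cost = mec_cost(data, groups)
        if cost < best_cost:
            best_cost = cost
            best_groups = groups
    return best_groups, int(best_cost)


def _greedy_sweep(data: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Assign reads in ``order`` to the better-matching running consensus."""
    n, m = data.shape
    counts = np.zeros((2, m, 2), dtype=np.int64)  # group × column × {ref,alt}
    groups = np.zeros(n, dtype=np.int8)
    for idx in order:
        row = data[idx]
        cols = np.nonzero(row)[0]
        scores = np.zeros(2, dtype=np.int64)
        for g in (0, 1):
            n_ref = counts[g, cols, 0]
            n_alt = counts[g, cols, 1]
            maj = np.where(n_alt > n_ref, ALT, np.where(n_ref > n_alt, REF, MISSING))
            scores[g] = ((maj != MISSING) & (row[cols] != maj)).sum() - (
                (maj != MISSING) & (row[cols] == maj)
            ).sum()
        g = 0 if scores[0] <= scores[1] else 1
        groups[idx] = g
        counts[g, cols[row[cols] == REF], 0] += 1
        counts[g, cols[row[cols] == ALT], 1] += 1
    return groups


def _local_search(
    data: np.ndarray, groups: np.ndarray, max_iter: int
) -> np.ndarray:
    n = data.shape[0]
    is_ref = data == REF
    is_alt = data == ALT
    for _ in range(max_iter):
        cons = _consensus(data, groups)
        mism = np.empty((n, 2), dtype=np.int64)
        for g in (0, 1):
            h = cons[g]
            mism[:, g] = (is_ref[:, h == ALT]).sum(axis=1) + (is_alt[:, h == REF]).sum(axis=1)
        new = np.where(
            mism[:, 1] < mism[:, 0], 1, np.where(mism[:, 0] < mism[:, 1], 0, groups)
        ).astype(np.int8)
        if np.array_equal(new, groups):
            break
        groups = new
    return groups


def phase_region(
    matrix: ReadAlleleMatrix,
    min_overlap_reads: int = 2,
    min_shared_snps: int = 1,
    n_starts: int = 8,
    max_iter: int = 50,
    seed: int = 0,
    chrom: str = "chrX",
    exact_max_reads: int = 12,
) -> PhasedTargetRegion:
    """Partition reads into two haplotype groups minimizing MEC cost.

    Instances with ≤ ``exact_max_reads`` reads are solved exactly by
    enumerating all bipartitions. Larger instances use iterated local
    search: a greedy positional sweep plus seeded random restarts, each
    refined by consensus/reassignment alternation; the best partition wins,
    with ties broken by first occurrence so the result is deterministic.
    Adjacent columns join one phase block only if ≥ ``min_overlap_reads``
    reads observe both while sharing ≥ ``min_shared_snps`` observed columns.
    """
    if matrix.n_reads == 0:
        raise ValueError("empty matrix: nothing to phase")
    data = matrix.data
    n = matrix.n_reads
    rng = np.random.default_rng(seed)

    if n <= exact_max_reads:
        best_groups, best_cost = _exact_partition(data)
    else:
        starts_cols = np.argmax(data != MISSING, axis=1)
        sweep = _greedy_sweep(data, np.argsort(starts_cols, kind="stable"))
        best_groups = _local_search(data, sweep, max_iter)
        best_cost = mec_cost(data, best_groups)
        for _ in range(n_starts - 1):
            groups = _local_search(data, rng.integers(0, 2, n).astype(np.int8), max_iter)
            cost = mec_cost(data, groups)
            if cost < best_cost:
                best_cost = cost
                best_groups = groups
    assert best_groups is not None

    cons = _consensus(data, best_groups)
    hap1 = cons[0].copy()
    comp2 = np.where(cons[1] == REF, ALT, np.where(cons[1] == ALT, REF, MISSING)).astype(np.int8)
    # fill hap1 from group 2's complement where group 1 is silent
    hap1 = np.where(hap1 == MISSING, comp2, hap1).astype(np.int8)
    hap2 = np.where(hap1 == REF, ALT, np.where(hap1 == ALT, REF, MISSING)).astype(np.int8)

    # phase blocks from read spanning support
    covered = data != MISSING
    n_cols = matrix.n_sites
    support = np.zeros(max(n_cols - 1, 0), dtype=np.int64)
    for j in range(n_cols - 1):
        both = covered[:, j] & covered[:, j + 1]
        if min_shared_snps > 1:
            shared = covered[both].sum(axis=1)
            support[j] = int((shared >= min_shared_snps).sum())
        else:
            support[j] = int(both.sum())
    block_id = np.zeros(n_cols, dtype=np.int64)
    b = 0
    for j in range(1, n_cols):
        if support[j - 1] < min_overlap_reads:
            b += 1
        block_id[j] = b

    return PhasedTargetRegion(
        positions=matrix.positions.copy(),
        hap1=hap1,
        hap2=hap2,
        block_id=block_id,
        block_support=support,
        read_groups=best_groups,
        read_ids=list(matrix.read_ids),
        mec=int(best_cost),
        chrom=chrom,
    )


def assign_mutation_phase(
    phased: PhasedTargetRegion, matrix: ReadAlleleMatrix, mutation_pos: int
) -> str:
    """Assign the de novo mutation to hap1 or hap2 by read-group majority.

    Reads carrying the mutation's alternate allele vote for their group; a
    tie, an uncovered mutation column, or a mutation column unlinked to any
    other phased marker leaves the mutation unresolved. Updates ``phased``
    in place and returns the label.
    """
    col = matrix.column_of(mutation_pos)
    phased.mutation_pos = mutation_pos
    label = UNRESOLVED
    if col is not None:
        alt_reads = matrix.data[:, col] == ALT
        votes1 = int((alt_reads & (phased.read_groups == 0)).sum())
        votes2 = int((alt_reads & (phased.read_groups == 1)).sum())
        linked = phased.block_id == phased.block_id[col]
        if linked.sum() > 1 and votes1 != votes2:
            label = "hap1" if votes1 > votes2 else "hap2"
    phased.mutation_hap = label
    return label


def phased_site_table(
    phased: PhasedTargetRegion, sites: pd.DataFrame
) -> pd.DataFrame:
    """Join phase calls back onto the allele letters of the site table.

    Adds hap_mut/hap_wt allele columns (oriented by ``mutation_hap``) and a
    ``linked`` flag marking columns in the mutation's phase block; raises if
    the mutation phase is unresolved.
    """
    if phased.mutation_hap == UNRESOLVED:
        raise ValueError("mutation phase unresolved; cannot orient haplotypes")
    sites = sites.sort_values("pos").reset_index(drop=True)
    if len(sites) != len(phased.positions) or np.any(
        sites["pos"].to_numpy() != phased.positions
    ):
        raise ValueError("site table does not match phased positions")
    mut_codes = phased.hap1 if phased.mutation_hap == "hap1" else phased.hap2
    wt_codes = phased.hap2 if phased.mutation_hap == "hap1" else phased.hap1

    def decode(codes: np.ndarray) -> list[str | None]:
        out: list[str | None] = []
        for c, r, a in zip(codes, sites["ref"], sites["alt"]):
            out.append(None if c == MISSING else (str(r) if c == REF else str(a)))
        return out

    df = sites.copy()
    df["hap_mut"] = decode(mut_codes)
    df["hap_wt"] = decode(wt_codes)
    df["linked"] = phased.linked_to_mutation()
    return df
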