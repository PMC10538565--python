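# pgtlink

Reference-free preimplantation genetic testing for monogenic disease
(PGT-M) when the pathogenic variant is a **de novo mutation**: no affected
relatives exist from whom the risk haplotype could be inherited, so the
classic family-based linkage workup is impossible. `pgtlink` implements the
alternative strategy of establishing the carrier's haplotype phase
**directly from long reads**, then diagnosing embryo biopsies by
informative-SNP linkage with allele-dropout tolerance, alongside
low-coverage copy-number/karyotype calling — and ships a synthetic family
generator so the entire workflow is testable end to end without any patient
data.

## Who it is for

Developers and analysts of PGT-M pipelines who need a transparent,
deterministic, fully scriptable model of the long-read + low-pass-WGA
diagnostic workflow: every stage is a library function with a seeded
generator behind it, so edge cases (dropout, recombination, aneuploidy,
mosaic-free segmental CNVs) can be produced on demand.

## The method

**Phase.** The carrier is heterozygous for a single-base deletion on an
X-linked gene. Long reads (mean ~14.4 kb, ~28X) are QC-filtered as in the
standard long-read pass filter (mean qscore ≥ 7, 50 bp cropped per end,
post-crop length ≥ 1 kb) and projected onto the carrier's heterozygous
sites in a ±2 Mb window. Reads are partitioned into the two haplotype
groups by **minimum error correction** (MEC): find the bipartition *S* of
reads minimizing

&nbsp;&nbsp;&nbsp;&nbsp;MEC(S) = Σ<sub>columns j</sub> Σ<sub>groups g</sub> min(#ref<sub>g,j</sub>, #alt<sub>g,j</sub>),

which is maximum-likelihood under a symmetric allele-flip error. Small
instances are solved exactly by enumeration; larger ones by a greedy
positional sweep plus seeded multi-start local search. Adjacent markers
join one phase block only when ≥ 2 reads span both; the mutation is
assigned to the haplotype whose read group carries its alternate allele by
majority.

**Link.** Informative SNPs — heterozygous in the carrier, homozygous (or
hemizygous, male X) in the partner — are selected within the window, at
most 15 per side, nearest the gene first. Each embryo genotype observation
is reduced to the maternally inherited allele (for XX embryos by
subtracting the obligate paternal allele; XY embryos are read off
directly), and the embryo is diagnosed by majority vote with a margin rule:
*affected* when mutant-haplotype votes are ≥ 80% of informative votes and
at least 10 votes exist. Ambiguous observations abstain, so allele dropout
degrades toward *inconclusive* rather than toward a wrong call. A block of
≥ 3 consecutive markers switching haplotype flags a candidate
recombination, and votes are restricted to the gene-side block.

**Count.** Reads are binned at 1 Mb, GC-corrected (LOWESS of count on GC,
divided out) and scaled so 1.0 is the diploid expectation. Per chromosome,
**circular binary segmentation** (maximal arc t-statistic, permutation
acceptance, recursive splitting) partitions the ratios into constant-copy
segments; integer copies follow the ±50% dose rule (ratio 1.5 → 3 copies,
0.5 → 1), and events ≥ 4 Mb are rendered into a karyotype string such as
`47, XYY, +Y (×2)` or `46, XY, −21 (14000001→41000000, ∼27 Mb, ×1)`.

**Annotate.** The coding consequence of the single-base deletion is
computed as HGVS `p.<Aa><N><Bb>fs*<K>` (stop counted as position K in the
shifted frame), and ACMG evidence codes are combined by the published rules
— e.g. {PVS1, PM2, PM6} → Pathogenic.

## Worked example

```bash
pgtlink all --out-dir demo --seed 11
```

writes a phased VCF, the marker panel, a per-marker matrix and per-embryo
SEG files, and prints the embryo report:

```
embryo  cnv_result  haplotype_mutation  direct_mutation  concordant  flags
E1      46, XX      YES                 YES              YES
E2      46, XY      NO                  NO               YES
E3      46, XX      NO                  NO               YES
E4      46, XX      NO                  NO               YES  recombination; votes restricted to gene-side block
E5      46, XY      NO                  NO               YES
E6      46, XY      YES                 YES              YES
E7      46, XX      YES                 YES              YES
E8      46, XY      NO                  NO               YES
```

Reading E1's row: the biopsy's bin counts segment to a euploid female
karyotype; the informative-SNP vote says the embryo inherited the
maternal haplotype carrying the mutation (`YES`); the simulated direct
mutation assay agrees (`YES`); the two calls are concordant. E4 carries a
detected recombination between the marker panel and is still called from
the gene-containing block. Every diagnosis matches the generator's hidden
truth for this seed.

The same stages are available individually (`simulate`, `phase`, `cnv`,
`report`) and as library calls:

```python
import pgtlink as pg

family = pg.simulate_family(n_markers=30, window_bp=2_000_000, seed=1)
reads = pg.simulate_long_reads(family, depth=28, mean_len=14_400, seed=1)
matrix = pg.build_allele_matrix(pg.qc_filter_reads(reads), family.site_table())
phased = pg.phase_region(matrix, seed=0)
pg.assign_mutation_phase(phased, matrix, family.mutation_pos)   # 'hap1'
```

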