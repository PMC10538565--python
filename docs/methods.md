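# Methods

## Scope and model

`pgtlink` models the diagnostic core of reference-free PGT-M for a de novo
single-base deletion on an X-linked gene: establishing the carrier's
haplotype phase from long reads alone, diagnosing embryo biopsies by
informative-SNP linkage, and calling copy-number changes from shallow
sequencing. Wet-lab steps (IVF, biopsy, amplification chemistry,
basecalling, alignment) are outside the model; the package consumes either
synthetic observations with the right statistical structure or
already-aligned/called inputs in plain-text formats.

Coordinates are 1-based inclusive throughout, matching VCF convention.

## Synthetic family generator

The generator defines the conditions under which every downstream claim is
tested.

* **Marker geometry.** 30 biallelic SNP markers, all heterozygous in the
  carrier, split evenly between the flanks of the gene inside a ±2 Mb
  window; the partner is hemizygous at each (male, X-linked region), so by
  construction every marker is an informative candidate. The de novo
  deletion is placed uniformly inside the gene interval.
* **Phasing scaffold.** Phasing physically requires heterozygous sites
  spaced below the read length; 30 markers over 4 Mb (~130 kb spacing) can
  never be chained by ~14 kb reads. Real genomes provide this density
  naturally (an individual is heterozygous roughly every 1–2 kb), and the
  assay phases on all het sites before selecting informative markers. The
  generator therefore scatters a dense carrier-het scaffold (default 400
  SNPs/Mb) through the window, used only by the phasing stage.
* **Long reads.** Read count = depth × window / mean length, with depth
  28X and mean length 14.4 kb by default. Lengths follow a gamma law with
  shape 2 (heavy right tail typical of size-selected long-read libraries);
  starts are uniform. Each read originates from one haplotype by a fair
  coin and reports that haplotype's allele at every covered site, flipped
  independently with the per-site error rate (default 0.01). A
  configurable fraction of reads (default 5%) receives a mean qscore below
  the q = 7 filter threshold.
* **Embryos.** Each embryo inherits one carrier haplotype by a fair coin,
  with at most one recombination breakpoint per window (the ~4 Mb window
  makes two crossovers negligible). Allele dropout acts independently per
  allele (default rate 0.05; the study's WGA dropout rate is not published,
  so this default is a conventional WGA figure, configurable and not
  asserted as the study's value). A dropped allele is recorded as an
  explicit missing slot; the optional `homozygote` mode instead collapses
  a heterozygote to an apparently homozygous call, the classic
  misdiagnosis signature. XY embryos carry a single X allele and receive
  no paternal X.
* **Bin counts.** 1 Mb bins over hg19-sized chromosomes (trailing partial
  megabases dropped so all bins share one width). Counts are negative
  binomial with mean (copy/2) × reads-per-bin × gc\_bias(gc) and variance
  (1 + d)·mean; the dispersion d (default 0.1) is the fractional variance
  inflation over Poisson contributed by amplification noise, giving a
  per-bin CV ≈ 0.105 at the default 100 reads/bin — typical of low-pass
  WGA tracks. GC bias is a smooth unimodal efficiency curve peaked at GC
  0.45. The synthetic GC profile mixes an isochore-scale smoothed walk
  with independent per-bin variation; the independent component ensures
  every chromosome samples the full GC range, so a GC fit cannot absorb a
  chromosome's copy state.

What the generator does **not** emulate: base-level sequence and error
profiles, chimeric/split reads, mappability and centromere gaps, mosaicism,
reference bias, and locus-specific amplification artifacts. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on any real library.

## Phasing

Reads pass QC if their mean qscore is ≥ 7 and their length after cropping
50 bp per end is ≥ 1 kb (crop first, then length test). Observations in
cropped margins are discarded. The read–site matrix keeps reads covering
at least one heterozygous site.

Phasing minimizes the minimum-error-correction (MEC) objective — the
number of allele flips needed to make each read consistent with its
group's consensus — which is the maximum-likelihood bipartition under a
symmetric flip error. Instances with ≤ 12 reads are solved exactly by
enumerating all 2^(n−1) bipartitions. Larger instances use a greedy sweep
in read-start order (each read joins the better-matching running
consensus) refined by consensus/reassignment iteration, plus seeded random
restarts; ties keep the current assignment and the first-found best
partition wins, so results are bit-reproducible. The label pair
(hap1/hap2) is arbitrary; all downstream logic is orientation-free until
the mutation is assigned to the haplotype whose read group carries its
alternate allele by majority (ties, uncovered sites, or a mutation column
unlinked to any other marker yield `unresolved`).

Phase blocks: adjacent markers are linked when at least 2 reads observe
both (the spanning-read criterion); markers outside the mutation's block
are reported but excluded from the linkage panel.

## Linkage diagnosis

A marker enters the panel if the carrier is heterozygous with known phase,
the partner is homozygous or hemizygous, the site lies within the window
and in the mutation's phase block; when one side offers more than 15
candidates the nearest to the gene are kept. Observations reduce to the
maternal allele; a lone observed allele equal to the obligate paternal
allele is ambiguous (maternal match vs maternal dropout) and abstains.
This conservative rule makes the diagnosis monotone in dropout: raising
ADO can push a call to inconclusive but cannot flip it.

Vote thresholds (≥ 10 informative votes, ≥ 80% margin) are chosen so that
no single corrupted marker can flip a call; both are configuration keys.
Recombination is declared when two runs of ≥ 3 consecutive informative
markers disagree; votes then come from the gene-containing run, and a
switch straddling the gene itself is inconclusive (the inherited allele at
the gene cannot be determined from flanking markers). Genotypes containing
an allele seen in neither parent are counted as inconsistencies and
excluded from voting.

## Copy-number analysis

Bins are GC-corrected by LOWESS of count on GC over autosomal non-zero
bins (fit divided out), then scaled by the autosomal median so 1.0 is the
diploid expectation. Self-normalization is the default because no external
reference set ships with the package; a per-bin baseline can be supplied.

Segmentation is circular binary segmentation: per chromosome, the arc
(i, j] maximizing |mean_in − mean_out| / √(1/k + 1/(n−k)) is tested by
permutation (default 10,000 permutations, α = 0.01, seeded; early
rejection once the exceedance count exceeds α·n). Significant splits
recurse. Adjacent segments within 0.2 of diploid ratio are merged back, as
are same-copy neighbours. Integer copies are round(2 × ratio) with exact
half-way ties resolved toward diploid (conservative). Chromosomes shorter
than 3 bins are skipped with a warning.

Karyotype strings: sex-chromosome copies come from the X and Y mean
ratios; the leading total is the sum of autosomal whole-chromosome copies
plus the sex-chromosome copies. A chromosome is a whole-chromosome event
only when a single segment spans it; otherwise segments are reported
against the chromosome's expected copy, and only events ≥ 4 Mb (after
merging) are printed — smaller ones are suppressed. Without a cytoband
table event ranges are printed in bp; a BED-like band table switches the
output to band coordinates. If neither sex chromosome reaches one copy the
sex designation is reported as ambiguous with the raw ratios.

## Variant annotation

`codon_index` is ⌈position/3⌉. Frameshift consequences translate the
reference codon at the deletion, re-translate the shifted frame from that
codon, and name the first residue that genuinely differs (so deletions in
repeats never report an unchanged residue); K in `fs*K` counts the stop's
position in the new frame starting from the changed residue, `fs*?` when
no stop exists downstream, and an immediate stop is written
`p.<Aa><N>*`. Transcript retrieval is deliberately not built in — the CDS
is always supplied by the caller, keeping the package offline. ACMG
combination implements the published rule table verbatim; conflicting
pathogenic and benign evidence yields uncertain significance.

## Pipeline

`run_pipeline` derives one seed per stage from the master seed
(`numpy.random.SeedSequence.spawn`), so a rerun with the same
configuration is byte-identical. Embryo sex is inferred from the
CNV-stage X/Y ratios and fed to the linkage stage (hemizygosity
handling); a mismatch against the genotype-implied sex raises a flag.
Configuration is a flat `key = value` text file; CLI flags override file
values; `--strict` converts any inconclusive embryo into a non-zero exit.

## Problem sizes used in the test suite

Unit tests run on reduced windows (250–400 kb), reduced genomes (4–6
chromosomes) and 1,000–2,000 CBS permutations; the acceptance checks use
the full defaults where the claim demands them (30-marker panel with 500
embryos; 100 seeded replicates for CNV recovery and false-positive rate;
full-genome karyotypes). These sizes were chosen to exercise every claim
at meaningful statistical resolution while keeping the suite quick to run.

## Known limitations

* The MEC heuristic is exact only for ≤ 12 reads; beyond that optimality
  is empirical (it is verified against exhaustive search on small
  instances and against generator truth at realistic depth).
* Self-normalization assumes most of the genome is diploid; a genome
  mostly covered by CNVs would bias the median (mitigated, not removed, by
  the merging rules).
* No mosaicism model: segment ratios are interpreted as integer copies.
* The ADO model treats alleles independently; real WGA dropout is
  correlated along the genome.
* X-linked-region-first: autosomal mode exists (diploid partner
  subtraction) but paternal-haplotype linkage is not modelled, mirroring
  the maternal-only design of the workflow.
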