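# Methods

This note records the models behind each module, the defaults and why
they were chosen, and what the simulator does and does not emulate.

## The simulated study system

`simgenome` emulates the data-generating process of a re-sequencing +
genotyping-by-sequencing study of inbred crop lines:

**Reference genome.** Chromosome sequences are uniform random nucleotides
with protein-coding genes placed by a renewal process. Mean gene spacing
is 12 Kbp on the euchromatic arms and 140 Kbp inside the pericentromere (a
central interval covering 30% of each chromosome by default), reproducing
the arm/pericentromere gene-density contrast of a typical small grass
genome. Each gene has 1–4 exons, 60–300 codons, UTRs on the terminal
exons, and its CDS is overwritten with a clean open reading frame
(ATG … stop, no internal stop) so that consequence calling on simulated
variants behaves like it does on real annotation. Genes are non-
overlapping by construction.

**Polymorphism landscape.** Founder variant density is blockwise constant:
blocks of 50–300 Kbp drawn per chromosome, each assigned one of the
intensity levels {0.4, 2, 10, 40} SNP/Kbp (a 100-fold range). The level
is the *expected pairwise* SNP density between founders of different
races; each founder receives an independent Poisson draw at half that
rate per bp against the reference. Founders of the same race share a
fraction (default 0.7) of their draw through a race-level pool, which
compresses within-race distances and makes races cluster in dendrograms
without simulating a coalescent. 10% of variants are INDELs with
geometric lengths (mean 3 bp), plus a configurable handful (default 3 per
founder per chromosome) of large intergenic deletions of 25–500 bp that
later appear as zero-depth runs in depth tracks.

**Methylation.** Each restriction site is methylated by an independent
Bernoulli draw whose probability depends on context — genic 0.5,
intergenic 0.9, pericentromeric 0.97 by default, with precedence
genic > pericentromeric > intergenic for sites in genes inside the
pericentromere. These defaults put site recovery near 50% at genes and
near zero in the chromosome core, the qualitative pattern the assay is
designed to exploit.

**Meiosis.** Crossover counts per chromosome are Poisson with mean equal
to the genetic length in Morgans; positions are uniform on the cM scale
and mapped to bp through a piecewise-linear map in which the
pericentromere receives a fixed share (default 5%) of the genetic length.
There is no crossover interference. The 5% share is a free parameter: the
phenomenon (suppressed pericentromeric recombination) is well established
but no quantitative suppression factor was available, so the default was
chosen to make the cM/Mbp profile dip visibly without becoming exactly
zero.

**Pedigrees and selection.** Crosses are F1, selfing, or single-seed
descent for g generations. Selection loci are enforced by construction:
after each cross the stated founder's haplotype is written over the locus
interval on both haplotypes, i.e. selection is modelled as complete
fixation rather than as differential survival of gametes. This makes the
IBD-at-selection-locus truth exact, at the cost of not modelling partial
sweeps.

**RILs.** A RIL population of n lines is the F1 of two parents followed
by g−1 rounds of single-seed-descent selfing; residual heterozygosity is
(1/2)^(g−1) per locus (≈0.05% at F12). Marker genotypes are read from the
owning mosaic segment; heterozygous residues are emitted as missing.

**What the simulator does not emulate:** read-level sequencing (FASTQ),
alignment and base-calling error, transposon/repeat content, segmental
duplications, crossover interference, partial selection, and realistic
demography. Tests passing on simulated data therefore validate the
estimators' correctness under the stated generative model, not their
robustness to alignment artefacts — the dominant error source for real
INDEL calls.

## Digital-genotyping tags

The enzyme motif is fixed to GCCGGC with cut G^CCGGC (the standard NgoMIV
recognition/cut site).
Tags of 37 or 72 bp are read outward from the cut on both sides; tags
truncated by a chromosome end are dropped and counted. Tags whose exact
sequence occurs more than once in the genome (either strand) are flagged
non-unique and excluded from marker use; multiplicity is exact-match, no
mismatch tolerance. Recovery is Poisson: a site yields reads only if
unmethylated, with depth ~ Poisson(15) and a 5-read threshold, giving
per-site recovery probability P(Poisson(15) ≥ 5) = 0.99914 for
unmethylated sites. The windowed recovered/predicted fraction is
undefined — not zero — in windows with no predicted site.

Tag-versus-consensus QC classifies each pre-paired (site, side) pair by
exact equality, then equal-length substitution-only comparison, then a
global unit-cost alignment (edlib): any gap in the optimal alignment makes
the pair indel-discordant. A similarity search (as a BLAST step would do)
is unnecessary because tags and consensus are already keyed by site.

## Variant classification

Location categories follow the precedence coding > UTR > intron >
intergenic; a variant overlapping two genes takes the finest category and,
within coding, the more severe consequence (ranked stop_gained >
stop_lost > frameshift > missense > inframe > synonymous). SNP
consequences are computed codon-locally (strand-aware, standard code); the
test suite checks agreement with an independent brute-force oracle that
applies the variant, translates the whole CDS and diffs the protein, on
1000 random toy genes. INDELs are left-normalized before classification
(misaligned INDEL representations are a classic source of spurious
discordance between call sets, so comparisons must be
representation-invariant);
frameshift iff the net length change is not a multiple of 3, otherwise
the edited CDS is re-translated to detect gained/lost stops. UTRs are
reported as one class (5′/3′ are retained internally on the gene model).

A note on published category tables of this kind: the reference table
this layout mirrors heads its dominant SNP column "Intragenic" although
it carries the ~86% intergenic majority; this package labels that column
intergenic. Counts are always reported exactly as computed, with no
reconciliation against externally quoted percentages.

Large INDELs are maximal runs of exactly zero depth with length ≥ 25 bp;
adjacent runs separated by one covered base stay distinct. Densities are
variants per Kbp with the true window length in the denominator (the last
partial window is normalized by its own length); per-gene density uses
the full UTR-to-UTR span; the 10-Mbp regional profile divides genic and
intergenic counts by the genic/intergenic base totals per bin, with NaN
where a class has no bases.

## Haplotype tracing and IBD

Marker attribution is rule-based, not probabilistic: informative markers
(parents differ, offspring matches one) take that parent's label, lifted
recursively until a founder is reached. When a named parent was never
genotyped, offspring alleles that do not match the genotyped parent are
assigned to the other parent and flagged tentative (the standard treatment when one accession in a breeding pedigree was
never genotyped); a missing
individual call, by contrast, yields unknown-missing. Blocks are maximal
single-label runs over informative markers; isolated discordant runs of
at most one marker (configurable) flanked by agreeing labels are absorbed,
a deliberate guard against isolated genotyping errors; block boundaries
are reported at the midpoint of the flanking marker gap because breakpoint
position is only known to marker resolution. Runs under 5 markers are
kept but flagged low-confidence.

IBD detection offers two evidence types: density (maximal runs of 100-Kbp
windows under 0.05 SNP/Kbp totalling ≥ 1 Mbp) and haplotype-label overlap.
The three thresholds are free parameters exposed in configuration; the
density threshold is deliberately an order of magnitude below the lowest
simulated landscape intensity. Lowering the threshold can only shrink
segments (monotonicity is tested).

## Genetic maps

The estimator chain is: observed recombinant fraction R between adjacent
physically ordered markers (pairwise deletion of missing calls) → selfed-
RIL correction r = R/(2(1−R)), the inverse of R = 2r/(1+2r), assuming
fully inbred lines (residual F12 heterozygosity of (1/2)^11 is ignored) →
Kosambi distance, summed along each chromosome. Identical genotype columns
are collapsed to the first marker by position; markers whose best adjacent
LOD does not exceed 3.0 are dropped. Marker order is taken from physical
position; no maximum-likelihood reordering is attempted. Note an
intentional model mismatch: meioses are simulated without interference
(Haldane world) while estimation uses Kosambi, matching field practice for RIL maps; at the marker spacings involved (<1 cM) the difference is far below
the sampling noise, and a Haldane option exists for exact-model checks.
Under the study conditions (90 F12 lines, one 120-cM chromosome, 150
markers) the measured recovery across 20 fixed-seed replicates was within
13.7% per replicate and 2.1% in the mean — inside the ±15%/±5% bands the
test suite enforces.

The cM/window profile spreads each inter-marker interval's cM uniformly
over its physical span and sums overlaps per window, so the profile always
sums to the map length.

## Distances and dendrograms

Marker alleles are concatenated into a character matrix (one column per
site, padded with N for missing/width mismatch; N is removed pairwise).
TN93 uses base frequencies estimated from each pair itself and the two
transition proportions plus the transversion proportion; a non-positive
logarithm argument raises a saturation error for that pair (bootstrap
replicates fall back to p-distance when this happens). The implementation
was cross-checked against an independent reference implementation to
10 decimal places. UPGMA merges the closest pair at height d/2 with
size-weighted average linkage; ties break on the lexicographically
smallest (min-name, max-name) representative pair, making output unique
and deterministic. Bootstrap support resamples alignment columns with
replacement and counts, per original internal clade (by leaf-set
identity), the percentage of replicate trees containing it. Supports
attach to the original tree, not a consensus tree.

## Pipeline

Stages communicate through files in the run directory (FASTA, GFF3, VCF
4.2, bedGraph, TSV), so each stage can be re-run alone; every writer has
a reader and write→read→write is byte-identical. One master seed drives
named RNG substreams per stage, making full runs reproducible
checksum-for-checksum. The pipeline's dendrogram stage clusters only
(near-)inbred genotypes: heterozygous F1/backcross nodes have no
homozygous marker calls and would share no valid positions. Default
problem sizes (two chromosomes totalling 3.5 Mbp, four founders, 90 F12
RILs) were chosen so a full run with truth tables completes in about a
minute while keeping every per-window statistic well populated.

## Known limitations

- Tag QC on simulated data compares reference-predicted tags with each
  line's consensus, so its "perfect" percentage measures tag
  polymorphism content, not re-sequencing fidelity; emulating alignment
  infidelity at INDELs would require a read-level error model that is out
  of scope.
- Origin tracing is deterministic; it has no error model and no
  imputation, and short double-recombinant segments below marker
  resolution are invisible.
- The genetic map assumes selfed RILs; other mating designs need a
  different correction.
- TN93 is undefined for saturated pairs; the package reports the error
  rather than truncating distances.
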