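"""Forward simulation of inbred-crop genomes with known truth.

The generator emulates the structure of a small grain-crop genome as used
for polymorphism-density studies: chromosomes with gene-dense euchromatic
arms and a gene-poor pericentromere, founder accessions from distinct races
whose pairwise SNP density varies >100-fold across contiguous blocks,
methylation concentrated outside genes, and pedigrees built by crossing,
backcrossing and selfing with occasional fixed selection loci that create
identical-by-descent regions. Recombinant inbred line (RIL) populations are
produced by single-seed descent.

All randomness flows from one master seed through named substreams, so each
stage is individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotatedGenome, GeneModel, Interval, Variant

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP = [a + b + c for a in BASES for b in BASES for c in BASES
            if a + b + c not in STOP_CODONS]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from a master seed."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31),
                                                        spawn_key=(key,)))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a compact two-chromosome genome that preserves the
    statistical features of the real system: ~1 gene / 12 Kbp on the arms
    versus sparse genes in the central pericentromere, pairwise founder SNP
    density alternating between 0.4 and 40 SNP/Kbp in blocks of 50-300 Kbp,
    strongly methylated intergenic/pericentromeric restriction sites, and a
    90-line F12 RIL population.
    """

    seed: int = 0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000})
    genetic_lengths_cm: dict[str, float] = field(
        default_factory=lambda: {"chr1": 120.0, "chr2": 100.0})
    pericentromere_fraction: float = 0.3
    gene_spacing_arm_bp: float = 12_000.0
    gene_spacing_peri_bp: float = 140_000.0
    founders: dict[str, str] = field(
        default_factory=lambda: {"Kafir1": "Kafir", "Kafir2": "Kafir",
                                 "Durra1": "Durra", "Caudatum1": "Caudatum"})
    intensity_levels_snp_per_kbp: tuple[float, ...] = (0.4, 2.0, 10.0, 40.0)
    landscape_block_bp: tuple[int, int] = (50_000, 300_000)
    race_sharing: float = 0.7
    indel_fraction: float = 0.1
    indel_mean_bp: float = 3.0
    large_deletions_per_founder: int = 3
    large_deletion_bp: tuple[int, int] = (25, 500)
    methylation_probs: dict[str, float] = field(
        default_factory=lambda: {"genic": 0.5, "intergenic": 0.9,
                                 "pericentromeric": 0.97})
    peri_crossover_share: float = 0.05
    ril_n: int = 90
    ril_generations: int = 12

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        for name, n in self.chromosome_lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if not 0 <= self.pericentromere_fraction < 1:
            raise ValueError("pericentromere_fraction must be in [0, 1)")
        if any(v < 0 for v in self.intensity_levels_snp_per_kbp):
            raise ValueError("intensities must be >= 0")
        for ctx, p in self.methylation_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"methylation prob for {ctx} outside [0,1]")

    def pericentromere(self, chrom: str) -> Interval:
        n = self.chromosome_lengths[chrom]
        half = self.pericentromere_fraction / 2
        return (int(n * (0.5 - half)), int(n * (0.5 + half)))


# ---------------------------------------------------------------------------
# density landscape


@dataclass
class DensityLandscape:
    """Blockwise pairwise-SNP-density intensities (SNP/Kbp per founder pair).

    Blocks tile each chromosome exactly; the ratio of the largest to the
    smallest block intensity sets the realized density contrast.
    """

    blocks: dict[str, list[tuple[int, int, float]]]

    def __post_init__(self) -> None:
        for chrom, blks in self.blocks.items():
            pos = 0
            for s, e, lam in blks:
                if s != pos or e <= s:
                    raise ValueError(f"landscape blocks do not tile {chrom}")
                if lam < 0:
                    raise ValueError("negative intensity")
                pos = e

    def intensity_at(self, chrom: str, pos: int) -> float:
        for s, e, lam in self.blocks[chrom]:
            if s <= pos < e:
                return lam
        raise KeyError(f"{chrom}:{pos} outside landscape")


def build_landscape(config: SimulationConfig) -> DensityLandscape:
    """Random block landscape with the configured intensity levels."""
    rng = substream(config.seed, "landscape")
    levels = config.intensity_levels_snp_per_kbp
    lo, hi = config.landscape_block_bp
    blocks: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, n in config.chromosome_lengths.items():
        out, pos, prev = [], 0, None
        while pos < n:
            size = int(rng.integers(lo, hi + 1))
            end = min(pos + size, n)
            # avoid runs of the same level so contrast is locally visible
            choices = [l for l in levels if l != prev] or list(levels)
            lam = float(rng.choice(choices))
            out.append((pos, end, lam))
            pos, prev = end, lam
        blocks[chrom] = out
    return DensityLandscape(blocks)


# ---------------------------------------------------------------------------
# reference genome


def _random_gene(rng: np.random.Generator, gid: str, chrom: str,
                 start: int, limit: int) -> GeneModel | None:
    """Draw a gene model starting at `start`, or None if it cannot fit."""
    n_exons = int(rng.integers(1, 5))
    n_codons = int(rng.integers(60, 301))
    cds_len = 3 * n_codons
    # split CDS across exons at codon boundaries
    if n_exons == 1:
        cds_parts = [cds_len]
    else:
        cuts = np.sort(rng.choice(np.arange(1, n_codons), size=n_exons - 1,
                                  replace=False)) * 3
        cds_parts = np.diff([0, *cuts, cds_len]).tolist()
    introns = [int(rng.integers(80, 501)) for _ in range(n_exons - 1)]
    utr5 = int(rng.integers(50, 201))
    utr3 = int(rng.integers(50, 301))
    strand = "+" if rng.random() < 0.5 else "-"

    # lay out left-to-right in genomic coordinates; on '-' the 5' UTR is
    # rightmost, but interval bookkeeping is identical either way
    left_utr = utr5 if strand == "+" else utr3
    right_utr = utr3 if strand == "+" else utr5
    exons, cds = [], []
    pos = start
    for i, part in enumerate(cds_parts):
        ex_start = pos
        if i == 0:
            pos += left_utr
        cds.append((pos, pos + part))
        pos += part
        if i == n_exons - 1:
            pos += right_utr
        exons.append((ex_start, pos))
        if i < n_exons - 1:
            pos += introns[i]
    if pos > limit:
        return None
    left = [(s, e) for s, e in [(exons[0][0], cds[0][0])] if e > s]
    right = [(s, e) for s, e in [(cds[-1][1], exons[-1][1])] if e > s]
    u5, u3 = (left, right) if strand == "+" else (right, left)
    return GeneModel(gid, chrom, strand, exons, cds, u5, u3)


def _orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NONSTOP, size=n_codons - 2)
    stop = rng.choice(STOP_CODONS)
    return "ATG" + "".join(body) + str(stop)


def build_reference(config: SimulationConfig) -> AnnotatedGenome:
    """Simulate the annotated reference genome.

    Genes are placed by a spatial renewal process whose spacing is short on
    the euchromatic arms and long inside the pericentromere. Each CDS is
    overwritten with a valid open reading frame (ATG ... stop, no internal
    stop) so that consequence calling on simulated variants is meaningful.
    """
    rng = substream(config.seed, "reference")
    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    peri = {c: config.pericentromere(c) for c in config.chromosome_lengths}
    for chrom, n in config.chromosome_lengths.items():
        seq = rng.choice(list(BASES), size=n)
        ps, pe = peri[chrom]
        pos = int(rng.integers(200, 2000))
        k = 0
        while pos < n - 5000:
            in_peri = ps <= pos < pe
            spacing = (config.gene_spacing_peri_bp if in_peri
                       else config.gene_spacing_arm_bp)
            gene = _random_gene(rng, f"{chrom}g{k:04d}", chrom, pos, n - 100)
            if gene is None:
                break
            genes.append(gene)
            k += 1
            # write a clean ORF into the CDS intervals (translation order)
            orf = _orf(rng, gene.cds_length // 3)
            if gene.strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                orf = "".join(comp[b] for b in reversed(orf))
            off = 0
            for s, e in gene.cds:
                seq[s:e] = list(orf[off:off + (e - s)])
                off += e - s
            gap = rng.exponential(max(spacing - (gene.end - gene.start), 1000))
            pos = gene.end + max(int(gap), 200)
        chromosomes[chrom] = "".join(seq)
    return AnnotatedGenome(chromosomes, genes, peri)


# ---------------------------------------------------------------------------
# founder panels


@dataclass
class FounderPanel:
    """Founder accessions: race labels and variant lists vs the reference."""

    races: dict[str, str]
    variants: dict[str, list[Variant]]

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], tuple[list[int], list[Variant]]] = {}
        for fid, vs in self.variants.items():
            seen: set[tuple[str, int]] = set()
            for v in vs:
                key = (v.chrom, v.pos)
                if key in seen:
                    raise ValueError(f"duplicate position {key} in {fid}")
                seen.add(key)
                positions, variants = self._index.setdefault(
                    (fid, v.chrom), ([], []))
                positions.append(v.pos)
                variants.append(v)
        for positions, variants in self._index.values():
            order = sorted(range(len(positions)), key=positions.__getitem__)
            positions[:] = [positions[i] for i in order]
            variants[:] = [variants[i] for i in order]

    def founder_ids(self) -> list[str]:
        return sorted(self.races)

    def variants_in(self, fid: str, chrom: str, start: int, end: int
                    ) -> list[Variant]:
        import bisect

        positions, variants = self._index.get((fid, chrom), ([], []))
        lo = bisect.bisect_left(positions, start)
        hi = bisect.bisect_left(positions, end)
        return variants[lo:hi]

    def variant_at(self, fid: str, chrom: str, pos: int) -> Variant | None:
        import bisect

        positions, variants = self._index.get((fid, chrom), ([], []))
        i = bisect.bisect_left(positions, pos)
        if i < len(positions) and positions[i] == pos:
            return variants[i]
        return None


def _draw_variants(rng: np.random.Generator, genome: AnnotatedGenome,
                   chrom: str, start: int, end: int, rate_per_bp: float,
                   config: SimulationConfig) -> list[Variant]:
    seq = genome.chromosomes[chrom]
    n = rng.poisson(rate_per_bp * (end - start))
    out = []
    if n == 0:
        return out
    positions = rng.integers(start, end, size=n)
    for pos in sorted(set(int(p) for p in positions)):
        ref1 = seq[pos]
        if rng.random() >= config.indel_fraction:
            alt = BASES[(BASES.index(ref1) + int(rng.integers(1, 4))) % 4]
            out.append(Variant(chrom, pos, ref1, alt))
        else:
            length = int(rng.geometric(1.0 / config.indel_mean_bp))
            if rng.random() < 0.5 and pos + 1 + length <= len(seq):
                out.append(Variant(chrom, pos, seq[pos:pos + 1 + length], ref1))
            else:
                ins = "".join(rng.choice(list(BASES), size=length))
                out.append(Variant(chrom, pos, ref1, ref1 + ins))
    return out


def simulate_founder_variants(genome: AnnotatedGenome,
                              landscape: DensityLandscape,
                              races: dict[str, str],
                              seed: int,
                              config: SimulationConfig | None = None
                              ) -> FounderPanel:
    """Draw founder variant sets with Poisson placement per landscape block.

    A block intensity d (SNP/Kbp) is the expected pairwise density between
    founders of different races: each founder carries an independent Poisson
    set at rate d/2 per bp. Founders of the same race share a fraction
    `race_sharing` of that rate through a common race-level pool, which
    compresses within-race distances (emulating race clustering) without a
    coalescent model.
    """
    config = config or SimulationConfig()
    rng = substream(seed, "founders")
    shared: dict[tuple[str, str, int], list[Variant]] = {}
    race_list = sorted(set(races.values()))
    s = config.race_sharing
    # race-level shared pools, one per block
    for race in race_list:
        for chrom, blks in landscape.blocks.items():
            for bi, (bs, be, lam) in enumerate(blks):
                rate = s * (lam / 1000.0) / 2.0
                shared[(race, chrom, bi)] = _draw_variants(
                    rng, genome, chrom, bs, be, rate, config)
    variants: dict[str, list[Variant]] = {}
    for fid in sorted(races):
        race = races[fid]
        mine: dict[tuple[str, int], Variant] = {}
        for chrom, blks in landscape.blocks.items():
            for bi, (bs, be, lam) in enumerate(blks):
                for v in shared[(race, chrom, bi)]:
                    mine[(v.chrom, v.pos)] = v
                rate = (1 - s) * (lam / 1000.0) / 2.0
                for v in _draw_variants(rng, genome, chrom, bs, be, rate,
                                        config):
                    mine.setdefault((v.chrom, v.pos), v)
        # a few large intergenic deletions per founder (25-500 bp)
        lo, hi = config.large_deletion_bp
        for chrom in sorted(genome.chromosomes):
            seq = genome.chromosomes[chrom]
            for _ in range(config.large_deletions_per_founder):
                for _attempt in range(50):
                    length = int(rng.integers(lo, hi + 1))
                    pos = int(rng.integers(0, len(seq) - length - 2))
                    region = (chrom, pos, pos + length + 1)
                    if genome.genes_overlapping(*region):
                        continue
                    if any((c, p) in mine for c in [chrom]
                           for p in range(pos, pos + length + 1)):
                        continue
                    mine[(chrom, pos)] = Variant(
                        chrom, pos, seq[pos:pos + 1 + length], seq[pos])
                    break
        ordered = sorted(mine.values(), key=lambda v: (v.chrom, v.pos))
        kept, prev_end, prev_chrom = [], -1, None
        for v in ordered:  # deletions may overlap later draws; keep first
            if v.chrom != prev_chrom or v.pos >= prev_end:
                kept.append(v)
                prev_end, prev_chrom = v.end, v.chrom
        variants[fid] = kept
    return FounderPanel(dict(races), variants)


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationMap:
    """Per-restriction-site methylation truth: (chrom, pos) -> methylated."""

    states: dict[tuple[str, int], bool]

    def is_methylated(self, chrom: str, pos: int) -> bool:
        return self.states[(chrom, pos)]


def simulate_methylation(genome: AnnotatedGenome,
                         sites: list[tuple[str, int]],
                         config: SimulationConfig,
                         seed: int | None = None) -> MethylationMap:
    """Bernoulli methylation per site with context-dependent probability.

    Context precedence is genic > pericentromeric > intergenic: a site
    inside a gene uses the genic probability even within the
    pericentromere.
    """
    rng = substream(config.seed if seed is None else seed, "methylation")
    states: dict[tuple[str, int], bool] = {}
    for chrom, pos in sites:
        if chrom not in genome.chromosomes or not (
                0 <= pos < genome.length(chrom)):
            raise ValueError(f"site {chrom}:{pos} outside genome")
        p = config.methylation_probs[genome.site_context(chrom, pos)]
        states[(chrom, pos)] = bool(rng.random() < p)
    return MethylationMap(states)


# ---------------------------------------------------------------------------
# lines, gametes, pedigrees

Mosaic = dict[str, list[tuple[int, int, str]]]  # chrom -> (start, end, founder)


def _merge_segments(segs: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    for s, e, f in segs:
        if out and out[-1][2] == f and out[-1][1] == s:
            out[-1] = (out[-1][0], e, f)
        else:
            out.append((s, e, f))
    return out


@dataclass
class LineGenome:
    """A (possibly heterozygous) line as two founder-mosaic haplotypes."""

    id: str
    hap1: Mosaic
    hap2: Mosaic

    @property
    def is_inbred(self) -> bool:
        return self.hap1 == self.hap2

    def founder_at(self, chrom: str, pos: int, hap: int = 1) -> str:
        mosaic = self.hap1 if hap == 1 else self.hap2
        for s, e, f in mosaic[chrom]:
            if s <= pos < e:
                return f
        raise KeyError(f"{chrom}:{pos} not covered")

    def blocks(self, chrom: str) -> list[tuple[int, int, str]]:
        """Truth haplotype blocks of haplotype 1 (the full mosaic)."""
        return list(self.hap1[chrom])

    def variants(self, panel: FounderPanel) -> list[Variant]:
        """Homozygous variant list: union of founder variants over segments.

        Defined for inbred lines; heterozygous positions in non-inbred lines
        are excluded (mirroring a homozygous-call pipeline).
        """
        out: list[Variant] = []
        for chrom in sorted(self.hap1):
            for s, e, f in self.hap1[chrom]:
                for v in panel.variants_in(f, chrom, s, e):
                    if self.is_inbred:
                        out.append(v)
                    else:
                        f2 = self.founder_at(chrom, v.pos, hap=2)
                        if panel.variant_at(f2, chrom, v.pos) == v:
                            out.append(v)
        return out


def founder_line(fid: str, chromosome_lengths: dict[str, int]) -> LineGenome:
    mosaic = {c: [(0, n, fid)] for c, n in chromosome_lengths.items()}
    return LineGenome(fid, mosaic, {c: list(v) for c, v in mosaic.items()})


def _cm_to_bp_map(length_bp: int, peri: Interval, total_cm: float,
                  peri_share: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear genetic map: cumulative cM at bp breakpoints."""
    ps, pe = peri
    arm_bp = ps + (length_bp - pe)
    arm_cm = total_cm * (1 - peri_share)
    peri_cm = total_cm * peri_share
    bp = np.array([0, ps, pe, length_bp], dtype=float)
    cm_left = arm_cm * (ps / arm_bp) if arm_bp > 0 else 0.0
    cm = np.array([0.0, cm_left, cm_left + peri_cm, total_cm])
    return bp, cm


def make_gamete(line: LineGenome, chromosome_lengths: dict[str, int],
                genetic_lengths_cm: dict[str, float],
                pericentromere: dict[str, Interval],
                peri_crossover_share: float,
                rng: np.random.Generator) -> Mosaic:
    """One meiotic product: Poisson crossovers, no interference.

    Crossover count per chromosome is Poisson(genetic length in Morgans);
    positions are uniform on the cM scale and mapped to bp through the
    piecewise-linear arm/pericentromere map.
    """
    gamete: Mosaic = {}
    for chrom, n in chromosome_lengths.items():
        cm_total = genetic_lengths_cm[chrom]
        if cm_total < 0:
            raise ValueError("negative genetic length")
        k = rng.poisson(cm_total / 100.0) if cm_total > 0 else 0
        bp_knots, cm_knots = _cm_to_bp_map(
            n, pericentromere.get(chrom, (n // 2, n // 2)), cm_total,
            peri_crossover_share)
        if k > 0:
            cm_pos = np.sort(rng.uniform(0, cm_total, size=k))
            xovers = np.interp(cm_pos, cm_knots, bp_knots).astype(int).tolist()
        else:
            xovers = []
        cur = 1 if rng.random() < 0.5 else 2
        segs: list[tuple[int, int, str]] = []
        pos = 0
        for x in [*xovers, n]:
            if x <= pos:
                cur = 3 - cur
                continue
            src = line.hap1[chrom] if cur == 1 else line.hap2[chrom]
            for s, e, f in src:
                lo, hi = max(s, pos), min(e, x)
                if lo < hi:
                    segs.append((lo, hi, f))
            pos = x
            cur = 3 - cur
        gamete[chrom] = _merge_segments(segs)
    return gamete


@dataclass
class PedigreeGraph:
    """Directed pedigree: founders at the top, crosses and selfing below.

    `crosses` maps child id -> (parent1, parent2, cross_type) where
    cross_type is "F1", "self" (parent2 ignored) or "ssd:<g>" for g rounds
    of single-seed descent selfing. `selection_loci` lists intervals fixed
    to a stated founder in every line derived below the locus.
    """

    founders: list[str]
    crosses: dict[str, tuple[str, str | None, str]]
    selection_loci: list[tuple[str, int, int, str]] = field(default_factory=list)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        done = set(self.founders)
        pending = dict(self.crosses)
        while pending:
            ready = [c for c, (p1, p2, _) in pending.items()
                     if p1 in done and (p2 is None or p2 in done)]
            if not ready:
                raise ValueError("pedigree has a cycle or missing parent")
            for c in sorted(ready):
                order.append(c)
                done.add(c)
                del pending[c]
        return order


def _apply_selection(line: LineGenome,
                     loci: list[tuple[str, int, int, str]]) -> LineGenome:
    for chrom, start, end, fid in loci:
        for hap in (line.hap1, line.hap2):
            if chrom not in hap:
                continue
            segs = []
            for s, e, f in hap[chrom]:
                if e <= start or s >= end:
                    segs.append((s, e, f))
                else:
                    if s < start:
                        segs.append((s, start, f))
                    if e > end:
                        segs.append((end, e, f))
            segs.append((start, end, fid))
            hap[chrom] = _merge_segments(sorted(segs))
    return line


def breed(pedigree: PedigreeGraph, panel: FounderPanel,
          config: SimulationConfig) -> dict[str, LineGenome]:
    """Run the pedigree forward and return every line's mosaic genome.

    Selection loci are enforced by construction: after each cross the
    stated founder haplotype is written over the locus in both haplotypes,
    mimicking complete fixation under phenotypic selection.
    """
    rng = substream(config.seed, "breed")
    peri = {c: config.pericentromere(c) for c in config.chromosome_lengths}
    lines: dict[str, LineGenome] = {
        f: founder_line(f, config.chromosome_lengths)
        for f in pedigree.founders}

    def gamete(parent: LineGenome) -> Mosaic:
        return make_gamete(parent, config.chromosome_lengths,
                           config.genetic_lengths_cm, peri,
                           config.peri_crossover_share, rng)

    for child in pedigree.topological_order():
        p1, p2, ctype = pedigree.crosses[child]
        if ctype == "F1":
            if p2 is None:
                raise ValueError(f"F1 cross {child} needs two parents")
            line = LineGenome(child, gamete(lines[p1]), gamete(lines[p2]))
        elif ctype == "self":
            line = LineGenome(child, gamete(lines[p1]), gamete(lines[p1]))
        elif ctype.startswith("ssd:"):
            g = int(ctype.split(":", 1)[1])
            cur = lines[p1]
            for _ in range(g):
                cur = LineGenome(child, gamete(cur), gamete(cur))
            line = cur
        else:
            raise ValueError(f"unknown cross type {ctype!r}")
        lines[child] = _apply_selection(line, pedigree.selection_loci)
    return lines


def generate_ril_population(p1: LineGenome, p2: LineGenome, n: int,
                            generations: int, seed: int,
                            config: SimulationConfig) -> list[LineGenome]:
    """Bi-parental RIL population by single-seed descent.

    F1 is the cross of the two parents; generations-1 rounds of selfing
    follow (F12 means eleven rounds), leaving residual heterozygosity of
    about (1/2)^(generations-1) per locus.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if p1.hap1 == p2.hap1 and p1.hap2 == p2.hap2:
        raise ValueError("RIL parents must differ")
    rng = substream(seed, "ril")
    peri = {c: config.pericentromere(c) for c in config.chromosome_lengths}

    def gamete(parent: LineGenome) -> Mosaic:
        return make_gamete(parent, config.chromosome_lengths,
                           config.genetic_lengths_cm, peri,
                           config.peri_crossover_share, rng)

    rils = []
    for i in range(n):
        line = LineGenome(f"RIL{i:03d}", gamete(p1), gamete(p2))
        for _ in range(generations - 1):
            line = LineGenome(line.id, gamete(line), gamete(line))
        rils.append(line)
    return rils


# ---------------------------------------------------------------------------
# marker truth


def diagnostic_positions(panel: FounderPanel, f1: str, f2: str,
                         snps_only: bool = True) -> list[tuple[str, int]]:
    """Positions whose allele differs between two founders (marker truth)."""
    def keyset(fid: str) -> dict[tuple[str, int], Variant]:
        return {(v.chrom, v.pos): v for v in panel.variants[fid]
                if v.is_snp or not snps_only}

    a, b = keyset(f1), keyset(f2)
    out = [k for k in (set(a) | set(b))
           if a.get(k) is None or b.get(k) is None or a[k].alt != b[k].alt]
    return sorted(out)


def ril_genotype_calls(rils: list[LineGenome], markers: list[tuple[str, int]],
                       parent1: str, parent2: str) -> dict[str, list[str]]:
    """Call each RIL at marker positions by owning-segment founder label.

    Returns line id -> list of calls in marker order, 'A' for the
    parent-1 founder, 'B' for parent-2, 'H' where the two haplotypes
    disagree (residual heterozygosity).
    """
    calls: dict[str, list[str]] = {}
    for line in rils:
        row = []
        for chrom, pos in markers:
            fa = line.founder_at(chrom, pos, hap=1)
            fb = line.founder_at(chrom, pos, hap=2)
            if fa != fb:
                row.append("H")
            else:
                row.append("A" if fa == parent1 else "B")
        calls[line.id] = row
    return calls
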