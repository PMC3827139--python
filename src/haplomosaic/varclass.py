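"""Variant consequence classification and polymorphism-density profiling.

Variants are assigned one location category (coding > UTR > intron >
intergenic by precedence) and, in coding sequence, a consequence from the
standard genetic code: synonymous, missense, stop_gained, stop_lost for
SNPs; frameshift or inframe (with stop checks) for INDELs. Density
profiles follow the study conventions: 600-bp windows, per-gene SNP/Kbp
over the full UTR-to-UTR span, and 10-Mbp genic/intergenic bins. Large
INDELs are recovered as maximal zero-depth runs in a depth track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import AnnotatedGenome, GeneModel, Variant, left_normalize

LOCATION_CATEGORIES = ("coding", "UTR", "intron", "intergenic")
_SEVERITY = {"stop_gained": 6, "stop_lost": 5, "frameshift": 4,
             "missense": 3, "inframe": 2, "synonymous": 1, "none": 0}


@dataclass
class CallFilter:
    """Depth and allele-frequency acceptance rules for candidate calls.

    Defaults follow the study: coverage between 5 and 150 inclusive, and a
    locus is called homozygous only when the allele frequency exceeds 0.75;
    heterozygous survivors are excluded.
    """

    min_depth: int = 5
    max_depth: int = 150
    hom_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.min_depth <= self.max_depth:
            raise ValueError("need 0 < min_depth <= max_depth")
        if not 0.5 < self.hom_threshold <= 1:
            raise ValueError("hom_threshold must be in (0.5, 1]")

    def accepts(self, depth: int, allele_frequency: float) -> bool:
        return (self.min_depth <= depth <= self.max_depth
                and allele_frequency > self.hom_threshold)


def apply_call_filter(candidates: list[tuple[Variant, int, float]],
                      filt: CallFilter | None = None) -> list[Variant]:
    """Keep candidates passing depth bounds and the homozygosity threshold."""
    filt = filt or CallFilter()
    return [v for v, depth, af in candidates if filt.accepts(depth, af)]


@dataclass
class ConsequenceRecord:
    variant: Variant
    category: str  # intergenic | intron | UTR | coding
    consequence: str  # none unless category == coding
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in LOCATION_CATEGORIES:
            raise ValueError(f"bad category {self.category}")
        if (self.consequence != "none") != (self.category == "coding"):
            raise ValueError("coding consequence iff coding category")


def _locate_in_gene(gene: GeneModel, start: int, end: int) -> str:
    """Finest category a [start, end) span touches within one gene."""
    if any(s < end and e > start for s, e in gene.cds):
        return "coding"
    if any(s < end and e > start for s, e in gene.utr5 + gene.utr3):
        return "UTR"
    return "intron"


def _snp_consequence(v: Variant, gene: GeneModel, seq: str) -> str:
    off = gene.cds_offset(v.pos)
    assert off is not None
    cds = gene.cds_sequence(seq)
    codon_i = off // 3
    codon = cds[3 * codon_i:3 * codon_i + 3]
    alt_base = v.alt
    if gene.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    within = off % 3
    new_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if aa_old == aa_new:
        return "synonymous"
    if aa_new == "*":
        return "stop_gained"
    if aa_old == "*":
        return "stop_lost"
    return "missense"


def _indel_consequence(v: Variant, gene: GeneModel, seq: str) -> str:
    # bases actually inserted/deleted start after the anchor base
    if v.length_change % 3 != 0:
        return "frameshift"
    # in-frame: re-translate the edited CDS and look for stop changes
    prot_old = str(Seq(gene.cds_sequence(seq)).translate())
    edited = apply_variants_to_sequence(seq, [v])
    new_cds_ivs = [(s + (v.length_change if s > v.pos else 0),
                    e + (v.length_change if e > v.pos else 0))
                   for s, e in gene.cds]
    cds_new = "".join(edited[s:e] for s, e in new_cds_ivs)
    if gene.strand == "-":
        cds_new = str(Seq(cds_new).reverse_complement())
    prot_new = str(Seq(cds_new[:3 * (len(cds_new) // 3)]).translate())
    stop_new = prot_new.find("*")
    if stop_new == -1:
        return "stop_lost" if "*" in prot_old else "inframe"
    if stop_new < len(prot_new) - 1:
        return "stop_gained"
    return "inframe"


def classify_variant(v: Variant, genome: AnnotatedGenome,
                     normalize: bool = True) -> ConsequenceRecord:
    """Assign location category and coding consequence to one variant.

    INDELs are left-normalized first. When a variant overlaps several
    genes, the finest category wins (coding > UTR > intron); among coding
    overlaps the more severe consequence is kept.
    """
    seq = genome.chromosomes[v.chrom]
    if seq[v.pos:v.pos + len(v.ref)] != v.ref:
        raise ValueError(
            f"ref allele mismatch at {v.chrom}:{v.pos} "
            f"({v.ref!r} vs genome {seq[v.pos:v.pos + len(v.ref)]!r})")
    if normalize and not v.is_snp:
        v = left_normalize(v, seq)
    # for an anchored INDEL the affected bases start after the anchor
    if v.is_snp:
        a_start, a_end = v.pos, v.pos + 1
    else:
        a_start, a_end = v.pos + 1, max(v.end, v.pos + 2)
    hits = genome.genes_overlapping(v.chrom, a_start, a_end)
    if not hits:
        return ConsequenceRecord(v, "intergenic", "none")
    best_rank: tuple[int, int] | None = None
    best_cat, best_cons, best_gene = "intergenic", "none", None
    for gene in hits:
        cat = _locate_in_gene(gene, a_start, a_end)
        if cat == "coding":
            cons = (_snp_consequence(v, gene, seq) if v.is_snp
                    else _indel_consequence(v, gene, seq))
        else:
            cons = "none"
        rank = (-LOCATION_CATEGORIES.index(cat), _SEVERITY[cons])
        if best_rank is None or rank > best_rank:
            best_rank, best_cat, best_cons, best_gene = rank, cat, cons, gene.id
    return ConsequenceRecord(v, best_cat, best_cons, best_gene)


def apply_variants_to_sequence(seq: str, variants: list[Variant]) -> str:
    """Apply non-overlapping variants to a sequence (for oracle checks)."""
    out, pos = [], 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.pos < pos:
            raise ValueError("overlapping variants")
        out.append(seq[pos:v.pos])
        out.append(v.alt)
        pos = v.pos + len(v.ref)
    out.append(seq[pos:])
    return "".join(out)


@dataclass
class CategoryCounts:
    """Table-style accounting of variant locations and coding consequences.

    `location` holds intergenic/intron/UTR/coding counts (a partition of
    the variant set); `coding` breaks the coding class down further.
    """

    location: dict[str, int] = field(default_factory=dict)
    coding: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.location.values())

    def to_frame(self) -> pd.DataFrame:
        row = {"Intergenic": self.location.get("intergenic", 0),
               "Intron": self.location.get("intron", 0),
               "UTR": self.location.get("UTR", 0),
               "Coding": self.location.get("coding", 0),
               "AA Change": self.coding.get("missense", 0),
               "Premature Stop": self.coding.get("stop_gained", 0),
               "Stop Loss": self.coding.get("stop_lost", 0),
               "Frame Shift": self.coding.get("frameshift", 0)}
        return pd.DataFrame([row])


def summarize_categories(records: list[ConsequenceRecord]) -> CategoryCounts:
    loc = {c: 0 for c in LOCATION_CATEGORIES}
    cod = {c: 0 for c in _SEVERITY if c != "none"}
    for r in records:
        loc[r.category] += 1
        if r.consequence != "none":
            cod[r.consequence] += 1
    return CategoryCounts(loc, cod)


# ---------------------------------------------------------------------------
# densities


@dataclass
class DensityProfile:
    """Windowed variant counts and densities over one region."""

    windows: list[tuple[int, int]]
    counts: np.ndarray
    window_size: int

    @property
    def densities(self) -> np.ndarray:
        lengths = np.array([e - s for s, e in self.windows], dtype=float)
        return self.counts / (lengths / 1000.0)


def window_density(variants: list[Variant], chrom: str,
                   region: tuple[int, int],
                   window_size: int = 600) -> DensityProfile:
    """Variant density in half-open tiling windows (variants per Kbp).

    The last partial window is normalized by its true length.
    """
    start, end = region
    if end <= start:
        raise ValueError("empty region")
    if window_size <= 0:
        raise ValueError("window size must be positive")
    windows = [(s, min(s + window_size, end))
               for s in range(start, end, window_size)]
    positions = np.array(sorted(v.pos for v in variants
                                if v.chrom == chrom and start <= v.pos < end))
    edges = [w[0] for w in windows] + [end]
    counts, _ = np.histogram(positions, bins=edges)
    return DensityProfile(windows, counts.astype(int), window_size)


def per_gene_density(variants: list[Variant],
                     genes: list[GeneModel]) -> pd.DataFrame:
    """SNP/Kbp per gene over the full gene span (UTR to UTR)."""
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    for ps in by_chrom.values():
        ps.sort()
    rows = []
    for g in genes:
        span = g.end - g.start
        if span <= 0:
            raise ValueError(f"gene {g.id} has zero-length span")
        ps = by_chrom.get(g.chrom, [])
        n = int(np.searchsorted(ps, g.end) - np.searchsorted(ps, g.start))
        rows.append({"gene": g.id, "chrom": g.chrom, "start": g.start,
                     "end": g.end, "variants": n,
                     "density_per_kbp": n / (span / 1000.0)})
    return pd.DataFrame(rows)


def genic_mask(genome: AnnotatedGenome, chrom: str,
               region: tuple[int, int]) -> np.ndarray:
    """Boolean per-base mask of genic bases over a region."""
    start, end = region
    mask = np.zeros(end - start, dtype=bool)
    for g in genome.genes_overlapping(chrom, start, end):
        mask[max(g.start, start) - start:min(g.end, end) - start] = True
    return mask


def regional_density(variants: list[Variant], genome: AnnotatedGenome,
                     chrom: str, region: tuple[int, int],
                     bin_size: int = 10_000_000) -> pd.DataFrame:
    """Mean genic and intergenic SNP/Kbp per bin.

    Each bin's variants are split by genic membership of their position and
    divided by the genic (resp. intergenic) base count in the bin. A class
    with zero bases in a bin gets NaN density.
    """
    start, end = region
    mask = genic_mask(genome, chrom, region)
    rows = []
    for bs in range(start, end, bin_size):
        be = min(bs + bin_size, end)
        sub = mask[bs - start:be - start]
        genic_bp = int(sub.sum())
        inter_bp = (be - bs) - genic_bp
        gc = ic = 0
        for v in variants:
            if v.chrom == chrom and bs <= v.pos < be:
                if sub[v.pos - bs]:
                    gc += 1
                else:
                    ic += 1
        rows.append({
            "start": bs, "end": be,
            "genic_count": gc, "intergenic_count": ic,
            "genic_bp": genic_bp, "intergenic_bp": inter_bp,
            "genic_density": gc / (genic_bp / 1000.0) if genic_bp else np.nan,
            "intergenic_density": (ic / (inter_bp / 1000.0)
                                   if inter_bp else np.nan)})
    return pd.DataFrame(rows)


def gene_spacing_kbp(n_genes: int, region_bp: int) -> float:
    """Average Kbp of sequence per annotated gene in a region."""
    if n_genes <= 0:
        raise ValueError("no genes in region")
    return region_bp / n_genes / 1000.0


# ---------------------------------------------------------------------------
# large INDELs from depth


@dataclass(frozen=True)
class LargeIndelSpan:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_large_indels(depth: np.ndarray, chrom: str = "chr",
                        offset: int = 0,
                        min_length: int = 25) -> list[LargeIndelSpan]:
    """Maximal runs of exactly-zero depth of at least `min_length` bases.

    Zero-depth runs in an aligned line mark sequence present in the
    reference but absent (deleted) in the line.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        return []
    if (depth < 0).any():
        raise ValueError("negative depth")
    zero = depth == 0
    spans = []
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = ([0] if zero[0] else []) + (boundaries + 1)[
        zero[boundaries + 1]].tolist()
    ends = (boundaries + 1)[~zero[boundaries + 1]].tolist() + (
        [len(zero)] if zero[-1] else [])
    for s, e in zip(starts, ends):
        if e - s >= min_length:
            spans.append(LargeIndelSpan(chrom, offset + s, offset + e))
    return spans
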