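"""Core genome containers: annotated reference, gene models and variants.

Coordinates are 0-based half-open everywhere in memory; 1-based coordinates
appear only in VCF/GFF3 serialisation (see :mod:`haplomosaic.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

Interval = tuple[int, int]


def _check_sorted_disjoint(ivs: list[Interval], what: str) -> None:
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError(f"{what} intervals overlap or are unsorted: {ivs}")
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty {what} interval {(s, e)}")


def _contained(inner: list[Interval], outer: list[Interval]) -> bool:
    """True if every inner interval lies within the union of outer intervals."""
    for s, e in inner:
        if not any(os <= s and e <= oe for os, oe in outer):
            return False
    return True


@dataclass
class GeneModel:
    """A protein-coding gene: exon structure, CDS and UTRs on one strand.

    Intervals are 0-based half-open on the chromosome, sorted by start.
    For minus-strand genes the CDS is read from the last interval backwards
    on the reverse complement.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        _check_sorted_disjoint(self.exons, "exon")
        _check_sorted_disjoint(self.cds, "CDS")
        if not _contained(self.cds, self.exons):
            raise ValueError(f"gene {self.id}: CDS not contained in exons")
        if not _contained(self.utr5 + self.utr3, self.exons):
            raise ValueError(f"gene {self.id}: UTR not contained in exons")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in translation order (reverse-complemented on '-')."""
        parts = [chrom_seq[s:e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """Translation-order offset of a genomic position within the CDS.

        Returns None when the position does not fall in the CDS.
        """
        if not any(s <= pos < e for s, e in self.cds):
            return None
        before = 0
        for s, e in self.cds:
            if s <= pos < e:
                off = before + (pos - s)
                break
            before += e - s
        if self.strand == "-":
            off = self.cds_length - 1 - off
        return off


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus gene models and pericentromere annotation."""

    chromosomes: dict[str, str]
    genes: list[GeneModel]
    pericentromere: dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} is empty")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.id} extends past chromosome end")
        self._genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._genes_by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._genes_by_chrom.values():
            glist.sort(key=lambda g: g.start)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._genes_by_chrom.get(chrom, [])

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        return [g for g in self.genes_on(chrom) if g.start < end and g.end > start]

    def is_genic(self, chrom: str, pos: int) -> bool:
        return any(g.start <= pos < g.end for g in self.genes_on(chrom))

    def is_pericentromeric(self, chrom: str, pos: int) -> bool:
        iv = self.pericentromere.get(chrom)
        return iv is not None and iv[0] <= pos < iv[1]

    def site_context(self, chrom: str, pos: int) -> str:
        """'genic', 'pericentromeric' or 'intergenic' (genic wins in overlap)."""
        if self.is_genic(chrom, pos):
            return "genic"
        if self.is_pericentromeric(chrom, pos):
            return "pericentromeric"
        return "intergenic"


@dataclass(frozen=True)
class Variant:
    """A homozygous sequence difference against the reference.

    SNPs have single-base ref and alt. INDELs use the VCF anchor-base
    convention: position of the base preceding the inserted/deleted run,
    ref and alt both starting with that base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("empty allele")
        if self.ref == self.alt:
            raise ValueError("ref and alt identical")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def type(self) -> str:
        return "SNP" if self.is_snp else "INDEL"

    @property
    def end(self) -> int:
        """End of the reference span (half-open)."""
        return self.pos + len(self.ref)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


def left_normalize(v: Variant, chrom_seq: str) -> Variant:
    """Shift an INDEL to its leftmost equivalent position.

    Multi-base variants in repeat runs have several equivalent encodings;
    normalising makes per-position comparisons between call sets well
    defined. SNPs are returned unchanged.
    """
    if v.is_snp:
        return v
    ref, alt, pos = v.ref, v.alt, v.pos
    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1] and (min(len(ref), len(alt)) > 1 or pos > 0):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                prev = chrom_seq[pos - 1]
                ref, alt, pos = prev + ref, prev + alt, pos - 1
            changed = True
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
            changed = True
    return Variant(v.chrom, pos, ref, alt)
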