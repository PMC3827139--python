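"""Restriction-site tag prediction and methylation-sensitive recovery.

Digital Genotyping reduces a genome to short tags (37 or 72 bp) flanking
the recognition sites of the methylation-sensitive enzyme NgoMIV
(recognition GCCGGC, cut G^CCGGC). Methylated sites are not cut and yield
no tag, so the fraction of in-silico-predicted tags recovered by
sequencing profiles methylation along a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .genome import AnnotatedGenome
from .simgenome import MethylationMap, substream

NGOMIV_MOTIF = "GCCGGC"
NGOMIV_CUT_OFFSET = 1  # G^CCGGC
TAG_LENGTHS = (37, 72)


@dataclass(frozen=True)
class RestrictionSite:
    chrom: str
    pos: int  # 0-based offset of the motif start
    motif: str = NGOMIV_MOTIF


@dataclass(frozen=True)
class DGTag:
    chrom: str
    site_pos: int
    side: str  # "left" | "right"
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if len(self.sequence) != self.length:
            raise ValueError("tag sequence length mismatch")


def find_restriction_sites(sequence: str, motif: str = NGOMIV_MOTIF,
                           chrom: str = "chr") -> list[RestrictionSite]:
    """All motif start offsets, overlapping occurrences included.

    The NgoMIV motif is its own reverse complement, so a forward scan is
    complete. Ambiguity codes are not supported.
    """
    if not motif:
        raise ValueError("empty motif")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"unsupported characters in motif {motif!r}")
    sites = []
    i = sequence.find(motif)
    while i != -1:
        sites.append(RestrictionSite(chrom, i, motif))
        i = sequence.find(motif, i + 1)
    return sites


@dataclass
class DGTagSet:
    tags: list[DGTag]
    dropped_at_ends: int = 0
    non_unique: list[DGTag] = field(default_factory=list)

    def by_site(self) -> dict[tuple[str, int], list[DGTag]]:
        out: dict[tuple[str, int], list[DGTag]] = {}
        for t in self.tags:
            out.setdefault((t.chrom, t.site_pos), []).append(t)
        return out

    def site_positions(self) -> list[tuple[str, int]]:
        return sorted({(t.chrom, t.site_pos) for t in self.tags})


def extract_dg_tags(genome: AnnotatedGenome | dict[str, str],
                    sites: list[RestrictionSite], length: int = 72,
                    uniqueness_filter: bool = True) -> DGTagSet:
    """One tag per site side, reading outward from the cut position.

    The cut falls after the first motif base (G^CCGGC): the left tag is the
    `length` bases ending at the cut, the right tag the `length` bases
    starting at the cut. Tags truncated by a chromosome end are dropped and
    counted. Tags whose sequence occurs more than once in the genome
    (either strand) are moved to `non_unique` when the filter is on,
    mirroring the unique-mapping requirement for usable markers.
    """
    if length not in TAG_LENGTHS:
        raise ValueError(f"tag length must be one of {TAG_LENGTHS}")
    chroms = (genome.chromosomes if isinstance(genome, AnnotatedGenome)
              else genome)
    tags: list[DGTag] = []
    dropped = 0
    for site in sites:
        seq = chroms[site.chrom]
        cut = site.pos + NGOMIV_CUT_OFFSET
        if cut - length >= 0:
            tags.append(DGTag(site.chrom, site.pos, "left", length,
                              seq[cut - length:cut]))
        else:
            dropped += 1
        if cut + length <= len(seq):
            tags.append(DGTag(site.chrom, site.pos, "right", length,
                              seq[cut:cut + length]))
        else:
            dropped += 1
    non_unique: list[DGTag] = []
    if uniqueness_filter:
        comp = str.maketrans("ACGT", "TGCA")
        unique: list[DGTag] = []
        for t in tags:
            rc = t.sequence.translate(comp)[::-1]
            hits = sum(_count_overlapping(s, t.sequence) for s in chroms.values())
            if rc != t.sequence:
                hits += sum(_count_overlapping(s, rc) for s in chroms.values())
            (unique if hits == 1 else non_unique).append(t)
        tags = unique
    return DGTagSet(tags, dropped, non_unique)


def _count_overlapping(haystack: str, needle: str) -> int:
    n, i = 0, haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


@dataclass
class TagRecovery:
    """Observed read counts per site and the depth model that produced them."""

    counts: dict[tuple[str, int], int]
    mean_depth: float = 15.0
    min_depth: int = 5

    def is_recovered(self, chrom: str, pos: int) -> bool:
        return self.counts[(chrom, pos)] >= self.min_depth

    def recovered_sites(self) -> list[tuple[str, int]]:
        return sorted(k for k, c in self.counts.items() if c >= self.min_depth)


def simulate_tag_recovery(tag_set: DGTagSet, methylation: MethylationMap,
                          mean_depth: float = 15.0, min_depth: int = 5,
                          seed: int = 0) -> TagRecovery:
    """Poisson sequencing depth per unmethylated site; methylated sites get 0.

    A site counts as recovered when its depth reaches `min_depth` (the
    study used a 5-read minimum at ~15x mean depth per tag).
    """
    rng = substream(seed, "recovery")
    counts: dict[tuple[str, int], int] = {}
    for chrom, pos in tag_set.site_positions():
        if (chrom, pos) not in methylation.states:
            raise ValueError(f"no methylation state for site {chrom}:{pos}")
        if methylation.is_methylated(chrom, pos):
            counts[(chrom, pos)] = 0
        else:
            counts[(chrom, pos)] = int(rng.poisson(mean_depth))
    return TagRecovery(counts, mean_depth, min_depth)


@dataclass
class MethylationProfile:
    """Windowed recovered/predicted site fractions (None where no sites)."""

    rows: list[tuple[tuple[int, int], int, int, float | None]]

    def fractions(self) -> list[float | None]:
        return [r[3] for r in self.rows]


def methylation_profile(predicted_sites: list[tuple[str, int]],
                        recovery: TagRecovery,
                        windows: list[tuple[int, int]],
                        chrom: str) -> MethylationProfile:
    """Fraction of predicted sites recovered, per window.

    The fraction is undefined (None), not zero, in windows with no
    predicted site. Windows must not overlap.
    """
    for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
        if s1 < e0:
            raise ValueError("windows overlap")
    rows = []
    for start, end in windows:
        in_win = [(c, p) for c, p in predicted_sites
                  if c == chrom and start <= p < end]
        pred = len(in_win)
        rec = sum(recovery.is_recovered(c, p) for c, p in in_win)
        frac = rec / pred if pred else None
        rows.append(((start, end), pred, rec, frac))
    return MethylationProfile(rows)


@dataclass
class TagMatchReport:
    """Per-tag comparison classes against re-sequenced consensus.

    Classes partition the validated tag set: perfect (exact string match),
    snp_mismatch (same length, substitutions only in the optimal
    alignment), indel_discordant (optimal alignment requires a gap),
    missing (no consensus available).
    """

    classes: dict[tuple[str, int, str], str]

    def counts(self) -> dict[str, int]:
        out = {"perfect": 0, "snp_mismatch": 0, "indel_discordant": 0,
               "missing": 0}
        for c in self.classes.values():
            out[c] += 1
        return out

    @property
    def total(self) -> int:
        return len(self.classes)

    @property
    def perfect_percentage(self) -> float:
        c = self.counts()
        return 100.0 * c["perfect"] / self.total if self.total else float("nan")


def compare_tags_to_consensus(tags: dict[tuple[str, int, str], str],
                              consensus: dict[tuple[str, int, str], str]
                              ) -> TagMatchReport:
    """Classify validated tags against consensus sequences keyed by site.

    Tags and consensus are pre-paired by (chrom, site, side), so a global
    unit-cost alignment replaces the similarity search a BLAST step would
    perform on unpaired data.
    """
    classes: dict[tuple[str, int, str], str] = {}
    for key, tag_seq in tags.items():
        cons = consensus.get(key)
        if cons is None:
            classes[key] = "missing"
        elif tag_seq == cons:
            classes[key] = "perfect"
        elif len(tag_seq) != len(cons):
            classes[key] = "indel_discordant"
        else:
            aln = edlib.align(tag_seq, cons, task="path", mode="NW")
            cigar = aln["cigar"] or ""
            if "I" in cigar or "D" in cigar:
                classes[key] = "indel_discordant"
            else:
                classes[key] = "snp_mismatch"
    return TagMatchReport(classes)


def pooled_perfect_percentage(reports: list[TagMatchReport],
                              ndigits: int = 1) -> float:
    """Perfect-match percentage pooled over several genotype reports."""
    perfect = sum(r.counts()["perfect"] for r in reports)
    total = sum(r.total for r in reports)
    if total == 0:
        raise ValueError("no tags to pool")
    return round(100.0 * perfect / total, ndigits)


def recovery_probability(mean_depth: float, min_depth: int) -> float:
    """P(Poisson(mean_depth) >= min_depth): chance an unmethylated site
    clears the depth threshold."""
    from scipy.stats import poisson

    return float(poisson.sf(min_depth - 1, mean_depth))


def tile_windows(start: int, end: int, size: int) -> list[tuple[int, int]]:
    """Half-open tiling of [start, end); last window may be partial."""
    if size <= 0 or end <= start:
        raise ValueError("bad window parameters")
    return [(s, min(s + size, end)) for s in range(start, end, size)]
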