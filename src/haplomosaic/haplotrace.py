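"""Pedigree haplotype-origin tracing, block segmentation and IBD detection.

Marker alleles of a progeny line are compared with its parents to decide
which parent contributed each marker; labels are then lifted recursively
through the pedigree to founder accessions. Runs of a single founder label
form haplotype blocks. Identical-by-descent (IBD) segments between two
lines are detected either as long runs of windows with near-zero pairwise
polymorphism density or as runs of matching founder labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Variant

MISSING = None

UNKNOWN_UNINFORMATIVE = "unknown-uninformative"
UNKNOWN_MISSING = "unknown-missing"
CONFLICT = "conflict"


@dataclass
class MarkerMatrix:
    """Ordered markers x lines -> allele call (or None for missing)."""

    markers: list[tuple[str, int, str]]  # (chrom, pos, marker-id)
    calls: dict[str, list[str | None]]  # line id -> calls in marker order

    def __post_init__(self) -> None:
        prev = None
        for chrom, pos, _ in self.markers:
            if prev is not None and (chrom, pos) < prev:
                raise ValueError("markers not sorted by chromosome, position")
            prev = (chrom, pos)
        for line, row in self.calls.items():
            if len(row) != len(self.markers):
                raise ValueError(f"call row length mismatch for {line}")
            if any(c == "" for c in row):
                raise ValueError("empty allele string (use None for missing)")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, line: str) -> list[str | None]:
        return self.calls[line]


def marker_origin(offspring: str | None, p1: str | None,
                  p2: str | None) -> str:
    """Attribute one offspring allele to a parent.

    Returns "parent1"/"parent2" for informative markers, and the unknown /
    conflict labels otherwise.
    """
    if offspring is None or p1 is None or p2 is None:
        return UNKNOWN_MISSING
    if p1 == p2:
        return UNKNOWN_UNINFORMATIVE
    if offspring == p1:
        return "parent1"
    if offspring == p2:
        return "parent2"
    return CONFLICT


@dataclass
class Pedigree:
    """child -> (parent1, parent2); None for an ungenotyped/unknown parent."""

    parents: dict[str, tuple[str | None, str | None]]

    def ancestors_known(self, line: str) -> bool:
        return line in self.parents


@dataclass
class OriginCall:
    """Founder-level origin labels per marker for one line."""

    line: str
    labels: list[str]  # founder id or unknown-* / conflict
    tentative: list[bool]

    def informative_fraction(self) -> float:
        inf = [l for l in self.labels
               if not l.startswith("unknown") and l != CONFLICT]
        return len(inf) / len(self.labels) if self.labels else 0.0


def trace_pedigree(pedigree: Pedigree, matrix: MarkerMatrix,
                   line: str) -> OriginCall:
    """Trace a line's marker alleles to founder origins through the pedigree.

    A marker is first attributed to one of the line's parents; if that
    parent is itself a pedigree child, the attribution is lifted
    recursively until a founder (a node with no recorded parents) is
    reached. When only one parent is genotyped, alleles that do not match
    it are tentatively assigned to the other, ungenotyped parent and
    flagged tentative.
    """
    n = matrix.n_markers

    def resolve(node: str, idx: int) -> tuple[str, bool]:
        if node not in pedigree.parents:
            return node, False  # founder
        p1, p2 = pedigree.parents[node]
        child_call = matrix.calls[node][idx] if node in matrix.calls else None
        if child_call is None:
            return UNKNOWN_MISSING, False
        p1_typed = p1 is not None and p1 in matrix.calls
        p2_typed = p2 is not None and p2 in matrix.calls
        c1 = matrix.calls[p1][idx] if p1_typed else None
        c2 = matrix.calls[p2][idx] if p2_typed else None
        if p1_typed and p2_typed:
            origin = marker_origin(child_call, c1, c2)
            if origin == "parent1":
                return resolve(p1, idx)
            if origin == "parent2":
                return resolve(p2, idx)
            return origin, False
        if p1_typed or p2_typed:
            known = p1 if p1_typed else p2
            other = p2 if p1_typed else p1
            kc = c1 if p1_typed else c2
            if kc is None:
                return UNKNOWN_MISSING, False
            if child_call == kc:
                return resolve(known, idx)
            if other is None:
                return CONFLICT, False
            return other, True  # tentative-other-parent
        return UNKNOWN_MISSING, False

    labels, tentative = [], []
    for i in range(n):
        lab, tent = resolve(line, i)
        labels.append(lab)
        tentative.append(tent)
    return OriginCall(line, labels, tentative)


@dataclass
class HaplotypeBlock:
    line: str
    chrom: str
    start: int  # position of first supporting marker
    end: int  # position of last supporting marker (inclusive bound)
    founder: str
    n_markers: int
    low_confidence: bool = False


def segment_blocks(origin: OriginCall, markers: list[tuple[str, int, str]],
                   min_markers: int = 5,
                   smoothing_window: int = 1) -> list[HaplotypeBlock]:
    """Segment per-marker origin labels into maximal single-founder runs.

    Uninformative/conflict markers are skipped. Isolated discordant runs of
    at most `smoothing_window` markers flanked by agreeing labels are
    absorbed into the flanking label (a genotyping-error guard). Runs
    supported by fewer than `min_markers` markers are kept but flagged
    low-confidence.
    """
    idx = [i for i, l in enumerate(origin.labels)
           if not l.startswith("unknown") and l != CONFLICT]
    labels = [origin.labels[i] for i in idx]
    # absorb short discordant islands
    if smoothing_window > 0 and len(labels) > 2:
        smoothed = list(labels)
        i = 0
        while i < len(smoothed):
            j = i
            while j < len(smoothed) and smoothed[j] == smoothed[i]:
                j += 1
            run_len = j - i
            if (0 < i and j < len(smoothed) and run_len <= smoothing_window
                    and smoothed[i - 1] == smoothed[j]):
                for k in range(i, j):
                    smoothed[k] = smoothed[i - 1]
            i = j
        labels = smoothed
    blocks: list[HaplotypeBlock] = []
    i = 0
    while i < len(labels):
        j = i
        chrom = markers[idx[i]][0]
        while (j < len(labels) and labels[j] == labels[i]
               and markers[idx[j]][0] == chrom):
            j += 1
        support = j - i
        blocks.append(HaplotypeBlock(
            origin.line, chrom,
            markers[idx[i]][1], markers[idx[j - 1]][1],
            labels[i], support, low_confidence=support < min_markers))
        i = j
    return blocks


def block_boundaries(blocks: list[HaplotypeBlock]) -> list[int]:
    """Midpoints between the last marker of one block and the first of the
    next (per chromosome order)."""
    out = []
    for a, b in zip(blocks, blocks[1:]):
        if a.chrom == b.chrom:
            out.append((a.end + b.start) // 2)
    return out


@dataclass
class IBDSegment:
    line_pair: tuple[str, str]
    chrom: str
    start: int
    end: int
    mean_density: float  # SNP/Kbp over the segment
    evidence: str  # "density" | "haplotype-label"

    @property
    def length(self) -> int:
        return self.end - self.start


def pairwise_differences(v1: list[Variant], v2: list[Variant]) -> list[Variant]:
    """Variant positions present in exactly one line, or with differing
    alleles: the sites at which the two lines differ."""
    m1 = {(v.chrom, v.pos): v for v in v1}
    m2 = {(v.chrom, v.pos): v for v in v2}
    out = []
    for k in set(m1) | set(m2):
        a, b = m1.get(k), m2.get(k)
        if a is None or b is None or a.alt != b.alt or a.ref != b.ref:
            out.append(a if a is not None else b)
    return sorted(out, key=lambda v: (v.chrom, v.pos))


def detect_ibd_density(differences: list[Variant], chrom: str,
                       region: tuple[int, int],
                       line_pair: tuple[str, str] = ("line1", "line2"),
                       density_threshold: float = 0.05,
                       min_length: int = 1_000_000,
                       window: int = 100_000) -> list[IBDSegment]:
    """IBD candidate segments: maximal runs of low-density windows.

    Windows of `window` bp tile the region; a run of consecutive windows
    whose pairwise density stays below `density_threshold` SNP/Kbp and
    whose total span reaches `min_length` is reported as IBD.
    """
    start, end = region
    positions = np.array(sorted(v.pos for v in differences
                                if v.chrom == chrom and start <= v.pos < end))
    edges = list(range(start, end, window)) + [end]
    counts, _ = np.histogram(positions, bins=edges)
    lengths = np.diff(edges)
    dens = counts / (lengths / 1000.0)
    low = dens < density_threshold
    segments = []
    i = 0
    while i < len(low):
        if not low[i]:
            i += 1
            continue
        j = i
        while j < len(low) and low[j]:
            j += 1
        seg_start, seg_end = edges[i], edges[j]
        if seg_end - seg_start >= min_length:
            total = counts[i:j].sum()
            segments.append(IBDSegment(
                line_pair, chrom, seg_start, seg_end,
                float(total / ((seg_end - seg_start) / 1000.0)), "density"))
        i = j
    return segments


def detect_ibd_labels(blocks1: list[HaplotypeBlock],
                      blocks2: list[HaplotypeBlock],
                      line_pair: tuple[str, str],
                      min_length: int = 1_000_000) -> list[IBDSegment]:
    """IBD segments as overlaps of same-founder haplotype blocks."""
    segments = []
    for a in blocks1:
        for b in blocks2:
            if a.chrom != b.chrom or a.founder != b.founder:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if hi - lo >= min_length:
                segments.append(IBDSegment(line_pair, a.chrom, lo, hi, 0.0,
                                           "haplotype-label"))
    return sorted(segments, key=lambda s: (s.chrom, s.start))
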