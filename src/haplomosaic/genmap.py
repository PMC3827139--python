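"""Genetic-map construction from recombinant inbred line genotypes.

Adjacent-marker recombination fractions are estimated from RIL genotype
columns, corrected from the observed RIL fraction R to the per-meiosis
fraction r (R = 2r/(1+2r) for selfed RILs at fixation), converted to cM
with the Kosambi mapping function, filtered by pairwise LOD, and summed
into per-chromosome cumulative maps. Co-segregating markers (identical
genotype columns) are collapsed to one representative first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RILGenotypes:
    """Markers x lines: calls 'A' (parent-1 allele), 'B', or None/'H' missing.

    Heterozygous residual calls are treated as missing; markers must be
    sorted by chromosome then physical position.
    """

    markers: list[tuple[str, int, str]]  # (chrom, pos, id)
    calls: dict[str, list[str | None]]  # line -> calls

    def __post_init__(self) -> None:
        prev = None
        for chrom, pos, _ in self.markers:
            if prev is not None and (chrom, pos) < prev:
                raise ValueError("markers must be sorted")
            prev = (chrom, pos)
        for line, row in self.calls.items():
            if len(row) != len(self.markers):
                raise ValueError(f"row length mismatch for line {line}")

    @property
    def lines(self) -> list[str]:
        return sorted(self.calls)

    def column(self, marker_index: int) -> list[str | None]:
        cleaned = []
        for line in self.lines:
            c = self.calls[line][marker_index]
            cleaned.append(c if c in ("A", "B") else None)
        return cleaned


@dataclass
class RecombEstimate:
    n: int  # lines with both markers called
    k: int  # recombinant lines among them
    R: float  # observed RIL fraction k/n
    r: float  # corrected per-meiosis fraction

    @classmethod
    def from_counts(cls, k: int, n: int) -> "RecombEstimate":
        if n <= 0:
            raise ValueError("no informative lines for this marker pair")
        R = k / n
        return cls(n, k, R, ril_correct(R))


def ril_correct(R: float) -> float:
    """Per-meiosis fraction r from the observed selfed-RIL fraction R.

    Inverts R = 2r/(1+2r); clipped into [0, 0.5].
    """
    if not 0 <= R <= 1:
        raise ValueError("R outside [0, 1]")
    if R >= 0.5:
        return 0.5
    return min(0.5, R / (2.0 * (1.0 - R)))


def ril_observed(r: float) -> float:
    """Expected observed RIL fraction R = 2r/(1+2r)."""
    return 2.0 * r / (1.0 + 2.0 * r)


def recomb_fraction(col1: list[str | None],
                    col2: list[str | None]) -> RecombEstimate:
    """Observed and corrected recombination fraction between two markers."""
    if len(col1) != len(col2):
        raise ValueError("marker columns differ in length")
    n = k = 0
    for a, b in zip(col1, col2):
        if a in ("A", "B") and b in ("A", "B"):
            n += 1
            k += a != b
    return RecombEstimate.from_counts(k, n)


def kosambi(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM."""
    if not 0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cm: float) -> float:
    """r = (e^{4d/100} - 1) / (2 (e^{4d/100} + 1))."""
    e = math.exp(4.0 * d_cm / 100.0)
    return (e - 1.0) / (2.0 * (e + 1.0))


def haldane(r: float) -> float:
    """Haldane map distance d = -50 ln(1-2r) in cM (no interference)."""
    if not 0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_inverse(d_cm: float) -> float:
    return 0.5 * (1.0 - math.exp(-d_cm / 50.0))


def pairwise_lod(est: RecombEstimate) -> float:
    """LOD = n [R log10 R + (1-R) log10(1-R) - log10 0.5], with 0 log 0 = 0."""
    R, n = est.R, est.n
    term = 0.0
    if R > 0:
        term += R * math.log10(R)
    if R < 1:
        term += (1.0 - R) * math.log10(1.0 - R)
    return n * (term - math.log10(0.5))


@dataclass
class GeneticMap:
    """Ordered retained markers with cumulative cM positions."""

    markers: list[tuple[str, int, str]]  # retained, physical order
    cumulative_cm: list[float]
    interval_cm: list[float]  # between consecutive retained markers
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def length_cm(self) -> float:
        return float(sum(self.interval_cm))

    def chromosome_lengths_cm(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (m0, m1), d in zip(zip(self.markers, self.markers[1:]),
                               self.interval_cm):
            if m0[0] == m1[0]:
                out[m0[0]] = out.get(m0[0], 0.0) + d
        for chrom, _, _ in self.markers:
            out.setdefault(chrom, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": [m[2] for m in self.markers],
             "chrom": [m[0] for m in self.markers],
             "pos_bp": [m[1] for m in self.markers],
             "cm": self.cumulative_cm})


def assemble_map(genotypes: RILGenotypes, lod_threshold: float = 3.0,
                 mapping_function: str = "kosambi") -> GeneticMap:
    """Build per-chromosome genetic maps from physically ordered markers.

    Identical genotype columns are collapsed to the first marker by
    position; a marker is dropped when its best LOD against either
    physical neighbour does not exceed `lod_threshold`. Cumulative cM
    restarts at each chromosome; `length_cm` sums all chromosomes.
    """
    fn = {"kosambi": kosambi, "haldane": haldane}[mapping_function]
    cols = [genotypes.column(i) for i in range(len(genotypes.markers))]
    dropped: list[tuple[str, str]] = []
    kept: list[int] = []
    seen: dict[tuple, int] = {}
    for i, (marker, col) in enumerate(zip(genotypes.markers, cols)):
        key = (marker[0], tuple(col))
        if key in seen:
            dropped.append((marker[2], "co-segregating"))
        else:
            seen[key] = i
            kept.append(i)
    # LOD screen against physical neighbours among retained markers
    retained: list[int] = []
    for j, i in enumerate(kept):
        lods = []
        for nb in (j - 1, j + 1):
            if 0 <= nb < len(kept) and \
                    genotypes.markers[kept[nb]][0] == genotypes.markers[i][0]:
                est = recomb_fraction(cols[i], cols[kept[nb]])
                lods.append(pairwise_lod(est))
        if lods and max(lods) <= lod_threshold:
            dropped.append((genotypes.markers[i][2], "low LOD"))
        else:
            retained.append(i)
    if len(retained) < 2:
        raise ValueError("fewer than 2 markers retained")
    markers = [genotypes.markers[i] for i in retained]
    cumulative, intervals = [0.0], []
    for a, b in zip(retained, retained[1:]):
        if genotypes.markers[a][0] != genotypes.markers[b][0]:
            d = 0.0  # chromosome break: restart
        else:
            est = recomb_fraction(cols[a], cols[b])
            d = fn(min(est.r, 0.499999))
        intervals.append(d)
        cumulative.append(0.0 if d == 0.0 and
                          genotypes.markers[a][0] != genotypes.markers[b][0]
                          else cumulative[-1] + d)
    return GeneticMap(markers, cumulative, intervals, dropped)


def map_density(gmap: GeneticMap, window_bp: int = 10_000_000
                ) -> pd.DataFrame:
    """cM per physical window, marker intervals attributed proportionally.

    Each inter-marker interval's cM is spread uniformly over its physical
    span and summed into tiling windows, giving the cM/window
    recombination profile along each chromosome.
    """
    rows: dict[tuple[str, int], float] = {}
    for (m0, m1), d in zip(zip(gmap.markers, gmap.markers[1:]),
                           gmap.interval_cm):
        if m0[0] != m1[0]:
            continue
        chrom, lo, hi = m0[0], m0[1], m1[1]
        span = max(hi - lo, 1)
        w = lo // window_bp
        while w * window_bp < hi:
            ws, we = w * window_bp, (w + 1) * window_bp
            overlap = max(0, min(hi, we) - max(lo, ws))
            rows[(chrom, ws)] = rows.get((chrom, ws), 0.0) + d * overlap / span
            w += 1
    out = [{"chrom": c, "start": s, "end": s + window_bp, "cm": v}
           for (c, s), v in sorted(rows.items())]
    return pd.DataFrame(out)
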