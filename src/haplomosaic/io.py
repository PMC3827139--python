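"""Readers and writers for the standard formats the pipeline touches.

In-memory coordinates are 0-based half-open; GFF3 and VCF are written
1-based per their specifications. Every writer has a matching reader and
write -> read -> write is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, GeneModel, Variant
from .simgenome import FounderPanel, LineGenome


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


_FEATURE_ORDER = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR")


def write_gff3(path: str | Path, genome: AnnotatedGenome) -> None:
    """Gene models as gene/mRNA/exon/CDS/UTR features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.chromosomes):
            fh.write(f"##sequence-region {chrom} 1 {genome.length(chrom)}\n")
        for g in genome.genes:
            def line(ftype: str, s: int, e: int, attrs: str) -> str:
                return (f"{g.chrom}\thaplomosaic\t{ftype}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n")

            mrna = f"{g.id}.1"
            fh.write(line("gene", g.start, g.end, f"ID={g.id}"))
            fh.write(line("mRNA", g.start, g.end,
                          f"ID={mrna};Parent={g.id}"))
            parts = ([("exon", iv) for iv in g.exons]
                     + [("CDS", iv) for iv in g.cds]
                     + [("five_prime_UTR", iv) for iv in g.utr5]
                     + [("three_prime_UTR", iv) for iv in g.utr3])
            for ftype, (s, e) in parts:
                fh.write(line(ftype, s, e, f"Parent={mrna}"))


def read_gff3(path: str | Path,
              sequences: dict[str, str]) -> AnnotatedGenome:
    """Rebuild an AnnotatedGenome from GFF3 plus sequences.

    Pericentromere annotation is not part of GFF3 and comes back empty;
    attach it separately when needed.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                            keep_order=True)
    genes = []
    for gf in db.features_of_type("gene"):
        exons, cds, u5, u3 = [], [], [], []
        for child in db.children(gf.id, level=None):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                u5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                u3.append(iv)
        genes.append(GeneModel(gf.id, gf.seqid, gf.strand, sorted(exons),
                               sorted(cds), sorted(u5), sorted(u3)))
    return AnnotatedGenome(sequences, genes)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path: str | Path, variants: list[Variant], sample: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Single-sample VCF 4.2 with homozygous-alt GT calls, 1-based POS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, n in sorted((contig_lengths or {}).items()):
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t"
                     "PASS\t.\tGT\t1/1\n")


def read_vcf(path: str | Path) -> list[Variant]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.append(Variant(rec.CHROM, rec.POS - 1, rec.REF, alt))
    return out


# ---------------------------------------------------------------------------
# bedGraph depth


def write_bedgraph(path: str | Path,
                   tracks: dict[str, np.ndarray]) -> None:
    """Per-base depth as run-length bedGraph rows (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="depth"\n')
        for chrom in sorted(tracks):
            depth = np.asarray(tracks[chrom])
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(depth[s])}\n")


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", skiprows=1,
                     names=["chrom", "start", "end", "depth"])
    tracks = {}
    for chrom, sub in df.groupby("chrom"):
        n = int(sub["end"].max())
        arr = np.zeros(n, dtype=int)
        for _, row in sub.iterrows():
            arr[row["start"]:row["end"]] = row["depth"]
        tracks[chrom] = arr
    return tracks


def simulated_depth_track(genome: AnnotatedGenome, variants: list[Variant],
                          mean_depth: int = 25,
                          min_deletion: int = 25) -> dict[str, np.ndarray]:
    """Uniform depth with zero-depth runs over large true deletions.

    A deletion of d >= min_deletion bases removes its reference span (the
    bases after the anchor) from the line, so aligned reads leave a
    zero-depth run of exactly that length.
    """
    tracks = {c: np.full(genome.length(c), mean_depth, dtype=int)
              for c in genome.chromosomes}
    for v in variants:
        removed = len(v.ref) - len(v.alt)
        if removed >= min_deletion:
            tracks[v.chrom][v.pos + len(v.alt):v.end] = 0
    return tracks


# ---------------------------------------------------------------------------
# TSV tables


def write_marker_matrix(path: str | Path,
                        markers: list[tuple[str, int, str]],
                        calls: dict[str, list[str | None]]) -> None:
    """Marker matrix TSV: rows = markers (chrom, pos, id), cols = lines."""
    lines = sorted(calls)
    df = pd.DataFrame(
        {"chrom": [m[0] for m in markers],
         "pos": [m[1] for m in markers],
         "marker": [m[2] for m in markers]})
    for line in lines:
        df[line] = [c if c is not None else "NA" for c in calls[line]]
    df.to_csv(path, sep="\t", index=False)


def read_marker_matrix(path: str | Path
                       ) -> tuple[list[tuple[str, int, str]],
                                  dict[str, list[str | None]]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    markers = [(c, int(p), m)
               for c, p, m in zip(df["chrom"], df["pos"], df["marker"])]
    calls = {}
    for col in df.columns[3:]:
        calls[col] = [None if v == "NA" else v for v in df[col]]
    return markers, calls


def write_truth_blocks(path: str | Path,
                       lines: dict[str, LineGenome]) -> None:
    rows = []
    for lid in sorted(lines):
        line = lines[lid]
        for hap_i, hap in ((1, line.hap1), (2, line.hap2)):
            for chrom in sorted(hap):
                for s, e, f in hap[chrom]:
                    rows.append({"line": lid, "hap": hap_i, "chrom": chrom,
                                 "start": s, "end": e, "founder": f})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_blocks(path: str | Path) -> dict[str, LineGenome]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, LineGenome] = {}
    for lid, sub in df.groupby("line"):
        haps: dict[int, dict[str, list]] = {1: {}, 2: {}}
        for _, row in sub.iterrows():
            haps[row["hap"]].setdefault(row["chrom"], []).append(
                (int(row["start"]), int(row["end"]), row["founder"]))
        out[lid] = LineGenome(lid, haps[1], haps[2])
    return out


def write_pedigree(path: str | Path,
                   parents: dict[str, tuple[str | None, str | None]]) -> None:
    rows = [{"child": c, "parent1": p1 or "NA", "parent2": p2 or "NA"}
            for c, (p1, p2) in sorted(parents.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path
                  ) -> dict[str, tuple[str | None, str | None]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {r["child"]: (None if r["parent1"] == "NA" else r["parent1"],
                         None if r["parent2"] == "NA" else r["parent2"])
            for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# dataset export


def export_dataset(out_dir: str | Path, genome: AnnotatedGenome,
                   panel: FounderPanel | None = None,
                   lines: dict[str, LineGenome] | None = None,
                   marker_matrix: tuple[list[tuple[str, int, str]],
                                        dict[str, list[str | None]]] | None = None,
                   mean_depth: int = 25) -> dict[str, str]:
    """Write the full synthetic dataset; returns logical name -> path.

    Emits genome FASTA, gene GFF3, one VCF and one depth bedGraph per
    inbred line, the marker matrix TSV and the truth block table. All
    files round-trip through this module's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = out / "genome.fasta"
    write_fasta(p, genome.chromosomes)
    paths["genome_fasta"] = str(p)

    p = out / "genes.gff3"
    write_gff3(p, genome)
    paths["genes_gff3"] = str(p)

    contigs = {c: genome.length(c) for c in genome.chromosomes}
    if panel is not None and lines is not None:
        for lid in sorted(lines):
            line = lines[lid]
            if not line.is_inbred:
                continue
            variants = line.variants(panel)
            p = out / f"{lid}.vcf"
            write_vcf(p, variants, lid, contigs)
            paths[f"vcf_{lid}"] = str(p)
            p = out / f"{lid}.depth.bedgraph"
            write_bedgraph(p, simulated_depth_track(genome, variants,
                                                    mean_depth))
            paths[f"depth_{lid}"] = str(p)
        p = out / "truth_blocks.tsv"
        write_truth_blocks(p, lines)
        paths["truth_blocks"] = str(p)

    if marker_matrix is not None:
        markers, calls = marker_matrix
        p = out / "markers.tsv"
        write_marker_matrix(p, markers, calls)
        paths["marker_matrix"] = str(p)
    return paths
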