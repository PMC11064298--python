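"""Flat-file readers and writers.

Conventions: FASTA via Biopython; bedGraph 4-column, 0-based half-open,
run-length encoded, zero-depth intervals written so every base is covered;
GFF3 1-based inclusive with gene/mRNA/exon/CDS features (exons are coding in
this pipeline, so exon and CDS lines coincide); tables are TSV with headers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ChromosomeRecord, CoverageTrack, GeneModel


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    d = np.asarray(track.depths)
    # run-length encode contiguous equal depths
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(d)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{int(d[s])}\n")


def read_bedgraph(path: str | os.PathLike, *, sample_id: str = "", sex: str = "") -> list[CoverageTrack]:
    """Read one bedGraph file into per-chromosome tracks.

    Intervals must jointly cover each chromosome from 0 with no holes
    (the writer guarantees this by emitting zero-depth runs).
    """
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            per_chrom.setdefault(chrom, []).append((int(s), int(e), int(float(v))))
    tracks = []
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        length = ivals[-1][1]
        depths = np.zeros(length, dtype=np.int64)
        prev_end = 0
        for s, e, v in ivals:
            if s != prev_end:
                raise ValueError(f"bedGraph {path}: gap or overlap at {chrom}:{s}")
            depths[s:e] = v
            prev_end = e
        tracks.append(CoverageTrack(chrom=chrom, depths=depths, sample_id=sample_id, sex=sex))
    return tracks


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path: str | os.PathLike, *, source: str = "wzgenefate") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            s1, e1 = g.start + 1, g.end  # 1-based inclusive
            fh.write(f"{g.chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t{source}\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            # CDS phase on the coding strand
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            consumed = 0
            rows = []
            for i, (xs, xe) in enumerate(exons, 1):
                phase = (3 - consumed % 3) % 3
                rows.append((xs, xe, i, phase))
                consumed += xe - xs
            for xs, xe, i, phase in sorted(rows):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{xs + 1}\t{xe}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models back from GFF3 (gene strand + exon intervals)."""
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    exons: dict[str, list[tuple[int, int]]] = {}
    mrna_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                meta[attr["ID"]] = (chrom, strand)
            elif ftype == "mRNA":
                mrna_gene[attr["ID"]] = attr["Parent"]
            elif ftype == "exon":
                gene = mrna_gene[attr["Parent"]]
                exons.setdefault(gene, []).append((int(start) - 1, int(end)))
    return [
        GeneModel(gene_id=gid, chrom=meta[gid][0], strand=meta[gid][1], exons=sorted(exons[gid]))
        for gid in meta
    ]


# ---------------------------------------------------------------- tables

def write_manifest(samples: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(samples), "sex": [samples[s] for s in samples]}
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "sex"} <= set(df.columns):
        raise ValueError(f"manifest {path} needs columns sample_id and sex")
    return dict(zip(df["sample_id"], df["sex"]))


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def genome_to_fasta(genome: list[ChromosomeRecord], path: str | os.PathLike) -> None:
    write_fasta({c.name: c.sequence for c in genome}, path)
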