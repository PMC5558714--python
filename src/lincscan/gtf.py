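"""GTF and attribute-table I/O.

Reading goes through pyranges (which already yields 0-based half-open
coordinates); writing converts back to GTF's 1-based inclusive convention.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
import pyranges as pr

from .models import GeneLocus, TranscriptModel


def read_transcripts(path) -> list[TranscriptModel]:
    """Read transcript models (exon features) from a GTF file.

    Per-transcript FPKM and coverage are taken from the `FPKM` and `cov`
    attributes when present (assembler-reported; never recomputed).
    """
    df = pr.read_gtf(path).df
    exons = df[df["Feature"] == "exon"]
    out: list[TranscriptModel] = []
    for tid, grp in exons.groupby("transcript_id", sort=False):
        grp = grp.sort_values("Start")
        first = grp.iloc[0]
        out.append(
            TranscriptModel(
                id=tid,
                chrom=str(first["Chromosome"]),
                strand=str(first.get("Strand", ".")),
                exons=list(zip(grp["Start"].astype(int), grp["End"].astype(int))),
                fpkm=float(first["FPKM"]) if "FPKM" in grp.columns else 0.0,
                coverage=float(first["cov"]) if "cov" in grp.columns else 0.0,
                gene_id=str(first["gene_id"]) if "gene_id" in grp.columns else None,
            )
        )
    return out


def read_loci(path, biotype: str) -> list[GeneLocus]:
    """Read gene-level loci from a GTF; the span of each gene_id's exons."""
    df = pr.read_gtf(path).df
    df = df[df["Feature"].isin(["exon", "transcript"])]
    out = []
    for gid, grp in df.groupby("gene_id", sort=False):
        tids = sorted(set(grp["transcript_id"].dropna()))
        out.append(
            GeneLocus(
                id=gid,
                chrom=str(grp["Chromosome"].iloc[0]),
                start=int(grp["Start"].min()),
                end=int(grp["End"].max()),
                biotype=biotype,
                transcript_ids=tids,
            )
        )
    return out


def write_transcripts(transcripts: Iterable[TranscriptModel], path,
                      source: str = "lincscan") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            gid = t.gene_id or t.id
            attrs = (
                f'gene_id "{gid}"; transcript_id "{t.id}"; '
                f'FPKM "{t.fpkm:.6g}"; cov "{t.coverage:.6g}";'
            )
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"{attrs}\n"
                )


def read_cpc_scores(path) -> dict[str, float]:
    """TSV with columns transcript_id, score (coding potential)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["transcript_id"], df["score"].astype(float)))


def read_homology_hits(path) -> dict[str, list[tuple[float, float]]]:
    """TSV with columns transcript_id, aln_len, evalue; one row per hit."""
    df = pd.read_csv(path, sep="\t")
    hits: dict[str, list[tuple[float, float]]] = {}
    for tid, ln, ev in zip(df["transcript_id"], df["aln_len"], df["evalue"]):
        hits.setdefault(tid, []).append((float(ln), float(ev)))
    return hits


def attach_attributes(transcripts: list[TranscriptModel],
                      cpc: dict[str, float] | None = None,
                      hits: dict[str, list[tuple[float, float]]] | None = None,
                      ) -> list[TranscriptModel]:
    for t in transcripts:
        if cpc is not None:
            t.cpc_score = cpc.get(t.id)
        if hits is not None:
            t.homology_hits = hits.get(t.id, [])
    return transcripts
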