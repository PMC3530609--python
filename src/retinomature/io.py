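"""Readers and writers for the tabular formats the pipeline consumes.

Genomic coordinates are 0-based half-open everywhere inside the package;
GFF3 (1-based, end-inclusive) is converted at the I/O boundary.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .reannotate import TranscriptRecord

GFF3_COLUMNS = ["seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes"]


def write_gff3(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write CDS features, one line per exon, grouped by transcript."""
    lines = ["##gff-version 3"]
    for tr in transcripts:
        for start, end in tr.cds_exons:
            attrs = f"ID=cds:{tr.transcript_id};Parent={tr.transcript_id}"
            lines.append("\t".join([
                tr.chrom, tr.source_db, "CDS",
                str(start + 1), str(end),  # to 1-based inclusive
                ".", tr.strand, "0", attrs,
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_transcripts(path: str | Path) -> list[TranscriptRecord]:
    """Read CDS features from a GFF3 file into transcript records.

    Exons are grouped by the ``Parent`` attribute; each transcript's exons
    must share one chromosome and strand (enforced by ``TranscriptRecord``).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ValueError(f"CDS feature without Parent/ID in {path}")
        tid = parents[0]
        exons[tid].append((feat.start - 1, feat.end))  # to 0-based half-open
        meta[tid] = (feat.seqid, feat.strand, feat.source)
    records = []
    for tid in sorted(exons):
        chrom, strand, source = meta[tid]
        merged = _merge_touching(sorted(exons[tid]))
        records.append(TranscriptRecord(
            transcript_id=tid, source_db=source, chrom=chrom,
            strand=strand, cds_exons=tuple(merged)))
    return records


def _merge_touching(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent intervals so records satisfy their invariant."""
    out: list[tuple[int, int]] = []
    for s, e in exons:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_gmt(catalog: dict[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    """Write a GMT gene-set file: term_id <tab> description <tab> genes..."""
    lines = []
    for term_id in sorted(catalog):
        desc, genes = catalog[term_id]
        lines.append("\t".join([term_id, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out[fields[0]] = (fields[1], set(fields[2:]))
    return out


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(df: pd.DataFrame, path: str | Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", **kw)


def read_intensities(path: str | Path) -> pd.DataFrame:
    """Intensity TSV: first column is the row id, header holds sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in intensity matrix {path}")
    return df
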