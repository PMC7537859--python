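"""Readers and writers for genome sequences and gene models.

FASTA (optionally gzipped) goes through Biopython.  Gene models come from
GFF3 CDS features (frame taken from the phase column) or from a simple
5-column TSV.  All user-facing coordinates are 1-based inclusive, as in
GFF3; internally everything is 0-based half-open.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .motifscan import Gene, GenomeRecord


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(
    path: str | Path,
    largest_only: bool = True,
    origin: int | None = None,
    terminus: int | None = None,
) -> GenomeRecord:
    """Read a FASTA file into a GenomeRecord.

    Multi-record files keep only the largest replicon (the default,
    matching per-replicon analysis).  With ``largest_only=False`` a
    multi-record file is refused outright rather than silently merged.
    """
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if len(records) > 1 and not largest_only:
        raise ValueError(
            f"{path} holds {len(records)} replicons; analyses are per-replicon "
            "(pass largest_only=True or split the file)"
        )
    rec = max(records, key=lambda r: len(r.seq))
    return GenomeRecord(
        id=rec.id, sequence=str(rec.seq), origin=origin, terminus=terminus
    )


def write_fasta(record: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        for i in range(0, len(record.sequence), width):
            fh.write(record.sequence[i : i + width] + "\n")


def read_genes_gff3(path: str | Path, seqid: str | None = None) -> list[Gene]:
    """CDS features from a GFF3 file as 0-based half-open Gene tuples."""
    genes: list[Gene] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            if seqid is not None and fields[0] != seqid:
                continue
            start = int(fields[3]) - 1
            end = int(fields[4])
            strand = fields[6] if fields[6] in "+-" else "+"
            frame = int(fields[7]) if fields[7] in "012" else 0
            genes.append(Gene(start=start, end=end, strand=strand, frame=frame))
    return genes


def write_genes_gff3(
    genes: list[Gene], seqid: str, path: str | Path, source: str = "periodscope"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seqid}\t{source}\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t{g.frame}\tID=cds{g.start}\n"
            )


def read_genes_tsv(path: str | Path, seqid: str | None = None) -> list[Gene]:
    """Gene models from a 5-column TSV: seqid, start, end, strand, frame
    (coordinates 1-based inclusive, as in GFF3)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["seqid", "start", "end", "strand", "frame"],
        dtype={"seqid": str, "strand": str},
    )
    if seqid is not None:
        df = df[df["seqid"] == seqid]
    return [
        Gene(start=int(r.start) - 1, end=int(r.end), strand=r.strand, frame=int(r.frame))
        for r in df.itertuples()
    ]


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
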