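"""Plain-text format helpers (FASTA/FASTQ/TSV) shared across the pipeline."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .simulate import FastqRead, QUALITY_CHAR


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{QUALITY_CHAR * len(r.seq)}\n")


def read_fastq(path) -> list[FastqRead]:
    return [
        FastqRead(rec.description or rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_counts_tsv(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tcount\n")
        for target in sorted(counts):
            fh.write(f"{target}\t{counts[target]}\n")


def read_counts_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
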