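"""Readers and writers for the plain-text interchange formats.

Haplotypes and reads travel as FASTA/FASTQ (via Biopython), traces as TSV
with a ``pos A C G T`` header, cohorts as TSV, gene models as JSON.
Key=value pairs on FASTA description lines carry haplotype metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genemodel import GeneModel
from .simulate import Haplotype
from .tracedecomp import CHANNELS, Chromatogram


def write_haplotypes_fasta(haplotypes: Sequence[Haplotype], path) -> None:
    records = []
    for hap in haplotypes:
        desc = f"chromosome={hap.chromosome} role={hap.role}"
        records.append(SeqRecord(Seq(hap.sequence), id=hap.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_haplotypes_fasta(path) -> list[Haplotype]:
    haps = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        haps.append(
            Haplotype(rec.id, str(rec.seq),
                      meta.get("chromosome", "Z"), meta.get("role", "other"))
        )
    return haps


def write_trace_tsv(trace: Chromatogram, path) -> None:
    df = pd.DataFrame(trace.heights, columns=list(CHANNELS))
    df.insert(0, "pos", np.arange(trace.anchor, trace.anchor + trace.n_positions))
    df.to_csv(path, sep="\t", index=False)


def read_trace_tsv(path) -> Chromatogram:
    df = pd.read_csv(path, sep="\t")
    missing = {"pos", *CHANNELS} - set(df.columns)
    if missing:
        raise ValueError(f"trace TSV is missing columns: {sorted(missing)}")
    return Chromatogram(df[list(CHANNELS)].to_numpy(float),
                        anchor=int(df["pos"].iloc[0]))


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_reads_fasta(reads: Sequence[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[tuple[str, str]]:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_gene_model_json(model: GeneModel, path) -> None:
    payload = {"name": model.name, "exons": model.exon_lengths,
               "introns": model.intron_lengths}
    if model.sequence is not None:
        payload["sequence"] = model.sequence
    if model.cds is not None:
        payload["cds"] = list(model.cds)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_gene_model_json(path) -> GeneModel:
    payload = json.loads(Path(path).read_text())
    return GeneModel(
        name=payload["name"],
        exon_lengths=list(payload["exons"]),
        intron_lengths=list(payload.get("introns", [])),
        sequence=payload.get("sequence"),
        cds=tuple(payload["cds"]) if payload.get("cds") else None,
    )


def read_aligned_fasta_pair(path):
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError("aligned FASTA must contain exactly two records")
    return str(records[0].seq), str(records[1].seq)
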