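"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular formats go through pandas; FASTA through Bio.SeqIO.  Coordinates
are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathType = Union[str, PathLike]

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "start", "end"]
PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "conc_q", "conc_a"]


def read_genes(path: PathType) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return genes


def write_genes(genes: pd.DataFrame, path: PathType) -> None:
    genes.loc[:, GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peaks(path: PathType) -> pd.DataFrame:
    peaks = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return peaks


def write_peaks(peaks: pd.DataFrame, path: PathType) -> None:
    peaks.loc[:, PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fasta(path: PathType) -> dict[str, str]:
    """Return a mapping sequence id -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathType) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression(path: PathType) -> pd.DataFrame:
    """Expression CSV: first column gene_id, remaining columns '<cond>_<rep>'."""
    return pd.read_csv(path, index_col=0)


def write_expression(matrix: pd.DataFrame, path: PathType) -> None:
    matrix.to_csv(path, index_label="gene_id")


def read_gmt(path: PathType) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: term <tab> description <tab> member ids."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line!r}")
        term, description, members = fields[0], fields[1], fields[2:]
        sets[term] = (description, frozenset(m for m in members if m))
    return sets


def write_gmt(sets: dict[str, tuple[str, frozenset[str]]], path: PathType) -> None:
    lines = []
    for term in sorted(sets):
        description, members = sets[term]
        lines.append("\t".join([term, description, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: PathType) -> pd.DataFrame:
    trace = pd.read_csv(path)
    if not {"time_h", "value"} <= set(trace.columns):
        raise ValueError("trace CSV requires columns time_h,value")
    return trace


def write_trace(trace: pd.DataFrame, path: PathType) -> None:
    trace.loc[:, ["time_h", "value"]].to_csv(path, index=False)


def read_cohort(path: PathType) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(cohort: pd.DataFrame, path: PathType) -> None:
    cohort.to_csv(path, index=False)


def read_truth(path: PathType) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth: dict, path: PathType) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
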