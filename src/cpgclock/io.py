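"""Readers and writers for the plain-text formats the pipeline exchanges.

Genomes are held in memory as plain ``{name: sequence}`` mappings keyed by
the first whitespace-delimited token of the FASTA header, which is how
downstream coordinate lookups address contigs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an id -> sequence mapping.

    The id is the first whitespace-delimited token of the header line.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff_features(path: str | Path, feature_types: tuple[str, ...] = ("gene", "mRNA")) -> pd.DataFrame:
    """Read a GFF3 file and keep rows of the requested feature types.

    Returns a DataFrame with GFF columns; ``start``/``end`` stay 1-based
    inclusive as in the file. Callers convert to 0-based where needed.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str, "type": str, "strand": str},
    )
    df = df[df["type"].isin(feature_types)].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_bed(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read a BED file of loci as (name, contig, start, end), 0-based half-open.

    The 4th BED column (name) identifies the promoter; unnamed rows get
    ``locus{i}``.
    """
    loci = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"locus{i}"
            loci.append((name, contig, start, end))
    return loci


def write_bed(loci: list[tuple[str, str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, contig, start, end in loci:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_divergence_csv(path: str | Path) -> pd.DataFrame:
    """Square species x species divergence-time matrix (MYA), ids on both axes."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_species_csv(path: str | Path) -> pd.DataFrame:
    """Species table: species_id, class, max_lifespan_yrs, source."""
    df = pd.read_csv(path, dtype={"species_id": str, "class": str})
    required = {"species_id", "class", "max_lifespan_yrs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df
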