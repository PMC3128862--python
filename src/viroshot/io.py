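"""Readers and writers for the package's plain-text interchange formats:
FASTA reads, tab-separated hit tables, gradient profiles, contig reports
and library metadata."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .accounting import GradientFraction
from .annotation import HIT_COLUMNS
from .assembly import AssemblyResult, Read
from .compare import LibraryProfile

GRADIENT_COLUMNS = ["fraction", "volume_ml", "mass_g", "vlp_per_ml"]
CONTIG_COLUMNS = [
    "contig_id", "members", "n_members", "classification", "consensus_length",
]
LIBRARY_COLUMNS = ["name", "n_sequences", "mean_read_length"]


def read_fasta(path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(reads: list[Read], path) -> None:
    records = (
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads
    )
    SeqIO.write(records, str(path), "fasta")


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[list(hits.columns)].to_csv(path, sep="\t", index=False)


def write_empty_hit_table(path) -> None:
    pd.DataFrame(columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_gradient(fractions: list[GradientFraction], path) -> None:
    pd.DataFrame(
        [
            {
                "fraction": f.index,
                "volume_ml": f.volume_ml,
                "mass_g": repr(f.mass_g),
                "vlp_per_ml": f.vlp_per_ml,
            }
            for f in fractions
        ],
        columns=GRADIENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gradient(path) -> list[GradientFraction]:
    df = pd.read_csv(path, sep="\t")
    for col in GRADIENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gradient table {path}: missing column {col!r}")
    return [
        GradientFraction(
            index=int(row.fraction),
            volume_ml=float(row.volume_ml),
            mass_g=float(row.mass_g),
            vlp_per_ml=float(row.vlp_per_ml),
        )
        for row in df.itertuples()
    ]


def write_contig_report(result: AssemblyResult, path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": c.id,
                "members": ",".join(c.member_ids),
                "n_members": c.n_members,
                "classification": c.classification,
                "consensus_length": len(c.consensus),
            }
            for c in result.contigs
        ],
        columns=CONTIG_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_library_metadata(path) -> list[LibraryProfile]:
    df = pd.read_csv(path, sep="\t")
    for col in LIBRARY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"library metadata {path}: missing column {col!r}")
    return [
        LibraryProfile(
            name=str(row.name), n_sequences=int(row.n_sequences),
            mean_read_length=float(row.mean_read_length),
        )
        for row in df.itertuples(index=False)
    ]
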