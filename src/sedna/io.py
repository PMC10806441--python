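"""Readers and writers for the plain-text formats used by the pipeline.

Count tables: TSV, rows = ASVs, first column ``asv_id``, remaining
columns = samples. Taxonomy: TSV with ``asv_id`` then the seven rank
columns (empty cell = unassigned) and an optional ``marine`` 0/1 column.
Metadata: TSV with ``sample_id``, ``role``, ``lat``, ``lon`` and any
number of covariate columns. Sequences: FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import RANKS, MarkerCountTable, TaxonomyTable


def write_count_table(table: MarkerCountTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_count_table(path, roles: pd.Series, marker: str = "marker") -> MarkerCountTable:
    df = pd.read_csv(path, sep="\t", index_col="asv_id")
    df.index.name = None
    return MarkerCountTable(counts=df, roles=roles.reindex(df.columns), marker=marker)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.ranks.copy()
    if tax.marine is not None:
        df["marine"] = tax.marine.astype(int)
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col="asv_id", keep_default_na=False, dtype=str)
    marine = None
    if "marine" in df.columns:
        marine = df["marine"].replace("", "0").astype(int).astype(bool)
        df = df.drop(columns=["marine"])
    df.index.name = None
    if marine is not None:
        marine.index.name = None
    return TaxonomyTable(ranks=df[list(RANKS)], marine=marine)


def write_metadata(meta: pd.DataFrame, path) -> None:
    df = meta.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def roles_from_metadata(meta: pd.DataFrame) -> pd.Series:
    if "role" not in meta.columns:
        raise ValueError("metadata lacks a 'role' column")
    return meta["role"].astype(str)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
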