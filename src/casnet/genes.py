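"""Per-genome gene coordinate tables and their GFF3 / flat-TSV serializations."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List
from urllib.parse import quote, unquote

import pandas as pd

__all__ = ["GeneTable", "write_gene_tables_tsv", "read_gene_tables_tsv",
           "write_gene_tables_gff3", "read_gene_tables_gff3"]

GENE_COLUMNS = ["contig_id", "start", "end", "strand", "family_id", "is_cas"]


@dataclass
class GeneTable:
    """Gene records of one genome.

    ``genes`` holds one row per gene with columns ``contig_id``, ``start``,
    ``end`` (1-based inclusive bp), ``strand`` (+/-), ``family_id`` and the
    boolean ``is_cas``.  Genes on a contig may overlap; nothing is assumed
    sorted.
    """

    genome_id: str
    genes: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        self.genes = self.genes[GENE_COLUMNS].reset_index(drop=True).astype(
            {"start": int, "end": int, "is_cas": bool}
        )
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError(f"genome {self.genome_id}: gene with start > end")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"genome {self.genome_id}: invalid strand value")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def contigs(self) -> List[str]:
        return list(dict.fromkeys(self.genes["contig_id"]))


def write_gene_tables_tsv(tables: Iterable[GeneTable], path) -> None:
    frames = []
    for t in tables:
        df = t.genes.copy()
        df.insert(0, "genome_id", t.genome_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gene_tables_tsv(path) -> List[GeneTable]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "contig_id": str,
                                            "family_id": str})
    if "is_cas" in df.columns and df["is_cas"].dtype == object:
        df["is_cas"] = df["is_cas"].astype(str).str.lower().isin(["true", "1", "yes"])
    return [
        GeneTable(genome, sub.drop(columns="genome_id"))
        for genome, sub in df.groupby("genome_id", sort=False)
    ]


def write_gene_tables_gff3(tables: Iterable[GeneTable], path) -> None:
    """Write all genomes as GFF3; genome and family ride along in attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tables:
            for _, g in t.genes.iterrows():
                attrs = (
                    f"genome={quote(t.genome_id)};family={quote(g.family_id)};"
                    f"is_cas={'true' if g.is_cas else 'false'}"
                )
                fh.write(
                    f"{g.contig_id}\tcasnet\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_gene_tables_gff3(path) -> List[GeneTable]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _src, _type, start, end, _score, strand, _phase, attrs = fields
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            if "genome" not in kv or "family" not in kv:
                raise ValueError("GFF3 attributes must carry genome= and family=")
            rows.append(
                {
                    "genome_id": unquote(kv["genome"]),
                    "contig_id": contig,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "family_id": unquote(kv["family"]),
                    "is_cas": kv.get("is_cas", "false").lower() == "true",
                }
            )
    df = pd.DataFrame(rows)
    return [
        GeneTable(genome, sub.drop(columns="genome_id"))
        for genome, sub in df.groupby("genome_id", sort=False)
    ]
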