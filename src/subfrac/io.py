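"""Readers and writers for the pipeline's on-disk formats.

Coordinates follow format conventions: BED and the internal frames are
0-based half-open; GFF3 is written/read 1-based closed.  Signal tracks are
bedGraph-like TSVs (chrom, position, value columns); the small-RNA track
carries its library size in a ``# library_total=N`` header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tracks import SignalTrack

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "subgenome"]


# ---------------------------------------------------------------- GFF3 / BED

def write_gff3(genes: pd.DataFrame, path) -> int:
    """Write gene features (frame columns per GENE_COLUMNS) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            attrs = f"ID={g.gene_id};subgenome={g.subgenome}"
            fh.write(
                f"{g.chrom}\tsubfrac_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
    return len(genes)


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(
                {
                    "gene_id": attrs.get("ID"),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "subgenome": attrs.get("subgenome"),
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end", "name")) -> int:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)
    return len(df)


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=list(names))


def write_bedpe(loops: pd.DataFrame, path) -> int:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    loops[cols].to_csv(path, sep="\t", header=False, index=False)
    return len(loops)


def read_bedpe(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )


# -------------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path) -> int:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return len(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -------------------------------------------------------------------- TSVs

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_matrix(path) -> pd.DataFrame:
    """Genes x tissues matrix with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ------------------------------------------------------------------- tracks

def write_sirna_track(df: pd.DataFrame, library_total: int, path) -> int:
    with open(path, "w") as fh:
        fh.write(f"# library_total={library_total}\n")
        df[["chrom", "pos", "count"]].to_csv(fh, sep="\t", index=False)
    return len(df)


def read_sirna_track(path) -> SignalTrack:
    with open(path) as fh:
        header = fh.readline()
    library_total = None
    if header.startswith("# library_total="):
        library_total = float(header.strip().split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    return SignalTrack(df, "sirna", library_total=library_total)


def write_methylation_track(df: pd.DataFrame, path) -> int:
    df[["chrom", "pos", "context", "meth", "total"]].to_csv(path, sep="\t", index=False)
    return len(df)


def read_methylation_track(path) -> SignalTrack:
    return SignalTrack(pd.read_csv(path, sep="\t"), "methylation")


def write_histone_track(df: pd.DataFrame, path) -> int:
    df[["chrom", "pos", "treat", "input"]].to_csv(path, sep="\t", index=False)
    return len(df)


def read_histone_track(path) -> SignalTrack:
    return SignalTrack(pd.read_csv(path, sep="\t"), "histone")


# ----------------------------------------------------------------- manifest

def write_manifest(records: dict[str, int], out_dir, extra: dict | None = None) -> Path:
    path = Path(out_dir) / "manifest.json"
    payload = {"files": records}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(data_dir) -> dict:
    with open(Path(data_dir) / "manifest.json") as fh:
        return json.load(fh)
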