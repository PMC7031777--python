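"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open (BED convention).  The
formats are deliberately simple and text-only:

* ENCODE narrowPeak (BED6+4) for ChIP-seq and open-chromatin peaks;
* a BED-like TSV gene annotation (gene_id, chrom, start, end, strand,
  tss, is_tf);
* genes x samples expression matrices as TSV with a header row of sample
  ids;
* per-sample copy-number segment tables (sample, chrom, start, end,
  log_ratio);
* CpG beta tables (cpg_id, chrom, pos, gene_id, one column per sample);
* seed gene lists, one id per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "is_tf"]


def read_narrowpeak(path) -> pd.DataFrame:
    """Read an ENCODE narrowPeak (BED6+4) file into a DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=NARROWPEAK_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int},
        comment="#",
    )
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"]].index[0]
        raise ValueError(f"narrowPeak row {bad}: start >= end in {path}")
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    df = df.loc[:, NARROWPEAK_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read the gene annotation table; index is gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    return df.set_index("gene_id", drop=False)


def write_annotation(df: pd.DataFrame, path) -> None:
    df.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in expression matrix {path}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_segments(path) -> pd.DataFrame:
    """Read a segment table (sample, chrom, start, end, log_ratio)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "start", "end", "log_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"segment file {path} lacks {required - set(df.columns)}")
    return df


def write_segments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cpg_table(path) -> pd.DataFrame:
    """Read a CpG beta table; sample columns follow the 4 site columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"cpg_id", "chrom", "pos", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"CpG table {path} lacks {required - set(df.columns)}")
    return df


def write_cpg_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_seed_list(path) -> list[str]:
    """Read a seed gene list, one gene id per line; blank lines skipped."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_seed_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def write_fasta(records: dict[str, str], path) -> None:
    """Write chromosome sequences to FASTA (60-column wrapping)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
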