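"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; loci, domain, expression and Ct tables as TSV via
pandas.  All writes are atomic (write to a temp file in the target
directory, then rename), so an interrupted run never leaves a truncated
output behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOCI_COLUMNS = ["gene", "chromosome", "start", "end", "strand", "locus_rank"]


def atomic_write(path: str | Path, text: str) -> None:
    """Write text atomically: temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}; duplicate ids are rejected."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        s = str(rec.seq)
        lines.extend(s[i : i + width] for i in range(0, len(s), width))
    atomic_write(path, "\n".join(lines) + "\n")


def read_loci(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"loci table missing column(s) {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in loci table")
    return df.set_index("gene")


def write_loci(loci: pd.DataFrame, path: str | Path) -> None:
    out = loci.reset_index()[LOCI_COLUMNS]
    atomic_write(path, out.to_csv(sep="\t", index=False))


def read_domains(path: str | Path) -> dict[str, list[str]]:
    """TSV (gene, comma-separated domains) -> {gene: [domains]}."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in domain table")
    return {
        row["gene"]: [d for d in str(row["domains"]).split(",") if d]
        for _, row in df.iterrows()
    }


def write_domains(domains: dict[str, list[str]], path: str | Path) -> None:
    lines = ["gene\tdomains"]
    lines += [f"{g}\t{','.join(ds)}" for g, ds in domains.items()]
    atomic_write(path, "\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV matrix; every cell must be numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in matrix")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna().argmax()]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r}")
        df[col] = converted
    return df


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    atomic_write(path, m.to_csv(sep="\t"))


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing column(s) {sorted(missing)}")
    return df


def read_ct(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "sample", "condition", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    atomic_write(path, df.to_csv(sep="\t", index=index))
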