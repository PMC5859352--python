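"""Readers and writers for the flat text formats used across the pipeline.

All genomic coordinates are 0-based, half-open. Aligned-read intervals are
exchanged as BED6 plus two extra columns (SAM flag bitfield and CIGAR
string), i.e. a minimal SAM-derived tab format:

    chrom  start  end  name  mapq  strand  flag  cigar

A plain BED6 file (without the last two columns) is also accepted; missing
fields default to flag 0 and CIGAR "<len>M".
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_CLEAN_CIGAR = re.compile(r"^\d+M$")

READ_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand", "flag", "cigar"]


def cigar_is_clean(cigar: str | Iterable[str]):
    """True when the CIGAR is a single ungapped match (no indels/clips)."""
    if isinstance(cigar, str):
        return bool(_CLEAN_CIGAR.match(cigar))
    return np.array([bool(_CLEAN_CIGAR.match(c)) for c in cigar], dtype=bool)


# ---------------------------------------------------------------------------
# annotation


def write_annotation(annotation: pd.DataFrame, path) -> None:
    """Write gene annotation (gene_id, chrom, tss, strand); TSS is 0-based."""
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return ann


# ---------------------------------------------------------------------------
# count / coverage matrices


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a features x samples matrix; first column holds feature ids."""
    matrix.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# reads


def write_reads(reads: pd.DataFrame, path) -> None:
    """Write read intervals as BED6+2 (flag, cigar); no header line."""
    out = reads.copy()
    if "name" not in out.columns:
        out["name"] = [f"r{i}" for i in range(len(out))]
    out[READ_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_reads(path) -> pd.DataFrame:
    """Read BED6(+2) intervals into a read table with a cigar_clean column."""
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    ncol = first.shape[1] if len(first) else 8
    if ncol not in (6, 8):
        raise ValueError(f"{path}: expected 6 or 8 tab-separated columns, got {ncol}")
    names = READ_COLUMNS[:ncol]
    reads = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=names,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "mapq": np.int32, "strand": str},
    )
    if ncol == 6:
        reads["flag"] = 0
        reads["cigar"] = (reads["end"] - reads["start"]).astype(str) + "M"
    reads["cigar_clean"] = cigar_is_clean(reads["cigar"].to_numpy())
    if (reads["start"] >= reads["end"]).any():
        raise ValueError(f"{path}: read intervals must satisfy start < end")
    return reads


# ---------------------------------------------------------------------------
# sequences


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# SNP tables


def write_snp_table(snps: pd.DataFrame, path) -> None:
    out = snps.copy()
    if not isinstance(out["set_label"].iloc[0] if len(out) else "", str):
        out["set_label"] = out["set_label"].map(lambda s: ",".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos", "pvalue", "set_label"}
    missing = required - set(snps.columns)
    if missing:
        raise ValueError(f"SNP table {path} lacks columns: {sorted(missing)}")
    bad = (snps["pvalue"] <= 0) | (snps["pvalue"] > 1)
    if bad.any():
        raise ValueError(f"SNP table {path}: association p-values must lie in (0, 1]")
    return snps


def snp_labels(snps: pd.DataFrame) -> pd.Series:
    """Per-SNP frozenset of source-set labels from the comma-joined column."""
    return snps["set_label"].map(lambda s: frozenset(str(s).split(",")))
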