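"""Readers and writers for the pipeline's TSV interchange formats.

All formats are plain tab-separated text with a header row:

* expression / centroid matrices — first column ``gene_id``, remaining
  columns samples (or subtypes);
* gene lists — one identifier per line, no header;
* signature gene sets — two columns ``signature_name`` and ``gene_id``;
* variant tables — the MAF-like column set documented in
  :mod:`mammotype.mutations` (``VARIANT_COLUMNS``);
* reference signature matrices — 96 context rows (``A[C>A]A`` style
  labels, COSMIC v2 layout) by signature columns;
* genome trinucleotide frequencies — ``context`` and ``frequency`` columns;
* CNA tables — long format ``tumor_id``, ``gene``, ``status``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mutations import VARIANT_COLUMNS, validate_variant_table
from .scoring import GeneSignature

__all__ = [
    "read_expression", "write_expression",
    "read_gene_list", "read_signatures",
    "read_variants", "write_variants",
    "read_signature_matrix", "read_trinuc_freqs",
    "read_cna", "write_cna", "read_census",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression or centroid TSV -> genes x samples DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_signatures(path: str | Path) -> list[GeneSignature]:
    """Signature gene-set TSV (``signature_name<TAB>gene_id``, one gene per row)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneSignature(str(name), tuple(sub["gene_id"].astype(str)))
        for name, sub in df.groupby("signature_name", sort=True)
    ]


def read_variants(path: str | Path) -> pd.DataFrame:
    """MAF-like candidate-variant TSV; validates the record invariants."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "gene": str, "aa_change": str, "trinucleotide": str},
        keep_default_na=False, na_values=[],
    )
    df["caller_pass"] = df["caller_pass"].astype(str).str.lower().isin({"true", "1", "yes"})
    for col in ("pos", "total_depth", "alt_depth", "alt_forward", "alt_reverse"):
        df[col] = df[col].astype(int)
    validate_variant_table(df)
    return df


def write_variants(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """COSMIC-v2-layout reference signature TSV (96 context rows x signatures)."""
    from .mutations import validate_signature_matrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_signature_matrix(df)
    return df


def read_trinuc_freqs(path: str | Path) -> pd.Series:
    """Genome trinucleotide frequency TSV (``context``, ``frequency``)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["frequency"].to_numpy(), index=df["context"].astype(str))


def read_cna(path: str | Path) -> pd.DataFrame:
    """Long-format CNA TSV -> genes x tumors status matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"tumor_id": str, "gene": str})
    wide = df.pivot(index="gene", columns="tumor_id", values="status").fillna(0).astype(int)
    wide.columns.name = None
    return wide


def write_cna(profiles: pd.DataFrame, path: str | Path) -> None:
    long = profiles.stack().rename("status").reset_index()
    long.columns = ["gene", "tumor_id", "status"]
    long[["tumor_id", "gene", "status"]].to_csv(path, sep="\t", index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    """Cancer-gene-census-like TSV: ``gene``, ``role``, ``alteration``."""
    return pd.read_csv(path, sep="\t", dtype=str)
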