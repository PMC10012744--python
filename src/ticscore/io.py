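"""TSV readers/writers for the pipeline's tabular interchange formats.

Expression TSV: first column the gene identifier, header row of sample
ids, tab-separated floats. NA cells are tolerated and imputed by the
gene-wise mean (logged) so downstream z-scoring sees finite values.

Clinical TSV: required columns ``sample_id``, ``time_months``, ``event``;
any further columns are carried as covariates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "write_scores_tsv",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene identifiers")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample identifiers")
    df = df.astype(float)
    if df.isna().any().any():
        n_na = int(df.isna().sum().sum())
        log.warning("%s: imputing %d NA cell(s) by gene-wise mean", path, n_na)
        means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)
        if df.isna().any().any():
            raise ParseError(f"{path}: gene row(s) entirely NA")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


_REQUIRED_CLINICAL = ("time_months", "event")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    for col in _REQUIRED_CLINICAL:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id values")
    df = df.set_index("sample_id")
    t = df["time_months"].astype(float)
    if (t <= 0).any() or t.isna().any():
        raise ParseError(f"{path}: time_months must be positive and non-missing")
    e = df["event"]
    if not e.isin([0, 1]).all():
        raise ParseError(f"{path}: event must be 0/1")
    df["time_months"] = t
    df["event"] = e.astype(int)
    return df


def write_clinical_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
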