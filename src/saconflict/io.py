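"""Readers and writers for the pipeline's tab-separated table formats.

All tables are TSV with a header row.  Positions in SNP tables are 1-based;
recombination-map windows, gene intervals and liftover blocks are BED-style
0-based half-open.  The conversion between the two conventions happens here,
exactly once, at the I/O boundary.

Schema violations raise :class:`ValidationError` naming the file and the
offending column (and row where determinable); unknown extra columns only
warn.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .recomb_assoc import LiftoverBlock, LiftoverMap, RecombWindow

__all__ = [
    "read_snp_table",
    "write_snp_table",
    "read_recomb_map",
    "write_recomb_map",
    "read_gene_bed",
    "write_gene_bed",
    "read_paralog_pairs",
    "write_paralog_pairs",
    "read_liftover_map",
    "write_liftover_map",
    "write_test_results",
]

SNP_COLUMNS = (
    "snp_id", "chrom", "pos", "gene_id", "category",
    "d_male", "d_female", "weight", "allele_freq",
)
SNP_NUMERIC = ("pos", "d_male", "d_female", "weight", "allele_freq")
MAP_COLUMNS = ("chrom", "start", "end", "rate_cM_per_Mb")
GENE_COLUMNS = ("chrom", "start", "end", "gene_id")
PAIR_COLUMNS = ("gene_a", "gene_b", "diopt_score")
LIFTOVER_COLUMNS = (
    "src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "strand",
)


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=3)
    return df[list(required)]


def _require_numeric(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1 header + 1-based
            raise ValidationError(
                f"{path}: non-numeric or missing value in column {col!r}, line {row}"
            )
        df[col] = values


def read_snp_table(path) -> pd.DataFrame:
    """Read a candidate-SA SNP table (positions 1-based)."""
    df = _read_tsv(path, SNP_COLUMNS)
    _require_numeric(df, SNP_NUMERIC, path)
    df["pos"] = df["pos"].astype(int)
    if (df["weight"] <= 0).any():
        row = int(np.argmax((df["weight"] <= 0).to_numpy())) + 2
        raise ValidationError(f"{path}: non-positive weight, line {row}")
    bad_freq = ~((df["allele_freq"] > 0) & (df["allele_freq"] <= 0.5))
    if bad_freq.any():
        row = int(np.argmax(bad_freq.to_numpy())) + 2
        raise ValidationError(
            f"{path}: allele_freq outside (0, 0.5], line {row}"
        )
    bad_cat = ~df["category"].isin(("missense", "synonymous", "regulatory"))
    if bad_cat.any():
        row = int(np.argmax(bad_cat.to_numpy())) + 2
        raise ValidationError(f"{path}: unknown category, line {row}")
    return df


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[list(SNP_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_recomb_map(path) -> list[RecombWindow]:
    """Read a BED4-like windowed recombination map (0-based half-open)."""
    df = _read_tsv(path, MAP_COLUMNS)
    _require_numeric(df, ("start", "end", "rate_cM_per_Mb"), path)
    windows = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.rate_cM_per_Mb < 0:
            raise ValidationError(
                f"{path}: negative recombination rate, line {i + 2}"
            )
        windows.append(
            RecombWindow(row.chrom, int(row.start), int(row.end),
                         float(row.rate_cM_per_Mb))
        )
    _check_sorted_disjoint(windows, path)
    return windows


def _check_sorted_disjoint(windows: list[RecombWindow], path) -> None:
    by_chrom: dict[str, list[RecombWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        for a, b in zip(ws, ws[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{path}: windows on {chrom} overlapping or unsorted near "
                    f"{a.chrom}:{a.start}-{a.end}"
                )


def write_recomb_map(windows: list[RecombWindow], path) -> None:
    pd.DataFrame(
        [(w.chrom, w.start, w.end, w.rate) for w in windows],
        columns=MAP_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_bed(path) -> pd.DataFrame:
    """Read BED-like gene intervals (chrom, start, end, gene_id)."""
    df = _read_tsv(path, GENE_COLUMNS)
    _require_numeric(df, ("start", "end"), path)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: gene interval with start >= end")
    return df


def write_gene_bed(df: pd.DataFrame, path) -> None:
    df[list(GENE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_paralog_pairs(path) -> list[tuple[str, str, int]]:
    df = _read_tsv(path, PAIR_COLUMNS)
    _require_numeric(df, ("diopt_score",), path)
    return [
        (str(r.gene_a), str(r.gene_b), int(r.diopt_score))
        for r in df.itertuples(index=False)
    ]


def write_paralog_pairs(pairs, path) -> None:
    pd.DataFrame(pairs, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_liftover_map(path) -> LiftoverMap:
    df = _read_tsv(path, LIFTOVER_COLUMNS)
    _require_numeric(df, ("src_start", "src_end", "tgt_start"), path)
    blocks = [
        LiftoverBlock(
            str(r.src_chrom), int(r.src_start), int(r.src_end),
            str(r.tgt_chrom), int(r.tgt_start), str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]
    return LiftoverMap(blocks)


def write_liftover_map(lmap: LiftoverMap, path) -> None:
    rows = [
        (b.src_chrom, b.src_start, b.src_end, b.tgt_chrom, b.tgt_start, b.strand)
        for blist in lmap.blocks.values()
        for b in blist
    ]
    pd.DataFrame(rows, columns=LIFTOVER_COLUMNS).to_csv(path, sep="\t", index=False)


def write_test_results(rows: list[dict], path) -> None:
    """Write test outcomes as TSV (analysis, method, statistic, df, p_raw, p_adjusted)."""
    cols = ("analysis", "method", "statistic", "df", "p_raw", "p_adjusted")
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = None
    df[list(cols)].to_csv(path, sep="\t", index=False)
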