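"""Conflict-intensity tertiles and the nonparametric test battery.

Gene-level pooling of the sexual antagonism index, assignment of recombination
rates from a windowed cM/Mb map, coordinate liftover between assembly
releases, tertile formation, and the tests used to compare recombination rate
across conflict-intensity groups: the Brown–Mood k-sample median test, its
signed two-sample normal-approximation form, Levene's dispersion test and
Bonferroni-adjusted post-hoc pairwise median tests.

Coordinate conventions: recombination windows and liftover blocks are BED
style, 0-based half-open; SNP and gene positions arriving from tables are
1-based and converted exactly once at the I/O boundary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "RecombWindow",
    "GeneConflict",
    "TestResult",
    "LiftoverMap",
    "liftover",
    "pool_gene_sai",
    "assign_recomb_rate",
    "assign_tertiles",
    "moods_median_test",
    "two_sample_median_z",
    "levenes_test",
    "pairwise_posthoc_median",
]

TERTILE_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class RecombWindow:
    """A genomic window carrying a recombination rate in cM/Mb."""

    chrom: str
    start: int  # 0-based, half-open
    end: int
    rate: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"window {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.rate < 0:
            raise ValidationError(
                f"negative recombination rate in window "
                f"{self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class GeneConflict:
    """Per-gene pooled conflict intensity with genomic context."""

    gene_id: str
    chrom: str
    start: int
    end: int
    mean_sai: float
    n_snps: int = 0
    recomb_rate: float | None = None
    tertile: str | None = None


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    df: int | tuple | None
    p_value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LiftoverBlock:
    src_chrom: str
    src_start: int  # 0-based half-open
    src_end: int
    tgt_chrom: str
    tgt_start: int
    strand: str = "+"


class LiftoverMap:
    """Affine per-block coordinate map between two assembly releases.

    Blocks map source intervals (0-based half-open) onto target intervals of
    the same length; within a block the map is affine and order-preserving
    (reversed for '-' strand).  Source intervals must not overlap.
    """

    def __init__(self, blocks: Iterable[LiftoverBlock]):
        self.blocks: dict[str, list[LiftoverBlock]] = {}
        for b in blocks:
            self.blocks.setdefault(b.src_chrom, []).append(b)
        for chrom, blist in self.blocks.items():
            blist.sort(key=lambda b: b.src_start)
            for a, b in itertools.pairwise(blist):
                if b.src_start < a.src_end:
                    raise ValidationError(
                        f"overlapping liftover source blocks on {chrom}: "
                        f"[{a.src_start},{a.src_end}) and [{b.src_start},{b.src_end})"
                    )

    @classmethod
    def from_tuples(cls, rows) -> "LiftoverMap":
        return cls(LiftoverBlock(*row) for row in rows)

    def invert(self) -> "LiftoverMap":
        """The inverse map; round-trips every mapped position."""
        inv = []
        for blist in self.blocks.values():
            for b in blist:
                length = b.src_end - b.src_start
                inv.append(
                    LiftoverBlock(
                        b.tgt_chrom, b.tgt_start, b.tgt_start + length,
                        b.src_chrom, b.src_start, b.strand,
                    )
                )
        return LiftoverMap(inv)

    def map_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Map a 1-based position; ``None`` when no block covers it."""
        p0 = pos - 1
        for b in self.blocks.get(chrom, ()):
            if b.src_start <= p0 < b.src_end:
                offset = p0 - b.src_start
                if b.strand == "-":
                    offset = (b.src_end - b.src_start - 1) - offset
                return b.tgt_chrom, b.tgt_start + offset + 1
            if b.src_start > p0:
                break
        return None


def liftover(chrom: str, pos: int, lmap: LiftoverMap) -> tuple[str, int] | None:
    """Lift a single 1-based position through ``lmap`` (None if unmapped)."""
    return lmap.map_position(chrom, pos)


def liftover_frame(df: pd.DataFrame, lmap: LiftoverMap) -> tuple[pd.DataFrame, int]:
    """Lift a table with ``chrom``/``pos`` columns; drops unmapped rows.

    Returns the lifted table and the count of unmapped rows (never silently
    discarded: callers record the count in the run manifest).
    """
    mapped = [lmap.map_position(c, p) for c, p in zip(df["chrom"], df["pos"])]
    keep = [m is not None for m in mapped]
    out = df.loc[keep].copy()
    out["chrom"] = [m[0] for m in mapped if m is not None]
    out["pos"] = [m[1] for m in mapped if m is not None]
    return out, int(len(df) - len(out))


# ---------------------------------------------------------------------------
# Gene-level pooling and recombination-rate assignment
# ---------------------------------------------------------------------------


def pool_gene_sai(
    snps: pd.DataFrame,
    gene_intervals: pd.DataFrame | None = None,
    category: str | None = None,
) -> list[GeneConflict]:
    """Pool per-SNP SAI to a mean per gene.

    ``snps`` must carry ``gene_id`` and ``sai`` columns (see
    ``annotate_snp_frame``); optionally restrict to one functional
    ``category`` first (the windowed recombination maps have limited
    resolution, so conflict intensity is aggregated per gene).  Genes with no
    qualifying SNP are absent from the output.  ``gene_intervals`` supplies
    BED-style gene spans (chrom, start, end, gene_id); without it the SNP
    positions bound each gene.
    """
    df = snps
    if category is not None and category != "all":
        df = df[df["category"] == category]
    spans: dict[str, tuple[str, int, int]] = {}
    if gene_intervals is not None:
        for row in gene_intervals.itertuples(index=False):
            spans[row.gene_id] = (row.chrom, int(row.start), int(row.end))
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        if gene_id in spans:
            chrom, start, end = spans[gene_id]
        else:
            chrom = sub["chrom"].iloc[0]
            start = int(sub["pos"].min()) - 1
            end = int(sub["pos"].max())
        out.append(
            GeneConflict(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                mean_sai=float(sub["sai"].mean()),
                n_snps=len(sub),
            )
        )
    return out


def assign_recomb_rate(
    chrom: str,
    start: int,
    end: int,
    windows: Sequence[RecombWindow],
) -> float | None:
    """Length-weighted mean rate of map windows overlapping [start, end).

    A gene contained in a single window inherits that window's rate; a gene
    overlapping no window yields ``None`` (callers count missing rates).
    Splitting a window into contiguous equal-rate sub-windows leaves the
    result unchanged.
    """
    if start >= end:
        raise ValidationError(f"empty interval {chrom}:{start}-{end}")
    total = 0.0
    weighted = 0.0
    for w in windows:
        if w.chrom != chrom:
            continue
        ov = min(end, w.end) - max(start, w.start)
        if ov > 0:
            total += ov
            weighted += ov * w.rate
    if total == 0:
        return None
    return weighted / total


def assign_rates_to_genes(
    genes: list[GeneConflict], windows: Sequence[RecombWindow]
) -> tuple[list[GeneConflict], int]:
    """Assign length-weighted mean rates in place.

    Returns (genes with a rate, count of genes overlapping no window).
    Equivalent to per-gene :func:`assign_recomb_rate` but uses a binary
    search over the sorted per-chromosome windows.
    """
    by_chrom: dict[str, list[RecombWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    arrays = {}
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.start)
        arrays[chrom] = (
            np.array([w.start for w in ws]),
            np.array([w.end for w in ws]),
            np.array([w.rate for w in ws]),
        )
    kept = []
    missing = 0
    for g in genes:
        if g.chrom not in arrays:
            missing += 1
            continue
        starts, ends, rates = arrays[g.chrom]
        lo = int(np.searchsorted(ends, g.start, side="right"))
        hi = int(np.searchsorted(starts, g.end, side="left"))
        if lo >= hi:
            missing += 1
            continue
        ov = np.minimum(g.end, ends[lo:hi]) - np.maximum(g.start, starts[lo:hi])
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total == 0:
            missing += 1
            continue
        g.recomb_rate = float((ov * rates[lo:hi]).sum() / total)
        kept.append(g)
    return kept, missing


# ---------------------------------------------------------------------------
# Tertiles
# ---------------------------------------------------------------------------


def assign_tertiles(values, ids=None) -> list[str]:
    """Split conflict-index values into low/medium/high intensity tertiles.

    More-negative SAI means stronger conflict, so the most negative third is
    labelled ``high`` (intensity).  Group sizes differ by at most one; when
    n is not divisible by 3 the extra members go to the higher-intensity
    groups first.  Ties are broken by the accompanying identifier (or input
    order), making membership deterministic under permutation of the input.
    """
    values = list(values)
    n = len(values)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 values for tertiles, got {n}")
    if ids is None:
        ids = list(range(n))
    order = sorted(range(n), key=lambda i: (values[i], ids[i]))  # most negative first
    base, rem = divmod(n, 3)
    size_high = base + (1 if rem >= 1 else 0)
    size_medium = base + (1 if rem >= 2 else 0)
    labels = [""] * n
    for rank, i in enumerate(order):
        if rank < size_high:
            labels[i] = "high"
        elif rank < size_high + size_medium:
            labels[i] = "medium"
        else:
            labels[i] = "low"
    return labels


def assign_tertiles_to_genes(genes: list[GeneConflict]) -> list[GeneConflict]:
    labels = assign_tertiles([g.mean_sai for g in genes], [g.gene_id for g in genes])
    for g, lab in zip(genes, labels):
        g.tertile = lab
    return genes


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


def _median_table(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, float]:
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError(
            "all pooled observations identical: median test undefined"
        )
    grand = float(np.median(pooled))
    above = np.array([np.sum(g > grand) for g in groups], dtype=float)
    at_or_below = np.array([np.sum(g <= grand) for g in groups], dtype=float)
    return np.vstack([above, at_or_below]), grand


def _pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Uncorrected Pearson chi-square on a 2 x k contingency table."""
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = rowsum * colsum / total
    if np.any(expected == 0):
        raise DegenerateDataError("zero expected count in median-test table")
    stat = float(np.sum((table - expected) ** 2 / expected))
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def moods_median_test(
    groups: Sequence, *, continuity_correction: bool = False
) -> TestResult:
    """Brown–Mood k-sample median test.

    Counts observations strictly above vs at-or-below the pooled grand
    median per group and applies an uncorrected Pearson chi-square with
    df = k - 1 to the resulting 2 x k table.  Ties with the grand median are
    counted in the at-or-below row.  The statistic depends only on each
    observation's position relative to the pooled median, so it is invariant
    under any strictly increasing transformation of the data.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("median test needs at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValidationError(f"group {i} is empty")
    table, grand = _median_table(arrays)
    if continuity_correction and table.shape[1] == 2:
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        total = table.sum()
        expected = rowsum * colsum / total
        adj = np.maximum(np.abs(table - expected) - 0.5, 0.0)
        stat = float(np.sum(adj**2 / expected))
        df = 1
    else:
        stat, df = _pearson_chi2(table)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        method="brown-mood median",
        statistic=stat,
        df=df,
        p_value=p,
        extra={"grand_median": grand, "table": table.tolist()},
    )


def two_sample_median_z(a, b) -> TestResult:
    """Signed two-sample Brown–Mood median test (normal approximation).

    From the 2 x 2 table of (above, at-or-below) the pooled grand median,
    the count of group-a observations above the median is compared with its
    hypergeometric expectation; Z = (observed - E) / sqrt(Var) with the
    finite-population hypergeometric variance, p two-sided.  Z > 0 means
    group a tends to exceed the pooled median more often than expected.
    Z^2 equals the uncorrected 2 x 2 chi-square times (N - 1)/N.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    table, grand = _median_table([a, b])
    m_above = table[0].sum()  # total above the grand median
    n_tot = table.sum()
    n_a = a.size
    observed = table[0, 0]
    expected = n_a * m_above / n_tot
    var = (
        n_a * b.size * m_above * (n_tot - m_above) / (n_tot**2 * (n_tot - 1))
    )
    if var == 0:
        raise DegenerateDataError("zero variance in median table")
    z = float((observed - expected) / math.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(
        method="brown-mood two-sample Z",
        statistic=z,
        df=None,
        p_value=p,
        extra={"grand_median": grand, "table": table.tolist()},
    )


def levenes_test(groups: Sequence, *, center: str = "mean") -> TestResult:
    """Levene's test for homogeneity of dispersion across k groups.

    One-way ANOVA F on absolute deviations from each group's center
    (``mean`` = classic Levene, default; ``median`` = Brown–Forsythe),
    df = (k - 1, N - k).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("Levene's test needs at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 members")
    if center not in ("mean", "median"):
        raise ValidationError("center must be 'mean' or 'median'")
    stat, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    n_tot = sum(a.size for a in arrays)
    return TestResult(
        method=f"levene ({center}-centered)",
        statistic=float(stat),
        df=(k - 1, n_tot - k),
        p_value=float(p),
    )


def pairwise_posthoc_median(
    groups: Sequence, labels: Sequence[str] | None = None
) -> list[TestResult]:
    """Post-hoc pairwise Brown–Mood median tests with Bonferroni adjustment.

    Each unordered pair is tested with its own pooled grand median; raw and
    Bonferroni-adjusted p-values are both reported.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValidationError("post-hoc testing expects at least 3 groups")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        res = moods_median_test([arrays[i], arrays[j]])
        out.append(
            TestResult(
                method=f"brown-mood median ({labels[i]} vs {labels[j]})",
                statistic=res.statistic,
                df=res.df,
                p_value=res.p_value,
                extra={
                    "pair": (labels[i], labels[j]),
                    "p_adjusted": min(1.0, res.p_value * m),
                    **res.extra,
                },
            )
        )
    return out
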