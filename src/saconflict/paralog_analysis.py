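"""Paralogue-family construction and the gene-duplication test battery.

A gene pair with a DIOPT score of at least 1 (i.e. supported by at least one
bioinformatic homology tool) counts as a paralogue pair.  Families are the
connected components of the resulting graph over the gene universe; a gene's
paralogue count is its number of distinct direct qualifying partners (a
``family_size - 1`` alternative is available, since a chain A-B-C gives B two
partners but A and C one each).

Tests: per-tertile 2x2 chi-square of with/without-paralogue proportions
against a genome-wide background, and Wilcoxon rank-sum comparisons of
paralogue counts between tertiles and of recombination rates between genes
with and without paralogues.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .recomb_assoc import TestResult

__all__ = [
    "ParalogPair",
    "ParalogFamily",
    "build_paralog_families",
    "proportion_with_paralogs_test",
    "wilcoxon_rank_sum",
    "paralog_count_tertile_tests",
]

#: Sample-size bound below which the rank-sum p-value is computed by exact
#: enumeration (requires no ties); above it, normal approximation with
#: midranks and tie correction.
EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class ParalogPair:
    """Unordered scored gene pair; canonicalised so gene_a < gene_b."""

    gene_a: str
    gene_b: str
    diopt_score: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair for gene {self.gene_a}")
        if self.diopt_score < 0:
            raise ValidationError("DIOPT score must be >= 0")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @staticmethod
    def make(a: str, b: str, score: int) -> "ParalogPair":
        lo, hi = sorted((a, b))
        return ParalogPair(lo, hi, score)


@dataclass(frozen=True)
class ParalogFamily:
    family_id: str
    members: frozenset


def build_paralog_families(
    pairs,
    gene_universe=None,
    min_score: int = 1,
    *,
    count_mode: str = "partners",
) -> tuple[list[ParalogFamily], dict[str, int]]:
    """Assign genes to paralogue families and count each gene's paralogues.

    Families are connected components of the graph on ``gene_universe`` whose
    edges are pairs with ``diopt_score >= min_score``; genes in no qualifying
    pair are singleton families.  ``count_mode='partners'`` (default) counts
    distinct direct qualifying partners; ``'family'`` counts family size - 1.

    Returns (families sorted by smallest member, per-gene count dict); the
    family sizes always sum to the universe size.

    Raises
    ------
    ValidationError
        On a self-pair or a duplicate canonical pair with conflicting scores.
    """
    if min_score < 1:
        raise ValidationError("min_score must be >= 1")
    if count_mode not in ("partners", "family"):
        raise ValidationError("count_mode must be 'partners' or 'family'")
    canonical: dict[tuple[str, str], int] = {}
    for p in pairs:
        if not isinstance(p, ParalogPair):
            p = ParalogPair.make(*p)
        key = (p.gene_a, p.gene_b)
        if key in canonical and canonical[key] != p.diopt_score:
            raise ValidationError(
                f"duplicate pair {key} with conflicting scores "
                f"{canonical[key]} and {p.diopt_score}"
            )
        canonical[key] = p.diopt_score

    universe = set(gene_universe) if gene_universe is not None else set()
    universe.update(g for key in canonical for g in key)

    graph = nx.Graph()
    graph.add_nodes_from(universe)
    graph.add_edges_from(
        key for key, score in canonical.items() if score >= min_score
    )

    families = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        families.append(ParalogFamily(family_id=f"FAM_{min(members)}", members=members))
    families.sort(key=lambda f: f.family_id)

    if count_mode == "partners":
        counts = {g: graph.degree(g) for g in universe}
    else:
        counts = {}
        for f in families:
            for g in f.members:
                counts[g] = len(f.members) - 1
    return families, counts


def _chi2_2x2(table: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Uncorrected Pearson chi-square on a 2x2 table (df = 1)."""
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        raise DegenerateDataError("empty 2x2 table")
    expected = rowsum * colsum / total
    if np.any(expected == 0):
        raise DegenerateDataError("zero expected count in 2x2 table")
    stat = float(np.sum((table - expected) ** 2 / expected))
    return stat, float(stats.chi2.sf(stat, 1)), expected


def proportion_with_paralogs_test(
    tertile_counts: dict[str, tuple[int, int]],
    background_with: int,
    background_without: int,
    *,
    continuity_correction: bool = False,
) -> dict[str, TestResult]:
    """Per-tertile 2x2 chi-square of with/without-paralogue proportions.

    ``tertile_counts`` maps tertile label -> (n_with, n_without); each
    tertile is compared against the genome-wide background counts with an
    uncorrected Pearson chi-square on the 2x2 table (df = 1).  A result
    gains ``extra['low_expected']`` when any expected cell falls below 1.
    """
    if background_with <= 0 or background_without <= 0:
        raise ValidationError("background counts must be positive")
    out = {}
    for tertile, (n_with, n_without) in tertile_counts.items():
        if n_with + n_without == 0:
            raise ValidationError(f"tertile {tertile!r} is empty")
        table = np.array(
            [[n_with, n_without], [background_with, background_without]],
            dtype=float,
        )
        if continuity_correction:
            res = stats.chi2_contingency(table, correction=True)
            stat, p = float(res.statistic), float(res.pvalue)
            expected = res.expected_freq
        else:
            stat, p, expected = _chi2_2x2(table)
        out[tertile] = TestResult(
            method="chi-square (proportion with paralogues)",
            statistic=stat,
            df=1,
            p_value=p,
            extra={
                "proportion": n_with / (n_with + n_without),
                "background_proportion": background_with
                / (background_with + background_without),
                "low_expected": bool(np.any(expected < 1)),
            },
        )
    return out


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``statistic`` is the rank-sum W of the first sample using midranks for
    ties; ``extra['u_statistic']`` carries the equivalent Mann–Whitney U of
    the first sample (W - n1(n1+1)/2), the convention R's ``wilcox.test``
    prints.  The p-value is exact (full enumeration) when both samples have
    at most 25 observations and there are no ties, otherwise a normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    small = x.size <= EXACT_THRESHOLD and y.size <= EXACT_THRESHOLD
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    u1 = float(res.statistic)
    w = u1 + x.size * (x.size + 1) / 2.0
    return TestResult(
        method=f"wilcoxon rank-sum ({method})",
        statistic=w,
        df=None,
        p_value=float(res.pvalue),
        extra={"u_statistic": u1, "n_x": int(x.size), "n_y": int(y.size)},
    )


def paralog_count_tertile_tests(
    counts_by_tertile: dict[str, list],
    *,
    restrict_to_positive: bool = True,
) -> dict[tuple[str, str], TestResult | str]:
    """Pairwise Wilcoxon rank-sum tests of paralogue counts between tertiles.

    With ``restrict_to_positive`` (the default, matching the convention of
    excluding genes without paralogues from the count comparison) zero
    counts are filtered out first.  A tertile emptied by the filter yields
    the marker string ``"skipped"`` for its pairs instead of a test.
    """
    if len(counts_by_tertile) != 3:
        raise ValidationError("expected exactly three tertile groups")
    filtered = {}
    for tert, counts in counts_by_tertile.items():
        arr = np.asarray(counts, dtype=float)
        if restrict_to_positive:
            arr = arr[arr > 0]
        filtered[tert] = arr
    out: dict[tuple[str, str], TestResult | str] = {}
    for a, b in itertools.combinations(sorted(filtered), 2):
        if filtered[a].size == 0 or filtered[b].size == 0:
            out[(a, b)] = "skipped"
            continue
        out[(a, b)] = wilcoxon_rank_sum(filtered[a], filtered[b])
    return out
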