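"""End-to-end orchestration: the :class:`ConflictStudy` model object.

``ConflictStudy`` bundles the three analyses into one fitted object:

1. allele-frequency regressions on the cross-sex effect-size ratio (pooled,
   category interaction, stratified);
2. recombination rate across conflict-intensity tertiles (Brown–Mood median
   test, Levene's dispersion test, post-hoc pairwise median tests; repeated
   per functional category);
3. paralogue enrichment (per-tertile with/without-paralogue chi-square
   against a background panel, rank-sum tests of paralogue counts between
   tertiles, and recombination rate of genes with vs without paralogues).

``run_pipeline`` drives the study from a :class:`PipelineConfig` (real input
files or the synthetic generator), writes the report bundle atomically and
returns it.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .effect_stats import annotate_snp_frame
from .errors import DegenerateDataError, ValidationError
from .freq_models import FrequencyRatioModel
from .paralog_analysis import (
    build_paralog_families,
    paralog_count_tertile_tests,
    proportion_with_paralogs_test,
    wilcoxon_rank_sum,
)
from .recomb_assoc import (
    TERTILE_LABELS,
    assign_rates_to_genes,
    assign_tertiles_to_genes,
    levenes_test,
    liftover_frame,
    moods_median_test,
    pairwise_posthoc_median,
    pool_gene_sai,
    two_sample_median_z,
)
from .synthetic_data import SyntheticConfig, generate_all

__all__ = ["ConflictStudy", "ConflictStudyResults", "PipelineConfig", "run_pipeline"]


class ConflictStudy:
    """The full conflict-intensity study, statsmodels-style.

    Parameters
    ----------
    snps : DataFrame
        Candidate-SA SNP table (see :data:`saconflict.io.SNP_COLUMNS`).
    windows : list of RecombWindow, optional
        Windowed recombination map.
    genes : DataFrame, optional
        BED-style gene intervals; without it gene spans are bounded by their
        SNPs.
    pairs : list of (gene_a, gene_b, diopt_score), optional
        Scored paralogue pairs.
    liftover_map : LiftoverMap, optional
        Applied to SNP coordinates before any map overlap.
    background : (int, int), optional
        Genome-wide (with-paralogue, without-paralogue) gene counts for the
        per-tertile proportion chi-square; defaults to the analysis set's own
        totals when absent.
    granularity : {"gene", "snp"}
        Unit of the recombination analysis: pooled mean SAI per gene
        (default) or each SNP individually.
    pool_category : str
        Functional category pooled for gene-level conflict intensity
        ("missense" by default; "all" disables the filter).
    species : array-like, optional
        Per-SNP species labels; with exactly two labels a two-group SAI
        comparison (median Z + Levene) is added.
    """

    def __init__(
        self,
        snps: pd.DataFrame,
        windows=None,
        genes: pd.DataFrame | None = None,
        pairs=None,
        liftover_map=None,
        background: tuple[int, int] | None = None,
        *,
        granularity: str = "gene",
        pool_category: str = "missense",
        exclude_zero_paralogs: bool = True,
        species=None,
    ):
        if granularity not in ("gene", "snp"):
            raise ValidationError("granularity must be 'gene' or 'snp'")
        self.snps = snps
        self.windows = windows
        self.genes = genes
        self.pairs = list(pairs) if pairs is not None else None
        self.liftover_map = liftover_map
        self.background = background
        self.granularity = granularity
        self.pool_category = pool_category
        self.exclude_zero_paralogs = exclude_zero_paralogs
        self.species = None if species is None else np.asarray(species)

    @classmethod
    def from_synthetic(cls, cfg: SyntheticConfig, **kwargs) -> "ConflictStudy":
        data = generate_all(cfg)
        study = cls(
            data["snps"], data["windows"], data["genes"], data["pairs"], **kwargs
        )
        study.synthetic_truth = data["truth"]
        return study

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "ConflictStudyResults":
        manifest: dict = {"n_snps_in": int(len(self.snps))}
        annotated = annotate_snp_frame(self.snps)
        manifest["n_sa"] = int(annotated["is_sa"].sum())
        manifest["n_non_sa"] = int((~annotated["is_sa"]).sum())

        freq_results = FrequencyRatioModel.from_dataframe(annotated).fit()

        working = annotated
        if self.liftover_map is not None:
            working, unmapped = liftover_frame(working, self.liftover_map)
            manifest["n_unmapped"] = unmapped
        else:
            manifest["n_unmapped"] = 0

        recomb = self._recomb_analyses(working, manifest)
        paralogs = self._paralog_analyses(recomb.get("conflicts"), manifest)
        species_cmp = self._species_comparison(annotated)

        return ConflictStudyResults(
            self, freq_results, recomb, paralogs, species_cmp, manifest
        )

    def _units(self, working: pd.DataFrame, category: str | None):
        """Analysis units: pooled genes or individual SNPs."""
        if self.granularity == "gene":
            return pool_gene_sai(working, self.genes, category=category)
        df = working
        if category is not None and category != "all":
            df = df[df["category"] == category]
        from .recomb_assoc import GeneConflict

        return [
            GeneConflict(
                gene_id=str(r.snp_id), chrom=r.chrom,
                start=int(r.pos) - 1, end=int(r.pos),
                mean_sai=float(r.sai), n_snps=1,
            )
            for r in df.itertuples(index=False)
        ]

    def _tertile_battery(self, conflicts) -> dict:
        """Median/dispersion tests of recombination rate across tertiles."""
        assign_tertiles_to_genes(conflicts)
        groups = {
            t: np.array([g.recomb_rate for g in conflicts if g.tertile == t])
            for t in TERTILE_LABELS
        }
        ordered = [groups[t] for t in TERTILE_LABELS]
        out: dict = {"groups": groups, "conflicts": conflicts}
        try:
            out["median_test"] = moods_median_test(ordered)
            out["posthoc"] = pairwise_posthoc_median(ordered, TERTILE_LABELS)
        except (DegenerateDataError, ValidationError) as exc:
            out["median_test"] = f"skipped: {exc}"
        try:
            out["levene"] = levenes_test(ordered)
        except (ValidationError,) as exc:
            out["levene"] = f"skipped: {exc}"
        return out

    def _recomb_analyses(self, working: pd.DataFrame, manifest: dict) -> dict:
        if self.windows is None:
            return {}
        conflicts = self._units(working, self.pool_category)
        conflicts, missing = assign_rates_to_genes(conflicts, self.windows)
        manifest["n_units_pooled"] = len(conflicts)
        manifest["n_units_missing_rate"] = missing
        out: dict = {}
        if len(conflicts) >= 3:
            out = self._tertile_battery(conflicts)
        out["per_category"] = {}
        for cat in ("missense", "synonymous", "regulatory"):
            units = self._units(working, cat)
            units, _ = assign_rates_to_genes(units, self.windows)
            if len(units) >= 6:
                out["per_category"][cat] = self._tertile_battery(units)
            else:
                out["per_category"][cat] = "skipped: too few units"
        return out

    def _paralog_analyses(self, conflicts, manifest: dict) -> dict:
        if self.pairs is None or not conflicts:
            return {}
        conflict_ids = [g.gene_id for g in conflicts]
        universe = set(conflict_ids) | {
            g for p in self.pairs for g in (p[0], p[1])
        }
        families, counts = build_paralog_families(self.pairs, universe)
        manifest["n_families"] = len(families)
        manifest["n_genes_universe"] = len(universe)

        by_tertile: dict[str, tuple[int, int]] = {}
        counts_by_tertile: dict[str, list[int]] = {t: [] for t in TERTILE_LABELS}
        for g in conflicts:
            c = counts.get(g.gene_id, 0)
            n_with, n_without = by_tertile.get(g.tertile, (0, 0))
            if c > 0:
                n_with += 1
            else:
                n_without += 1
            by_tertile[g.tertile] = (n_with, n_without)
            counts_by_tertile[g.tertile].append(c)

        if self.background is not None:
            bg_with, bg_without = self.background
        else:
            # Default background: the analysis set itself (the partner genes
            # introduced by the pair list all have a paralogue by
            # construction and would bias a universe-wide background).
            bg_with = sum(1 for g in conflict_ids if counts.get(g, 0) > 0)
            bg_without = len(conflict_ids) - bg_with

        out: dict = {
            "families": families,
            "counts": counts,
            "by_tertile": by_tertile,
            "background": (bg_with, bg_without),
        }
        try:
            out["proportion_tests"] = proportion_with_paralogs_test(
                by_tertile, bg_with, bg_without
            )
        except (ValidationError, DegenerateDataError) as exc:
            out["proportion_tests"] = f"skipped: {exc}"
        out["count_tests"] = paralog_count_tertile_tests(
            counts_by_tertile, restrict_to_positive=self.exclude_zero_paralogs
        )
        rates_with = [
            g.recomb_rate for g in conflicts if counts.get(g.gene_id, 0) > 0
        ]
        rates_without = [
            g.recomb_rate for g in conflicts if counts.get(g.gene_id, 0) == 0
        ]
        if rates_with and rates_without:
            out["recomb_with_vs_without"] = wilcoxon_rank_sum(
                rates_with, rates_without
            )
        return out

    def _species_comparison(self, annotated: pd.DataFrame):
        if self.species is None:
            return None
        labels = pd.unique(self.species)
        if len(labels) != 2:
            return None
        a = annotated.loc[self.species == labels[0], "sai"].to_numpy()
        b = annotated.loc[self.species == labels[1], "sai"].to_numpy()
        return {
            "labels": (str(labels[0]), str(labels[1])),
            "median_z": two_sample_median_z(a, b),
            "levene": levenes_test([a, b]),
        }


class ConflictStudyResults:
    """Fitted results of a :class:`ConflictStudy`.

    Attributes
    ----------
    freq : FrequencyRatioResults
    recomb : dict
        Tertile battery (``median_test``, ``levene``, ``posthoc``,
        ``per_category``, ``conflicts``).
    paralogs : dict
        Families, counts, per-tertile proportion chi-squares, pairwise
        count rank-sum tests, with-vs-without recombination comparison.
    species : dict or None
    manifest : dict
        Record accounting: every input row is kept, filtered or unmapped.
    """

    def __init__(self, model, freq, recomb, paralogs, species, manifest):
        self.model = model
        self.freq = freq
        self.recomb = recomb
        self.paralogs = paralogs
        self.species = species
        self.manifest = manifest

    # -- tabular export ---------------------------------------------------

    def regression_table(self) -> pd.DataFrame:
        return self.freq.table()

    def recomb_table(self) -> pd.DataFrame:
        rows = []

        def add(analysis, res):
            if isinstance(res, str) or res is None:
                return
            rows.append(
                {
                    "analysis": analysis,
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": str(res.df),
                    "p_raw": res.p_value,
                    "p_adjusted": res.extra.get("p_adjusted", ""),
                }
            )

        add("all_tertiles", self.recomb.get("median_test"))
        add("all_tertiles", self.recomb.get("levene"))
        for res in self.recomb.get("posthoc", []):
            add("posthoc", res)
        for cat, battery in self.recomb.get("per_category", {}).items():
            if isinstance(battery, str):
                continue
            add(f"category:{cat}", battery.get("median_test"))
            add(f"category:{cat}", battery.get("levene"))
            for res in battery.get("posthoc", []):
                add(f"category:{cat}:posthoc", res)
        if self.species is not None:
            add("species", self.species["median_z"])
            add("species", self.species["levene"])
        return pd.DataFrame(
            rows,
            columns=["analysis", "method", "statistic", "df", "p_raw", "p_adjusted"],
        )

    def paralog_table(self) -> pd.DataFrame:
        rows = []
        props = self.paralogs.get("proportion_tests")
        if isinstance(props, dict):
            for tert in TERTILE_LABELS:
                if tert not in props:
                    continue
                res = props[tert]
                rows.append(
                    {
                        "analysis": f"proportion:{tert}",
                        "method": res.method,
                        "statistic": res.statistic,
                        "df": str(res.df),
                        "p_raw": res.p_value,
                        "p_adjusted": "",
                        "proportion": res.extra["proportion"],
                    }
                )
        for pair, res in self.paralogs.get("count_tests", {}).items():
            if res == "skipped":
                continue
            rows.append(
                {
                    "analysis": f"counts:{pair[0]}-vs-{pair[1]}",
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": "",
                    "p_raw": res.p_value,
                    "p_adjusted": "",
                    "proportion": "",
                }
            )
        rvw = self.paralogs.get("recomb_with_vs_without")
        if rvw is not None:
            rows.append(
                {
                    "analysis": "recomb:with-vs-without",
                    "method": rvw.method,
                    "statistic": rvw.statistic,
                    "df": "",
                    "p_raw": rvw.p_value,
                    "p_adjusted": "",
                    "proportion": "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["analysis", "method", "statistic", "df", "p_raw",
                     "p_adjusted", "proportion"],
        )

    def gene_table(self) -> pd.DataFrame:
        conflicts = self.recomb.get("conflicts", [])
        counts = self.paralogs.get("counts", {})
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "mean_sai": g.mean_sai,
                    "n_snps": g.n_snps,
                    "recomb_rate": g.recomb_rate,
                    "tertile": g.tertile,
                    "n_paralogs": counts.get(g.gene_id, 0),
                }
                for g in conflicts
            ]
        )

    def summary(self) -> str:
        lines = [self.freq.summary(), ""]
        med = self.recomb.get("median_test")
        if med is not None and not isinstance(med, str):
            lines.append(
                "Recombination rate across conflict tertiles: "
                f"chi2 = {med.statistic:.3f}, df = {med.df}, p = {med.p_value:.3g}"
            )
        lev = self.recomb.get("levene")
        if lev is not None and not isinstance(lev, str):
            lines.append(
                f"Dispersion (Levene): F = {lev.statistic:.4f}, "
                f"df = {lev.df}, p = {lev.p_value:.4g}"
            )
        props = self.paralogs.get("proportion_tests")
        if isinstance(props, dict):
            for tert in TERTILE_LABELS:
                if tert in props:
                    r = props[tert]
                    lines.append(
                        f"Paralogue proportion ({tert}): "
                        f"{r.extra['proportion']:.3f}  chi2 = {r.statistic:.2f}, "
                        f"p = {r.p_value:.3g}"
                    )
        return "\n".join(lines)

    def plot_recomb(self, ax=None):
        """Diagnostic boxplot of recombination rate by conflict tertile;
        requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = self.recomb.get("groups", {})
        ax.boxplot([groups.get(t, []) for t in TERTILE_LABELS],
                   tick_labels=list(TERTILE_LABELS))
        ax.set_xlabel("conflict intensity tertile")
        ax.set_ylabel("recombination rate (cM/Mb)")
        return ax


# ---------------------------------------------------------------------------
# File-driven pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of (``synthetic=True``, real input paths) must be active.
    Switch defaults match the documented analysis conventions: gene-level
    granularity, missense pooling for conflict intensity, zero-paralogue
    exclusion in count comparisons, Bonferroni post-hoc adjustment, no
    continuity corrections.
    """

    out_dir: str | Path = "saconflict_out"
    seed: int = 0
    synthetic: bool = False
    synthetic_config: SyntheticConfig | None = None
    snp_table: str | None = None
    recomb_map: str | None = None
    gene_bed: str | None = None
    paralog_pairs: str | None = None
    liftover: str | None = None
    granularity: str = "gene"
    pool_category: str = "missense"
    exclude_zero_paralogs: bool = True
    adjust: str = "bonferroni"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synthetic == (self.snp_table is not None):
            raise ValidationError(
                "exactly one of synthetic mode or a real SNP table must be active"
            )
        if self.adjust not in ("bonferroni", "none"):
            raise ValidationError("adjust must be 'bonferroni' or 'none'")


def _build_study(cfg: PipelineConfig) -> ConflictStudy:
    kwargs = dict(
        granularity=cfg.granularity,
        pool_category=cfg.pool_category,
        exclude_zero_paralogs=cfg.exclude_zero_paralogs,
    )
    if cfg.synthetic:
        syn = cfg.synthetic_config or SyntheticConfig(seed=cfg.seed)
        syn = dataclasses.replace(syn, seed=cfg.seed)
        return ConflictStudy.from_synthetic(syn, **kwargs)
    snps = sio.read_snp_table(cfg.snp_table)
    windows = sio.read_recomb_map(cfg.recomb_map) if cfg.recomb_map else None
    genes = sio.read_gene_bed(cfg.gene_bed) if cfg.gene_bed else None
    pairs = sio.read_paralog_pairs(cfg.paralog_pairs) if cfg.paralog_pairs else None
    lmap = sio.read_liftover_map(cfg.liftover) if cfg.liftover else None
    return ConflictStudy(snps, windows, genes, pairs, lmap, **kwargs)


def run_pipeline(cfg: PipelineConfig) -> ConflictStudyResults:
    """Run the study and write the report bundle under ``cfg.out_dir``.

    Outputs: ``regression.tsv`` (Table-1-style), ``recomb_tests.tsv``,
    ``paralog_tests.tsv``, ``gene_conflicts.tsv`` and ``manifest.json``.
    Files are staged in a temporary directory and moved into place only
    after every analysis has succeeded, so failures never leave partial
    outputs behind.
    """
    study = _build_study(cfg)
    results = study.fit()

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(results.manifest)
    manifest["seed"] = cfg.seed
    from . import __version__

    manifest["saconflict_version"] = __version__
    manifest["granularity"] = cfg.granularity
    manifest["pool_category"] = cfg.pool_category

    with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
        tmp = Path(tmp)
        results.regression_table().to_csv(tmp / "regression.tsv", sep="\t", index=False)
        results.recomb_table().to_csv(tmp / "recomb_tests.tsv", sep="\t", index=False)
        results.paralog_table().to_csv(tmp / "paralog_tests.tsv", sep="\t", index=False)
        results.gene_table().to_csv(tmp / "gene_conflicts.tsv", sep="\t", index=False)
        (tmp / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        for name in ("regression.tsv", "recomb_tests.tsv", "paralog_tests.tsv",
                     "gene_conflicts.tsv", "manifest.json"):
            os.replace(tmp / name, out_dir / name)
    return results
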