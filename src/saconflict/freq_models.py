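"""Inverse-variance-weighted regressions of effect-allele frequency on the
cross-sex effect-size ratio.

Population-genetic theory predicts that SA alleles with net-beneficial
cross-sex effects (effect-size ratio < -1) segregate at higher frequencies
than net-deleterious ones, i.e. a negative slope of minor-allele frequency on
the ratio.  Three fits are provided, all Gaussian-identity weighted least
squares with inverse-variance weights:

* a pooled model ``freq ~ ratio``;
* a category-interaction model ``freq ~ ratio * category`` with nested-model
  F-tests for the category main effect and the category x ratio interaction;
* per-category stratified models.

``FrequencyRatioModel`` is the statsmodels-style entry point: build from a
DataFrame, call :meth:`~FrequencyRatioModel.fit`, read the results off the
returned :class:`FrequencyRatioResults`.  The functional wrappers
(:func:`fit_weighted_regression` etc.) operate on the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .recomb_assoc import TestResult

__all__ = [
    "RegressionResult",
    "InteractionResult",
    "FrequencyRatioModel",
    "FrequencyRatioResults",
    "fit_weighted_regression",
    "fit_interaction_model",
    "fit_stratified",
    "stratified_table",
]

#: Deterministic reference ordering for the category factor.
CATEGORY_ORDER = ("missense", "regulatory", "synonymous")


@dataclass(frozen=True)
class RegressionResult:
    """Weighted linear fit of allele frequency on effect-size ratio.

    ``deviance`` is the weighted residual sum of squares, ``df`` the residual
    degrees of freedom (n - p), ``rse`` = sqrt(deviance / df) the residual
    standard error, and ``p_value`` the two-sided t-test p-value of the slope.
    """

    slope: float
    slope_se: float
    intercept: float
    deviance: float
    df: int
    p_value: float
    rse: float
    n: int

    def __post_init__(self) -> None:
        assert self.df >= 1 and self.deviance >= -1e-12


@dataclass(frozen=True)
class InteractionResult:
    """Nested-model F-tests from the category-interaction model."""

    main_effect_test: TestResult
    interaction_test: TestResult
    full_deviance: float
    full_df: int


def _validate(ratio: np.ndarray, freq: np.ndarray, weight: np.ndarray) -> None:
    if len(ratio) < 3:
        raise InsufficientDataError(
            f"need at least 3 records to fit a slope, got {len(ratio)}"
        )
    if not np.all(weight > 0):
        raise ValidationError("all weights must be > 0")
    if not np.all(np.isfinite(ratio)):
        raise ValidationError("non-finite effect-size ratios in input")
    if np.ptp(ratio) == 0:
        raise ValidationError("zero variance in ratio: singular design")


def _wls_fit(ratio, freq, weight) -> RegressionResult:
    ratio = np.asarray(ratio, dtype=float)
    freq = np.asarray(freq, dtype=float)
    weight = np.asarray(weight, dtype=float)
    _validate(ratio, freq, weight)
    X = sm.add_constant(ratio)
    res = sm.WLS(freq, X, weights=weight).fit()
    deviance = float(np.sum(weight * res.resid**2))
    df = int(res.df_resid)
    rse = float(np.sqrt(deviance / df)) if df > 0 else float("nan")
    return RegressionResult(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        deviance=deviance,
        df=df,
        p_value=float(res.pvalues[1]),
        rse=rse,
        n=len(ratio),
    )


def _frame(records) -> pd.DataFrame:
    """Accept a DataFrame (ratio/allele_freq/weight[/category]) or records."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "ratio": [r.ratio for r in records],
            "allele_freq": [r.allele_freq for r in records],
            "weight": [r.weight for r in records],
            "category": [r.category for r in records],
        }
    )


def fit_weighted_regression(records) -> RegressionResult:
    """Pooled weighted fit ``allele_freq ~ 1 + ratio``.

    Gaussian family, identity link; weights are inverse variances and only
    their relative magnitudes matter.
    """
    df = _frame(records)
    return _wls_fit(df["ratio"], df["allele_freq"], df["weight"])


def _design(df: pd.DataFrame, *, interaction: bool, category: bool) -> np.ndarray:
    cats = [c for c in CATEGORY_ORDER if c in set(df["category"])]
    cols = [np.ones(len(df)), df["ratio"].to_numpy(float)]
    for c in cats[1:]:
        ind = (df["category"] == c).to_numpy(float)
        if category:
            cols.append(ind)
        if interaction:
            cols.append(ind * df["ratio"].to_numpy(float))
    return np.column_stack(cols)


def _wls_deviance(df: pd.DataFrame, X: np.ndarray) -> tuple[float, int]:
    w = df["weight"].to_numpy(float)
    res = sm.WLS(df["allele_freq"].to_numpy(float), X, weights=w).fit()
    return float(np.sum(w * res.resid**2)), int(res.df_resid)


def fit_interaction_model(records) -> InteractionResult:
    """Full model ``freq ~ ratio * category`` with nested deviance F-tests.

    The category main effect compares ``freq ~ ratio + category`` against
    ``freq ~ ratio``; the interaction compares the full model against
    ``freq ~ ratio + category``.  Each test is an F-test on the weighted
    deviance difference, scaled by the full model's residual deviance.
    """
    df = _frame(records)
    counts = df["category"].value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 categories for the interaction model")
    small = counts[counts < 3]
    if len(small):
        raise ValidationError(
            "categories with fewer than 3 records: " + ", ".join(small.index)
        )
    dev_full, df_full = _wls_deviance(df, _design(df, interaction=True, category=True))
    dev_add, df_add = _wls_deviance(df, _design(df, interaction=False, category=True))
    dev_base, df_base = _wls_deviance(
        df, _design(df, interaction=False, category=False)
    )

    def ftest(dev_reduced, df_reduced, dev_nested, df_nested, name) -> TestResult:
        q = df_reduced - df_nested
        scale = dev_full / df_full if df_full > 0 else float("nan")
        diff = max(dev_reduced - dev_nested, 0.0)
        stat = diff / q / scale if scale > 0 else 0.0
        p = float(stats.f.sf(stat, q, df_full)) if scale > 0 else 1.0
        return TestResult(
            method=f"F ({name})",
            statistic=float(stat),
            df=q,
            p_value=p,
            extra={"deviance_diff": float(diff), "df_denom": df_full},
        )

    return InteractionResult(
        main_effect_test=ftest(dev_base, df_base, dev_add, df_add, "category"),
        interaction_test=ftest(dev_add, df_add, dev_full, df_full, "interaction"),
        full_deviance=dev_full,
        full_df=df_full,
    )


def fit_stratified(records, min_records: int = 3) -> dict:
    """One pooled fit per category; under-filled categories marked skipped.

    Returns a mapping ``category -> RegressionResult`` with skipped
    categories mapped to the string ``"skipped"`` rather than dropped.
    """
    df = _frame(records)
    out: dict = {}
    for cat, sub in df.groupby("category", sort=True):
        if len(sub) < min_records:
            out[cat] = "skipped"
            continue
        try:
            out[cat] = _wls_fit(sub["ratio"], sub["allele_freq"], sub["weight"])
        except (InsufficientDataError, ValidationError):
            out[cat] = "skipped"
    return out


def stratified_table(results: Mapping, pooled: RegressionResult | None = None) -> pd.DataFrame:
    """Tabulate stratified fits (one row per category plus a pooled row)."""
    rows = []
    for cat, res in results.items():
        if res == "skipped":
            rows.append({"functional_category": cat, "slope": np.nan,
                         "deviance": np.nan, "p_value": np.nan, "rse": np.nan,
                         "n": 0, "note": "skipped"})
        else:
            rows.append({"functional_category": cat, "slope": res.slope,
                         "deviance": res.deviance, "p_value": res.p_value,
                         "rse": res.rse, "n": res.n, "note": ""})
    if pooled is not None:
        rows.append({"functional_category": "pooled", "slope": pooled.slope,
                     "deviance": pooled.deviance, "p_value": pooled.p_value,
                     "rse": pooled.rse, "n": pooled.n, "note": ""})
    return pd.DataFrame(rows)


class FrequencyRatioModel:
    """Weighted regression model of allele frequency on effect-size ratio.

    Parameters
    ----------
    ratio, freq, weight : array-like
        Per-SNP effect-size ratio, minor-allele frequency and
        inverse-variance weight.
    category : array-like of str, optional
        Variant functional category; enables the interaction and stratified
        fits.

    Examples
    --------
    >>> model = FrequencyRatioModel.from_dataframe(snps)
    >>> res = model.fit()
    >>> res.pooled.slope  # doctest: +SKIP
    -0.126
    """

    def __init__(self, ratio, freq, weight, category=None):
        self.data = pd.DataFrame(
            {"ratio": np.asarray(ratio, float),
             "allele_freq": np.asarray(freq, float),
             "weight": np.asarray(weight, float)}
        )
        if category is not None:
            self.data["category"] = np.asarray(category, dtype=object)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, sa_only: bool = True
                       ) -> "FrequencyRatioModel":
        """Build from an annotated SNP table (see ``annotate_snp_frame``).

        ``sa_only`` restricts to records with opposite-sign sex effects,
        which are the only ones with a defined effect-size ratio.
        """
        if "ratio" not in df.columns:
            from .effect_stats import annotate_snp_frame

            df = annotate_snp_frame(df)
        if sa_only and "is_sa" in df.columns:
            df = df[df["is_sa"]]
        cat = df["category"] if "category" in df.columns else None
        return cls(df["ratio"], df["allele_freq"], df["weight"], cat)

    def fit(self) -> "FrequencyRatioResults":
        pooled = fit_weighted_regression(self.data)
        interaction = None
        stratified = None
        if "category" in self.data.columns and self.data["category"].nunique() >= 2:
            counts = self.data["category"].value_counts()
            if (counts >= 3).all():
                interaction = fit_interaction_model(self.data)
            stratified = fit_stratified(self.data)
        elif "category" in self.data.columns:
            stratified = fit_stratified(self.data)
        return FrequencyRatioResults(self, pooled, interaction, stratified)


class FrequencyRatioResults:
    """Results container for :class:`FrequencyRatioModel`.

    Attributes
    ----------
    pooled : RegressionResult
    interaction : InteractionResult or None
    stratified : dict or None
        ``category -> RegressionResult`` (or ``"skipped"``).
    """

    def __init__(self, model, pooled, interaction, stratified):
        self.model = model
        self.pooled = pooled
        self.interaction = interaction
        self.stratified = stratified

    def summary(self) -> str:
        """Human-readable fit summary (Table-1-style)."""
        lines = ["Allele frequency ~ effect-size ratio (inverse-variance WLS)",
                 "=" * 60]
        p = self.pooled
        lines.append(
            f"pooled       slope {p.slope:+.4f} (SE {p.slope_se:.4f})  "
            f"deviance {p.deviance:.2f}  df {p.df}  p {p.p_value:.3g}  "
            f"RSE {p.rse:.3f}"
        )
        if self.stratified:
            for cat in sorted(self.stratified):
                r = self.stratified[cat]
                if r == "skipped":
                    lines.append(f"{cat:<12s} skipped (too few records)")
                else:
                    lines.append(
                        f"{cat:<12s} slope {r.slope:+.4f} (SE {r.slope_se:.4f})  "
                        f"deviance {r.deviance:.2f}  df {r.df}  "
                        f"p {r.p_value:.3g}  RSE {r.rse:.3f}"
                    )
        if self.interaction:
            m, i = self.interaction.main_effect_test, self.interaction.interaction_test
            lines.append(
                f"category main effect: F = {m.statistic:.3f}, df = {m.df}, "
                f"p = {m.p_value:.3g}"
            )
            lines.append(
                f"category x ratio:     F = {i.statistic:.3f}, df = {i.df}, "
                f"p = {i.p_value:.3g}"
            )
        return "\n".join(lines)

    def table(self) -> pd.DataFrame:
        return stratified_table(self.stratified or {}, self.pooled)

    def plot(self, ax=None):
        """Diagnostic scatter of allele frequency vs effect-size ratio with
        the pooled fitted line; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.scatter(d["ratio"], d["allele_freq"], s=4, alpha=0.3)
        xs = np.linspace(d["ratio"].min(), d["ratio"].max(), 50)
        ax.plot(xs, self.pooled.intercept + self.pooled.slope * xs, "k-")
        ax.axvline(-1.0, ls=":", color="k")
        ax.set_xlabel("effect-size ratio (benefit / detriment)")
        ax.set_ylabel("minor-allele frequency")
        return ax
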