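"""Seeded generators for every input table the pipeline consumes.

The generators emulate the statistical structure the analysis assumes, on one
synthetic chromosome:

* a candidate-SA SNP table with opposite-sign sex effects, inverse-variance
  weights and minor-allele frequencies that decline linearly with the
  cross-sex effect-size ratio;
* a piecewise-constant windowed recombination map whose rates can be elevated
  over genes in the highest conflict-intensity tertile;
* a paralogue pair list whose per-gene incidence follows a logistic model in
  standardized recombination rate and conflict tertile;
* an invertible block liftover map with a small intentionally unmapped
  fraction.

Every generator is a pure function of (config, seed): the same seed yields
byte-identical output.  Each returns a truth record carrying the generating
parameters and per-record latent values, sufficient to recompute any latent
quantity downstream checks need.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .recomb_assoc import GeneConflict, LiftoverBlock, LiftoverMap, RecombWindow

__all__ = [
    "SyntheticConfig",
    "generate_snp_table",
    "generate_recomb_map",
    "generate_paralog_pairs",
    "generate_liftover_map",
    "generate_all",
]

CATEGORIES = ("missense", "synonymous", "regulatory")
CHROM = "chrS"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the scale of the real candidate set this pipeline is
    aimed at: a few hundred genes carrying a few thousand SA SNPs, Cohen's d
    effects of a few tenths, frequencies on the minor-allele scale, a
    ~100 kb-resolution recombination map with rates of a few cM/Mb, and
    paralogue incidence around one gene in two.
    """

    n_genes: int = 337
    snps_per_gene: float = 7.0      # mean of a zero-truncated Poisson
    effect_sd: float = 0.3          # half-normal scale of the deleterious |d|
    ratio_log_sd: float = 0.35      # log-normal spread of |benefit/detriment|
    freq_intercept: float = 0.08    # allele-frequency model intercept
    freq_slope: float = -0.126      # frequency change per unit ratio
    freq_noise_sd: float = 0.05     # frequency units
    category_probs: tuple = (0.15, 0.15, 0.70)  # missense, synonymous, regulatory
    gene_length_range: tuple = (1_000, 5_000)   # bp
    gene_gap_range: tuple = (50_000, 150_000)   # bp; candidate genes are sparse
    window_size: int = 100_000      # bp, recombination-map resolution
    rate_log_mean: float = float(np.log(2.0))   # log cM/Mb
    rate_log_sd: float = 0.5
    sai_recomb_effect: float = 2.0  # rate multiplier over high-conflict genes
    paralog_base_logodds: float = -0.32
    paralog_recomb_coef: float = 0.3
    paralog_sai_coef: float = 0.23  # per tertile step (low=0, medium=1, high=2)
    paralog_count_mean: float = 2.5  # zero-truncated Poisson mean
    liftover_block_range: tuple = (50_000, 200_000)  # bp
    liftover_drop_prob: float = 0.04  # fraction of blocks left unmapped
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValidationError("category_probs must sum to 1")
        if self.sai_recomb_effect < 1:
            raise ValidationError("sai_recomb_effect must be >= 1")
        for name in ("effect_sd", "ratio_log_sd", "window_size",
                     "rate_log_sd", "paralog_count_mean", "snps_per_gene"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.freq_noise_sd < 0:
            raise ValidationError("freq_noise_sd must be >= 0")


def _rng(cfg: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def _zt_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (rate = ``mean``; mean ≈ rate for rate >> 1)."""
    out = rng.poisson(mean, size=size)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(mean, size=int(zeros.sum()))


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator):
    """Non-overlapping gene intervals (0-based half-open) on one chromosome."""
    starts, ends = [], []
    cursor = int(rng.integers(*cfg.gene_gap_range))
    for _ in range(cfg.n_genes):
        length = int(rng.integers(*cfg.gene_length_range))
        starts.append(cursor)
        ends.append(cursor + length)
        cursor += length + int(rng.integers(*cfg.gene_gap_range))
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    return pd.DataFrame(
        {"chrom": CHROM, "start": starts, "end": ends, "gene_id": gene_ids}
    )


def generate_snp_table(cfg: SyntheticConfig):
    """Simulate the candidate-SA SNP table.

    Per SNP the deleterious effect magnitude is half-normal with scale
    ``effect_sd``; the beneficial magnitude is set through a log-normal
    cross-sex ratio (``ratio_log_sd``) so that the effect-size ratio stays
    within the band where the linear frequency model produces frequencies
    inside (0.005, 0.5] with only rare clamping.  The sex receiving the
    benefit is random per SNP.  Frequencies follow
    ``freq_intercept + freq_slope * ratio + N(0, freq_noise_sd)``, clamped to
    (0.005, 0.5]; the unclamped latent values are kept in the truth record.

    Returns
    -------
    (snps, genes, truth)
        ``snps``: the SNP table (1-based positions); ``genes``: BED-style
        gene intervals; ``truth``: dict of generating parameters and
        per-SNP latents (``true_ratio``, ``latent_freq``, ``n_clamped``).
    """
    rng = _rng(cfg, 1)
    genes = _place_genes(cfg, rng)
    n_per_gene = _zt_poisson(rng, cfg.snps_per_gene, cfg.n_genes)
    n = int(n_per_gene.sum())

    gene_idx = np.repeat(np.arange(cfg.n_genes), n_per_gene)
    g_start = genes["start"].to_numpy()[gene_idx]
    g_end = genes["end"].to_numpy()[gene_idx]
    pos = rng.integers(g_start, g_end) + 1  # 1-based

    detriment = np.abs(rng.normal(0.0, cfg.effect_sd, size=n))
    detriment = np.maximum(detriment, 1e-6 * cfg.effect_sd)
    abs_ratio = np.exp(rng.normal(0.0, cfg.ratio_log_sd, size=n))
    benefit = abs_ratio * detriment
    male_benefits = rng.random(n) < 0.5
    d_male = np.where(male_benefits, benefit, -detriment)
    d_female = np.where(male_benefits, -detriment, benefit)
    ratio = -abs_ratio  # benefit / (-detriment)

    se = np.exp(rng.normal(np.log(0.05), 0.3, size=n))
    weight = 1.0 / se**2

    # Noise scales with each SNP's effect SE, so the inverse-variance
    # weighted fit is the correctly specified model for these data.
    noise_sd = cfg.freq_noise_sd * se / 0.05
    latent_freq = (
        cfg.freq_intercept + cfg.freq_slope * ratio
        + rng.normal(0.0, 1.0, size=n) * noise_sd
    )
    allele_freq = np.clip(latent_freq, 0.005, 0.5)
    n_clamped = int(np.sum(latent_freq != allele_freq))

    category = rng.choice(CATEGORIES, size=n, p=list(cfg.category_probs))

    snps = pd.DataFrame(
        {
            "snp_id": [f"S{i:05d}" for i in range(n)],
            "chrom": CHROM,
            "pos": pos.astype(int),
            "gene_id": genes["gene_id"].to_numpy()[gene_idx],
            "category": category,
            "d_male": d_male,
            "d_female": d_female,
            "weight": weight,
            "allele_freq": allele_freq,
        }
    )
    truth = {
        "config": asdict(cfg),
        "true_ratio": ratio,
        "latent_freq": latent_freq,
        "n_clamped": n_clamped,
        "chrom_length": int(genes["end"].max() + 10_000),
    }
    return snps, genes, truth


def generate_recomb_map(
    cfg: SyntheticConfig,
    gene_conflicts: list[GeneConflict],
    chrom_length: int | None = None,
):
    """Simulate a windowed recombination map over the synthetic chromosome.

    Contiguous ``window_size`` windows tile [0, chrom_length); base rates are
    log-normal(rate_log_mean, rate_log_sd).  Windows overlapping any gene in
    the highest conflict-intensity tertile (most negative pooled SAI) have
    their rate multiplied by ``sai_recomb_effect``; with the multiplier at 1
    the map is independent of conflict intensity (the null construction).
    """
    from .recomb_assoc import assign_tertiles

    rng = _rng(cfg, 2)
    if chrom_length is None:
        chrom_length = max(g.end for g in gene_conflicts) + 10_000
    n_windows = int(np.ceil(chrom_length / cfg.window_size))
    starts = np.arange(n_windows) * cfg.window_size
    ends = np.minimum(starts + cfg.window_size, chrom_length)
    rates = np.exp(rng.normal(cfg.rate_log_mean, cfg.rate_log_sd, size=n_windows))

    labels = assign_tertiles(
        [g.mean_sai for g in gene_conflicts], [g.gene_id for g in gene_conflicts]
    )
    boosted = np.zeros(n_windows, dtype=bool)
    if cfg.sai_recomb_effect != 1.0:
        for g, lab in zip(gene_conflicts, labels):
            if lab != "high":
                continue
            first = int(g.start // cfg.window_size)
            last = int((g.end - 1) // cfg.window_size)
            boosted[first : last + 1] = True
        rates = np.where(boosted, rates * cfg.sai_recomb_effect, rates)

    windows = [
        RecombWindow(CHROM, int(s), int(e), float(r))
        for s, e, r in zip(starts, ends, rates)
    ]
    truth = {"boosted_windows": boosted, "tertile_labels": labels}
    return windows, truth


def generate_paralog_pairs(
    cfg: SyntheticConfig,
    gene_conflicts: list[GeneConflict],
    recomb_rates: dict[str, float] | None = None,
):
    """Simulate paralogue pairs for the conflict genes.

    Each gene acquires at least one paralogue with probability
    ``logistic(base + recomb_coef * z_rate + sai_coef * tertile_index)``
    (tertile index: low = 0, medium = 1, high = 2; z_rate is the gene's
    recombination rate standardized across genes).  Genes with a paralogue
    receive a zero-truncated Poisson number of partners; partners are fresh
    synthetic gene ids and every emitted pair has a DIOPT score drawn
    uniformly from 1..15.
    """
    from .recomb_assoc import assign_tertiles

    rng = _rng(cfg, 3)
    labels = assign_tertiles(
        [g.mean_sai for g in gene_conflicts], [g.gene_id for g in gene_conflicts]
    )
    tert_idx = np.array([{"low": 0, "medium": 1, "high": 2}[t] for t in labels])
    if recomb_rates is None:
        rates = np.array(
            [g.recomb_rate if g.recomb_rate is not None else np.nan
             for g in gene_conflicts]
        )
    else:
        rates = np.array([recomb_rates.get(g.gene_id, np.nan) for g in gene_conflicts])
    rates = np.where(np.isnan(rates), np.nanmean(rates) if np.isfinite(np.nanmean(rates)) else 0.0, rates)
    sd = rates.std()
    z = (rates - rates.mean()) / sd if sd > 0 else np.zeros_like(rates)

    logit = (
        cfg.paralog_base_logodds
        + cfg.paralog_recomb_coef * z
        + cfg.paralog_sai_coef * tert_idx
    )
    prob = expit(logit)
    has_paralog = rng.random(len(gene_conflicts)) < prob

    pairs = []
    counter = 0
    for g, hp in zip(gene_conflicts, has_paralog):
        if not hp:
            continue
        k = int(_zt_poisson(rng, cfg.paralog_count_mean, 1)[0])
        for _ in range(k):
            partner = f"PARA_{counter:05d}"
            counter += 1
            score = int(rng.integers(1, 16))
            pairs.append((g.gene_id, partner, score))
    truth = {
        "tertile_labels": labels,
        "paralog_prob": prob,
        "has_paralog": has_paralog,
    }
    return pairs, truth


def generate_liftover_map(
    cfg: SyntheticConfig, chrom_length: int = 2_000_000
) -> tuple[LiftoverMap, dict]:
    """Simulate an invertible block liftover map of the synthetic chromosome.

    The chromosome is partitioned into blocks of random length; each block is
    shifted by a random offset into the target assembly (blocks laid out in
    order with random gaps, so the map is invertible by construction).  A
    fraction ``liftover_drop_prob`` of blocks is intentionally left unmapped
    to exercise the unmapped path; expected coverage is >= 95% with the
    default.
    """
    rng = _rng(cfg, 4)
    blocks = []
    src = 0
    tgt = int(rng.integers(0, 10_000))
    dropped_bp = 0
    # hard cap: never leave more than 5% of the chromosome unmapped
    drop_budget = int(0.05 * chrom_length)
    while src < chrom_length:
        length = int(rng.integers(*cfg.liftover_block_range))
        length = min(length, chrom_length - src)
        if (rng.random() < cfg.liftover_drop_prob
                and dropped_bp + length <= drop_budget):
            dropped_bp += length
        else:
            blocks.append(LiftoverBlock(CHROM, src, src + length, CHROM, tgt, "+"))
            tgt += length + int(rng.integers(0, 5_000))
        src += length
    truth = {
        "dropped_bp": dropped_bp,
        "chrom_length": chrom_length,
        "mapped_fraction": 1.0 - dropped_bp / chrom_length,
    }
    return LiftoverMap(blocks), truth


def generate_all(cfg: SyntheticConfig):
    """Generate the full consistent set of synthetic inputs.

    Returns a dict with keys ``snps``, ``genes``, ``windows``, ``pairs``,
    ``liftover`` and ``truth`` (per-generator truth records).  Gene-level
    conflict pooling for the map and paralogue generators uses the missense
    category when it yields at least 3 genes, else all SNPs.
    """
    from .effect_stats import annotate_snp_frame
    from .recomb_assoc import assign_rates_to_genes, pool_gene_sai

    snps, genes, snp_truth = generate_snp_table(cfg)
    annotated = annotate_snp_frame(snps)
    conflicts = pool_gene_sai(annotated, genes, category="missense")
    if len(conflicts) < 3:
        conflicts = pool_gene_sai(annotated, genes, category=None)
    windows, map_truth = generate_recomb_map(
        cfg, conflicts, snp_truth["chrom_length"]
    )
    conflicts, _missing = assign_rates_to_genes(conflicts, windows)
    pairs, pair_truth = generate_paralog_pairs(cfg, conflicts)
    lmap, lift_truth = generate_liftover_map(cfg, snp_truth["chrom_length"])
    return {
        "snps": snps,
        "genes": genes,
        "windows": windows,
        "pairs": pairs,
        "liftover": lmap,
        "truth": {
            "snps": snp_truth,
            "recomb": map_truth,
            "paralogs": pair_truth,
            "liftover": lift_truth,
        },
    }
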