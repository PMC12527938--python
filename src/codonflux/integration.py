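"""Codon composition to proteome integration.

Preprocesses protein intensity tables (log2 transform, valid-value
filtering, mixed kNN/MinProb imputation), aggregates per-gene wobble-base
codon fractions to pathway level, and correlates pathway codon
composition with mean protein fold change — the read-out that links
slow decoding of A-ending codons to reduced protein output of A-rich
gene sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)


def filter_and_impute(
    intensities: pd.DataFrame,
    groups: pd.Series,
    min_valid_frac: float = 0.7,
    knn_valid_frac: float = 0.6,
    k: int = 10,
    width: float = 0.2,
    downshift: float = 1.8,
    seed: int | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Filter and impute a protein intensity matrix (proteins x samples).

    Intensities are log2-transformed (zeros/negatives treated as
    missing).  Proteins with less than ``min_valid_frac`` valid values
    in every group are dropped.  Within each group, missing values of a
    protein are imputed by kNN over proteins (k nearest by Euclidean
    distance on shared-valid entries) when the group has at least
    ``knn_valid_frac`` valid values for that protein; remaining missing
    values are drawn from a down-shifted Gaussian per sample
    (mean - downshift*sd, width*sd of that sample's observed values).
    Observed values are never altered.
    """
    groups = groups.reindex(intensities.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    group_levels = groups.unique()
    if len(group_levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in group_levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    X = intensities.astype(float).copy()
    if log_transform:
        X = X.where(X > 0)
        X = np.log2(X)

    valid_frac = {
        g: X.loc[:, groups == g].notna().mean(axis=1) for g in group_levels
    }
    keep = pd.concat(valid_frac, axis=1).ge(min_valid_frac).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d proteins below the valid-value threshold", dropped)
    X = X.loc[keep]

    rng = np.random.default_rng(seed)
    out = X.copy()
    for g in group_levels:
        cols = X.columns[groups == g]
        block = X[cols]
        knn_rows = block.notna().mean(axis=1) >= knn_valid_frac
        has_missing = block.isna().any(axis=1)
        todo = knn_rows & has_missing
        if todo.any():
            # fit kNN on all knn-eligible proteins of the group so the
            # imputed rows have enough complete neighbours
            fit_block = block.loc[knn_rows]
            imputer = KNNImputer(n_neighbors=min(k, max(1, knn_rows.sum() - 1)))
            imputed = pd.DataFrame(
                imputer.fit_transform(fit_block),
                index=fit_block.index,
                columns=cols,
            )
            mask = block.loc[knn_rows].isna()
            out.loc[knn_rows, cols] = block.loc[knn_rows].where(~mask, imputed)
    # MinProb: remaining missing values, per sample
    for col in out.columns:
        missing = out[col].isna()
        if not missing.any():
            continue
        observed = X[col].dropna()
        mu = observed.mean() - downshift * observed.std()
        sd = width * observed.std()
        out.loc[missing, col] = rng.normal(mu, sd, size=int(missing.sum()))
    return out


def pathway_fraction(
    gene_fractions: pd.Series, gene_sets: dict[str, list[str]]
) -> pd.Series:
    """Unweighted mean of member-gene fractions per pathway.

    Genes missing from ``gene_fractions`` are logged and skipped; a
    gene in multiple pathways contributes to each independently.
    Pathways with no measured genes are skipped with a warning.
    """
    out = {}
    for pw, genes in gene_sets.items():
        present = [g for g in genes if g in gene_fractions.index]
        missing = len(genes) - len(present)
        if missing:
            logger.info("pathway %s: %d member genes without fractions", pw, missing)
        if not present:
            logger.warning("pathway %s has no measured genes; skipped", pw)
            continue
        out[pw] = float(gene_fractions[present].mean())
    return pd.Series(out, name=gene_fractions.name)


def fraction_foldchange_correlation(
    pathway_fractions: pd.Series, pathway_log2fc: pd.Series
) -> dict[str, float]:
    """Pearson correlation and OLS line of codon fraction vs protein change.

    A negative slope indicates that pathways richer in the slow codon
    class lose protein under treatment.  Returns r, p-value, slope,
    intercept and n; raises on zero variance in either axis.
    """
    common = pathway_fractions.index.intersection(pathway_log2fc.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared pathways")
    x = pathway_fractions[common].to_numpy(dtype=float)
    y = pathway_log2fc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one axis; correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "r": float(r),
        "p_value": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": len(common),
    }


def gene_pausing_protein_report(
    pausing_sums: pd.DataFrame,
    third_base_fractions: pd.DataFrame,
    protein_log2fc: pd.Series,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Join per-gene pausing sums and codon fractions with protein change.

    ``pausing_sums`` is a genes x bases table of wobble-base pausing
    sums; the report is ranked by the A bucket (descending) and carries
    the Pearson correlation between the A-bucket pausing sum and the
    protein log2 fold change (NaN correlation when fold changes are
    constant).
    """
    common = pausing_sums.index.intersection(protein_log2fc.index)
    if len(common) == 0:
        raise ValueError("no shared genes between pausing sums and protein table")
    report = pausing_sums.loc[common].add_prefix("pausing_sum_")
    report = report.join(third_base_fractions.add_prefix("frac_"), how="left")
    report["protein_log2fc"] = protein_log2fc[common]
    report = report.sort_values("pausing_sum_A", ascending=False)
    y = report["protein_log2fc"].to_numpy(dtype=float)
    x = report["pausing_sum_A"].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0 or len(common) < 3:
        corr = {"r": float("nan"), "p_value": float("nan"), "n": len(common)}
    else:
        r, p = stats.pearsonr(x, y)
        corr = {"r": float(r), "p_value": float(p), "n": len(common)}
    return report, corr
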