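"""Single-sample gene-set activity scores and cohort correlation tools.

Activity scoring uses the weighted-Z method: genes are standardized
across the cohort, then each sample's score for a set G is

    Z_s = sum_{g in G} w_g z_{g,s} / sqrt(sum_{g in G} w_g^2)

with unit weights by default.  Correlations are Spearman's rho with a
two-sided p from the t-distribution on n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import Cohort, GeneSet

logger = logging.getLogger("targetomics")


def standardize_genes(c: Cohort) -> pd.DataFrame:
    """Per-gene z-scores across cohort samples (mean 0, sd 1, ddof=1).

    Constant genes cannot be standardized and are dropped with a log
    entry.
    """
    expr = c.expression
    sd = expr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info(
            "standardize_genes: dropped %d constant genes",
            int(constant.sum()),
        )
        expr = expr[~constant]
        sd = sd[~constant]
    return expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)


def weighted_z_activity(zmat: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample weighted-Z activity score for one gene set.

    Set genes absent from the matrix are dropped with a log entry; an
    error is raised if none remain.
    """
    present = [g for g in sorted(gene_set.genes) if g in zmat.index]
    if not present:
        raise ValueError(
            f"gene set {gene_set.name!r}: no member gene in matrix"
        )
    if len(present) < len(gene_set.genes):
        logger.info(
            "weighted_z_activity(%s): %d/%d genes absent from matrix",
            gene_set.name, len(gene_set.genes) - len(present),
            len(gene_set.genes),
        )
    w = np.array([gene_set.weight(g) for g in present])
    scores = (zmat.loc[present].T @ w) / np.sqrt((w**2).sum())
    scores.name = gene_set.name
    return scores


@dataclass
class CorrelationRecord:
    x_name: str
    y_name: str
    rho: float
    p: float
    n: int


def spearman_corr(
    x, y, x_name: str = "x", y_name: str = "y"
) -> CorrelationRecord:
    """Spearman correlation with mid-rank ties and a t-based p-value.

    rho is the Pearson correlation of mid-ranks; the two-sided p uses
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.  With
    |rho| = 1 the p is reported as the smallest positive double.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman rho undefined")
    rx = stats.rankdata(x)  # mid-ranks
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        rho = float(np.sign(rho))
        p = float(np.nextafter(0.0, 1.0))
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationRecord(x_name=x_name, y_name=y_name, rho=rho, p=p, n=n)


def rank_genes_by_activity_correlation(
    zmats: dict[str, pd.DataFrame],
    gene_list: list[str],
    targets: dict[str, pd.Series],
) -> pd.DataFrame:
    """Rank genes by their mean (across cohorts) Spearman correlation
    with a target activity score.

    ``zmats`` and ``targets`` are keyed by cohort name.  A gene absent
    from some cohort is averaged over the cohorts where it is present
    and flagged ``all_cohorts=False``.  The table is sorted by mean rho
    descending, ties broken lexicographically by gene.
    """
    if set(zmats) != set(targets):
        raise ValueError("cohorts of z-matrices and targets differ")
    rows = []
    for gene in gene_list:
        rhos = {}
        for cohort, zmat in zmats.items():
            if gene not in zmat.index:
                continue
            scores = targets[cohort]
            rec = spearman_corr(
                zmat.loc[gene, scores.index], scores.to_numpy()
            )
            rhos[cohort] = rec.rho
        if not rhos:
            logger.info("gene %s absent from every cohort; skipped", gene)
            continue
        row = {"gene": gene, "mean_rho": float(np.mean(list(rhos.values()))),
               "all_cohorts": len(rhos) == len(zmats)}
        for cohort in zmats:
            row[f"rho_{cohort}"] = rhos.get(cohort, np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(
        ["mean_rho", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("gene")


def overexpression_frequency(
    c: Cohort,
    gene: str,
    reference_stage: int,
    z_threshold: float = 2.0,
) -> pd.Series:
    """Fraction of samples per stage with expression z > threshold,
    where z is computed against the reference stage's mean and sd
    (e.g. tumor-adjacent normal tissue).
    """
    if gene not in c.expression.index:
        raise KeyError(f"gene {gene!r} not in cohort expression")
    ref_samples = c.stage.index[c.stage == reference_stage]
    if len(ref_samples) < 3:
        raise ValueError(
            f"reference stage {reference_stage} has "
            f"{len(ref_samples)} samples (< 3)"
        )
    x = c.expression.loc[gene]
    mu = x[ref_samples].mean()
    sd = x[ref_samples].std(ddof=1)
    if sd == 0:
        raise ValueError("reference stage has zero expression variance")
    z = (x - mu) / sd
    freq = {}
    for stage in sorted(c.stage.unique()):
        members = c.stage.index[c.stage == stage]
        freq[stage] = float((z[members] > z_threshold).mean())
    out = pd.Series(freq, name=f"overexpression_freq_{gene}")
    out.index.name = "stage"
    return out
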