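"""Druggable-target triage, contingency trend statistics and
Kaplan-Meier / log-rank survival analysis.

Triage applies three criteria to each candidate gene: (1) recurrent
copy-number amplification (frequency > 10% in at least two cohorts of
lethal metastatic disease), (2) strong monotone association of mRNA
with disease progression (Spearman rho > 0.9, p < 0.01 on stage means),
and (3) druggability (an approved inhibitor, or a chemical probe with
activity < 30 nM).  Genes meeting all three form the candidate target
intersection.

Survival analysis stratifies a cohort by a gene's expression and
compares strata with the log-rank test; the hazard ratio is the
observed/expected ratio (O1/E1)/(O2/E2) with a 95% CI of
exp(ln HR +/- 1.96 * sqrt(1/E1 + 1/E2)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_scores import spearman_corr
from .io_tables import Cohort

logger = logging.getLogger("targetomics")


# ---------------------------------------------------------------------------
# Alteration frequency and progression correlation
# ---------------------------------------------------------------------------

def alteration_frequency(
    c: Cohort, genes: str | list[str], levels: set[int]
) -> float:
    """Fraction of samples whose CNA call is in ``levels`` — jointly for
    all listed genes (co-alteration when two genes are given)."""
    if isinstance(genes, str):
        genes = [genes]
    for g in genes:
        if g not in c.cna_calls.index:
            raise KeyError(f"gene {g!r} not in CNA calls")
    if not levels:
        return 0.0
    mask = np.ones(len(c.sample_ids), dtype=bool)
    for g in genes:
        mask &= c.cna_calls.loc[g].isin(levels).to_numpy()
    return float(mask.mean())


def progression_correlation(
    c: Cohort, gene: str, mode: str = "stage_mean"
) -> tuple[float, float]:
    """Spearman correlation of a gene's expression with disease stage.

    Default ``stage_mean`` mode correlates per-stage mean expression
    with stage rank (the trend-view convention under which rho > 0.9 is
    attainable); ``sample`` mode correlates sample-level expression with
    stage codes.
    """
    if gene not in c.expression.index:
        raise KeyError(f"gene {gene!r} not in cohort expression")
    stages = sorted(c.stage.unique())
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    x = c.expression.loc[gene]
    if mode == "stage_mean":
        means = [x[c.stage.index[c.stage == s]].mean() for s in stages]
        rec = spearman_corr(list(range(len(stages))), means)
    elif mode == "sample":
        rec = spearman_corr(c.stage.loc[x.index].to_numpy(), x.to_numpy())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rec.rho, rec.p


# ---------------------------------------------------------------------------
# Three-criteria triage
# ---------------------------------------------------------------------------

@dataclass
class TriageResult:
    """Per-gene criterion flags, Venn region counts and the intersection.

    ``venn_counts`` keys are frozensets of criterion names among
    {"c1", "c2", "c3"}; the empty frozenset counts genes meeting none.
    ``intersection`` is sorted by maximal amplification frequency,
    descending.
    """

    table: pd.DataFrame
    venn_counts: dict[frozenset, int]
    intersection: list[str]


def triage_targets(
    records: pd.DataFrame,
    amp_freq_min: float = 0.10,
    min_cohorts: int = 2,
    rho_min: float = 0.9,
    p_max: float = 0.01,
) -> TriageResult:
    """Apply the three-criteria druggable-target triage.

    ``records`` is indexed by gene with columns ``amp_freq_<cohort>``
    (one per CNA cohort), ``progression_rho``, ``progression_p`` and
    boolean ``druggable``.  Criterion 1: amplification frequency
    strictly above ``amp_freq_min`` in at least ``min_cohorts`` cohorts;
    criterion 2: rho > rho_min and p < p_max; criterion 3: druggable.
    Missing inputs make the criterion false (logged).
    """
    freq_cols = [c for c in records.columns if c.startswith("amp_freq_")]
    if not freq_cols:
        raise ValueError("no amp_freq_<cohort> columns")
    freqs = records[freq_cols].astype(float)
    c1 = (freqs > amp_freq_min).sum(axis=1) >= min_cohorts
    rho = records["progression_rho"].astype(float)
    pv = records["progression_p"].astype(float)
    c2 = (rho > rho_min) & (pv < p_max)
    c2 = c2.fillna(False)
    c3 = records["druggable"].fillna(False).astype(bool)
    n_missing = int(records[freq_cols + ["progression_rho",
                                         "progression_p"]].isna().any(
        axis=1).sum())
    if n_missing:
        logger.info("triage_targets: %d genes with missing inputs "
                    "(criterion treated as false)", n_missing)

    table = pd.DataFrame(
        {"meets_c1": c1, "meets_c2": c2, "meets_c3": c3},
        index=records.index,
    )
    table["in_intersection"] = c1 & c2 & c3
    table["max_amp_freq"] = freqs.max(axis=1)

    venn_counts: dict[frozenset, int] = {}
    for combo_size in range(4):
        for combo in itertools.combinations(("c1", "c2", "c3"), combo_size):
            key = frozenset(combo)
            mask = pd.Series(True, index=table.index)
            for crit in ("c1", "c2", "c3"):
                want = crit in key
                mask &= table[f"meets_{crit}"] == want
            venn_counts[key] = int(mask.sum())

    inter = table[table["in_intersection"]]
    intersection = list(
        inter.sort_values(
            ["max_amp_freq"], ascending=False, kind="mergesort"
        ).index
    )
    return TriageResult(
        table=table, venn_counts=venn_counts, intersection=intersection
    )


# ---------------------------------------------------------------------------
# Contingency trend and effect size
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    chi2: float
    p: float
    cramers_v: float
    label: str


def trend_effect_size(table: np.ndarray | pd.DataFrame) -> TrendResult:
    """Pearson chi-square (upper-tail p) and Cramér's V for a stage x
    status contingency table, with the conventional effect-size labels
    (< 0.2 weak, < 0.6 moderate, else strong)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a 2-D table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    r, c = t.shape
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1)))) if min(r, c) > 1 else 0.0
    label = "weak" if v < 0.2 else ("moderate" if v < 0.6 else "strong")
    return TrendResult(chi2=chi2, p=p, cramers_v=v, label=label)


# ---------------------------------------------------------------------------
# Expression stratification
# ---------------------------------------------------------------------------

def stratify_by_expression(
    c: Cohort,
    gene: str,
    method: str = "median",
    cut: float | None = None,
) -> tuple[pd.Series, float | tuple[float, float]]:
    """High/low labels per sample by a gene's expression.

    ``median``: split at the median (ties at the cut go to "low");
    ``tertile``: outer tertiles labeled, middle labeled "mid";
    ``custom``: split at ``cut``.  Returns (labels, cut value(s)).
    """
    if gene not in c.expression.index:
        raise KeyError(f"gene {gene!r} not in cohort expression")
    x = c.expression.loc[gene]
    if x.nunique() == 1:
        raise ValueError("all-equal expression: cannot stratify")
    if method == "median":
        cutval = float(x.median())
        labels = pd.Series(
            np.where(x > cutval, "high", "low"), index=x.index
        )
        return labels, cutval
    if method == "tertile":
        lo, hi = x.quantile([1 / 3, 2 / 3])
        labels = pd.Series("mid", index=x.index)
        labels[x <= lo] = "low"
        labels[x > hi] = "high"
        return labels, (float(lo), float(hi))
    if method == "custom":
        if cut is None:
            raise ValueError("custom method needs a cut value")
        labels = pd.Series(
            np.where(x > cut, "high", "low"), index=x.index
        )
        return labels, float(cut)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    """Log-rank comparison of two survival strata.

    ``curves`` maps group label -> DataFrame(time, at_risk, survival);
    ``hr`` is (O_a/E_a)/(O_b/E_b) for the group order given, with its
    95% CI.
    """

    curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    observed: dict[str, float] = field(default_factory=dict)
    expected: dict[str, float] = field(default_factory=dict)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct event time (plus t=0): the number at
    risk just before the time and the survival just after it.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = [(0.0, len(t), 1.0)]
    surv = 1.0
    for ti in np.unique(t[e == 1]):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(ti), at_risk, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "survival"])


def km_logrank(times, events, groups) -> SurvivalResult:
    """Two-group log-rank test with O/E hazard ratio.

    At each distinct event time the observed and hypergeometric-expected
    events per group are accumulated; chi2 = (O_a - E_a)^2 / V with the
    standard log-rank variance.  HR and its CI follow the O/E
    formulation; the first group label (sorted order) is the numerator.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if e.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    in_a = g == labels[0]
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        raise ValueError("a group has no subjects at risk")

    obs_a = exp_a = var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = int(((t == ti) & (e == 1)).sum())
        d_a = int(((t == ti) & (e == 1) & in_a).sum())
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    obs_b = float(e.sum() - obs_a)
    exp_b = float(e.sum() - exp_a)

    chi2 = (obs_a - exp_a) ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1))
    if obs_a == 0 or obs_b == 0 or exp_a == 0 or exp_b == 0:
        logger.warning("km_logrank: zero observed/expected; HR degenerate")
        hr = np.nan
        ci = (np.nan, np.nan)
    else:
        hr = (obs_a / exp_a) / (obs_b / exp_b)
        half = 1.96 * np.sqrt(1.0 / exp_a + 1.0 / exp_b)
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))

    curves = {
        lab: km_curve(t[g == lab], e[g == lab]) for lab in labels
    }
    return SurvivalResult(
        curves=curves,
        logrank_chi2=float(chi2),
        p=p,
        hr=float(hr),
        hr_ci=ci,
        observed={labels[0]: float(obs_a), labels[1]: obs_b},
        expected={labels[0]: float(exp_a), labels[1]: exp_b},
    )
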