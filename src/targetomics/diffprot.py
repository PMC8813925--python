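"""Per-clone differential protein expression and cross-clone consensus.

The workflow mirrors the standard Perseus-style label-free analysis:
log2-transform LFQ intensities, keep features with enough valid values
per group, run unpaired two-tailed Welch's t-tests per knockout clone
against control, adjust with Benjamini-Hochberg, combine clones with a
signed Stouffer z, and call consensus differential proteins that pass
the per-clone criteria in every clone with a consistent direction and a
combined q below threshold.

Orientation: contrasts are (clone - control), so a "down" feature is
lower in the knockout clones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import DesignError, GeneSet, QuantMatrix

logger = logging.getLogger("targetomics")

# Signed z-scores are capped here when a per-clone p underflows to 0.
Z_MAX = 37.0

#: smallest positive double, used as the degenerate-Welch p convention
P_FLOOR = np.nextafter(0.0, 1.0)


# ---------------------------------------------------------------------------
# Matrix preparation
# ---------------------------------------------------------------------------

def average_technical_runs(
    m: QuantMatrix, run_map: dict[str, str]
) -> QuantMatrix:
    """Average technical LC-MS/MS runs into one column per biological
    replicate before testing, to avoid pseudo-replication.

    Linear-scale intensities are combined as the geometric mean (the
    arithmetic mean on the log2 scale), keeping replicate values
    symmetric on the scale the downstream t-tests operate on; log-scale
    matrices are averaged arithmetically.  ``run_map`` maps each run
    sample id to its biological replicate id; the replicate inherits the
    group of its runs (which must agree).
    """
    groups_by_rep: dict[str, str] = {}
    cols_by_rep: dict[str, list[str]] = {}
    for run, rep in run_map.items():
        if run not in m.data.columns:
            raise KeyError(f"run {run!r} not in matrix")
        g = m.design[run]
        if groups_by_rep.setdefault(rep, g) != g:
            raise DesignError(f"replicate {rep!r} spans multiple groups")
        cols_by_rep.setdefault(rep, []).append(run)
    if m.log_scale:
        data = pd.DataFrame(
            {rep: m.data[cols].mean(axis=1)
             for rep, cols in cols_by_rep.items()}
        )
    else:
        logged = np.log2(m.data)
        data = pd.DataFrame(
            {rep: np.exp2(logged[cols].mean(axis=1))
             for rep, cols in cols_by_rep.items()}
        )
    return QuantMatrix(data=data, design=groups_by_rep, log_scale=m.log_scale)


def prepare_matrix(
    m: QuantMatrix,
    min_valid: int = 3,
    groups: list[str] | None = None,
) -> tuple[QuantMatrix, pd.Series]:
    """log2-transform and flag features testable in every compared group.

    A feature is testable when it has at least ``min_valid`` present
    values in each of ``groups`` (default: all design groups).  All
    features are retained in the returned matrix; the boolean Series
    marks the testable ones.
    """
    if min_valid < 2:
        raise ValueError("min_valid must be >= 2")
    if m.log_scale:
        raise ValueError("matrix already log-scale")
    group_cols = m.groups()
    if groups is None:
        groups = list(group_cols)
    for g in groups:
        if g not in group_cols:
            raise DesignError(f"group {g!r} not in design")
        if len(group_cols[g]) < min_valid:
            raise DesignError(
                f"group {g!r} has {len(group_cols[g])} replicates, "
                f"fewer than min_valid={min_valid}"
            )
    logged = np.log2(m.data)
    testable = pd.Series(True, index=m.data.index)
    for g in groups:
        n_valid = logged[group_cols[g]].notna().sum(axis=1)
        testable &= n_valid >= min_valid
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info(
            "prepare_matrix: %d features excluded (<%d valid values in "
            "some group)", n_dropped, min_valid,
        )
    out = QuantMatrix(data=logged, design=dict(m.design), log_scale=True)
    return out, testable


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def _welch_arrays(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float, float, float]:
    """Welch t statistic, Satterthwaite df, two-tailed p, mean diff.

    Degenerate conventions: when both groups have zero variance, p = 1
    if the means agree and the smallest representable positive p
    otherwise.
    """
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    diff = ma - mb
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0, diff
        logger.warning("welch: zero variance with unequal means; p floored")
        return np.inf if diff > 0 else -np.inf, float(na + nb - 2), P_FLOOR, diff
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), float(diff)


def welch_contrast(
    m: QuantMatrix,
    group_a: str,
    group_b: str,
    features: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-feature Welch contrast (a - b) on a log2 matrix.

    Returns a DataFrame indexed by feature with columns ``mean_log2_a``,
    ``mean_log2_b``, ``log2fc``, ``t_stat``, ``df``, ``p``, ``q``,
    ``n_valid_a`` and ``n_valid_b``.  Features with fewer than two valid
    values in either group get NaN statistics and are excluded from the
    BH family.
    """
    if not m.log_scale:
        raise ValueError("welch_contrast expects a log2-scale matrix")
    cols_a = m.samples_in(group_a)
    cols_b = m.samples_in(group_b)
    if not cols_a or not cols_b:
        raise DesignError(f"empty group among {group_a!r}, {group_b!r}")
    data = m.data if features is None else m.data.loc[features]

    a = data[cols_a].to_numpy(dtype=float)
    b = data[cols_b].to_numpy(dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    tested = (na >= 2) & (nb >= 2)

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    diff = ma - mb

    t = np.full(len(data), np.nan)
    df = np.full(len(data), np.nan)
    p = np.full(len(data), np.nan)

    both_const = tested & (va == 0) & (vb == 0)
    regular = tested & ~both_const
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / na + vb / nb
        t[regular] = diff[regular] / np.sqrt(se2[regular])
        df[regular] = se2[regular] ** 2 / (
            (va / na) ** 2 / np.maximum(na - 1, 1)
            + (vb / nb) ** 2 / np.maximum(nb - 1, 1)
        )[regular]
        p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df[regular])

    eq = both_const & (diff == 0)
    t[eq], df[eq], p[eq] = 0.0, (na + nb - 2)[eq], 1.0
    ne = both_const & (diff != 0)
    if ne.any():
        logger.warning(
            "welch: %d features with zero variance and unequal means; "
            "p floored", int(ne.sum()),
        )
        t[ne] = np.where(diff[ne] > 0, np.inf, -np.inf)
        df[ne] = (na + nb - 2)[ne]
        p[ne] = P_FLOOR

    res = pd.DataFrame(
        {
            "mean_log2_a": np.where(tested, ma, np.nan),
            "mean_log2_b": np.where(tested, mb, np.nan),
            "log2fc": np.where(tested, diff, np.nan),
            "t_stat": t,
            "df": df,
            "p": p,
            "n_valid_a": na,
            "n_valid_b": nb,
        },
        index=data.index,
    )
    res["q"] = np.nan
    res.loc[tested, "q"] = bh_adjust(p[tested])
    return res


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted q-values.

    q_(i) = min_{j>=i} p_(j) * m / j, clipped to [0, 1]; order-preserving
    under ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# Stouffer consensus across clones
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Signed-Stouffer consensus over per-clone Welch contrasts.

    ``table`` is indexed by feature with columns ``combined_z``,
    ``combined_p``, ``combined_q``, ``direction_consistent``, plus
    ``log2fc_<clone>``, ``p_<clone>`` and ``hit_<clone>`` per clone.
    """

    table: pd.DataFrame
    clones: list[str]
    per_clone: dict[str, pd.DataFrame]


def signed_z(p: float, log2fc: float) -> float:
    """Signed z from a two-tailed p: sign(log2fc) * Phi^-1(1 - p/2)."""
    z = stats.norm.isf(p / 2.0)
    if not np.isfinite(z) or z > Z_MAX:
        logger.warning("signed_z: p=%g underflows; z capped at %g", p, Z_MAX)
        z = Z_MAX
    return float(np.sign(log2fc) * z) if log2fc != 0 else 0.0


def stouffer_combine(
    per_clone: dict[str, pd.DataFrame],
    p_max: float = 0.05,
    lfc_min: float = 0.5,
) -> ConsensusResult:
    """Combine per-clone contrasts with equal-weight signed Stouffer.

    combined_z = sum_i z_i / sqrt(k) over the k clones, with
    z_i = sign(log2fc_i) * Phi^-1(1 - p_i/2); combined_p two-tailed
    normal; combined_q by BH over all features tested in every clone.
    Per-clone hit flags record p < p_max and |log2fc| > lfc_min.
    """
    if len(per_clone) < 2:
        raise ValueError("stouffer_combine needs >= 2 clones")
    clones = list(per_clone)
    tested = None
    for c in clones:
        ok = per_clone[c].index[per_clone[c]["p"].notna()]
        tested = ok if tested is None else tested.intersection(ok)
    tested = tested.sort_values()

    k = len(clones)
    table = pd.DataFrame(index=tested)
    zsum = np.zeros(len(tested))
    signs = np.zeros((k, len(tested)))
    for i, c in enumerate(clones):
        sub = per_clone[c].loc[tested]
        z = np.array(
            [signed_z(p, fc) for p, fc in zip(sub["p"], sub["log2fc"])]
        )
        zsum += z
        signs[i] = np.sign(sub["log2fc"].to_numpy())
        table[f"log2fc_{c}"] = sub["log2fc"]
        table[f"p_{c}"] = sub["p"]
        table[f"hit_{c}"] = (sub["p"] < p_max) & (sub["log2fc"].abs() > lfc_min)
    combined_z = zsum / np.sqrt(k)
    table["combined_z"] = combined_z
    table["combined_p"] = 2.0 * stats.norm.sf(np.abs(combined_z))
    table["combined_q"] = bh_adjust(table["combined_p"].to_numpy())
    table["direction_consistent"] = np.all(signs == signs[0], axis=0) & (
        signs[0] != 0
    )
    return ConsensusResult(table=table, clones=clones, per_clone=per_clone)


# ---------------------------------------------------------------------------
# Consensus differential proteins and signatures
# ---------------------------------------------------------------------------

@dataclass
class DEPSets:
    """Features consistently lower (down) or higher (up) in the KO clones."""

    down: frozenset[str]
    up: frozenset[str]

    def __post_init__(self) -> None:
        self.down = frozenset(self.down)
        self.up = frozenset(self.up)
        if self.down & self.up:
            raise ValueError("down and up sets overlap")


def consensus_deps(
    c: ConsensusResult,
    p_max: float = 0.05,
    lfc_min: float = 0.5,
    q_max: float = 0.005,
) -> DEPSets:
    """Call consensus differential features.

    A feature enters ``down`` (resp. ``up``) iff in EVERY clone it has
    p < p_max and |log2fc| > lfc_min with consistently negative (resp.
    positive) clone-vs-control fold change, AND its combined q < q_max.
    """
    if min(p_max, lfc_min, q_max) <= 0:
        raise ValueError("thresholds must be positive")
    t = c.table
    all_hit = np.ones(len(t), dtype=bool)
    for clone in c.clones:
        all_hit &= (
            (t[f"p_{clone}"] < p_max)
            & (t[f"log2fc_{clone}"].abs() > lfc_min)
        ).to_numpy()
    consistent = t["direction_consistent"].to_numpy()
    q_ok = (t["combined_q"] < q_max).to_numpy()
    passing = all_hit & consistent & q_ok
    sign0 = np.sign(t[f"log2fc_{c.clones[0]}"].to_numpy())
    down = frozenset(t.index[passing & (sign0 < 0)])
    up = frozenset(t.index[passing & (sign0 > 0)])
    return DEPSets(down=down, up=up)


def extract_signatures(
    d: DEPSets,
    feature_to_gene: dict[str, str | list[str]],
    induced_name: str = "KO_DOWN_SIGNATURE",
    repressed_name: str = "KO_UP_SIGNATURE",
) -> tuple[GeneSet, GeneSet]:
    """Map DEP features to gene-symbol signatures.

    The *induced* signature holds genes of the down-in-KO set (genes the
    target normally induces); *repressed* holds genes of the up set.
    Protein groups mapping to multiple gene symbols contribute all of
    them; unmapped features are dropped with a log entry.
    """
    def genes_for(features: frozenset[str]) -> frozenset[str]:
        out: set[str] = set()
        unmapped = 0
        for f in features:
            mapped = feature_to_gene.get(f)
            if mapped is None:
                unmapped += 1
                continue
            if isinstance(mapped, str):
                out.add(mapped)
            else:
                if len(mapped) > 1:
                    logger.info(
                        "feature %s maps to %d gene symbols; all kept",
                        f, len(mapped),
                    )
                out.update(mapped)
        if unmapped:
            logger.info("extract_signatures: %d unmapped features dropped",
                        unmapped)
        return frozenset(out)

    induced = GeneSet(name=induced_name, genes=genes_for(d.down))
    repressed = GeneSet(name=repressed_name, genes=genes_for(d.up))
    return induced, repressed
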