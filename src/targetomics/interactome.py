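"""Controlled IP-MS interactor calling.

A five-group affinity-purification design — two experimental pulldowns
carrying the intact bait construct, two plain controls (e.g. IgG and
empty vector), and one domain-negative control expressing the bait with
the domain of interest deleted — is analyzed with the Perseus-style
recipe: log2 LFQ intensities, per-sample down-shifted-normal imputation
of missing values, pairwise Welch + BH enrichment tests, and a
two-criterion Boolean caller:

1. the protein is significantly enriched (q < q_max and log2fc >
   lfc_min) in EVERY experimental group versus EVERY control group, and
2. the protein is NOT significantly enriched in the domain-negative
   control versus any plain control.

A protein is called an interactor of the deleted domain iff both hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffprot import welch_contrast
from .io_tables import ConsistencyError, DesignError, QuantMatrix

logger = logging.getLogger("targetomics")

ROLE_EXPERIMENTAL = "experimental"
ROLE_CONTROL = "control"
ROLE_DOMAIN_NEGATIVE = "domain_negative_control"
_VALID_ROLES = {ROLE_EXPERIMENTAL, ROLE_CONTROL, ROLE_DOMAIN_NEGATIVE}


@dataclass
class IPMSDesign:
    """Group roles and replicate membership for an IP-MS experiment."""

    roles: dict[str, str]
    replicates: dict[str, list[str]]

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values()} - _VALID_ROLES
        if bad:
            raise DesignError(f"unknown roles: {sorted(bad)}")
        if not self.experimental_groups:
            raise DesignError("design needs >= 1 experimental group")
        if len(self.plain_controls) < 2:
            raise DesignError("design needs >= 2 plain control groups")
        if len(self.domain_negative_controls) > 1:
            raise DesignError("at most one domain-negative control group")
        seen: set[str] = set()
        for g, reps in self.replicates.items():
            if g not in self.roles:
                raise DesignError(f"replicates listed for unknown group {g!r}")
            overlap = seen & set(reps)
            if overlap:
                raise DesignError(f"samples in multiple groups: {overlap}")
            seen.update(reps)

    @property
    def experimental_groups(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == ROLE_EXPERIMENTAL]

    @property
    def plain_controls(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == ROLE_CONTROL]

    @property
    def domain_negative_controls(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == ROLE_DOMAIN_NEGATIVE]

    @property
    def control_groups(self) -> list[str]:
        """All controls: plain plus the domain-negative one."""
        return self.plain_controls + self.domain_negative_controls

    def design_map(self) -> dict[str, str]:
        return {s: g for g, reps in self.replicates.items() for s in reps}


@dataclass
class ImputationParams:
    """Down-shifted-normal imputation parameters (per-sample scale).

    Missing values are drawn from Normal(mean_obs - downshift * sd_obs,
    (width * sd_obs)^2) using each sample's observed log2 intensities —
    the standard missing-not-at-random model for intensities below the
    detection limit.
    """

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


def impute_missing(m: QuantMatrix, params: ImputationParams) -> QuantMatrix:
    """Impute missing log2 intensities per sample from a down-shifted
    normal distribution; observed entries are untouched.

    Deterministic under ``params.seed``.  Raises if any sample has fewer
    than two observed values (no sd to anchor the distribution).
    """
    if not m.log_scale:
        raise ValueError("impute_missing expects a log2-scale matrix")
    rng = np.random.default_rng(params.seed)
    data = m.data.copy()
    for s in data.columns:
        col = data[s]
        obs = col.dropna()
        if len(obs) < 2:
            raise ValueError(
                f"sample {s!r} has {len(obs)} observed values; "
                "cannot fit imputation distribution"
            )
        mu = obs.mean()
        sd = obs.std(ddof=1)
        mask = col.isna()
        n_miss = int(mask.sum())
        if n_miss:
            draws = rng.normal(
                mu - params.downshift * sd, params.width * sd, size=n_miss
            )
            data.loc[mask, s] = draws
    return QuantMatrix(data=data, design=dict(m.design), log_scale=True)


POOLED_CONTROL = "__pooled_control__"


def pairwise_enrichment(
    m: QuantMatrix, design: IPMSDesign, pooled_controls: bool = False
) -> dict[tuple[str, str], pd.DataFrame]:
    """Welch + BH contrasts for every pair the caller needs.

    Computes each experimental group versus each control group, plus the
    domain-negative control versus each plain control.  Keys are ordered
    (enriched-candidate group, reference group); log2fc > 0 means higher
    in the first group.  With ``pooled_controls`` the experimental
    contrasts run against all control samples merged into one group
    (key ``(exp, POOLED_CONTROL)``); the domain-negative-vs-plain
    contrasts stay pairwise.
    """
    if m.data.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    results: dict[tuple[str, str], pd.DataFrame] = {}
    if pooled_controls:
        pooled_design = {
            s: (POOLED_CONTROL if g in design.control_groups else g)
            for s, g in m.design.items()
        }
        pooled = QuantMatrix(
            data=m.data, design=pooled_design, log_scale=True
        )
        for e in design.experimental_groups:
            results[(e, POOLED_CONTROL)] = welch_contrast(
                pooled, e, POOLED_CONTROL
            )
    else:
        for e in design.experimental_groups:
            for c in design.control_groups:
                results[(e, c)] = welch_contrast(m, e, c)
    for d in design.domain_negative_controls:
        for c in design.plain_controls:
            results[(d, c)] = welch_contrast(m, d, c)
    return results


@dataclass
class InteractorCalls:
    """Per-protein criterion flags; ``called = criterion1 & criterion2``."""

    table: pd.DataFrame

    @property
    def called(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["called"]])


def call_interactors(
    results: dict[tuple[str, str], pd.DataFrame],
    design: IPMSDesign,
    q_max: float = 0.05,
    lfc_min: float = 2.0,
    criterion2_q_only: bool = False,
) -> InteractorCalls:
    """Apply the two-criterion Boolean interactor logic.

    criterion 1: enriched (q < q_max AND log2fc > lfc_min) in every
    experimental-vs-control contrast; criterion 2: the domain-negative
    control is NOT enriched versus any plain control (same compound
    threshold by default; ``criterion2_q_only`` switches criterion 2 to
    q alone).
    """
    pooled = any(
        (e, POOLED_CONTROL) in results for e in design.experimental_groups
    )
    if pooled:
        required = [(e, POOLED_CONTROL) for e in design.experimental_groups]
    else:
        required = [
            (e, c)
            for e in design.experimental_groups
            for c in design.control_groups
        ]
    dnc_pairs = [
        (d, c)
        for d in design.domain_negative_controls
        for c in design.plain_controls
    ]
    for pair in required + dnc_pairs:
        if pair not in results:
            raise ConsistencyError(f"missing contrast {pair}")

    index = results[required[0]].index
    c1 = pd.Series(True, index=index)
    for pair in required:
        r = results[pair]
        c1 &= (r["q"] < q_max) & (r["log2fc"] > lfc_min)

    c2 = pd.Series(True, index=index)
    for pair in dnc_pairs:
        r = results[pair]
        if criterion2_q_only:
            enriched = (r["q"] < q_max) & (r["log2fc"] > 0)
        else:
            enriched = (r["q"] < q_max) & (r["log2fc"] > lfc_min)
        c2 &= ~enriched.fillna(False)

    table = pd.DataFrame(
        {
            "criterion1_pass": c1.fillna(False),
            "criterion2_pass": c2.fillna(False),
        }
    )
    table["called"] = table["criterion1_pass"] & table["criterion2_pass"]
    for (a, b), r in results.items():
        table[f"log2fc_{a}_vs_{b}"] = r["log2fc"]
        table[f"q_{a}_vs_{b}"] = r["q"]
    return InteractorCalls(table=table)
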