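"""Upstream-regulator scoring over a signed causal network.

Given a signed regulator->target network (+1 activating, -1 inhibiting)
and the observed direction (+1 up, -1 down) of each differential
feature, a regulator's activation z is the direction-consistency
statistic

    z = sum_t sign(edge_t) * direction(t) / sqrt(n_overlap)

over its targets present in the observed set: +sqrt(n) at full
consistency with activation, -sqrt(n) at full consistency with
inhibition.  Overlap significance is the upper-tail hypergeometric
probability of observing at least n_overlap of the regulator's targets
in the differential set.  The knowledge content (the network) is a
user-supplied table; only the statistics are provided here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import RegulatorNetwork

logger = logging.getLogger("targetomics")


@dataclass
class RegulatorScore:
    regulator: str
    n_overlap: int
    activation_z: float
    overlap_p: float = np.nan


def activation_z(
    network: RegulatorNetwork, observed: dict[str, int]
) -> list[RegulatorScore]:
    """Direction-consistency activation z per regulator.

    ``observed`` maps each differential gene to its direction (+1 higher
    with the regulator active, -1 lower).  Regulators with no target in
    ``observed`` are omitted.  Scores are sorted by z descending, ties
    broken by regulator symbol.
    """
    bad = {d for d in observed.values()} - {1, -1}
    if bad:
        raise ValueError(f"directions must be +1/-1, got {sorted(bad)}")
    scores = []
    for reg in sorted(network.regulators()):
        targets = network.targets_of(reg)
        hits = [(t, s) for t, s in targets.items() if t in observed]
        if not hits:
            continue
        consistency = sum(s * observed[t] for t, s in hits)
        z = consistency / np.sqrt(len(hits))
        scores.append(
            RegulatorScore(regulator=reg, n_overlap=len(hits),
                           activation_z=float(z))
        )
    scores.sort(key=lambda r: (-r.activation_z, r.regulator))
    return scores


def regulator_overlap_p(
    network: RegulatorNetwork,
    observed_genes: set[str],
    universe_size: int,
) -> dict[str, float]:
    """Upper-tail hypergeometric overlap p per regulator.

    With a universe of N genes, K observed differential genes and a
    regulator with n targets (within the universe), the p-value is
    P[X >= n_overlap] for X ~ Hypergeom(N, K, n).
    """
    n_obs = len(observed_genes)
    if universe_size < n_obs:
        raise ValueError("universe smaller than observed set")
    out = {}
    for reg in sorted(network.regulators()):
        targets = set(network.targets_of(reg))
        if len(targets) > universe_size:
            raise ValueError(
                f"{reg}: {len(targets)} targets exceed universe "
                f"{universe_size}"
            )
        k = len(targets & observed_genes)
        if k == 0:
            out[reg] = 1.0
            continue
        # P[X >= k] = sf(k - 1)
        out[reg] = float(
            stats.hypergeom.sf(k - 1, universe_size, n_obs, len(targets))
        )
    return out


def score_regulators(
    network: RegulatorNetwork,
    observed: dict[str, int],
    universe_size: int,
) -> list[RegulatorScore]:
    """Activation z plus overlap p for every regulator with >= 1 target
    in the observed set, sorted by z descending."""
    pvals = regulator_overlap_p(network, set(observed), universe_size)
    scores = activation_z(network, observed)
    for s in scores:
        s.overlap_p = pvals[s.regulator]
    return scores


def link_interactors_to_kinases(
    network: RegulatorNetwork,
    interactors: set[str],
    kinases: set[str],
    kinase_activities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bipartite activating edges from interactor candidates to kinases.

    Emits (interactor, kinase) rows for every +1 network edge whose
    source is a called interactor and whose target is a quantified
    kinase; inhibitory edges are excluded (the link of interest is
    direct activation).  If ``kinase_activities`` (kinase-indexed, one
    column per contrast) is given, the kinase's per-contrast activities
    are appended.
    """
    rows = []
    for reg, tgt, sign in sorted(network.edges):
        if sign == 1 and reg in interactors and tgt in kinases:
            rows.append({"interactor": reg, "kinase": tgt})
    out = pd.DataFrame(rows, columns=["interactor", "kinase"])
    if kinase_activities is not None and not out.empty:
        for col in kinase_activities.columns:
            out[f"activity_{col}"] = out["kinase"].map(
                kinase_activities[col]
            )
    return out
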