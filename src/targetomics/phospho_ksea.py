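"""Phosphosite filtering, protein normalization and kinase activity
inference (KSEA).

Site-level log2(Ctrl/KO) ratios confound kinase signal with the
abundance change of the carrier protein, so each site ratio is
normalized by subtracting the matched protein's log2 ratio from the
label-free proteome before substrate-set averaging.  A kinase's
activity change is the arithmetic mean of its annotated substrate-site
ratios (sites at p < 0.05), reported only when at least
``min_substrates`` (default 5) substrate sites were quantified.

Orientation: ratios are Ctrl minus KO on the log2 scale, so a positive
activity means the kinase is more active in control cells — i.e.
activated by the knocked-out protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffprot import welch_contrast
from .io_tables import (
    KinaseSubstrateMap,
    PhosphoSiteRecord,
    QuantMatrix,
    sites_to_quant_matrix,
)

logger = logging.getLogger("targetomics")


def filter_sites(
    records: list[PhosphoSiteRecord], min_loc_prob: float = 0.75
) -> list[PhosphoSiteRecord]:
    """Keep confidently localized sites: probability strictly > cutoff."""
    kept = [r for r in records if r.localization_probability > min_loc_prob]
    if len(kept) < len(records):
        logger.info(
            "filter_sites: %d/%d sites below localization probability %g",
            len(records) - len(kept), len(records), min_loc_prob,
        )
    return kept


def site_contrasts(
    records: list[PhosphoSiteRecord],
    design: dict[str, str],
    group_ctrl: str,
    group_ko: str,
) -> pd.DataFrame:
    """Per-site raw log2(Ctrl/KO) ratio and Welch p-value.

    Returns a DataFrame indexed by site_id with columns ``protein_id``,
    ``residue``, ``position``, ``raw_log2_ratio`` and ``p``.  Sites with
    fewer than two valid values in either group are dropped with a log
    entry.
    """
    qm = sites_to_quant_matrix(records, design)
    logged = QuantMatrix(
        data=np.log2(qm.data), design=dict(design), log_scale=True
    )
    res = welch_contrast(logged, group_ctrl, group_ko)
    meta = pd.DataFrame(
        {
            "protein_id": {r.site_id: r.protein_id for r in records},
            "residue": {r.site_id: r.residue for r in records},
            "position": {r.site_id: r.position for r in records},
        }
    )
    out = meta.join(res[["log2fc", "p"]]).rename(
        columns={"log2fc": "raw_log2_ratio"}
    )
    dropped = out["p"].isna()
    if dropped.any():
        logger.info(
            "site_contrasts: %d sites dropped (<2 valid values per group)",
            int(dropped.sum()),
        )
    out = out[~dropped]
    out.index.name = "site_id"
    return out


def normalize_to_protein(
    site_ratios: pd.DataFrame,
    protein_log2_ratio: pd.Series,
    drop_unquantified: bool = True,
) -> pd.DataFrame:
    """Subtract the carrier protein's log2 ratio from each site ratio.

    ``protein_log2_ratio`` must be in the same Ctrl-minus-KO orientation
    (this cannot be verified here — caller contract).  Sites whose
    protein is unquantified are flagged ``protein_quantified=False`` and
    dropped by default.
    """
    out = site_ratios.copy()
    out["protein_log2_ratio"] = out["protein_id"].map(protein_log2_ratio)
    out["protein_quantified"] = out["protein_log2_ratio"].notna()
    out["normalized_log2_ratio"] = (
        out["raw_log2_ratio"] - out["protein_log2_ratio"]
    )
    n_missing = int((~out["protein_quantified"]).sum())
    if n_missing:
        logger.info(
            "normalize_to_protein: %d sites lack a protein ratio%s",
            n_missing, " (excluded)" if drop_unquantified else " (flagged)",
        )
    if drop_unquantified:
        out = out[out["protein_quantified"]]
    return out


@dataclass
class KinaseActivityRecord:
    """Inferred activity change of one kinase in one contrast."""

    kinase: str
    n_sites: int
    activity_log2: float
    contrast_id: str = ""


def ksea_scores(
    site_ratios: pd.DataFrame,
    ksmap: KinaseSubstrateMap,
    min_substrates: int = 5,
    p_max: float = 0.05,
    ratio_column: str = "normalized_log2_ratio",
    contrast_id: str = "",
) -> list[KinaseActivityRecord]:
    """Mean substrate-site ratio per kinase, gated on substrate count.

    Substrate sites are exact (protein, residue, position) matches in
    the kinase-substrate map with site p < p_max.  Kinases with fewer
    than ``min_substrates`` qualifying sites are omitted.
    """
    if not ksmap.edges:
        logger.warning("ksea_scores: empty kinase-substrate map")
        return []
    if ratio_column not in site_ratios.columns:
        raise KeyError(f"missing ratio column {ratio_column!r}")
    usable = site_ratios[site_ratios["p"] < p_max]
    by_site: dict[tuple[str, str, int], float] = {
        (row.protein_id, row.residue, int(row.position)): getattr(
            row, ratio_column
        )
        for row in usable.itertuples()
    }
    records = []
    for kinase in sorted(ksmap.kinases()):
        ratios = [
            by_site[key]
            for key in ksmap.substrates_of(kinase)
            if key in by_site and not np.isnan(by_site[key])
        ]
        if len(ratios) < min_substrates:
            continue
        records.append(
            KinaseActivityRecord(
                kinase=kinase,
                n_sites=len(ratios),
                activity_log2=float(np.mean(ratios)),
                contrast_id=contrast_id,
            )
        )
    return records


def ksea_z_scores(
    site_ratios: pd.DataFrame,
    ksmap: KinaseSubstrateMap,
    min_substrates: int = 5,
    p_max: float = 0.05,
    ratio_column: str = "normalized_log2_ratio",
) -> pd.DataFrame:
    """Optional secondary score: the KSEA z-statistic
    (mean_set - mean_all) * sqrt(m) / sd_all, where mean_all/sd_all are
    over all qualifying sites.  Clearly distinct from the primary plain
    mean in :func:`ksea_scores`.
    """
    usable = site_ratios[site_ratios["p"] < p_max]
    all_ratios = usable[ratio_column].dropna()
    mean_all = all_ratios.mean()
    sd_all = all_ratios.std(ddof=1)
    by_site = {
        (row.protein_id, row.residue, int(row.position)): getattr(
            row, ratio_column
        )
        for row in usable.itertuples()
    }
    rows = []
    for kinase in sorted(ksmap.kinases()):
        ratios = [
            by_site[key]
            for key in ksmap.substrates_of(kinase)
            if key in by_site and not np.isnan(by_site[key])
        ]
        m = len(ratios)
        if m < min_substrates:
            continue
        z = (np.mean(ratios) - mean_all) * np.sqrt(m) / sd_all
        rows.append((kinase, m, float(z)))
    return pd.DataFrame(
        rows, columns=["kinase", "n_sites", "ksea_z"]
    ).set_index("kinase")


def consensus_kinases(
    records_by_contrast: dict[str, list[KinaseActivityRecord]],
) -> tuple[frozenset[str], pd.DataFrame]:
    """Kinases quantified in all contrasts and those activated in all.

    Returns (activated set, wide table of per-contrast activities for
    the overlap).  A kinase is *activated* when its activity_log2 is
    positive in every contrast.
    """
    if len(records_by_contrast) < 2:
        raise ValueError("consensus_kinases needs >= 2 contrasts")
    frames = {
        cid: pd.Series(
            {r.kinase: r.activity_log2 for r in recs}, dtype=float
        )
        for cid, recs in records_by_contrast.items()
    }
    table = pd.DataFrame(frames).dropna()
    table.index.name = "kinase"
    activated = frozenset(table.index[(table > 0).all(axis=1)])
    return activated, table
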