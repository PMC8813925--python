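"""Synthetic generators for every pipeline input, with planted truth.

Each generator emulates one data layer of the study design — a
label-free proteome with a control and several knockout clones, a
five-group IP-MS pulldown, a phosphoproteome whose site ratios confound
kinase signal with protein abundance, and a staged cohort with
dosage-coupled expression, planted gene-set activity and activity-linked
survival — and returns the generated object together with a truth table
describing what was planted.  All generators are bit-for-bit
deterministic under their seed.

Defaults reflect the emulated study conditions: 3 knockout clones plus
control at 3 replicates each, 10% differential features at |log2FC| =
1.5, log-normal LFQ intensities (log2 mean 25, sd 2), residual noise sd
0.4, and intensity-dependent (logistic, MNAR) missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import (
    Cohort,
    GeneSet,
    KinaseSubstrateMap,
    PhosphoSiteRecord,
    QuantMatrix,
)
from .interactome import (
    IPMSDesign,
    ROLE_CONTROL,
    ROLE_DOMAIN_NEGATIVE,
    ROLE_EXPERIMENTAL,
)

logger = logging.getLogger("targetomics")


@dataclass
class SimParams:
    """Shared simulation parameters.

    ``missing_model`` is (midpoint, slope) of a logistic on log2
    intensity: P(missing | x) = 1 / (1 + exp(slope * (x - midpoint))),
    so low-abundance features go missing more often (MNAR).
    """

    n_features: int = 2000
    n_replicates: int = 3
    n_clones: int = 3
    n_tech_runs: int = 2
    frac_de: float = 0.10
    effect_log2: float = 1.5
    intensity_log2_mean: float = 25.0
    intensity_log2_sd: float = 2.0
    noise_sd: float = 0.4
    missing_model: tuple[float, float] = (19.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.intensity_log2_sd <= 0 or self.noise_sd < 0:
            raise ValueError("sds must be positive")
        if self.n_replicates < 3:
            raise ValueError("need >= 3 replicates per group")


@dataclass
class TruthTable:
    """Planted ground truth for one simulated data set.

    ``features`` is indexed by feature / kinase / gene id with the
    labels relevant to the generator that produced it; optional
    sample-level fields carry per-sample latent values.
    """

    features: pd.DataFrame
    sample_activity: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def _missing_mask(
    rng: np.random.Generator, log2_intensity: np.ndarray,
    midpoint: float, slope: float,
) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(slope * (log2_intensity - midpoint)))
    return rng.random(log2_intensity.shape) < p


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def simulate_proteome(params: SimParams) -> tuple[QuantMatrix, TruthTable]:
    """Simulate a control + k-clone label-free proteome.

    Differential features are shifted by +/- ``effect_log2`` in every
    clone group (consistent direction); intensities are log-normal with
    per-run measurement noise (``noise_sd``), and missingness follows
    the logistic-in-intensity model at the run level.

    Each biological replicate is measured in ``n_tech_runs`` LC-MS/MS
    runs (columns ``<group>_r<i>_run<j>``), mirroring the emulated
    acquisition design; the run->replicate map is returned in
    ``truth.extras["run_map"]`` for technical-run averaging before
    testing.
    """
    rng = np.random.default_rng(params.seed)
    groups = ["ctrl"] + [f"ko{i + 1}" for i in range(params.n_clones)]
    features = [f"P{i:05d}" for i in range(params.n_features)]
    n_de = int(round(params.frac_de * params.n_features))
    is_de = np.zeros(params.n_features, dtype=bool)
    is_de[:n_de] = True
    direction = np.zeros(params.n_features, dtype=int)
    direction[:n_de] = rng.choice([-1, 1], size=n_de)

    base = rng.normal(
        params.intensity_log2_mean, params.intensity_log2_sd,
        size=params.n_features,
    )
    cols = {}
    design = {}
    run_map = {}
    mid, slope = params.missing_model
    for g in groups:
        shift = (
            direction * params.effect_log2 if g != "ctrl"
            else np.zeros(params.n_features)
        )
        for r in range(params.n_replicates):
            rep = f"{g}_r{r + 1}"
            for j in range(params.n_tech_runs):
                sample = (
                    rep if params.n_tech_runs == 1 else f"{rep}_run{j + 1}"
                )
                design[sample] = g
                run_map[sample] = rep
                log2_vals = base + shift + rng.normal(
                    0.0, params.noise_sd, size=params.n_features
                )
                vals = np.exp2(log2_vals)
                vals[_missing_mask(rng, log2_vals, mid, slope)] = np.nan
                cols[sample] = vals
    data = pd.DataFrame(cols, index=features)
    truth = TruthTable(
        features=pd.DataFrame(
            {
                "is_de": is_de,
                "direction": direction,
                "effect_log2": np.where(
                    is_de, direction * params.effect_log2, 0.0
                ),
            },
            index=features,
        ),
        extras={"run_map": run_map},
    )
    return QuantMatrix(data=data, design=design), truth


# ---------------------------------------------------------------------------
# IP-MS
# ---------------------------------------------------------------------------

def default_ipms_design(n_replicates: int = 4) -> IPMSDesign:
    """The five-group pulldown layout: two experimental groups carrying
    the intact bait, two plain controls, one domain-negative control.

    Four replicates per group, matching the emulated 20-run
    acquisition over five pulldown conditions."""
    groups = {
        "G1": ROLE_CONTROL,
        "G2": ROLE_CONTROL,
        "G4": ROLE_DOMAIN_NEGATIVE,
        "G3": ROLE_EXPERIMENTAL,
        "G5": ROLE_EXPERIMENTAL,
    }
    replicates = {
        g: [f"{g}_r{r + 1}" for r in range(n_replicates)] for g in groups
    }
    return IPMSDesign(roles=groups, replicates=replicates)


def simulate_ipms(
    design: IPMSDesign,
    params: SimParams,
    n_true: int = 20,
    n_decoy: int = 10,
    separation_log2: float = 5.0,
) -> tuple[QuantMatrix, TruthTable]:
    """Simulate a controlled IP-MS pulldown with planted interactors.

    True interactors are present at high intensity only in the
    experimental groups (missing, i.e. below detection, in every
    control).  Decoys bind the domain retained by the domain-negative
    construct: high in the experimental groups AND the domain-negative
    control, missing in the plain controls.  Background proteins are
    uniform across groups with MNAR missingness.
    """
    rng = np.random.default_rng(params.seed)
    n_bg = params.n_features
    feats = (
        [f"TRUE{i:03d}" for i in range(n_true)]
        + [f"DECOY{i:03d}" for i in range(n_decoy)]
        + [f"BG{i:05d}" for i in range(n_bg)]
    )
    base = rng.normal(
        params.intensity_log2_mean, params.intensity_log2_sd, size=n_bg
    )
    planted_level = params.intensity_log2_mean + separation_log2
    exp_groups = set(design.experimental_groups)
    dnc_groups = set(design.domain_negative_controls)
    mid, slope = params.missing_model

    cols = {}
    for g, reps in design.replicates.items():
        for s in reps:
            vals = np.full(len(feats), np.nan)
            # planted proteins: detected only where their domain is present
            present_true = g in exp_groups
            present_decoy = g in exp_groups or g in dnc_groups
            for i in range(n_true):
                if present_true:
                    vals[i] = planted_level + rng.normal(0, params.noise_sd)
            for i in range(n_decoy):
                if present_decoy:
                    vals[n_true + i] = planted_level + rng.normal(
                        0, params.noise_sd
                    )
            bg = base + rng.normal(0, params.noise_sd, size=n_bg)
            bg[_missing_mask(rng, bg, mid, slope)] = np.nan
            vals[n_true + n_decoy:] = bg
            cols[s] = np.exp2(vals)
    data = pd.DataFrame(cols, index=feats)
    truth = TruthTable(
        features=pd.DataFrame(
            {
                "is_true_interactor": [True] * n_true
                + [False] * (n_decoy + n_bg),
                "is_decoy": [False] * n_true + [True] * n_decoy
                + [False] * n_bg,
            },
            index=feats,
        ),
        extras={"separation_log2": separation_log2},
    )
    return QuantMatrix(data=data, design=design.design_map()), truth


# ---------------------------------------------------------------------------
# Phosphoproteome
# ---------------------------------------------------------------------------

def simulate_phospho(
    ksmap: KinaseSubstrateMap,
    params: SimParams,
    shifted_kinases: dict[str, float],
    protein_shifts: dict[str, float] | None = None,
    n_background_sites: int = 200,
    frac_low_localization: float = 0.2,
) -> tuple[list[PhosphoSiteRecord], QuantMatrix, TruthTable]:
    """Simulate phosphosite and matched protein tables.

    Each substrate site's control-vs-KO log2 ratio is the sum of its
    kinase's planted activity shift and its carrier protein's abundance
    shift, plus noise — so protein normalization is required to recover
    the pure kinase signal.  The matched protein matrix carries only the
    abundance shifts.  A stated fraction of sites receives a
    localization probability below 0.75.

    Groups are ``ctrl`` and one ``ko<i>`` per clone, ``n_replicates``
    samples each; ratios are oriented Ctrl - KO, so a positive kinase
    shift means the kinase is more active in control.
    """
    for k in shifted_kinases:
        if not ksmap.substrates_of(k):
            raise ValueError(f"shifted kinase {k!r} absent from map")
    protein_shifts = dict(protein_shifts or {})
    rng = np.random.default_rng(params.seed)

    # site catalog: all mapped substrate sites plus unmapped background
    site_rows = []
    for kin, prot, res, pos in sorted(ksmap.edges):
        site_rows.append((f"{prot}_{res}{pos}", prot, res, pos, kin))
    for i in range(n_background_sites):
        site_rows.append((f"BGSITE{i:04d}_S1", f"BGPROT{i:04d}", "S", 1, None))

    groups = ["ctrl"] + [f"ko{i + 1}" for i in range(params.n_clones)]
    design = {
        f"{g}_r{r + 1}": g
        for g in groups for r in range(params.n_replicates)
    }

    seen: dict[str, int] = {}
    records = []
    truth_rows = []
    low_loc = rng.random(len(site_rows)) < frac_low_localization
    for idx, (sid, prot, res, pos, kin) in enumerate(site_rows):
        if sid in seen:  # same site annotated for several kinases
            continue
        seen[sid] = idx
        kin_shift = shifted_kinases.get(kin, 0.0) if kin else 0.0
        prot_shift = protein_shifts.get(prot, 0.0)
        base = rng.normal(
            params.intensity_log2_mean, params.intensity_log2_sd
        )
        intens = {}
        for s, g in design.items():
            # ctrl carries the planted shifts; KO clones sit at baseline
            shift = (kin_shift + prot_shift) if g == "ctrl" else 0.0
            intens[s] = float(
                np.exp2(base + shift + rng.normal(0, params.noise_sd))
            )
        loc = (
            rng.uniform(0.2, 0.75) if low_loc[idx]
            else rng.uniform(0.8, 1.0)
        )
        records.append(
            PhosphoSiteRecord(
                site_id=sid, protein_id=prot, residue=res, position=pos,
                localization_probability=float(loc), intensities=intens,
            )
        )
        truth_rows.append(
            (sid, kin, kin_shift, prot_shift, bool(low_loc[idx]))
        )

    # matched protein matrix: abundance shifts only
    proteins = sorted({r.protein_id for r in records})
    pbase = rng.normal(
        params.intensity_log2_mean, params.intensity_log2_sd,
        size=len(proteins),
    )
    pcols = {}
    for s, g in design.items():
        shifts = np.array([
            protein_shifts.get(p, 0.0) if g == "ctrl" else 0.0
            for p in proteins
        ])
        pcols[s] = np.exp2(
            pbase + shifts + rng.normal(0, params.noise_sd,
                                        size=len(proteins))
        )
    protein_matrix = QuantMatrix(
        data=pd.DataFrame(pcols, index=proteins), design=dict(design)
    )
    truth = TruthTable(
        features=pd.DataFrame(
            truth_rows,
            columns=["site_id", "kinase", "kinase_shift_log2",
                     "protein_shift_log2", "low_localization"],
        ).set_index("site_id"),
        extras={"shifted_kinases": dict(shifted_kinases),
                "protein_shifts": protein_shifts},
    )
    return records, protein_matrix, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    params: SimParams,
    signature: GeneSet,
    n_samples: int = 500,
    n_genes: int = 300,
    n_stages: int = 4,
    stage_effect: float = 0.5,
    activity_sd: float = 1.0,
    loading: float = 1.0,
    dosage_gene: str | None = None,
    dosage_r: float = 0.7,
    survival_link: float = 0.0,
    base_hazard: float = 0.02,
    censor_time: float = 120.0,
) -> tuple[Cohort, TruthTable]:
    """Simulate a staged cohort with planted gene-set activity.

    Per sample: latent activity = stage_effect * stage_code +
    Normal(0, activity_sd); signature-gene expression = loading *
    activity + Normal(0, noise_sd); other genes are pure noise.  One
    designated gene's expression is coupled to its copy-number call at
    target Pearson correlation ``dosage_r``.  Survival times are
    exponential with log-hazard = log(base_hazard) + survival_link *
    standardized activity, censored uniformly on (0, censor_time].
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    missing_sig = set(signature.genes) - set(genes)
    if missing_sig:
        raise ValueError(
            f"signature genes outside the simulated universe: "
            f"{sorted(missing_sig)[:5]}"
        )
    if n_stages < 2:
        raise ValueError("need >= 2 ordered stages")
    samples = [f"S{i:04d}" for i in range(n_samples)]
    stages = rng.integers(0, n_stages, size=n_samples)
    activity = stage_effect * stages + rng.normal(
        0.0, activity_sd, size=n_samples
    )

    expr = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    sig_idx = [genes.index(g) for g in sorted(signature.genes)]
    for i in sig_idx:
        expr[i] = loading * activity + rng.normal(
            0.0, params.noise_sd, size=n_samples
        )

    # discrete copy-number calls; one gene dosage-coupled at target r
    cna = rng.choice(
        [-2, -1, 0, 1, 2], p=[0.02, 0.13, 0.55, 0.2, 0.1],
        size=(n_genes, n_samples),
    )
    if dosage_gene is not None:
        if dosage_gene not in genes:
            raise ValueError(f"dosage gene {dosage_gene!r} not simulated")
        gi = genes.index(dosage_gene)
        calls = cna[gi].astype(float)
        z_calls = (calls - calls.mean()) / calls.std()
        expr[gi] = dosage_r * z_calls + np.sqrt(
            max(0.0, 1.0 - dosage_r**2)
        ) * rng.normal(0.0, 1.0, size=n_samples)

    act_std = (activity - activity.mean()) / activity.std()
    hazard = base_hazard * np.exp(survival_link * act_std)
    event_time = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0.0, censor_time, size=n_samples)
    time = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(int)

    cohort = Cohort(
        expression=pd.DataFrame(expr, index=genes, columns=samples),
        stage=pd.Series(stages, index=samples),
        survival_time=pd.Series(time, index=samples),
        survival_event=pd.Series(event, index=samples),
        cna_calls=pd.DataFrame(cna, index=genes, columns=samples),
    )
    truth = TruthTable(
        features=pd.DataFrame(
            {"in_signature": [g in signature.genes for g in genes]},
            index=genes,
        ),
        sample_activity=pd.Series(activity, index=samples),
        extras={
            "stage_effect": stage_effect,
            "dosage_gene": dosage_gene,
            "dosage_r": dosage_r if dosage_gene else None,
            "survival_link": survival_link,
        },
    )
    return cohort, truth


def simulate_two_group_survival(
    n_per_group: int,
    hr: float,
    base_hazard: float = 0.02,
    censor_time: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential survival for two strata at an exact planted hazard
    ratio, with independent uniform censoring on (0, censor_time].

    Returns (times, events, group labels 'high'/'low'); the 'high' group
    carries hazard ``base_hazard * hr``.  The default follow-up window
    yields roughly half the subjects as events, the regime in which the
    observed/expected log-rank estimator of the hazard ratio is close
    to unbiased (long follow-up lets the low-hazard arm dominate late
    risk sets and compresses O/E toward 1).
    """
    rng = np.random.default_rng(seed)
    haz = np.concatenate([
        np.full(n_per_group, base_hazard * hr),
        np.full(n_per_group, base_hazard),
    ])
    groups = np.array(["high"] * n_per_group + ["low"] * n_per_group)
    event_time = rng.exponential(1.0 / haz)
    censor = rng.uniform(0.0, censor_time, size=2 * n_per_group)
    time = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(int)
    return time, event, groups


def random_kinase_substrate_map(
    n_kinases: int = 10,
    substrates_per_kinase: int = 10,
    seed: int = 0,
) -> KinaseSubstrateMap:
    """A synthetic kinase->substrate annotation with disjoint substrate
    proteins per kinase (one site per protein)."""
    rng = np.random.default_rng(seed)
    edges = set()
    prot_idx = 0
    for k in range(n_kinases):
        for _ in range(substrates_per_kinase):
            res = rng.choice(["S", "T", "Y"], p=[0.7, 0.2, 0.1])
            pos = int(rng.integers(1, 500))
            edges.add((f"KIN{k:02d}", f"SUB{prot_idx:04d}", str(res), pos))
            prot_idx += 1
    return KinaseSubstrateMap(edges=frozenset(edges))


def random_signature(
    n_genes_universe: int = 300, set_size: int = 50, seed: int = 0,
    name: str = "PLANTED_SET",
) -> GeneSet:
    """A random gene set drawn from the simulated cohort universe."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes_universe)]
    members = rng.choice(genes, size=set_size, replace=False)
    return GeneSet(name=name, genes=frozenset(str(g) for g in members))
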