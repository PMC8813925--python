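"""Typed readers and writers for every table the pipeline touches.

All on-disk formats are plain text: tab-separated values (UTF-8, lines
starting with ``#`` ignored) for matrices, phosphosites, kinase-substrate
maps, clinical annotations, copy-number calls and signed regulator
networks; GMT for gene sets.

Conventions
-----------
* Intensity matrices use the MaxQuant LFQ dialect: an intensity of 0 on
  disk means "not quantified" and is represented in memory as missing
  (NaN).  The conversion happens exactly once, at read time; in-memory
  matrices never contain observed zeros.
* All identifiers are opaque, case-sensitive strings.  Gene-symbol
  harmonization is the caller's concern.
* Phosphosite positions are 1-based in protein coordinates (``S62`` is
  the 62nd residue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("targetomics")

VALID_RESIDUES = frozenset({"S", "T", "Y"})
VALID_CNA_CALLS = frozenset({-2, -1, 0, 1, 2})


class FormatError(ValueError):
    """A file does not conform to its declared table format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. matrix and design) do not."""


class DesignError(ValueError):
    """An experimental design violates a structural requirement."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class QuantMatrix:
    """A feature x sample intensity matrix with a sample->group design.

    Parameters
    ----------
    data
        DataFrame indexed by feature id, columns are sample ids.  Missing
        values are NaN.  On the linear scale all present values must be
        non-negative; set ``log_scale=True`` after log2 transformation.
    design
        Mapping from sample id to group label.  Every sample column must
        have a group.
    log_scale
        Whether ``data`` holds log2 intensities (negatives allowed).
    """

    data: pd.DataFrame
    design: dict[str, str]
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        missing_design = [s for s in self.data.columns if s not in self.design]
        if missing_design:
            raise ConsistencyError(
                f"samples without a group label: {missing_design}"
            )
        if not self.log_scale:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative intensity in linear-scale matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def groups(self) -> dict[str, list[str]]:
        """Group label -> list of member sample ids (column order)."""
        out: dict[str, list[str]] = {}
        for s in self.data.columns:
            out.setdefault(self.design[s], []).append(s)
        return out

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.design[s] == group]


@dataclass
class PhosphoSiteRecord:
    """One phosphosite with per-sample intensities (NaN = missing)."""

    site_id: str
    protein_id: str
    residue: str
    position: int
    localization_probability: float
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValueError(
                f"{self.site_id}: residue {self.residue!r} not in S/T/Y"
            )
        if self.position < 1:
            raise ValueError(f"{self.site_id}: position must be >= 1")
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                f"{self.site_id}: localization probability "
                f"{self.localization_probability} outside [0, 1]"
            )


@dataclass
class GeneSet:
    """A named set of gene symbols with optional per-gene weights."""

    name: str
    genes: frozenset[str]
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if self.weights is not None:
            extra = set(self.weights) - self.genes
            if extra:
                raise ValueError(
                    f"{self.name}: weights for non-member genes {sorted(extra)}"
                )

    def weight(self, gene: str) -> float:
        if self.weights is None:
            return 1.0
        return self.weights.get(gene, 1.0)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class KinaseSubstrateMap:
    """Kinase -> substrate phosphosite annotation edges."""

    edges: frozenset[tuple[str, str, str, int]]  # (kinase, protein, residue, pos)

    def __post_init__(self) -> None:
        for kin, prot, res, pos in self.edges:
            if res not in VALID_RESIDUES:
                raise ValueError(
                    f"edge ({kin}, {prot}, {res}, {pos}): bad residue {res!r}"
                )
        self.edges = frozenset(self.edges)

    def substrates_of(self, kinase: str) -> set[tuple[str, str, int]]:
        return {(p, r, pos) for k, p, r, pos in self.edges if k == kinase}

    def kinases(self) -> set[str]:
        return {k for k, _, _, _ in self.edges}


@dataclass
class RegulatorNetwork:
    """Signed regulator -> target edges (+1 activating, -1 inhibiting)."""

    edges: frozenset[tuple[str, str, int]]

    def __post_init__(self) -> None:
        pairs: dict[tuple[str, str], int] = {}
        for reg, tgt, sign in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"edge ({reg}, {tgt}): sign must be +1/-1")
            if (reg, tgt) in pairs and pairs[(reg, tgt)] != sign:
                raise ValueError(
                    f"conflicting signs for edge ({reg}, {tgt})"
                )
            pairs[(reg, tgt)] = sign
        self.edges = frozenset(self.edges)

    def targets_of(self, regulator: str) -> dict[str, int]:
        return {t: s for r, t, s in self.edges if r == regulator}

    def regulators(self) -> set[str]:
        return {r for r, _, _ in self.edges}


@dataclass
class Cohort:
    """Gene x sample expression plus clinical and copy-number layers.

    ``expression`` is log-scale (median-centerable); ``stage`` holds
    ordinal stage codes ordered along the disease course; ``cna_calls``
    are discrete GISTIC-style calls in -2..2 (2 = amplification,
    1 = gain).
    """

    expression: pd.DataFrame
    stage: pd.Series
    survival_time: pd.Series
    survival_event: pd.Series
    cna_calls: pd.DataFrame
    subtype: pd.Series | None = None

    def __post_init__(self) -> None:
        samples = list(self.expression.columns)
        for name, layer in (
            ("stage", self.stage),
            ("survival_time", self.survival_time),
            ("survival_event", self.survival_event),
        ):
            missing = [s for s in samples if s not in layer.index]
            if missing:
                raise ConsistencyError(
                    f"{name} missing samples: {missing[:5]}"
                )
        bad_events = set(self.survival_event.unique()) - {0, 1}
        if bad_events:
            raise ValueError(f"survival events outside {{0,1}}: {bad_events}")
        if (self.survival_time < 0).any():
            raise ValueError("negative survival time")
        bad_calls = set(np.unique(self.cna_calls.to_numpy())) - VALID_CNA_CALLS
        if bad_calls:
            raise ValueError(f"CNA calls outside -2..2: {sorted(bad_calls)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


# ---------------------------------------------------------------------------
# QuantMatrix I/O
# ---------------------------------------------------------------------------

def read_quant_matrix(path, intensity_prefix: str, design_path) -> QuantMatrix:
    """Read an intensity matrix TSV plus its sample->group design.

    The matrix file has one feature-id column (the first) and one
    intensity column per sample named ``<intensity_prefix><sample_id>``.
    Zeros are converted to missing (MaxQuant dialect).  The design file
    is a two-column TSV ``sample<TAB>group``.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature-id column plus intensities")
    id_col = df.columns[0]
    int_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not int_cols:
        raise FormatError(
            f"{path}: no columns with intensity prefix {intensity_prefix!r}"
        )
    data = df.set_index(id_col)[int_cols].astype(float)
    data.columns = [c[len(intensity_prefix):] for c in int_cols]
    data.index = data.index.astype(str)
    data.index.name = None
    if (data.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative intensity")
    data = data.replace(0.0, np.nan)

    ddf = _read_tsv(design_path)
    if ddf.shape[1] < 2:
        raise FormatError(f"{design_path}: need sample and group columns")
    design = dict(zip(ddf.iloc[:, 0].astype(str), ddf.iloc[:, 1].astype(str)))
    absent = [s for s in design if s not in data.columns]
    if absent:
        raise ConsistencyError(
            f"design samples not in matrix {path}: {absent}"
        )
    data = data[[s for s in data.columns if s in design]]
    return QuantMatrix(data=data, design=design)


def write_quant_matrix(
    m: QuantMatrix, path, intensity_prefix: str, design_path
) -> None:
    """Write a linear-scale matrix; missing values become 0 on disk."""
    if m.log_scale:
        raise ValueError("refusing to write a log-scale matrix as LFQ TSV")
    out = m.data.fillna(0.0).copy()
    out.columns = [f"{intensity_prefix}{s}" for s in out.columns]
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    pd.DataFrame(
        {"sample": list(m.design), "group": [m.design[s] for s in m.design]}
    ).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phosphosite I/O
# ---------------------------------------------------------------------------

_PHOSPHO_META = ["site_id", "protein_id", "residue", "position",
                 "localization_prob"]


def read_phosphosites(path) -> list[PhosphoSiteRecord]:
    """Read a phosphosite TSV; intensity columns follow the meta columns."""
    df = _read_tsv(path)
    missing = [c for c in _PHOSPHO_META if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _PHOSPHO_META]
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["site_id"])
        if sid in seen:
            raise ValueError(f"{path}: duplicate site_id {sid}")
        seen.add(sid)
        intens = {}
        for c in sample_cols:
            v = float(row[c])
            if v < 0:
                raise ValueError(f"{path}: negative intensity at {sid}/{c}")
            intens[c] = np.nan if v == 0 else v
        records.append(
            PhosphoSiteRecord(
                site_id=sid,
                protein_id=str(row["protein_id"]),
                residue=str(row["residue"]),
                position=int(row["position"]),
                localization_probability=float(row["localization_prob"]),
                intensities=intens,
            )
        )
    return records


def write_phosphosites(records: list[PhosphoSiteRecord], path) -> None:
    sample_cols: list[str] = []
    for r in records:
        for s in r.intensities:
            if s not in sample_cols:
                sample_cols.append(s)
    rows = []
    for r in records:
        row = {
            "site_id": r.site_id,
            "protein_id": r.protein_id,
            "residue": r.residue,
            "position": r.position,
            "localization_prob": r.localization_probability,
        }
        for s in sample_cols:
            v = r.intensities.get(s, np.nan)
            row[s] = 0.0 if pd.isna(v) else v
        rows.append(row)
    pd.DataFrame(rows, columns=_PHOSPHO_META + sample_cols).to_csv(
        path, sep="\t", index=False
    )


def sites_to_quant_matrix(
    records: list[PhosphoSiteRecord], design: dict[str, str]
) -> QuantMatrix:
    """Assemble site intensities into a QuantMatrix keyed by site_id."""
    data = pd.DataFrame(
        {r.site_id: r.intensities for r in records}
    ).T
    data.index.name = "site_id"
    data = data[[s for s in data.columns if s in design]]
    return QuantMatrix(data=data, design=dict(design))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields"
                )
            name, _desc, *genes = fields
            members = frozenset(g for g in genes if g)
            sets.append(GeneSet(name=name, genes=members))
    return sets


def write_gene_sets(sets: list[GeneSet], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Kinase-substrate map
# ---------------------------------------------------------------------------

def read_kinase_substrate_map(path) -> KinaseSubstrateMap:
    """Read kinase/protein_id/residue/position edges; duplicates collapse."""
    df = _read_tsv(path)
    required = ["kinase", "protein_id", "residue", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    edges = set()
    n_dup = 0
    for _, row in df.iterrows():
        edge = (
            str(row["kinase"]),
            str(row["protein_id"]),
            str(row["residue"]),
            int(row["position"]),
        )
        if edge in edges:
            n_dup += 1
        edges.add(edge)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edges", path, n_dup)
    return KinaseSubstrateMap(edges=frozenset(edges))


def write_kinase_substrate_map(ksmap: KinaseSubstrateMap, path) -> None:
    pd.DataFrame(
        sorted(ksmap.edges),
        columns=["kinase", "protein_id", "residue", "position"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regulator network
# ---------------------------------------------------------------------------

def read_regulator_network(path) -> RegulatorNetwork:
    df = _read_tsv(path)
    required = ["regulator", "target", "sign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    edges = {
        (str(r["regulator"]), str(r["target"]), int(r["sign"]))
        for _, r in df.iterrows()
    }
    return RegulatorNetwork(edges=frozenset(edges))


def write_regulator_network(net: RegulatorNetwork, path) -> None:
    pd.DataFrame(
        sorted(net.edges), columns=["regulator", "target", "sign"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort bundle
# ---------------------------------------------------------------------------

def read_cohort(expr_path, clinical_path, cna_path) -> Cohort:
    """Assemble a cohort from expression, clinical and CNA tables.

    Sample sets are reconciled by intersection across the three files;
    the number of dropped samples is logged rather than raised, because
    portal extracts rarely align perfectly.
    """
    expr = _read_tsv(expr_path).set_index("gene").astype(float)
    clin = _read_tsv(clinical_path).set_index("sample")
    cna = _read_tsv(cna_path).set_index("gene")
    expr.index.name = cna.index.name = clin.index.name = None

    shared = [s for s in expr.columns if s in clin.index and s in cna.columns]
    if not shared:
        raise ConsistencyError("no samples shared by expression/clinical/CNA")
    n_dropped = (
        len(set(expr.columns) | set(clin.index) | set(cna.columns))
        - len(shared)
    )
    if n_dropped:
        logger.info(
            "cohort reconciliation: kept %d samples, dropped %d",
            len(shared), n_dropped,
        )

    expr = expr[shared]
    clin = clin.loc[shared]
    cna = cna[shared].astype(int)

    events = clin["event"].astype(int)
    if not set(events.unique()) <= {0, 1}:
        raise ValueError(
            f"{clinical_path}: event values outside {{0,1}}"
        )
    bad = set(np.unique(cna.to_numpy())) - VALID_CNA_CALLS
    if bad:
        raise ValueError(f"{cna_path}: CNA calls outside -2..2: {sorted(bad)}")

    subtype = None
    if "subtype" in clin.columns:
        subtype = clin["subtype"].astype(str)
    return Cohort(
        expression=expr,
        stage=clin["stage_code"].astype(int),
        survival_time=clin["time"].astype(float),
        survival_event=events,
        cna_calls=cna,
        subtype=subtype,
    )


def write_cohort(c: Cohort, expr_path, clinical_path, cna_path) -> None:
    expr = c.expression.copy()
    expr.index.name = "gene"
    expr.to_csv(expr_path, sep="\t")
    clin = pd.DataFrame(
        {
            "sample": c.sample_ids,
            "stage_code": [c.stage[s] for s in c.sample_ids],
            "time": [c.survival_time[s] for s in c.sample_ids],
            "event": [c.survival_event[s] for s in c.sample_ids],
        }
    )
    if c.subtype is not None:
        clin["subtype"] = [c.subtype[s] for s in c.sample_ids]
    clin.to_csv(clinical_path, sep="\t", index=False)
    cna = c.cna_calls.copy()
    cna.index.name = "gene"
    cna.to_csv(cna_path, sep="\t")
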