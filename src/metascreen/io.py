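"""Domain containers and plain-text readers/writers.

Every format is deliberately text-only and round-trippable: expression as
genes x samples TSV with a two-column sample->group sidecar, gene sets as
GMT, survival as CSV, ChIP candidate tables as TSV, and single-cell counts
as MatrixMarket triplets with gene/barcode/cluster sidecars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("metascreen")

TUMOR = "tumor"
NORMAL = "normal"
GROUP_LABELS = (TUMOR, NORMAL)


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortMatrix:
    """One platform's log2-scale expression with tumor/normal labels.

    ``values`` is a genes x samples DataFrame; ``group`` maps every sample
    (column) to "tumor" or "normal".
    """

    cohort_id: str
    platform_id: str
    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.group = pd.Series(self.group)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols in cohort {self.cohort_id}: {dups}")
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ValueError(
                f"cohort {self.cohort_id}: samples without group label: {missing}"
            )
        bad = set(self.group.loc[list(self.values.columns)]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"cohort {self.cohort_id}: unknown group labels {sorted(bad)}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError(f"cohort {self.cohort_id}: non-finite expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_mask(self, label: str) -> np.ndarray:
        return (self.group.loc[list(self.values.columns)] == label).to_numpy()

    def arm_values(self, gene: str, label: str) -> np.ndarray:
        """Expression of one gene in one arm (tumor or normal)."""
        row = self.values.loc[gene].to_numpy(dtype=float)
        return row[self.sample_mask(label)]

    def n_arm(self, label: str) -> int:
        return int(self.sample_mask(label).sum())


def read_cohort_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    cohort_id: str | None = None,
    platform_id: str | None = None,
    log2: bool = False,
) -> CohortMatrix:
    """Read a genes x samples TSV (first column gene symbols, header sample IDs).

    Duplicate gene rows are collapsed by their mean (logged); gene symbols are
    uppercased. ``log2=True`` applies log2(x+1) for raw-scale inputs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.upper()
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path.name}: non-numeric value at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise ValueError(f"{path.name}: samples missing from group map: {missing}")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene rows by mean", path.name, n_dup)
        df = df.groupby(level=0, sort=False).mean()
    if log2:
        df = np.log2(df + 1.0)
    name = cohort_id or path.stem
    group = pd.Series({s: group_map[s] for s in df.columns})
    return CohortMatrix(name, platform_id or name, df, group)


def write_cohort_matrix(cm: CohortMatrix, path: str | Path, group_path: str | Path | None = None) -> None:
    path = Path(path)
    cm.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
    if group_path is None:
        group_path = path.with_suffix("").with_suffix(".groups.tsv")
    cm.group.loc[list(cm.values.columns)].rename("group").to_csv(
        group_path, sep="\t", index_label="sample"
    )


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_cohort_dir(directory: str | Path, log2: bool = False) -> list[CohortMatrix]:
    """Read every ``<id>.tsv`` + ``<id>.groups.tsv`` pair in a directory."""
    directory = Path(directory)
    cohorts = []
    for expr_path in sorted(directory.glob("*.tsv")):
        if expr_path.name.endswith(".groups.tsv"):
            continue
        group_path = expr_path.with_suffix("").with_suffix(".groups.tsv")
        if not group_path.exists():
            raise FileNotFoundError(f"no group sidecar for {expr_path.name}")
        cohorts.append(
            read_cohort_matrix(expr_path, read_group_map(group_path), log2=log2)
        )
    if not cohorts:
        raise FileNotFoundError(f"no cohort TSVs found under {directory}")
    return cohorts


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("no gene sets")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: GMT line has < 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen = set()
            for m in fields[2:]:
                m = m.strip().upper()
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            sets[name] = members
    if not sets:
        raise ValueError(f"{path.name}: no gene sets")
    return GeneSetCollection(sets, source=source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# ChIP candidate tables
# ---------------------------------------------------------------------------

@dataclass
class ChipTargetTable:
    """Rows of (gene, regulatory-potential score, dataset_id)."""

    table: pd.DataFrame  # columns: gene, score, dataset_id

    def __post_init__(self) -> None:
        required = {"gene", "score", "dataset_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"ChIP table needs columns {sorted(required)}")
        t = self.table.copy()
        t["gene"] = t["gene"].astype(str).str.upper()
        t["score"] = t["score"].astype(float)
        if (t["score"] < 0).any():
            raise ValueError("negative regulatory-potential score")
        if t.duplicated(subset=["gene", "dataset_id"]).any():
            raise ValueError("duplicate (gene, dataset_id) rows in ChIP table")
        self.table = t.reset_index(drop=True)

    def max_scores(self) -> pd.Series:
        """Per-gene maximum score across datasets."""
        return self.table.groupby("gene")["score"].max()


def read_chip_table(path: str | Path) -> ChipTargetTable:
    df = pd.read_csv(path, sep="\t")
    return ChipTargetTable(df)


def write_chip_table(table: ChipTargetTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Per-patient time (months), event indicator, and named covariates."""

    data: pd.DataFrame  # columns: time, event, <covariates...>

    def __post_init__(self) -> None:
        if not {"time", "event"}.issubset(self.data.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate covariate names")
        t = self.data["time"].astype(float)
        if (t <= 0).any() or not np.isfinite(t).all():
            raise ValueError("survival times must be positive and finite")
        ev = set(self.data["event"].astype(int).unique())
        if not ev.issubset({0, 1}):
            raise ValueError("event indicator must be 0/1")
        self.data = self.data.reset_index(drop=True)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def __len__(self) -> int:
        return len(self.data)


def read_survival_csv(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path)
    if "id" in df.columns:
        df = df.drop(columns=["id"])
    return SurvivalTable(df)


def write_survival_csv(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# single-cell matrices
# ---------------------------------------------------------------------------

@dataclass
class SingleCellMatrix:
    """Sparse cell x gene integer counts with per-cell cluster labels."""

    counts: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]
    cell_cluster: pd.Series  # index: barcode, value: cluster label

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("counts shape does not match barcodes x genes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        unlabeled = [b for b in self.barcodes if b not in self.cell_cluster.index]
        if unlabeled:
            raise ValueError(f"cells without cluster label: {unlabeled[:5]}")
        self.genes = [g.upper() for g in self.genes]

    def gene_counts(self, gene: str) -> np.ndarray:
        idx = self.genes.index(gene.upper())
        return np.asarray(self.counts[:, idx].todense()).ravel()

    def cluster_mask(self, cluster: str) -> np.ndarray:
        labels = self.cell_cluster.loc[self.barcodes].to_numpy()
        return labels == cluster


def read_single_cell(
    mtx: str | Path, genes: str | Path, barcodes: str | Path, clusters: str | Path
) -> SingleCellMatrix:
    """Read MatrixMarket counts (gene x cell, cellranger-style) plus sidecars."""
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx)).T)  # stored genes x cells
    gene_list = [line.split("\t")[0].strip() for line in open(genes) if line.strip()]
    bc_list = [line.strip() for line in open(barcodes) if line.strip()]
    cl = pd.read_csv(clusters, sep="\t", dtype=str)
    cluster = pd.Series(cl.iloc[:, 1].values, index=cl.iloc[:, 0].values)
    return SingleCellMatrix(mat, gene_list, bc_list, cluster)


def write_single_cell(scm: SingleCellMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(scm.counts.T))
    (directory / "genes.tsv").write_text("".join(f"{g}\n" for g in scm.genes))
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in scm.barcodes))
    with open(directory / "clusters.tsv", "w") as fh:
        fh.write("barcode\tcluster\n")
        for b in scm.barcodes:
            fh.write(f"{b}\t{scm.cell_cluster[b]}\n")


def read_single_cell_dir(directory: str | Path) -> SingleCellMatrix:
    d = Path(directory)
    return read_single_cell(
        d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "clusters.tsv"
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds driving every stage, mirroring the screening rules:

    co-expression requires r >= r_min and p < p_max in >= min_platforms
    platforms; ChIP candidates require a regulatory-potential score >=
    chip_score_min in at least one dataset; per-cohort diagnostic flagging
    uses AUC >= auc_diag_min; random-effects pooling is selected when
    I^2 > i2_random_threshold (percent).
    """

    gene_of_interest: str = "FOXM1"
    r_min: float = 0.30
    p_max: float = 0.05
    min_platforms: int = 20
    chip_score_min: float = 1.0
    auc_diag_min: float = 0.7
    i2_random_threshold: float = 50.0
    bias_p: float = 0.05
    minprop: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.gene_of_interest = self.gene_of_interest.upper()
        if not (0 < self.p_max < 1 and 0 <= self.bias_p <= 1):
            raise ValueError("p thresholds must lie in (0,1)")
        if not (-1 <= self.r_min <= 1):
            raise ValueError("r_min out of range")
        if not (0 < self.minprop < 0.5):
            raise ValueError("minprop must lie in (0, 0.5)")
        if not (0.5 <= self.auc_diag_min <= 1):
            raise ValueError("auc_diag_min out of range")
        if self.min_platforms < 1 or self.chip_score_min < 0:
            raise ValueError("invalid screen thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
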