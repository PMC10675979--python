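"""Triple-intersection transcriptional-target screen.

Candidate targets are genes that (i) carry a ChIP regulatory-potential
score >= 1 in at least one dataset, (ii) are co-expressed with the gene of
interest (Pearson r >= 0.30, p < 0.05) in at least 20 platforms, and
(iii) are over-expressed in tumors (pooled SMD > 0, p < 0.05). The three
sets are intersected exactly; bulk-correlation and single-cell
co-expression verification re-examine the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ChipTargetTable, CohortMatrix, SingleCellMatrix, TUMOR
from .meta import hedges_g_matrix, pool_dl_columns

logger = logging.getLogger("metascreen")


@dataclass
class ScreenResult:
    chip_candidates: set[str]
    ceg_consensus: set[str]
    ceg_counts: pd.Series  # per-gene number of platforms passed
    heg: set[str]
    heg_table: pd.DataFrame  # gene, k, pooled_smd, p
    intersection: set[str]
    evidence: pd.DataFrame  # gene, in_chip, in_ceg, in_heg, in_intersection

    def summary(self) -> dict[str, int]:
        return {
            "n_chip": len(self.chip_candidates),
            "n_ceg": len(self.ceg_consensus),
            "n_heg": len(self.heg),
            "n_intersection": len(self.intersection),
        }


# ---------------------------------------------------------------------------
# the three candidate sets
# ---------------------------------------------------------------------------

def chip_candidate_filter(tables, score_min: float = 1.0) -> set[str]:
    """Genes whose maximum regulatory-potential score across datasets is
    >= score_min (boundary inclusive)."""
    if score_min < 0:
        raise ValueError("score_min must be nonnegative")
    if isinstance(tables, ChipTargetTable):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ValueError("no ChIP tables supplied")
    combined = pd.concat([t.table for t in tables], ignore_index=True)
    if combined.empty:
        return set()
    max_scores = combined.groupby("gene")["score"].max()
    return set(max_scores.index[max_scores >= score_min])


def pearson_vs_gene(
    cohort: CohortMatrix, gene_of_interest: str, tumor_only: bool = False
) -> pd.DataFrame:
    """Pearson r (and its t-test p, n-2 df) of every gene against the gene
    of interest across the cohort's samples. Constant genes yield NaN."""
    goi = gene_of_interest.upper()
    if goi not in cohort.values.index:
        raise KeyError(f"{goi} absent from cohort {cohort.cohort_id}")
    M = cohort.values.to_numpy(dtype=float)
    if tumor_only:
        M = M[:, cohort.sample_mask(TUMOR)]
    n = M.shape[1]
    if n < 3:
        raise ValueError(f"cohort {cohort.cohort_id}: need >= 3 samples for correlation")
    x = M[cohort.values.index.get_loc(goi)]
    if np.ptp(x) == 0:
        raise ValueError(f"gene of interest constant in cohort {cohort.cohort_id}")
    xc = x - x.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt((Mc**2).sum(axis=1) * (xc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return pd.DataFrame(
        {"gene": cohort.values.index, "platform_id": cohort.platform_id, "r": r, "p": p, "n": n}
    ).reset_index(drop=True)


def ceg_consensus(
    cohorts,
    gene_of_interest: str,
    r_min: float = 0.30,
    p_max: float = 0.05,
    min_platforms: int = 20,
    tumor_only: bool = False,
) -> tuple[set[str], pd.Series]:
    """Co-expressed-gene consensus: genes with r >= r_min and p < p_max
    against the gene of interest in at least min_platforms platforms.

    Returns (consensus set, per-gene platform-pass counts). The gene of
    interest itself is excluded. Cohorts where it is constant are skipped
    with a warning.
    """
    goi = gene_of_interest.upper()
    counts: dict[str, int] = {}
    for cohort in cohorts:
        try:
            df = pearson_vs_gene(cohort, goi, tumor_only=tumor_only)
        except ValueError as exc:
            logger.warning("skipping cohort %s: %s", cohort.cohort_id, exc)
            continue
        passed = df[(df["r"] >= r_min) & (df["p"] < p_max)]
        for gene in passed["gene"]:
            counts[gene] = counts.get(gene, 0) + 1
    counts.pop(goi, None)
    series = pd.Series(counts, dtype=int).sort_index()
    consensus = set(series.index[series >= min_platforms])
    return consensus, series


def heg_screen(
    cohorts, p_max: float = 0.05, exclude: tuple[str, ...] = ()
) -> tuple[set[str], pd.DataFrame]:
    """Highly-expressed-gene screen: per gene, per-cohort Hedges' g pooled
    by DerSimonian-Laird; HEG iff pooled SMD > 0 and pooled p < p_max.
    Genes usable in fewer than 2 cohorts are not assessed."""
    cohorts = list(cohorts)
    if len(cohorts) < 2:
        raise ValueError("HEG screen needs at least 2 cohorts")
    universe = sorted(set().union(*(c.genes for c in cohorts)))
    gene_pos = {g: i for i, g in enumerate(universe)}
    k, G = len(cohorts), len(universe)
    g_mat = np.full((k, G), np.nan)
    v_mat = np.full((k, G), np.nan)
    for i, cohort in enumerate(cohorts):
        tmask = cohort.sample_mask(TUMOR)
        M = cohort.values.to_numpy(dtype=float)
        if tmask.sum() < 2 or (~tmask).sum() < 2:
            logger.warning("cohort %s: fewer than 2 samples per arm; skipped", cohort.cohort_id)
            continue
        g, v, _ = hedges_g_matrix(M[:, tmask], M[:, ~tmask])
        idx = [gene_pos[gene] for gene in cohort.genes]
        g_mat[i, idx] = g
        v_mat[i, idx] = v
    pooled = pool_dl_columns(g_mat, v_mat)
    table = pd.DataFrame(
        {
            "gene": universe,
            "k": pooled["k"],
            "pooled_smd": pooled["pooled"],
            "p": pooled["p"],
            "I2": pooled["I2"],
        }
    )
    keep = (table["pooled_smd"] > 0) & (table["p"] < p_max)
    heg = set(table.loc[keep.fillna(False), "gene"]) - set(e.upper() for e in exclude)
    return heg, table


def intersect_targets(chip: set[str], ceg: set[str], heg: set[str]) -> ScreenResult:
    """Exact three-way intersection with a per-gene evidence table."""
    chip, ceg, heg = set(chip), set(ceg), set(heg)
    inter = chip & ceg & heg
    union = sorted(chip | ceg | heg)
    evidence = pd.DataFrame(
        {
            "gene": union,
            "in_chip": [g in chip for g in union],
            "in_ceg": [g in ceg for g in union],
            "in_heg": [g in heg for g in union],
            "in_intersection": [g in inter for g in union],
        }
    )
    return ScreenResult(
        chip_candidates=chip,
        ceg_consensus=ceg,
        ceg_counts=pd.Series(dtype=int),
        heg=heg,
        heg_table=pd.DataFrame(),
        intersection=inter,
        evidence=evidence,
    )


def run_screen(
    cohorts,
    chip_tables,
    gene_of_interest: str,
    r_min: float = 0.30,
    p_max: float = 0.05,
    min_platforms: int = 20,
    chip_score_min: float = 1.0,
    tumor_only: bool = False,
) -> ScreenResult:
    """Full screen: ChIP filter + CEG consensus + HEG screen, intersected.
    The gene of interest is excluded from all three candidate sets."""
    goi = gene_of_interest.upper()
    chip = chip_candidate_filter(chip_tables, score_min=chip_score_min) - {goi}
    ceg, counts = ceg_consensus(
        cohorts, goi, r_min=r_min, p_max=p_max, min_platforms=min_platforms,
        tumor_only=tumor_only,
    )
    heg, heg_table = heg_screen(cohorts, p_max=p_max, exclude=(goi,))
    result = intersect_targets(chip, ceg, heg)
    result.ceg_counts = counts
    result.heg_table = heg_table
    return result


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def verify_bulk_correlation(
    cohorts, gene_of_interest: str, targets,
    r_min: float = 0.30, p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-platform Pearson r/p of each screened target against the gene of
    interest; unknown symbols are listed as missing rather than fatal."""
    goi = gene_of_interest.upper()
    targets = [t.upper() for t in targets]
    rows = []
    for cohort in cohorts:
        df = pearson_vs_gene(cohort, goi).set_index("gene")
        for target in targets:
            if target in df.index:
                rec = df.loc[target]
                rows.append(
                    {
                        "target": target,
                        "platform_id": cohort.platform_id,
                        "status": "ok",
                        "r": float(rec["r"]),
                        "p": float(rec["p"]),
                        "n": int(rec["n"]),
                        "passes": bool(rec["r"] >= r_min and rec["p"] < p_max),
                    }
                )
            else:
                rows.append(
                    {
                        "target": target,
                        "platform_id": cohort.platform_id,
                        "status": "missing",
                        "r": np.nan,
                        "p": np.nan,
                        "n": 0,
                        "passes": False,
                    }
                )
    return pd.DataFrame(rows)


def verify_single_cell(
    sc: SingleCellMatrix, gene_of_interest: str, targets, cluster: str
) -> pd.DataFrame:
    """Within-cluster co-expression check: fraction of cells expressing
    both genes (> 0 counts) and Spearman correlation, inside the named
    cluster versus all other clusters pooled."""
    goi = gene_of_interest.upper()
    mask = sc.cluster_mask(cluster)
    if mask.sum() == 0:
        raise ValueError(f"empty cluster {cluster!r}")
    if goi not in sc.genes:
        raise KeyError(f"{goi} absent from single-cell matrix")
    x = sc.gene_counts(goi)
    rows = []
    for target in [t.upper() for t in targets]:
        if target not in sc.genes:
            rows.append(
                {"target": target, "compartment": cluster, "status": "missing",
                 "both_positive_fraction": np.nan, "spearman_r": np.nan, "n_cells": 0}
            )
            continue
        y = sc.gene_counts(target)
        for label, m in ((cluster, mask), ("other", ~mask)):
            if m.sum() == 0:
                continue
            both = float(np.mean((x[m] > 0) & (y[m] > 0)))
            if np.ptp(x[m]) == 0 or np.ptp(y[m]) == 0:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(x[m], y[m]).statistic)
            rows.append(
                {
                    "target": target,
                    "compartment": label,
                    "status": "ok",
                    "both_positive_fraction": both,
                    "spearman_r": rho,
                    "n_cells": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)
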