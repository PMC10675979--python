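"""End-to-end pipeline orchestration.

Runs the stages in analysis order — expression meta-analysis, diagnostic
meta-analysis, survival, target screen, enrichment, single-cell
verification — writing one plain-text table per stage plus a
machine-readable ``summary.json``. Outputs are deterministic for fixed
inputs and seed.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, enrich, meta, screen, survival
from .io import (
    ChipTargetTable,
    CohortMatrix,
    GeneSetCollection,
    PipelineConfig,
    SingleCellMatrix,
    SurvivalTable,
    TUMOR,
    NORMAL,
    read_chip_table,
    read_cohort_dir,
    read_gmt,
    read_single_cell_dir,
    read_survival_csv,
)
from .survival import HrRecord

logger = logging.getLogger("metascreen")

FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class PipelineInputs:
    cohorts: list[CohortMatrix]
    survival: SurvivalTable | None = None
    chip: ChipTargetTable | None = None
    gene_sets: GeneSetCollection | None = None
    single_cell: SingleCellMatrix | None = None
    hr_records: list[HrRecord] = field(default_factory=list)
    malignant_cluster: str = "malignant"

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path) -> "PipelineInputs":
        d = Path(bundle_dir)
        cohorts = read_cohort_dir(d / "cohorts")
        surv = read_survival_csv(d / "survival.csv") if (d / "survival.csv").exists() else None
        chip = read_chip_table(d / "chip.tsv") if (d / "chip.tsv").exists() else None
        gmt = read_gmt(d / "genesets.gmt") if (d / "genesets.gmt").exists() else None
        sc = read_single_cell_dir(d / "sc") if (d / "sc").is_dir() else None
        hr_records = []
        if (d / "hr_records.csv").exists():
            for _, row in pd.read_csv(d / "hr_records.csv").iterrows():
                hr_records.append(
                    HrRecord(str(row["label"]), float(row["hr"]),
                             float(row["ci_low"]), float(row["ci_high"]))
                )
        return cls(cohorts=cohorts, survival=surv, chip=chip, gene_sets=gmt,
                   single_cell=sc, hr_records=hr_records)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _effect_records(cohorts, gene):
    records = []
    for cm in cohorts:
        if gene not in cm.values.index:
            logger.warning("cohort %s lacks %s; skipped", cm.cohort_id, gene)
            continue
        if cm.n_arm(TUMOR) < 2 or cm.n_arm(NORMAL) < 2:
            logger.warning("cohort %s: < 2 samples per arm; skipped", cm.cohort_id)
            continue
        records.append(
            meta.hedges_g(cm.arm_values(gene, TUMOR), cm.arm_values(gene, NORMAL), cm.cohort_id)
        )
    return records


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs, outdir: str | Path
) -> dict:
    """Run every stage the inputs allow; write per-stage tables and a
    summary JSON under ``outdir``; return the summary dict.

    The target screen requires the ChIP table: its absence raises
    ``StageError("target_screen inputs missing")``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = config.gene_of_interest
    summary: dict = {"gene_of_interest": gene, "rng_seed": config.rng_seed}

    def stage(name):
        t0 = _time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0):
        logger.info("stage %s finished in %.2fs", name, _time.perf_counter() - t0)

    # ------------------------------------------------------------- effect meta
    t0 = stage("effect_meta")
    try:
        records = _effect_records(inputs.cohorts, gene)
        if not records:
            raise ValueError(f"no cohort usable for {gene}")
        pooled = meta.pool_auto(records, config.i2_random_threshold)
        forest = pd.DataFrame(
            [
                {
                    "cohort_id": r.cohort_id,
                    "g": r.g,
                    "var_g": r.var_g,
                    "ci_low": r.g - meta.Z95 * r.se,
                    "ci_high": r.g + meta.Z95 * r.se,
                    "n_tumor": r.n_tumor,
                    "n_normal": r.n_normal,
                    "p": r.p,
                }
                for r in records
            ]
        )
        _write(forest, outdir / "meta_forest.tsv")
        _write(pooled.to_frame(), outdir / "meta_summary.tsv")
        summary["effect_meta"] = {
            "k": pooled.k,
            "model": pooled.model,
            "pooled_smd": pooled.pooled,
            "ci95": list(pooled.ci95),
            "I2": pooled.I2,
            "tau2": pooled.tau2,
            "p": pooled.p_pooled,
        }
        if len(records) >= 3:
            bias = meta.publication_bias(records, config.bias_p)
            points, guides = meta.funnel_data(records, pooled)
            _write(points, outdir / "funnel_points.tsv")
            _write(guides, outdir / "funnel_guides.tsv")
            summary["publication_bias"] = {
                "egger_intercept": bias.egger_intercept,
                "egger_p": bias.egger_p,
                "begg_tau": bias.begg_tau,
                "begg_p": bias.begg_p,
                "significant": bias.significant,
            }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"effect_meta failed: {exc}") from exc
    done("effect_meta", t0)

    # --------------------------------------------------------- diagnostic meta
    t0 = stage("diagnostic_meta")
    try:
        studies = []
        for cm in inputs.cohorts:
            if gene not in cm.values.index:
                continue
            studies.append(
                diagnostics.youden_cutoff(
                    cm.arm_values(gene, TUMOR), cm.arm_values(gene, NORMAL), cm.cohort_id
                )
            )
        if not studies:
            raise ValueError(f"no cohort usable for {gene}")
        per_study = pd.DataFrame(
            [
                {
                    "cohort_id": s.cohort_id,
                    "auc": s.auc,
                    "auc_flag": s.auc >= config.auc_diag_min,
                    "cutoff": s.cutoff,
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "tn": s.tn,
                    "se": s.se,
                    "sp": s.sp,
                }
                for s in studies
            ]
        )
        dmeta = diagnostics.pool_diag(studies)
        _write(per_study, outdir / "diag_studies.tsv")
        _write(dmeta.to_frame(), outdir / "diag_summary.tsv")
        summary["diagnostic_meta"] = {
            "k": dmeta.k,
            "auc_flag_fraction": float(per_study["auc_flag"].mean()),
            "pooled_se": dmeta.pooled_se,
            "pooled_sp": dmeta.pooled_sp,
            "lr_pos": dmeta.lr_pos,
            "lr_neg": dmeta.lr_neg,
            "sroc_auc": dmeta.sroc.auc if dmeta.sroc else None,
        }
    except Exception as exc:
        raise StageError(f"diagnostic_meta failed: {exc}") from exc
    done("diagnostic_meta", t0)

    # ---------------------------------------------------------------- survival
    if inputs.survival is not None:
        t0 = stage("survival")
        try:
            surv = inputs.survival
            if gene not in surv.data.columns:
                raise ValueError(f"survival table lacks column {gene}")
            cut = survival.maxstat_cutpoint(surv, surv.data[gene], config.minprop)
            chi2, logrank_p = survival.logrank_test(surv, cut.groups)
            km = survival.km_estimate(surv, cut.groups)
            km_rows = []
            for label, df in sorted(km.items()):
                df = df.copy()
                df.insert(0, "group", label)
                km_rows.append(df)
            _write(pd.concat(km_rows, ignore_index=True), outdir / "km_curves.tsv")
            uni = survival.cox_fit(surv, [gene], scope="univariable")
            covars = [c for c in surv.covariates]
            multi = survival.cox_fit(surv, covars, scope="multivariable") if len(covars) > 1 else None
            cox_rows = [uni.table.assign(scope="univariable")]
            if multi is not None:
                cox_rows.append(multi.table.assign(scope="multivariable"))
            _write(pd.concat(cox_rows, ignore_index=True), outdir / "cox.tsv")
            cut_df = pd.DataFrame(
                [{"cutpoint": cut.cutpoint, "max_stat": cut.max_stat,
                  "n_high": int((cut.groups == "high").sum()),
                  "n_low": int((cut.groups == "low").sum()),
                  "logrank_chi2": chi2, "logrank_p": logrank_p}]
            )
            _write(cut_df, outdir / "cutpoint.tsv")
            # high-vs-low HR on the cutpoint groups, the scale literature HRs use
            surv_grp = SurvivalTable(
                surv.data.assign(expr_high=(cut.groups == "high").to_numpy().astype(float))[
                    ["time", "event", "expr_high"]
                ]
            )
            grp_cox = survival.cox_fit(surv_grp, ["expr_high"], scope="univariable")
            grp_row = grp_cox.table.iloc[0]
            records = list(inputs.hr_records)
            uni_row = uni.table.iloc[0]
            if bool(grp_row["estimable"]):
                records.append(
                    HrRecord("this_cohort", float(grp_row["hr"]),
                             float(grp_row["ci_low"]), float(grp_row["ci_high"]))
                )
            pooled_hr = survival.pool_hr(records) if records else None
            if pooled_hr is not None:
                _write(
                    pd.DataFrame(
                        [{"k": pooled_hr.k, "pooled_hr": pooled_hr.pooled_hr,
                          "ci_low": pooled_hr.ci95[0], "ci_high": pooled_hr.ci95[1],
                          "Q": pooled_hr.Q, "I2": pooled_hr.I2, "p": pooled_hr.p}]
                    ),
                    outdir / "pooled_hr.tsv",
                )
            summary["survival"] = {
                "cutpoint": cut.cutpoint,
                "max_stat": cut.max_stat,
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
                "hr_univariable": float(uni_row["hr"]),
                "hr_univariable_ci": [float(uni_row["ci_low"]), float(uni_row["ci_high"])],
                "hr_high_vs_low": float(grp_row["hr"]),
                "hr_multivariable": (
                    multi.hr(gene) if multi is not None and gene in list(multi.table["term"]) else None
                ),
                "pooled_hr": pooled_hr.pooled_hr if pooled_hr else None,
                "pooled_hr_ci": list(pooled_hr.ci95) if pooled_hr else None,
            }
        except Exception as exc:
            raise StageError(f"survival failed: {exc}") from exc
        done("survival", t0)

    # ------------------------------------------------------------ target screen
    if inputs.chip is None:
        raise StageError("target_screen inputs missing: no ChIP candidate table")
    t0 = stage("target_screen")
    try:
        if len(inputs.cohorts) >= 2:
            result = screen.run_screen(
                inputs.cohorts,
                inputs.chip,
                gene,
                r_min=config.r_min,
                p_max=config.p_max,
                min_platforms=config.min_platforms,
                chip_score_min=config.chip_score_min,
            )
        else:
            logger.warning("single cohort: HEG screen unavailable, intersection empty")
            chip_set = screen.chip_candidate_filter(inputs.chip, config.chip_score_min) - {gene}
            ceg, counts = screen.ceg_consensus(
                inputs.cohorts, gene, config.r_min, config.p_max, config.min_platforms
            )
            result = screen.intersect_targets(chip_set, ceg, set())
            result.ceg_counts = counts
        (outdir / "chip.txt").write_text("".join(f"{g}\n" for g in sorted(result.chip_candidates)))
        (outdir / "ceg.txt").write_text("".join(f"{g}\n" for g in sorted(result.ceg_consensus)))
        if not result.heg_table.empty:
            _write(result.heg_table, outdir / "heg.tsv")
        (outdir / "intersection.txt").write_text(
            "".join(f"{g}\n" for g in sorted(result.intersection))
        )
        _write(result.evidence, outdir / "evidence.tsv")
        verify = screen.verify_bulk_correlation(
            inputs.cohorts, gene, sorted(result.intersection),
            r_min=config.r_min, p_max=config.p_max,
        )
        if not verify.empty:
            _write(verify, outdir / "verify_bulk.tsv")
        summary["target_screen"] = result.summary()
        summary["target_screen"]["intersection"] = sorted(result.intersection)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"target_screen failed: {exc}") from exc
    done("target_screen", t0)

    # ---------------------------------------------------------------- enrichment
    if inputs.gene_sets is not None and result.intersection:
        t0 = stage("enrichment")
        try:
            universe = set().union(*(c.genes for c in inputs.cohorts))
            query = (result.intersection | {gene}) & universe
            rows = enrich.hypergeom_ora(query, inputs.gene_sets, universe)
            _write(rows, outdir / "enrichment.tsv")
            top = rows.iloc[0]
            summary["enrichment"] = {
                "n_sets": int(len(rows)),
                "top_set": str(top["set_name"]),
                "top_p_adj": float(top["p_adj"]),
            }
        except Exception as exc:
            raise StageError(f"enrichment failed: {exc}") from exc
        done("enrichment", t0)

    # ------------------------------------------------------------- single cell
    if inputs.single_cell is not None and result.intersection:
        t0 = stage("single_cell")
        try:
            sc_rows = screen.verify_single_cell(
                inputs.single_cell, gene, sorted(result.intersection),
                inputs.malignant_cluster,
            )
            _write(sc_rows, outdir / "verify_sc.tsv")
            in_cluster = sc_rows[
                (sc_rows["compartment"] == inputs.malignant_cluster)
                & (sc_rows["status"] == "ok")
            ]
            other = sc_rows[(sc_rows["compartment"] == "other") & (sc_rows["status"] == "ok")]
            summary["single_cell"] = {
                "n_targets": int(in_cluster["target"].nunique()),
                "mean_both_positive_malignant": float(in_cluster["both_positive_fraction"].mean())
                if len(in_cluster) else None,
                "mean_both_positive_other": float(other["both_positive_fraction"].mean())
                if len(other) else None,
            }
        except Exception as exc:
            raise StageError(f"single_cell failed: {exc}") from exc
        done("single_cell", t0)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
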