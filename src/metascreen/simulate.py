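"""Synthetic multi-platform test bed.

Generates the four input kinds the pipeline consumes — multi-platform
tumor/normal expression cohorts, expression-linked survival tables, scored
ChIP candidate tables, and zero-inflated single-cell counts — with the
statistical structure the analysis stages assume: a random-effects group
shift for the gene of interest and its true targets, a latent-factor
correlation block tying targets to the gene of interest, exponential event
times with a log-linear hazard in expression, and negative-binomial counts
with Bernoulli dropout concentrated in one "malignant" cluster.

All generators are pure functions of (spec, seed): independent seed streams
are derived per stage, so adding cohorts does not perturb the survival or
single-cell draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.optimize import brentq

from .io import (
    ChipTargetTable,
    CohortMatrix,
    GeneSetCollection,
    PipelineConfig,
    SingleCellMatrix,
    SurvivalTable,
    write_chip_table,
    write_cohort_matrix,
    write_gmt,
    write_single_cell,
    write_survival_csv,
)


@dataclass
class SimSpec:
    """Study conditions for the synthetic test bed.

    The defaults emulate the multi-platform design the pipeline is built
    for at desk scale: 39 platforms with 30-80 samples per arm, a gene of
    interest shifted by a standardized mean difference of 1.7 with
    between-platform SD 0.3 (strong heterogeneity), nine true targets with
    within-group correlation 0.5 to the gene of interest, survival with a
    hazard ratio of 1.30 per expression unit around a mean expression of
    2.7 (SD 1.4), and a literature hazard-ratio stratum centred on 2.0.
    """

    n_platforms: int = 39
    arm_min: int = 30
    arm_max: int = 80
    true_smd: float = 1.7
    tau: float = 0.3
    n_genes: int = 200
    n_true_targets: int = 9
    target_correlation: float = 0.5
    gene_of_interest: str = "FOXM1"
    # survival
    n_patients: int = 364
    expr_mean: float = 2.7
    expr_sd: float = 1.4
    baseline_log_hazard: float = float(np.log(0.03))  # per month
    log_hr_per_unit: float = float(np.log(1.30))
    censoring_rate: float = 0.35
    # literature hazard ratios
    lit_hr: float = 2.0
    lit_k: int = 14
    lit_tau: float = 0.1
    # ChIP
    n_chip_datasets: int = 41
    # single cell
    sc_cells: int = 2000
    sc_clusters: tuple[str, ...] = ("malignant", "hepatocyte", "immune", "endothelial")
    dropout_rate: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_targets >= self.n_genes:
            raise ValueError("n_true_targets must be smaller than n_genes")
        if not (0 < self.target_correlation < 1):
            raise ValueError("target_correlation must lie in (0, 1)")
        if not (0 <= self.censoring_rate < 1) or not (0 <= self.dropout_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.n_platforms, self.arm_min, self.n_genes, self.sc_cells) <= 0:
            raise ValueError("counts must be positive")
        if self.arm_max < self.arm_min:
            raise ValueError("arm_max < arm_min")
        self.gene_of_interest = self.gene_of_interest.upper()

    @property
    def true_targets(self) -> list[str]:
        return [f"TGT{i+1:03d}" for i in range(self.n_true_targets)]

    @property
    def decoys(self) -> list[str]:
        n_decoys = self.n_genes - self.n_true_targets - 1
        return [f"DEC{i+1:03d}" for i in range(n_decoys)]

    @property
    def gene_names(self) -> list[str]:
        return [self.gene_of_interest, *self.true_targets, *self.decoys]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed) % 2**31, stream])

    @classmethod
    def from_yaml(cls, path) -> "SimSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        if "sc_clusters" in raw:
            raw["sc_clusters"] = tuple(raw["sc_clusters"])
        return cls(**{k: v for k, v in raw.items() if k in known})


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def simulate_cohorts(spec: SimSpec) -> list[CohortMatrix]:
    """Per platform i, the gene of interest's tumor shift is
    delta_i ~ Normal(true_smd, tau^2) on a unit within-group SD, so the
    realized per-platform Cohen's d is centred on true_smd. True targets
    share a latent per-sample factor with the gene of interest (within-group
    correlation ~ target_correlation) and carry their own platform-level
    positive tumor shift; decoy genes are null."""
    rng = spec.rng(1)
    rho = spec.target_correlation
    load = np.sqrt(rho)
    genes = spec.gene_names
    n_corr = 1 + spec.n_true_targets  # gene of interest + true targets
    cohorts = []
    for i in range(spec.n_platforms):
        n_t = int(rng.integers(spec.arm_min, spec.arm_max + 1))
        n_n = int(rng.integers(spec.arm_min, spec.arm_max + 1))
        n = n_t + n_n
        factor = rng.normal(size=n)
        noise = rng.normal(size=(spec.n_genes, n))
        values = noise.copy()
        values[:n_corr] = load * factor + np.sqrt(1 - rho) * noise[:n_corr]
        delta = rng.normal(spec.true_smd, spec.tau, size=n_corr)
        values[:n_corr, :n_t] += delta[:, None]
        values += 8.0  # arbitrary log2 baseline
        samples = [f"P{i+1:02d}S{j+1:03d}" for j in range(n)]
        group = pd.Series(
            ["tumor"] * n_t + ["normal"] * n_n, index=samples
        )
        cohorts.append(
            CohortMatrix(
                cohort_id=f"PLAT{i+1:02d}",
                platform_id=f"PLAT{i+1:02d}",
                values=pd.DataFrame(values, index=genes, columns=samples),
                group=group,
            )
        )
    return cohorts


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _calibrate_censoring(rates: np.ndarray, target: float) -> float:
    """Upper bound of a Uniform(0, c) censoring time such that the expected
    censored fraction matches the target, given exponential event rates."""

    def censored_fraction(c: float) -> float:
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target and hi < 1e9:
        hi *= 2.0
    return brentq(lambda c: censored_fraction(c) - target, lo, hi, xtol=1e-10)


def simulate_survival(spec: SimSpec, expression) -> SurvivalTable:
    """Event times exponential with hazard exp(baseline + beta*x), censored
    by an independent uniform time calibrated to the target censoring rate."""
    x = np.asarray(expression, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    if not np.isfinite(spec.log_hr_per_unit):
        raise ValueError("non-finite log hazard ratio")
    rng = spec.rng(2)
    rates = np.exp(spec.baseline_log_hazard + spec.log_hr_per_unit * x)
    t_event = rng.exponential(1.0 / rates)
    if spec.censoring_rate <= 0:
        time, event = t_event, np.ones(x.size, dtype=int)
    else:
        c_max = _calibrate_censoring(rates, spec.censoring_rate)
        t_cens = rng.uniform(0.0, c_max, size=x.size)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "time": np.maximum(time, 1e-9),
            "event": event,
            spec.gene_of_interest: x,
        }
    )
    return SurvivalTable(df)


def simulate_survival_covariates(spec: SimSpec) -> pd.DataFrame:
    """Null clinical covariates (age, sex) to accompany the expression-driven
    survival table in multivariable fits."""
    rng = spec.rng(3)
    n = spec.n_patients
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(59.6, 13.4, size=n), 1),
            "sex": rng.choice(["female", "male"], size=n, p=[0.327, 0.673]),
        }
    )


def simulate_patient_expression(spec: SimSpec) -> np.ndarray:
    rng = spec.rng(4)
    return rng.normal(spec.expr_mean, spec.expr_sd, size=spec.n_patients)


def simulate_hr_records(spec: SimSpec):
    """Literature-style hazard-ratio records: per study,
    log HR ~ Normal(log(lit_hr), lit_tau^2) observed with an SE drawn
    uniformly from 0.10-0.35."""
    from .survival import HrRecord

    rng = spec.rng(5)
    records = []
    for i in range(spec.lit_k):
        se = rng.uniform(0.10, 0.35)
        log_hr = rng.normal(np.log(spec.lit_hr), spec.lit_tau) + rng.normal(0, se)
        records.append(
            HrRecord(
                label=f"STUDY{i+1:02d}",
                hr=float(np.exp(log_hr)),
                ci_low=float(np.exp(log_hr - 1.959963984540054 * se)),
                ci_high=float(np.exp(log_hr + 1.959963984540054 * se)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# ChIP score tables
# ---------------------------------------------------------------------------

def simulate_chip_scores(spec: SimSpec, true_targets=None) -> ChipTargetTable:
    """Regulatory-potential scores across datasets: true targets appear in
    ~90% of datasets with scores mostly >= 1 (1 + Exp(mean 1)); decoys
    appear sporadically with small scores (Exp(mean 0.3))."""
    rng = spec.rng(6)
    targets = [t.upper() for t in (true_targets if true_targets is not None else spec.true_targets)]
    rows = []
    for d in range(spec.n_chip_datasets):
        ds = f"CHIP{d+1:02d}"
        for gene in targets:
            if rng.random() < 0.9:
                rows.append((gene, float(1.0 + rng.exponential(1.0)), ds))
        for gene in spec.decoys:
            if rng.random() < 0.15:
                rows.append((gene, float(rng.exponential(0.3)), ds))
    table = pd.DataFrame(rows, columns=["gene", "score", "dataset_id"])
    return ChipTargetTable(table)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def simulate_single_cell(spec: SimSpec, true_targets=None) -> SingleCellMatrix:
    """Negative-binomial (size 2) counts with Bernoulli dropout. In the
    "malignant" cluster the gene of interest and the true targets share a
    per-cell lognormal activity that scales their means, producing the
    co-expression the verification stage looks for; other clusters and all
    decoy genes stay at a low baseline mean."""
    rng = spec.rng(7)
    targets = [t.upper() for t in (true_targets if true_targets is not None else spec.true_targets)]
    genes = spec.gene_names
    gene_idx = {g: i for i, g in enumerate(genes)}
    active = [spec.gene_of_interest, *[t for t in targets if t in gene_idx]]
    n_cells = spec.sc_cells
    clusters = np.array(
        [spec.sc_clusters[i % len(spec.sc_clusters)] for i in range(n_cells)]
    )
    mu = np.full((n_cells, len(genes)), 0.3)
    malignant = clusters == spec.sc_clusters[0]
    activity = np.exp(rng.normal(0.5, 0.5, size=int(malignant.sum())))
    for g in active:
        mu[malignant, gene_idx[g]] = 2.0 * activity
    size = 2.0
    counts = rng.negative_binomial(size, size / (size + mu))
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep
    barcodes = [f"CELL{i+1:05d}" for i in range(n_cells)]
    return SingleCellMatrix(
        counts=sp.csr_matrix(counts),
        genes=genes,
        barcodes=barcodes,
        cell_cluster=pd.Series(clusters, index=barcodes),
    )


# ---------------------------------------------------------------------------
# gene sets and the full bundle
# ---------------------------------------------------------------------------

def simulate_gene_sets(spec: SimSpec, n_decoy_sets: int = 10) -> GeneSetCollection:
    """A GMT collection with one set holding the true regulatory program
    (gene of interest + true targets) and random decoy sets."""
    rng = spec.rng(8)
    sets = {
        "TRUE_TARGET_PROGRAM": [spec.gene_of_interest, *spec.true_targets],
    }
    pool = spec.decoys
    for i in range(n_decoy_sets):
        size = int(rng.integers(10, 31))
        sets[f"DECOY_SET_{i+1:02d}"] = sorted(
            rng.choice(pool, size=min(size, len(pool)), replace=False).tolist()
        )
    return GeneSetCollection(sets, source="synthetic")


def write_bundle(spec: SimSpec, outdir) -> dict[str, str]:
    """Write every pipeline input to a directory in the formats the readers
    consume; returns the path map. Deterministic for a fixed spec."""
    outdir = Path(outdir)
    (outdir / "cohorts").mkdir(parents=True, exist_ok=True)
    cohorts = simulate_cohorts(spec)
    for cm in cohorts:
        write_cohort_matrix(cm, outdir / "cohorts" / f"{cm.cohort_id}.tsv")
    x = simulate_patient_expression(spec)
    surv = simulate_survival(spec, x)
    covars = simulate_survival_covariates(spec)
    surv = SurvivalTable(pd.concat([surv.data, covars], axis=1))
    write_survival_csv(surv, outdir / "survival.csv")
    write_chip_table(simulate_chip_scores(spec), outdir / "chip.tsv")
    write_gmt(simulate_gene_sets(spec), outdir / "genesets.gmt")
    write_single_cell(simulate_single_cell(spec), outdir / "sc")
    hr_rows = [
        {"label": r.label, "hr": r.hr, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in simulate_hr_records(spec)
    ]
    pd.DataFrame(hr_rows).to_csv(outdir / "hr_records.csv", index=False, float_format="%.6g")
    truth = {"gene_of_interest": spec.gene_of_interest, "true_targets": spec.true_targets}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    config = PipelineConfig(gene_of_interest=spec.gene_of_interest, rng_seed=spec.rng_seed)
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "simspec.yaml", "w") as fh:
        d = asdict(spec)
        d["sc_clusters"] = list(d["sc_clusters"])
        yaml.safe_dump(d, fh, sort_keys=True)
    return {"outdir": str(outdir)}
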