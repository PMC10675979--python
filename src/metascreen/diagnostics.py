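"""Per-cohort discrimination and pooled diagnostic accuracy.

Rank (Mann-Whitney) AUC, Youden-J optimal cutoffs with the resulting 2x2
confusion table, logit-scale pooling of sensitivity/specificity, likelihood
ratios, and the Moses-Littenberg summary ROC fitted by unweighted OLS in
(D, S) logit space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .meta import EffectRecord, pool_fixed, pool_random_dl


@dataclass
class DiagStudy:
    """One cohort's discrimination summary at its chosen cutoff."""

    cohort_id: str
    auc: float
    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class SrocFit:
    a: float
    b: float
    auc: float


@dataclass
class DiagMeta:
    k: int
    pooled_se: float
    se_ci95: tuple[float, float]
    pooled_sp: float
    sp_ci95: tuple[float, float]
    lr_pos: float
    lr_neg: float
    sroc: SrocFit | None

    def to_frame(self) -> pd.DataFrame:
        row = {
            "k": self.k,
            "pooled_se": self.pooled_se,
            "se_ci_low": self.se_ci95[0],
            "se_ci_high": self.se_ci95[1],
            "pooled_sp": self.pooled_sp,
            "sp_ci_low": self.sp_ci95[0],
            "sp_ci_high": self.sp_ci95[1],
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "sroc_a": self.sroc.a if self.sroc else np.nan,
            "sroc_b": self.sroc.b if self.sroc else np.nan,
            "sroc_auc": self.sroc.auc if self.sroc else np.nan,
        }
        return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# per-cohort discrimination
# ---------------------------------------------------------------------------

def auc_rank(tumor_values, normal_values) -> float:
    """Rank AUC: fraction of (tumor, normal) pairs with tumor > normal,
    counting ties as one half. Equals the normalized Mann-Whitney U."""
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("empty arm")
    combined = np.concatenate([t, n])
    ranks = stats.rankdata(combined)
    u = ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0
    return float(u / (t.size * n.size))


def youden_cutoff(tumor_values, normal_values, cohort_id: str = "") -> DiagStudy:
    """Cutoff maximizing Youden's J = Se + Sp - 1 over midpoints between
    adjacent sorted unique values; classify positive when value >= cutoff.
    Ties in J favour the cutoff with the higher sensitivity (then the
    smaller cutoff)."""
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("empty arm")
    uniq = np.unique(np.concatenate([t, n]))
    if uniq.size < 2:
        # all values identical: any cutoff is as bad as any other
        cut = float(uniq[0])
        tp, fp = int(t.size), int(n.size)
        return DiagStudy(cohort_id, auc_rank(t, n), cut, tp, fp, 0, 0)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    se = (t[:, None] >= cands[None, :]).mean(axis=0)
    sp = (n[:, None] < cands[None, :]).mean(axis=0)
    J = se + sp - 1.0
    # lexicographic argmax: J, then Se, then smaller cutoff (scan order)
    order = np.lexsort((cands, -se, -J))
    best = order[0]
    cut = float(cands[best])
    tp = int((t >= cut).sum())
    fn = int(t.size - tp)
    fp = int((n >= cut).sum())
    tn = int(n.size - fp)
    return DiagStudy(cohort_id, auc_rank(t, n), cut, tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def _corrected_cells(s: DiagStudy) -> tuple[float, float, float, float]:
    """0.5 added to every cell of a table containing a zero cell."""
    cells = (s.tp, s.fp, s.fn, s.tn)
    if min(cells) == 0:
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def _pool_logit(values_var: list[tuple[float, float]]) -> tuple[float, tuple[float, float]]:
    records = [
        EffectRecord(str(i), y, v, 2, 2, 1.0) for i, (y, v) in enumerate(values_var)
    ]
    summary = pool_random_dl(records) if len(records) >= 2 else pool_fixed(records)
    lo, hi = summary.ci95
    return float(expit(summary.pooled)), (float(expit(lo)), float(expit(hi)))


def pool_diag(studies) -> DiagMeta:
    """Pool logit(Se) and logit(Sp) across studies (DerSimonian-Laird when
    k >= 2, single-study passthrough otherwise), back-transform, and derive
    likelihood ratios LR+ = Se/(1-Sp), LR- = (1-Se)/Sp. The summary ROC is
    fitted when k >= 3."""
    studies = list(studies)
    if not studies:
        raise ValueError("no diagnostic studies to pool")
    se_parts, sp_parts = [], []
    for s in studies:
        tp, fp, fn, tn = _corrected_cells(s)
        se_parts.append((float(logit(tp / (tp + fn))), 1.0 / tp + 1.0 / fn))
        sp_parts.append((float(logit(tn / (tn + fp))), 1.0 / tn + 1.0 / fp))
    pooled_se, se_ci = _pool_logit(se_parts)
    pooled_sp, sp_ci = _pool_logit(sp_parts)
    lr_pos = pooled_se / (1.0 - pooled_sp)
    lr_neg = (1.0 - pooled_se) / pooled_sp
    sroc = None
    if len(studies) >= 3:
        try:
            sroc = sroc_moses(studies)
        except ValueError:
            sroc = None
    return DiagMeta(
        k=len(studies),
        pooled_se=pooled_se,
        se_ci95=se_ci,
        pooled_sp=pooled_sp,
        sp_ci95=sp_ci,
        lr_pos=float(lr_pos),
        lr_neg=float(lr_neg),
        sroc=sroc,
    )


def likelihood_ratios(se: float, sp: float) -> tuple[float, float]:
    """LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp from pooled accuracy."""
    if not (0 < se <= 1 and 0 < sp <= 1):
        raise ValueError("sensitivity/specificity must lie in (0, 1]")
    return se / (1.0 - sp), (1.0 - se) / sp


# ---------------------------------------------------------------------------
# summary ROC
# ---------------------------------------------------------------------------

def sroc_curve(a: float, b: float, fpr: np.ndarray) -> np.ndarray:
    """TPR of the Moses-Littenberg summary ROC at the given FPR values:
    logit(TPR) = a/(1-b) + ((1+b)/(1-b)) * logit(FPR)."""
    slope = (1.0 + b) / (1.0 - b)
    intercept = a / (1.0 - b)
    with np.errstate(divide="ignore"):
        return expit(intercept + slope * logit(fpr))


def sroc_moses(studies, n_grid: int = 2001) -> SrocFit:
    """Moses-Littenberg summary ROC.

    Per study D = logit(TPR) - logit(FPR) and S = logit(TPR) + logit(FPR)
    (0.5-corrected tables); unweighted OLS D = a + b*S; AUC by trapezoidal
    integration of the back-solved curve over FPR in (0, 1)."""
    studies = list(studies)
    if len(studies) < 3:
        raise ValueError("sROC needs at least 3 studies")
    D, S = [], []
    for s in studies:
        tp, fp, fn, tn = _corrected_cells(s)
        ltpr = float(logit(tp / (tp + fn)))
        lfpr = float(logit(fp / (fp + tn)))
        D.append(ltpr - lfpr)
        S.append(ltpr + lfpr)
    S_arr = np.asarray(S)
    if np.ptp(S_arr) < 1e-12:
        raise ValueError("degenerate sROC: no spread in S across studies")
    fit = sm.OLS(np.asarray(D), sm.add_constant(S_arr)).fit()
    a, b = float(fit.params[0]), float(fit.params[1])
    return SrocFit(a, b, sroc_auc(a, b, n_grid=n_grid))


def sroc_auc(a: float, b: float, n_grid: int = 2001) -> float:
    """Trapezoidal AUC of the summary ROC on an n_grid-point FPR grid."""
    if abs(1.0 - b) < 1e-6:
        raise ValueError("degenerate sROC slope (b ~ 1)")
    fpr = np.linspace(0.0, 1.0, n_grid)
    tpr = np.empty_like(fpr)
    tpr[1:-1] = sroc_curve(a, b, fpr[1:-1])
    slope = (1.0 + b) / (1.0 - b)
    if slope > 0:
        tpr[0], tpr[-1] = 0.0, 1.0
    elif slope == 0:
        tpr[0] = tpr[-1] = float(expit(a / (1.0 - b)))
    else:
        tpr[0], tpr[-1] = 1.0, 0.0
    return float(np.clip(np.trapezoid(tpr, fpr), 0.0, 1.0))
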