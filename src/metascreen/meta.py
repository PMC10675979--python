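"""Standardized-mean-difference meta-analysis.

Per-cohort Hedges' g (small-sample bias-corrected SMD) with its sampling
variance, inverse-variance fixed-effect pooling, DerSimonian-Laird
random-effects pooling with Cochran's Q / I^2 / tau^2 heterogeneity, and the
two classical funnel-asymmetry tests (Egger regression, Begg rank
correlation). Normal (z) critical values are used for all confidence
intervals; p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class EffectRecord:
    """One cohort's Hedges' g with variance and arm sizes."""

    cohort_id: str
    g: float
    var_g: float
    n_tumor: int
    n_normal: int
    p: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_g))


@dataclass
class MetaSummary:
    k: int
    model: str  # "fixed" | "random"
    pooled: float
    ci95: tuple[float, float]
    Q: float
    I2: float
    tau2: float
    p_pooled: float
    se: float

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame(
            [
                {
                    "k": self.k,
                    "model": self.model,
                    "pooled": self.pooled,
                    "ci_low": lo,
                    "ci_high": hi,
                    "se": self.se,
                    "Q": self.Q,
                    "I2": self.I2,
                    "tau2": self.tau2,
                    "p": self.p_pooled,
                }
            ]
        )


@dataclass
class BiasResult:
    egger_intercept: float
    egger_p: float
    begg_tau: float
    begg_p: float
    significant: bool


# ---------------------------------------------------------------------------
# per-cohort effect size
# ---------------------------------------------------------------------------

def hedges_g(tumor_values, normal_values, cohort_id: str = "") -> EffectRecord:
    """Hedges-corrected standardized mean difference tumor minus normal.

    d = (m_t - m_n) / s_pooled, g = J * d with J = 1 - 3/(4*df - 1),
    var_g = (n_t+n_n)/(n_t*n_n) + g^2 / (2*(n_t+n_n)); two-sided p from
    z = g / sqrt(var_g).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size < 2 or n.size < 2:
        raise ValueError("need at least 2 samples per arm")
    if not (np.isfinite(t).all() and np.isfinite(n).all()):
        raise ValueError("non-finite expression values")
    nt, nn = t.size, n.size
    df = nt + nn - 2
    sp2 = ((nt - 1) * t.var(ddof=1) + (nn - 1) * n.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("degenerate variance: pooled SD is zero")
    d = (t.mean() - n.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    var_g = (nt + nn) / (nt * nn) + g * g / (2.0 * (nt + nn))
    p = 2.0 * stats.norm.sf(abs(g) / np.sqrt(var_g))
    return EffectRecord(cohort_id, float(g), float(var_g), nt, nn, float(p))


def hedges_g_matrix(
    tumor: np.ndarray, normal: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Hedges' g for a genes x samples split into two arms.

    ``tumor``/``normal`` are (G, n_t) and (G, n_n) arrays. Genes with zero
    pooled variance yield NaN. Returns (g, var_g, p) arrays of length G.
    """
    nt, nn = tumor.shape[1], normal.shape[1]
    if nt < 2 or nn < 2:
        raise ValueError("need at least 2 samples per arm")
    df = nt + nn - 2
    sp2 = ((nt - 1) * tumor.var(axis=1, ddof=1) + (nn - 1) * normal.var(axis=1, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (tumor.mean(axis=1) - normal.mean(axis=1)) / np.sqrt(sp2)
    d = np.where(sp2 > 0, d, np.nan)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    var_g = (nt + nn) / (nt * nn) + g * g / (2.0 * (nt + nn))
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(g) / np.sqrt(var_g))
    return g, var_g, p


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValueError("no effect records to pool")
    g = np.array([r.g for r in records], dtype=float)
    v = np.array([r.var_g for r in records], dtype=float)
    if (v <= 0).any():
        raise ValueError("non-positive sampling variance")
    return g, v


def _summary(g, v, w, k, Q, tau2, model) -> MetaSummary:
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if (k > 1 and Q > 0) else 0.0
    p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    return MetaSummary(
        k=k,
        model=model,
        pooled=pooled,
        ci95=(pooled - Z95 * se, pooled + Z95 * se),
        Q=float(Q),
        I2=min(I2, 100.0),
        tau2=float(tau2),
        p_pooled=p,
        se=se,
    )


def pool_fixed(records) -> MetaSummary:
    """Inverse-variance fixed-effect pooling; Q = sum w (g - pooled)^2."""
    g, v = _as_arrays(records)
    k = g.size
    w = 1.0 / v
    pooled = np.sum(w * g) / np.sum(w)
    Q = float(np.sum(w * (g - pooled) ** 2))
    return _summary(g, v, w, k, Q, 0.0, "fixed")


def pool_random_dl(records) -> MetaSummary:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights, then re-weighting by 1/(var + tau^2).
    """
    g, v = _as_arrays(records)
    k = g.size
    if k < 2:
        raise ValueError("k < 2: use pool_fixed for a single cohort")
    w = 1.0 / v
    pooled_f = np.sum(w * g) / np.sum(w)
    Q = float(np.sum(w * (g - pooled_f) ** 2))
    C = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    return _summary(g, v, w_star, k, Q, tau2, "random")


def pool_auto(records, i2_random_threshold: float = 50.0) -> MetaSummary:
    """Pool fixed first; switch to DerSimonian-Laird when I^2 exceeds the
    threshold (percent), mirroring the strong-heterogeneity rule."""
    fixed = pool_fixed(records)
    if fixed.k >= 2 and fixed.I2 > i2_random_threshold:
        return pool_random_dl(records)
    return fixed


def select_model(i2: float, i2_random_threshold: float = 50.0) -> str:
    return "random" if i2 > i2_random_threshold else "fixed"


def pool_dl_columns(
    g: np.ndarray, var: np.ndarray
) -> dict[str, np.ndarray]:
    """Column-wise DerSimonian-Laird pooling for a (k, G) effect matrix.

    NaN entries (gene absent / degenerate in a cohort) are excluded per
    column; columns with fewer than 2 usable cohorts yield NaN.
    """
    g = np.asarray(g, dtype=float)
    var = np.asarray(var, dtype=float)
    valid = np.isfinite(g) & np.isfinite(var) & (var > 0)
    k = valid.sum(axis=0)
    w = np.where(valid, 1.0 / np.where(valid, var, 1.0), 0.0)
    sw = w.sum(axis=0)
    g0 = np.where(valid, g, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_f = (w * g0).sum(axis=0) / sw
        Q = (w * (g0 - pooled_f) ** 2 * valid).sum(axis=0)
        C = sw - (w**2).sum(axis=0) / sw
        tau2 = np.maximum(0.0, (Q - (k - 1)) / np.where(C > 0, C, np.nan))
        tau2 = np.where(np.isfinite(tau2), tau2, 0.0)
        w_star = np.where(valid, 1.0 / (var + tau2[None, :]), 0.0)
        sw_star = w_star.sum(axis=0)
        pooled = (w_star * g0).sum(axis=0) / sw_star
        se = 1.0 / np.sqrt(sw_star)
        p = 2.0 * stats.norm.sf(np.abs(pooled / se))
        I2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / np.where(Q > 0, Q, 1.0)) * 100.0, 0.0)
    bad = k < 2
    for arr in (pooled, se, p, tau2, Q, I2):
        arr[bad] = np.nan
    return {"k": k, "pooled": pooled, "se": se, "p": p, "tau2": tau2, "Q": Q, "I2": I2}


# ---------------------------------------------------------------------------
# publication bias
# ---------------------------------------------------------------------------

def egger_test(records) -> tuple[float, float]:
    """Egger regression asymmetry test.

    OLS of the standard normal deviate g/SE on precision 1/SE; returns the
    intercept and its two-sided t-test p-value (df = k - 2).
    """
    g, v = _as_arrays(records)
    if g.size < 3:
        raise ValueError("insufficient studies for Egger's test (k >= 3)")
    se = np.sqrt(v)
    y = g / se
    X = sm.add_constant(1.0 / se)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[0]), float(fit.pvalues[0])


def kendall_bias_correlation(deviates, variances) -> tuple[float, float]:
    """Kendall's tau between bias deviates and sampling variances.

    Exact permutation p for k < 10 without ties; tie-corrected normal
    approximation otherwise.
    """
    t = np.asarray(deviates, dtype=float)
    v = np.asarray(variances, dtype=float)
    has_ties = len(np.unique(t)) < t.size or len(np.unique(v)) < v.size
    method = "exact" if (t.size < 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(t, v, method=method)
    tau = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return tau, p


def begg_test(records) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation test.

    Correlates variance-stabilized deviations from the fixed-effect pooled
    value, t_i = (g_i - pooled) / sqrt(var_i - 1/sum(w)), with var_g.
    """
    g, v = _as_arrays(records)
    if g.size < 3:
        raise ValueError("insufficient studies for Begg's test (k >= 3)")
    if np.allclose(v, v[0]):
        raise ValueError("Begg undefined: all sampling variances tied")
    w = 1.0 / v
    pooled = np.sum(w * g) / np.sum(w)
    denom = np.sqrt(np.maximum(v - 1.0 / np.sum(w), 1e-12))
    t = (g - pooled) / denom
    return kendall_bias_correlation(t, v)


def publication_bias(records, bias_p: float = 0.05) -> BiasResult:
    e_int, e_p = egger_test(records)
    b_tau, b_p = begg_test(records)
    return BiasResult(e_int, e_p, b_tau, b_p, significant=(e_p < bias_p or b_p < bias_p))


def funnel_data(records, summary: MetaSummary, n_grid: int = 50):
    """Plot-ready funnel tables: study points (g, SE) and pseudo-95% CI
    guide lines pooled +/- 1.96*SE over an SE grid from 0 to max observed."""
    g, v = _as_arrays(records)
    se = np.sqrt(v)
    points = pd.DataFrame(
        {"cohort_id": [r.cohort_id for r in records], "g": g, "se": se}
    )
    grid = np.linspace(0.0, float(se.max()) * 1.05 if se.size else 1.0, n_grid)
    guides = pd.DataFrame(
        {
            "se": grid,
            "lo": summary.pooled - Z95 * grid,
            "hi": summary.pooled + Z95 * grid,
        }
    )
    return points, guides
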