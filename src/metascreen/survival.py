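"""Expression-based survival analysis.

Kaplan-Meier curves and the log-rank test (delegated to lifelines), optimal
dichotomization by maximally selected rank statistics (Lausen-Schumacher
linear-rank form with log-rank scores), proportional-hazards fitting by
Newton maximization of the Breslow partial likelihood with Wald inference
and separation reporting, and inverse-variance fixed-effect pooling of
hazard ratios on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import SurvivalTable
from .meta import Z95

__all__ = [
    "km_estimate",
    "logrank_test",
    "maxstat_cutpoint",
    "cox_fit",
    "pool_hr",
    "CutpointResult",
    "CoxResult",
    "PooledHR",
    "HrRecord",
]


@dataclass
class CutpointResult:
    cutpoint: float
    max_stat: float  # standardized log-rank statistic at the cutpoint (signed)
    groups: pd.Series  # per-patient "high" / "low"


@dataclass
class CoxResult:
    scope: str  # "univariable" | "multivariable"
    table: pd.DataFrame  # term, coef, se, hr, ci_low, ci_high, p, estimable
    n: int
    n_events: int
    loglik: float
    dropped: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def hr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "hr"])


@dataclass
class HrRecord:
    label: str
    hr: float
    ci_low: float
    ci_high: float

    @property
    def log_hr(self) -> float:
        return float(np.log(self.hr))

    @property
    def se(self) -> float:
        # SE recovered from the reported 95% CI width on the log scale
        return float((np.log(self.ci_high) - np.log(self.ci_low)) / (2 * Z95))


@dataclass
class PooledHR:
    k: int
    pooled_hr: float
    ci95: tuple[float, float]
    Q: float
    I2: float
    p: float


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(table: SurvivalTable, group) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group, with at-risk counts."""
    group = np.asarray(group)
    if group.size != len(table):
        raise ValueError("group labels do not match the table (empty group?)")
    out: dict[str, pd.DataFrame] = {}
    for label in pd.unique(group):
        mask = group == label
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(table.time[mask], table.event[mask])
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        at_risk = [
            int((table.time[mask] >= t).sum()) for t in df["time"]
        ]
        df["at_risk"] = at_risk
        out[str(label)] = df
    return out


def logrank_test(table: SurvivalTable, group) -> tuple[float, float]:
    """Two-sample log-rank test (O-E with hypergeometric variance summed
    over event times); returns (chi2, p) with 1 df."""
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError("log-rank test needs exactly 2 non-empty groups")
    if table.event.sum() == 0:
        raise ValueError("no events observed")
    m = group == labels[0]
    res = _ll_logrank(
        table.time[m], table.time[~m], event_observed_A=table.event[m],
        event_observed_B=table.event[~m],
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------

def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Savage-type) scores a_i = event_i - NelsonAalen(t_i)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    uniq, first = np.unique(t_sorted, return_index=True)
    n = time.size
    # at-risk count just before each unique time, events at each unique time
    at_risk = n - first
    d = np.array([event[order][t_sorted == u].sum() for u in uniq], dtype=float)
    cumhaz = np.cumsum(d / at_risk)
    idx = np.searchsorted(uniq, time)
    return event - cumhaz[idx]


def maxstat_cutpoint(
    table: SurvivalTable, expression, minprop: float = 0.10
) -> CutpointResult:
    """Optimal survival dichotomization by maximally selected rank statistics.

    Candidate cutpoints are the unique expression values whose induced
    high (x > c) / low (x <= c) split leaves at least ``minprop`` of
    patients in each group; for each candidate the standardized linear rank
    statistic with log-rank scores is computed and the |statistic| argmax is
    returned (ties: smaller cutpoint).
    """
    x = np.asarray(expression, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 subjects for cutpoint selection")
    if np.ptp(x) == 0:
        raise ValueError("constant expression: no cutpoint exists")
    a = logrank_scores(table.time, table.event)
    a_var = np.sum((a - a.mean()) ** 2)
    if a_var == 0:
        raise ValueError("no events: rank statistic degenerate")
    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    a_sorted = a[order]
    # split after position i (0-based): low = first i+1, high = rest
    csum = np.cumsum(a_sorted)
    total = csum[-1]
    uniq_last = np.nonzero(np.diff(x_sorted) > 0)[0]  # last index of each unique value
    n_low = uniq_last + 1
    n_high = n - n_low
    ok = (n_low >= minprop * n) & (n_high >= minprop * n)
    if not ok.any():
        raise ValueError("no candidate cutpoint respects minprop")
    n_low, n_high, split_idx = n_low[ok], n_high[ok], uniq_last[ok]
    S_high = total - csum[split_idx]
    mean_a = a.mean()
    E = n_high * mean_a
    V = n_high * n_low / (n * (n - 1.0)) * a_var
    z = (S_high - E) / np.sqrt(V)
    best = int(np.argmax(np.abs(z)))  # first maximum -> smallest cutpoint
    cut = float(x_sorted[split_idx[best]])
    groups = pd.Series(np.where(x > cut, "high", "low"), index=table.data.index)
    return CutpointResult(cutpoint=cut, max_stat=float(z[best]), groups=groups)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

def _design_matrix(
    table: SurvivalTable, covariates
) -> tuple[np.ndarray, list[str], list[str]]:
    cols, names, dropped = [], [], []
    for cov in covariates:
        if cov not in table.data.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        col = table.data[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                warnings.warn(f"covariate {cov!r} is constant; excluded")
                dropped.append(cov)
                continue
            for lev in levels[1:]:  # first sorted level is the reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
        else:
            arr = col.to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                warnings.warn(f"covariate {cov!r} is constant; excluded")
                dropped.append(cov)
                continue
            cols.append(arr)
            names.append(cov)
    if not cols:
        raise ValueError("no usable covariates after exclusions")
    return np.column_stack(cols), names, dropped


def breslow_loglik(
    beta: np.ndarray, time: np.ndarray, event: np.ndarray, X: np.ndarray
) -> float:
    """Breslow partial log-likelihood (reference evaluation; also used by
    the grid-search tests)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d_mask = (time == t) & (event == 1)
        ll += eta[d_mask].sum() - d_mask.sum() * np.log(np.exp(eta[at_risk]).sum())
    return float(ll)


def _cox_newton(time, event, X, max_iter=100, tol=1e-8):
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending time
    t_s, e_s, X_s = time[order], event[order], X[order]
    beta = np.zeros(p)
    ll_prev = -np.inf
    for it in range(max_iter):
        eta = X_s @ beta
        eta = np.clip(eta, -500, 500)
        r = np.exp(eta)
        # cumulative risk-set sums in descending-time order; ties share sums
        S0 = np.cumsum(r)
        S1 = np.cumsum(X_s * r[:, None], axis=0)
        S2 = np.cumsum(r[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)
        # index of the last subject with time >= t_i (ties included)
        last_idx = np.searchsorted(-t_s, -t_s, side="right") - 1
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        ev = np.nonzero(e_s)[0]
        # group events by unique time (Breslow: one denominator per time)
        uniq_t, inv = np.unique(-t_s[ev], return_inverse=True)
        for j in range(uniq_t.size):
            members = ev[inv == j]
            li = last_idx[members[0]]
            d = members.size
            s0, s1, s2 = S0[li], S1[li], S2[li]
            xbar = s1 / s0
            ll += eta[members].sum() - d * np.log(s0)
            grad += X_s[members].sum(axis=0) - d * xbar
            hess -= d * (s2 / s0 - np.outer(xbar, xbar))
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular Hessian in Cox fit (collinear covariates?)")
        # step-halving to keep the likelihood increasing
        new_beta = beta + step
        new_ll = breslow_loglik(new_beta, t_s, e_s, X_s)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = breslow_loglik(new_beta, t_s, e_s, X_s)
            halvings += 1
        beta = new_beta
        ll_prev = ll
        if np.max(np.abs(beta)) > 20.0:
            # monotone likelihood: a coefficient is running to +/- infinity
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(grad):.3g}, beta = {beta})"
        )
    cov = np.linalg.pinv(-hess)
    return beta, cov, float(ll)


def cox_fit(table: SurvivalTable, covariates, scope: str = "univariable") -> CoxResult:
    """Proportional-hazards fit by Newton maximization of the Breslow
    partial likelihood.

    Categorical covariates are expanded against their first sorted level;
    constant covariates are excluded with a warning. Monotone-likelihood
    (separation) terms are reported as non-estimable (HR = NaN) instead of
    a spurious huge hazard ratio.
    """
    if np.sum(table.event) == 0:
        raise ValueError("no events: Cox model is not identifiable")
    X, names, dropped = _design_matrix(table, list(covariates))
    beta, cov, ll = _cox_newton(table.time, table.event, X)
    se = np.sqrt(np.diag(cov))
    rows = []
    for j, name in enumerate(names):
        estimable = bool(abs(beta[j]) < 15.0 and se[j] < 100.0)
        hr = float(np.exp(beta[j])) if estimable else np.nan
        lo = float(np.exp(beta[j] - Z95 * se[j])) if estimable else np.nan
        hi = float(np.exp(beta[j] + Z95 * se[j])) if estimable else np.nan
        p = float(2 * stats.norm.sf(abs(beta[j] / se[j]))) if estimable else np.nan
        rows.append(
            {
                "term": name,
                "coef": float(beta[j]),
                "se": float(se[j]),
                "hr": hr,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
                "estimable": estimable,
            }
        )
    return CoxResult(
        scope=scope,
        table=pd.DataFrame(rows),
        n=len(table),
        n_events=int(np.sum(table.event)),
        loglik=ll,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# hazard-ratio pooling
# ---------------------------------------------------------------------------

def pool_hr(records) -> PooledHR:
    """Inverse-variance fixed-effect pooling of hazard ratios on the log
    scale; study SEs are recovered from the reported 95% CIs."""
    records = list(records)
    if not records:
        raise ValueError("no hazard-ratio records")
    for r in records:
        if r.ci_low >= r.ci_high:
            raise ValueError(f"invalid CI for {r.label}: lo >= hi")
        if r.hr <= 0 or r.ci_low <= 0:
            raise ValueError(f"hazard ratios must be positive ({r.label})")
    y = np.array([r.log_hr for r in records])
    se = np.array([r.se for r in records])
    w = 1.0 / se**2
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    Q = float(np.sum(w * (y - pooled) ** 2))
    k = len(records)
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if (k > 1 and Q > 0) else 0.0
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    return PooledHR(
        k=k,
        pooled_hr=float(np.exp(pooled)),
        ci95=(float(np.exp(pooled - Z95 * pooled_se)), float(np.exp(pooled + Z95 * pooled_se))),
        Q=Q,
        I2=min(I2, 100.0),
        p=p,
    )
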