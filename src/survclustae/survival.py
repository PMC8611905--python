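"""Survival statistics: univariate Cox models for bottleneck-feature
filtering, pairwise log-rank tests between clusters, Kaplan-Meier curves and
median-split prognostic validation.

The univariate Cox fit maximises the Breslow partial likelihood with a
step-capped Newton iteration and reports the *score* (log-rank) test P-value
of the single-covariate model.  Near-separated covariates can drive |beta|
arbitrarily large; the iteration caps each step and flags non-convergence
instead of silently emitting unbounded hazard ratios.  Log-rank and
Kaplan-Meier machinery is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, pairwise_logrank_test
from scipy import stats

from .io import SurvivalTable
from .losses import SurvivalOrder

_MAX_NEWTON_ITER = 50
_NEWTON_STEP_CAP = 1.0
_NEWTON_TOL = 1e-9
_BETA_BOUND = 50.0  # |beta| beyond this is treated as separation


@dataclass
class CoxFit:
    beta: float
    hazard_ratio: float
    p_value: float
    converged: bool
    se: float = float("nan")

    def ci95(self) -> tuple[float, float]:
        """95% Wald confidence interval for beta."""
        half = 1.959963984540054 * self.se
        return (self.beta - half, self.beta + half)


def _partial_likelihood_parts(beta: float, x: np.ndarray, order: SurvivalOrder):
    """Log-likelihood, score U and information I of the univariate Breslow
    partial likelihood, evaluated over descending-time prefix risk sets."""
    eta = beta * x
    m = eta.max()
    w = np.exp(eta - m)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    cwx2 = np.cumsum(w * x * x)
    stop = order.risk_stop - 1
    S0, S1, S2 = cw[stop], cwx[stop], cwx2[stop]
    delta = order.event.astype(float)
    ll = float((delta * (eta - (np.log(S0) + m))).sum())
    xbar = S1 / S0
    U = float((delta * (x - xbar)).sum())
    I = float((delta * (S2 / S0 - xbar ** 2)).sum())
    return ll, U, I


def cox_univariate(x: np.ndarray, surv: SurvivalTable) -> CoxFit:
    """Fit exp(beta * x) hazards by Newton's method on the Breslow partial
    likelihood; P-value is from the score test at beta = 0."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    if surv.event.sum() == 0:
        raise ValueError("no events: the partial likelihood is empty")
    if np.ptp(x) == 0.0:
        return CoxFit(float("nan"), float("nan"), 1.0, converged=False)

    order = SurvivalOrder.from_survival(surv.time, surv.event)
    xs = x[order.permutation]
    # score test at beta = 0 (identical to the log-rank test for group labels)
    _, U0, I0 = _partial_likelihood_parts(0.0, xs, order)
    if I0 <= 0.0:
        return CoxFit(float("nan"), float("nan"), 1.0, converged=False)
    p_score = float(stats.chi2.sf(U0 * U0 / I0, df=1))

    beta, converged = 0.0, False
    for _ in range(_MAX_NEWTON_ITER):
        _, U, I = _partial_likelihood_parts(beta, xs, order)
        if I <= 0.0:
            break
        step = np.clip(U / I, -_NEWTON_STEP_CAP, _NEWTON_STEP_CAP)
        beta += step
        if abs(step) < _NEWTON_TOL:
            converged = True
            break
        if abs(beta) > _BETA_BOUND:  # separation: likelihood is monotone
            break
    _, _, I_hat = _partial_likelihood_parts(beta, xs, order)
    se = float(1.0 / np.sqrt(I_hat)) if (converged and I_hat > 0) else float("nan")
    return CoxFit(beta=float(beta), hazard_ratio=float(np.exp(beta)),
                  p_value=p_score, converged=converged, se=se)


def filter_bottleneck(b: np.ndarray, surv: SurvivalTable, alpha: float = 0.05
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep bottleneck columns whose univariate Cox model is significant at
    ``alpha`` (score test); returns (kept column indices, per-feature table)."""
    b = np.asarray(b, dtype=float)
    rows = []
    for j in range(b.shape[1]):
        fit = cox_univariate(b[:, j], surv)
        rows.append({"feature": j, "beta": fit.beta, "hazard_ratio": fit.hazard_ratio,
                     "p_value": fit.p_value, "converged": fit.converged})
    table = pd.DataFrame(rows)
    kept = table.index[table["p_value"] < alpha].to_numpy()
    if kept.size == 0:
        raise ValueError("no bottleneck feature passed the Cox filter; inspect the "
                         "per-feature table (expected on the order of 10-20 survivors)")
    return kept, table


def pairwise_logrank(surv: SurvivalTable, labels: np.ndarray) -> pd.DataFrame:
    """Two-sided log-rank chi-square P-value for every pair of groups,
    returned as a symmetric DataFrame indexed by group label."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two non-empty groups")
    res = pairwise_logrank_test(surv.time, labels, surv.event)
    out = pd.DataFrame(np.ones((uniq.size, uniq.size)), index=uniq, columns=uniq)
    for (g1, g2), p in res.summary["p"].items():
        out.loc[g1, g2] = out.loc[g2, g1] = p
    np.fill_diagonal(out.values, np.nan)
    return out


def min_pairwise_logrank_p(surv: SurvivalTable, labels: np.ndarray) -> float:
    """Smallest pairwise log-rank P (the single P for two groups)."""
    table = pairwise_logrank(surv, labels)
    return float(np.nanmin(table.to_numpy()))


@dataclass
class KMCurve:
    times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival_prob": self.survival_prob,
                             "at_risk": self.at_risk})


def km_curve(surv: SurvivalTable, mask: np.ndarray | None = None) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate for the masked subset."""
    if mask is None:
        mask = np.ones(len(surv.sample_ids), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time[mask], surv.event[mask])
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    probs = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return KMCurve(times, probs, at_risk)


def median_split_test(values: np.ndarray, surv: SurvivalTable
                      ) -> tuple[np.ndarray | None, float]:
    """Split samples at the median (low: value <= median, high: value >
    median) and log-rank test the two groups.  If the high group is empty
    (all values at or below the median) the result is (None, nan)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    med = np.median(values)
    high = values > med
    if not high.any() or high.all():
        return None, float("nan")
    res = logrank_test(surv.time[~high], surv.time[high],
                       surv.event[~high], surv.event[high])
    return high.astype(int), float(res.p_value)
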