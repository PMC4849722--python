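"""Two-group survival primitives used by the expression screening.

Implements the standard two-sample log-rank test and a univariate Cox
proportional-hazards fit for a single binary covariate with the Breslow
approximation for tied event times.  Both are written directly on sorted
risk-set sums, which makes screening thousands of candidate cutoffs cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def _validate(time: np.ndarray, event: np.ndarray, group: np.ndarray):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if time.shape != event.shape or time.shape != group.shape:
        raise ValueError("time, event and group must have equal length")
    if (time < 0).any():
        raise ValueError("times must be non-negative")
    if not np.isin(event, (0, 1)).all() or not np.isin(group, (0, 1)).all():
        raise ValueError("event and group must be 0/1")
    return time, event, group


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Vectorised over distinct event times (risk-set counts via sorted
    suffix sums), so screening many candidate cutoffs stays cheap.
    """
    time, event, group = _validate(time, event, group)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted, g_sorted = time[order], event[order], group[order]

    event_times, inverse = np.unique(t_sorted[e_sorted == 1], return_inverse=True)
    if event_times.size == 0:
        return 0.0, 1.0
    d = np.bincount(inverse)
    d1 = np.bincount(inverse, weights=g_sorted[e_sorted == 1])
    # subjects with time >= t form a suffix of the sorted arrays
    start = np.searchsorted(t_sorted, event_times, side="left")
    n_total = t_sorted.size
    suffix_g = np.concatenate([np.cumsum(g_sorted[::-1])[::-1], [0.0]])
    n_at_risk = n_total - start
    n1_at_risk = suffix_g[start]

    frac = n1_at_risk / n_at_risk
    obs_minus_exp = float(np.sum(d1 - d * frac))
    ok = n_at_risk > 1
    variance = float(
        np.sum(
            d[ok]
            * frac[ok]
            * (1 - frac[ok])
            * (n_at_risk[ok] - d[ok])
            / (n_at_risk[ok] - 1)
        )
    )
    if variance <= 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxFit:
    beta: float
    se: float
    p: float
    converged: bool
    n_events: int

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))


def cox_binary_fit(time, event, group, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Univariate Cox PH with a single 0/1 covariate, Breslow ties.

    Newton-Raphson on the partial log-likelihood
    ``l(beta) = beta * sum_{events} x_i - sum_j d_j log(sum_{risk_j} e^{beta x})``.
    A negative beta means the group-1 (high-expression) arm has lower
    hazard.  Monotone likelihoods (a group with no events sharing risk
    sets) are reported non-converged.
    """
    time, event, group = _validate(time, event, group)
    n_events = int(event.sum())
    if n_events == 0 or group.min() == group.max():
        return CoxFit(np.nan, np.nan, np.nan, converged=False, n_events=n_events)

    order = np.argsort(-time, kind="stable")  # decreasing time for suffix sums
    t_sorted = time[order]
    e_sorted = event[order]
    x_sorted = group[order]

    event_times, inverse = np.unique(time[event == 1], return_inverse=True)
    d = np.bincount(inverse)  # deaths per distinct event time
    s = np.bincount(inverse, weights=group[event == 1])  # group-1 deaths

    def risk_sums(beta: float) -> tuple[np.ndarray, np.ndarray]:
        w = np.exp(beta * x_sorted)
        cw = np.cumsum(w)
        cwx = np.cumsum(w * x_sorted)
        # for each event time, risk set = subjects with time >= t
        idx = np.searchsorted(-t_sorted, -event_times, side="right") - 1
        return cw[idx], cwx[idx]

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        sw, swx = risk_sums(beta)
        mean = swx / sw
        score = float(np.sum(s - d * mean))
        # Breslow information: sum_j d_j * Var_j(x); x binary => E[x^2]=E[x]
        info = float(np.sum(d * mean * (1 - mean)))
        if info <= 0:
            break
        step = score / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            converged = True
            break
    if not converged or abs(beta) > 20:
        return CoxFit(float(beta), np.nan, np.nan, converged=False, n_events=n_events)
    sw, swx = risk_sums(beta)
    mean = swx / sw
    info = float(np.sum(d * mean * (1 - mean)))
    se = float(np.sqrt(1.0 / info))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return CoxFit(float(beta), se, p, converged=True, n_events=n_events)
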